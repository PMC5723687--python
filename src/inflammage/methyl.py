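"""Methylation-expression integration for delta-age.

Stages: an epigenome-wide scan of CpG beta-values on delta-age (same mixed
model as the expression scan); calling differentially methylated genes
(DMGs) among a gene list, with the gene-level cutoff 0.05/N where N is the
total number of CpG sites mapped to the tested genes; a permutation null for
the DMG count of random same-size gene sets; and a CpG-adjusted attenuation
analysis refitting each DMG's expression model with its most significant
CpG as an added covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd

from . import assoc
from .synthcohort import FeatureMatrix


@dataclass
class DMGCall:
    gene: str
    n_cpgs: int
    min_p: float
    cutoff: float
    is_dmg: bool
    top_cpg: Optional[str]
    direction: float  # sign of the top CpG's beta


@dataclass
class PermutationResult:
    observed: int
    n_perm: int
    null_counts: np.ndarray
    seed: int

    @property
    def null_mean(self) -> float:
        return float(self.null_counts.mean())

    @property
    def null_min(self) -> int:
        return int(self.null_counts.min())

    @property
    def null_max(self) -> int:
        return int(self.null_counts.max())

    @property
    def empirical_p(self) -> float:
        exceed = int(np.sum(self.null_counts >= self.observed))
        return (1 + exceed) / (self.n_perm + 1)

    def format_p(self) -> str:
        exceed = int(np.sum(self.null_counts >= self.observed))
        if exceed == 0:
            return f"<{1.0 / self.n_perm:.0e}"
        return f"{self.empirical_p:.3g}"


@dataclass
class AttenuationResult:
    gene: str
    beta_before: float
    beta_after: float
    attenuated: bool
    indeterminate: bool = False


def ewas_scan(
    meth: FeatureMatrix,
    delta_age,
    cohort: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    family_col: Optional[str] = "family_id",
    **kwargs,
) -> tuple[pd.DataFrame, assoc.ScanSummary]:
    """CpG-wise delta-age scan; identical contract to the expression scan."""
    return assoc.run_scan(
        meth, delta_age, cohort, covariate_names, family_col=family_col, **kwargs
    )


def call_dmgs(
    ewas_results: pd.DataFrame,
    cpg_map: pd.DataFrame,
    gene_list: Iterable[str],
) -> list[DMGCall]:
    """Call DMGs among ``gene_list``.

    N is the number of tested CpG sites mapped to genes in the list; a gene
    is a DMG iff any of its CpGs has p < 0.05/N.  The most significant CpG
    (ties: smallest p, then lexicographic id) is recorded per gene.  Genes
    with no mapped CpGs contribute 0 to N and are never DMGs.
    """
    if cpg_map.empty:
        raise ValueError("empty CpG map")
    genes = list(dict.fromkeys(gene_list))
    cmap = cpg_map.set_index("cpg_id")["gene_symbol"]
    res = ewas_results.set_index("feature")
    tested = res.index.intersection(cmap.index)
    gene_of = cmap.loc[tested]
    in_list = gene_of[gene_of.isin(genes)]
    n_total = int(len(in_list))
    if n_total == 0:
        raise ValueError("no tested CpGs map to the gene list")
    cutoff = 0.05 / n_total

    by_gene: Dict[str, list] = {}
    for cpg, gene in in_list.items():
        by_gene.setdefault(gene, []).append(cpg)

    calls = []
    for gene in genes:
        cpgs = sorted(by_gene.get(gene, []))
        if not cpgs:
            calls.append(DMGCall(gene, 0, np.nan, cutoff, False, None, 0.0))
            continue
        sub = res.loc[cpgs]
        order = sub.assign(_id=sub.index).sort_values(["p", "_id"], kind="stable")
        top = order.iloc[0]
        calls.append(
            DMGCall(
                gene=gene,
                n_cpgs=len(cpgs),
                min_p=float(top["p"]),
                cutoff=cutoff,
                is_dmg=bool(top["p"] < cutoff),
                top_cpg=str(order.index[0]),
                direction=float(np.sign(top["beta"])),
            )
        )
    return calls


def permutation_enrichment(
    universe: Sequence[str],
    dmg_genes: Iterable[str],
    observed: int,
    set_size: int,
    n_perm: int,
    seed: int,
    batch: int = 5000,
) -> PermutationResult:
    """Empirical enrichment p for an observed DMG count.

    Null: ``n_perm`` uniform random subsets of ``set_size`` genes drawn
    without replacement from ``universe``; the per-subset DMG count forms the
    null.  Empirical p = (1 + #{null >= observed}) / (n_perm + 1), never 0.
    """
    universe = list(universe)
    n = len(universe)
    if set_size > n:
        raise ValueError(f"set_size {set_size} exceeds universe size {n}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    dmg = set(dmg_genes)
    is_dmg = np.fromiter((g in dmg for g in universe), dtype=bool, count=n)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        counts[done : done + b] = is_dmg[idx].sum(axis=1)
        done += b
    return PermutationResult(observed=int(observed), n_perm=n_perm,
                             null_counts=counts, seed=seed)


def attenuation_analysis(
    expr: FeatureMatrix,
    meth: FeatureMatrix,
    dmg_calls: Sequence[DMGCall],
    delta_age,
    cohort: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    family_col: Optional[str] = "family_id",
    scan_results: Optional[pd.DataFrame] = None,
) -> list[AttenuationResult]:
    """Refit each DMG's expression model adding its top CpG as a covariate.

    ``beta_before`` is the gene's delta-age effect from the original model
    (taken from ``scan_results`` when supplied, else refit); ``beta_after``
    adds the gene's most significant CpG beta-values to the covariates.
    Attenuated iff |after| < |before|.  A constant CpG column makes the gene
    indeterminate (refit without it).
    """
    subjects = expr.subject_ids.intersection(meth.subject_ids)
    subjects = subjects.intersection(pd.Index(cohort["subject_id"]))
    cohort_sub = cohort.set_index("subject_id").loc[subjects].reset_index()
    if isinstance(delta_age, pd.Series):
        da = delta_age.reindex(subjects).to_numpy(dtype=float)
    else:
        da = pd.Series(np.asarray(delta_age, dtype=float),
                       index=cohort["subject_id"]).reindex(subjects).to_numpy()

    grouping = None
    if family_col is not None and family_col in cohort_sub.columns:
        grouping = assoc.KinshipEigen.from_families(cohort_sub[family_col].to_numpy())

    cov_df = cohort_sub[list(covariate_names)].reset_index(drop=True) if covariate_names else pd.DataFrame(index=range(len(subjects)))
    before_lookup = None
    if scan_results is not None:
        before_lookup = scan_results.drop_duplicates("feature").set_index("feature")["beta"]

    out = []
    for call in dmg_calls:
        if not call.is_dmg or call.top_cpg is None:
            continue
        gene = call.gene
        if gene not in expr.values.index or call.top_cpg not in meth.values.index:
            continue
        y = expr.values.loc[gene, subjects].to_numpy(dtype=float)
        cpg = meth.values.loc[call.top_cpg, subjects].to_numpy(dtype=float)

        if before_lookup is not None and gene in before_lookup.index:
            beta_before = float(before_lookup.loc[gene])
        else:
            beta_before = assoc.fit_feature_lmm(y, da, cov_df if len(cov_df.columns) else None,
                                                grouping, feature=gene).beta
        if np.ptp(cpg) == 0:
            out.append(AttenuationResult(gene, beta_before, beta_before,
                                         attenuated=False, indeterminate=True))
            continue
        cov_after = cov_df.copy()
        cov_after["_top_cpg"] = cpg
        beta_after = assoc.fit_feature_lmm(y, da, cov_after, grouping, feature=gene).beta
        out.append(
            AttenuationResult(gene, beta_before, float(beta_after),
                              attenuated=bool(abs(beta_after) < abs(beta_before)))
        )
    return out


def attenuated_fraction(results: Sequence[AttenuationResult]) -> float:
    usable = [r for r in results if not r.indeterminate]
    if not usable:
        return float("nan")
    return sum(r.attenuated for r in usable) / len(usable)
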