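"""Synthetic cohort generator.

Emulates the statistical structure of a family-based cohort of older adults
with an inflammatory-biomarker panel, whole-blood expression, 450K-style
methylation beta-values, a PPI network, gene sets and mortality follow-up,
so that every downstream analysis stage is testable offline against known
ground truth.

Data model
----------
Each subject has chronological age CA ~ Uniform(age_range) and a latent
biologic-age offset delta ~ N(0, delta_sd^2), independent of CA; the latent
biologic age is ``BA_true = CA + delta``.  Biomarkers are affine in BA_true
plus Gaussian noise, with noise variances solved so population biomarker-age
correlations equal their targets.  Expression of a "true" gene loads on
delta; CpGs of mediated genes carry part of that delta signal.  Mortality is
exponential with hazard proportional to exp(log-HR x standardized true
expression score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .config import BIOMARKERS, SURVIVAL_COVARIATES, SimConfig


class InfeasibleCorrelationError(ValueError):
    """Raised when target biomarker correlations imply a non-PSD covariance."""


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic cohort, for oracle tests."""

    true_gene_ids: Set[str]
    true_effects: Dict[str, float]  # gene -> signed effect (expr units / year)
    mediated_gene_ids: Set[str]
    mediator_cpg: Dict[str, str]  # mediated gene -> its signal-carrying CpG
    true_ba: np.ndarray  # per-subject latent biologic age, years
    delta: np.ndarray  # per-subject latent offset, years
    score_log_hr: float
    biomarker_slopes: np.ndarray = field(default=None)
    biomarker_intercepts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not self.mediated_gene_ids <= self.true_gene_ids:
            raise ValueError("mediated genes must be a subset of true genes")


@dataclass
class FeatureMatrix:
    """Features x subjects matrix with a feature -> gene-symbol annotation."""

    values: pd.DataFrame  # index: feature ids, columns: subject ids
    gene_map: pd.Series  # feature id -> gene symbol

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        self.gene_map = self.gene_map.reindex(self.values.index)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.columns


def _rng_streams(seed: int, names: Tuple[str, ...]) -> Dict[str, np.random.Generator]:
    """One root seed, deterministic named sub-streams per data type."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


_STREAMS = (
    "cohort",
    "expression",
    "methylation",
    "network",
    "genesets",
    "survival",
)

# Marker means/SDs loosely matching the observed distributions of the nine
# inflammatory biomarkers (native assay units).
_MARKER_MEAN = np.array([2.2, 285.0, 2.1, 200.0, 137.0, 375.0, 4.8, 40.0, 2450.0])
_MARKER_SD = np.array([2.0, 80.0, 1.5, 45.0, 34.0, 105.0, 1.4, 11.0, 820.0])

GENE_FMT = "G{:04d}"
CPG_FMT = "cg{:07d}"


def _biomarker_params(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Solve slopes and noise SDs so population corr(x_j, CA) hits targets.

    With CA ~ U(lo, hi) (variance V_C) and BA_true = CA + delta
    (variance V_B = V_C + delta_sd^2), a marker x = q + k*BA_true + e with
    noise variance s^2 has corr(x, CA) = k*sqrt(V_C)/sd(x).  Fixing the
    marker's total SD and target correlation determines k and s^2; s^2 < 0
    flags an infeasible target.
    """
    lo, hi = config.age_range
    v_c = (hi - lo) ** 2 / 12.0
    v_b = v_c + config.delta_sd**2
    m = config.n_biomarkers
    sd = _MARKER_SD[:m] if m <= len(_MARKER_SD) else np.resize(_MARKER_SD, m)
    r = np.asarray(config.biomarker_age_r, dtype=float)
    k = r * sd / np.sqrt(v_c)
    s2 = sd**2 - k**2 * v_b
    bad = np.flatnonzero(s2 <= 0)
    if bad.size:
        j = int(bad[0])
        raise InfeasibleCorrelationError(
            f"biomarker {j} ({BIOMARKERS[j] if j < len(BIOMARKERS) else j}): target "
            f"age correlation {r[j]:.3f} implies negative noise variance "
            f"(needs |r| < {np.sqrt(v_c / v_b):.3f} at these settings)"
        )
    # Extra shared factor for the designated high-correlation pair, carved out
    # of the pair's noise budget so total variances are unchanged.
    i, j = config.high_pair
    c2 = config.high_pair_r - k[i] * k[j] * v_b / (sd[i] * sd[j])
    if c2 < 0:
        raise InfeasibleCorrelationError(
            f"pair ({i},{j}): target r={config.high_pair_r} below the correlation "
            "already induced by the shared biologic-age factor"
        )
    a = np.sqrt(c2) * sd[[i, j]]
    if np.any(a**2 >= s2[[i, j]]):
        raise InfeasibleCorrelationError(
            f"pair ({i},{j}): target r={config.high_pair_r} exceeds the pair's "
            "available noise variance (non-positive-definite implied covariance)"
        )
    return k, np.sqrt(s2), a, v_c


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the phenotype table and its ground truth.

    Returns a subject table (subject_id, family_id, sex, age, nine biomarker
    columns, cell-count and technical covariates) and the :class:`SyntheticTruth`
    carrying the latent delta and biomarker generating parameters.
    """
    rng = _rng_streams(config.seed, _STREAMS)["cohort"]
    n = config.n_subjects
    lo, hi = config.age_range

    ca = rng.uniform(lo, hi, size=n)
    delta = rng.normal(0.0, config.delta_sd, size=n)
    # delta is by construction the age-orthogonal offset; remove the O(1/sqrt(n))
    # sampling correlation with CA so realized corr(delta, CA) = 0 exactly
    ca_c = ca - ca.mean()
    delta = delta - (delta @ ca_c) / (ca_c @ ca_c) * ca_c
    ba_true = ca + delta
    family = rng.integers(0, config.n_families, size=n)
    sex = rng.integers(0, 2, size=n)

    k, s, a_pair, _ = _biomarker_params(config)
    m = config.n_biomarkers
    mean = _MARKER_MEAN[:m] if m <= len(_MARKER_MEAN) else np.resize(_MARKER_MEAN, m)
    mean_ba = (lo + hi) / 2.0
    q = mean - k * mean_ba

    noise = rng.normal(size=(n, m)) * s
    shared = rng.normal(size=n)
    i, j = config.high_pair
    # Swap part of the pair's independent noise for a shared factor, keeping
    # each marker's total variance fixed.
    for idx, amp in zip((i, j), a_pair):
        resid_sd = np.sqrt(s[idx] ** 2 - amp**2)
        noise[:, idx] = amp * shared + rng.normal(0.0, resid_sd, size=n)
    x = q + k * ba_true[:, None] + noise

    names = list(BIOMARKERS[:m]) + [f"bm{j}" for j in range(len(BIOMARKERS), m)]
    pheno = pd.DataFrame(x, columns=names)
    pheno.insert(0, "age", ca)
    pheno.insert(0, "sex", sex)
    pheno.insert(0, "family_id", [f"F{f:05d}" for f in family])
    pheno.insert(0, "subject_id", [f"S{i:05d}" for i in range(n)])
    # Imputed-cell-count and technical covariates (given, not modeled).
    pheno["cell_neut"] = np.clip(rng.normal(0.6, 0.08, size=n), 0.2, 0.9)
    pheno["cell_lymph"] = np.clip(rng.normal(0.25, 0.06, size=n), 0.05, 0.6)
    pheno["tech_pc1"] = rng.normal(size=n)
    for name, prev in SURVIVAL_COVARIATES.items():
        pheno[name] = (rng.random(n) < prev).astype(int)

    genes = [GENE_FMT.format(i) for i in range(config.n_genes)]
    true_idx = rng.choice(config.n_genes, size=config.n_true_genes, replace=False)
    true_idx.sort()
    n_pos = int(round(config.frac_positive * config.n_true_genes))
    signs = np.array([1.0] * n_pos + [-1.0] * (config.n_true_genes - n_pos))
    rng.shuffle(signs)
    mags = config.effect_size_sd * rng.uniform(0.5, 1.5, size=config.n_true_genes)
    effects = {genes[i]: float(s_ * m_) for i, s_, m_ in zip(true_idx, signs, mags)}
    n_med = int(round(config.mediation_fraction * config.n_true_genes))
    med_ids = set(np.array(sorted(effects))[rng.choice(config.n_true_genes, n_med, replace=False)])

    truth = SyntheticTruth(
        true_gene_ids=set(effects),
        true_effects=effects,
        mediated_gene_ids=med_ids,
        mediator_cpg={},
        true_ba=ba_true,
        delta=delta,
        score_log_hr=config.score_log_hr,
        biomarker_slopes=k,
        biomarker_intercepts=q,
    )
    return pheno, truth


def generate_expression(
    cohort: pd.DataFrame, truth: SyntheticTruth, config: SimConfig
) -> FeatureMatrix:
    """Genes x subjects expression matrix (log2-like units).

    True genes load on the latent delta (the signed effect, per year); the
    mediated portion of a mediated gene's delta signal is routed through its
    mediator CpG's latent variable so that adjusting for the CpG attenuates
    the expression association.  All genes get sex/age/cell-count nuisance
    effects, a shared family intercept and i.i.d. noise.
    """
    n = len(cohort)
    if truth.delta.shape[0] != n:
        raise ValueError("cohort and truth dimensions do not match")
    rng = _rng_streams(config.seed, _STREAMS)["expression"]
    genes = [GENE_FMT.format(i) for i in range(config.n_genes)]

    base = rng.uniform(4.0, 12.0, size=config.n_genes)
    b_sex = rng.normal(0.0, 0.1, size=config.n_genes)
    b_age = rng.normal(0.0, 0.005, size=config.n_genes)
    b_cell = rng.normal(0.0, 0.3, size=config.n_genes)

    fam_codes, fam_idx = np.unique(cohort["family_id"].to_numpy(), return_inverse=True)
    fam_eff = rng.normal(0.0, config.family_sd, size=(config.n_genes, len(fam_codes)))

    delta = truth.delta
    # Latent CpG signal per mediated gene: delta (standardized) plus noise.
    med_latent = {}
    for g in sorted(truth.mediated_gene_ids):
        med_latent[g] = delta / config.delta_sd + config.cpg_noise_sd * rng.normal(size=n)
    truth._med_latent = med_latent  # shared with generate_methylation

    G = (
        base[:, None]
        + b_sex[:, None] * cohort["sex"].to_numpy()[None, :]
        + b_age[:, None] * cohort["age"].to_numpy()[None, :]
        + b_cell[:, None] * cohort["cell_neut"].to_numpy()[None, :]
        + fam_eff[:, fam_idx]
        + rng.normal(0.0, config.expr_noise_sd, size=(config.n_genes, n))
    )
    ms = config.mediation_strength
    for g, eff in truth.true_effects.items():
        i = int(g[1:])  # gene ids are positional: G0007 -> row 7
        if g in truth.mediated_gene_ids:
            G[i] += eff * ((1.0 - ms) * delta + ms * config.delta_sd * med_latent[g])
        else:
            G[i] += eff * delta

    values = pd.DataFrame(G, index=genes, columns=cohort["subject_id"].to_numpy())
    gene_map = pd.Series(genes, index=genes, name="gene")
    return FeatureMatrix(values=values, gene_map=gene_map)


def generate_methylation(
    cohort: pd.DataFrame, truth: SyntheticTruth, config: SimConfig
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """CpG beta-value matrix and CpG -> gene map.

    Each gene owns ``n_cpg_per_gene`` CpGs.  For a mediated gene, its first
    CpG's latent variable is the same delta-carrying latent injected into the
    gene's expression, so methylation and expression share a delta signal;
    all other CpG latents are pure noise.  Beta-values are a logistic squash
    of the latent, hence always in [0, 1].
    """
    n = len(cohort)
    if truth.delta.shape[0] != n:
        raise ValueError("cohort and truth dimensions do not match")
    rng = _rng_streams(config.seed, _STREAMS)["methylation"]
    med_latent = getattr(truth, "_med_latent", None)
    if med_latent is None:
        med_latent = {
            g: truth.delta / config.delta_sd + config.cpg_noise_sd * rng.normal(size=n)
            for g in sorted(truth.mediated_gene_ids)
        }

    genes = [GENE_FMT.format(i) for i in range(config.n_genes)]
    cpg_ids: List[str] = []
    cpg_gene: List[str] = []
    rows: List[np.ndarray] = []
    counter = 0
    ms = config.mediation_strength
    for gi, g in enumerate(genes):
        for k in range(config.n_cpg_per_gene):
            cid = CPG_FMT.format(counter)
            counter += 1
            if g in truth.mediated_gene_ids and k == 0:
                latent = ms * med_latent[g] + (1.0 - ms) * rng.normal(size=n)
                truth.mediator_cpg[g] = cid
            else:
                latent = rng.normal(size=n)
            mu = rng.uniform(-1.5, 1.5)
            beta = 1.0 / (1.0 + np.exp(-(mu + 0.8 * latent)))
            cpg_ids.append(cid)
            cpg_gene.append(g)
            rows.append(beta)

    values = pd.DataFrame(
        np.vstack(rows), index=cpg_ids, columns=cohort["subject_id"].to_numpy()
    )
    gene_map = pd.Series(cpg_gene, index=cpg_ids, name="gene")
    cpg_map = pd.DataFrame(
        {"cpg_id": cpg_ids, "gene_symbol": cpg_gene, "position": np.arange(len(cpg_ids))}
    )
    return FeatureMatrix(values=values, gene_map=gene_map), cpg_map


def generate_network(truth: SyntheticTruth, config: SimConfig):
    """Random PPI-like graph with a planted connected cluster of true genes.

    Background: G(n, p) with p set from ``net_mean_degree``.  Planted: the
    first ``planted_cluster_size`` true genes (by id order) are wired into a
    connected, dense subgraph (random spanning tree plus extra edges).
    Returns a :class:`networkx.Graph` whose nodes are gene symbols.
    """
    import networkx as nx

    rng = _rng_streams(config.seed, _STREAMS)["network"]
    n = config.n_genes
    genes = [GENE_FMT.format(i) for i in range(n)]
    cluster = sorted(truth.true_gene_ids)[: config.planted_cluster_size]
    if len(cluster) > n:
        raise ValueError("planted cluster larger than graph")

    p = min(1.0, config.net_mean_degree / max(n - 1, 1))
    G = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    G = nx.relabel_nodes(G, dict(enumerate(genes)))
    G.add_nodes_from(genes)

    # Spanning tree over the cluster, then densify to ~30% of possible edges.
    if len(cluster) >= 2:
        order = list(cluster)
        rng.shuffle(order)
        for a, b in zip(order, order[1:]):
            G.add_edge(a, b)
        want = int(0.3 * len(cluster) * (len(cluster) - 1) / 2)
        added = 0
        while added < want:
            a, b = rng.choice(len(cluster), size=2, replace=False)
            u, v = cluster[a], cluster[b]
            if not G.has_edge(u, v):
                G.add_edge(u, v)
                added += 1
    G.remove_edges_from(nx.selfloop_edges(G))
    return G


def generate_genesets(
    truth: SyntheticTruth, config: SimConfig
) -> dict[str, set[str]]:
    """Named gene sets; ``PLANTED_SET`` is enriched for true genes."""
    rng = _rng_streams(config.seed, _STREAMS)["genesets"]
    genes = np.array([GENE_FMT.format(i) for i in range(config.n_genes)])
    sets: dict[str, set[str]] = {}
    for s in range(config.n_gene_sets - 1):
        size = int(rng.integers(20, 120))
        sets[f"SET_{s:03d}"] = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
    true_list = sorted(truth.true_gene_ids)
    n_true_in = max(1, int(0.6 * len(true_list)))
    members = set(np.array(true_list)[rng.choice(len(true_list), n_true_in, replace=False)])
    fill = rng.choice(genes, size=n_true_in, replace=False)
    sets["PLANTED_SET"] = members | set(fill)
    return sets


def generate_survival(
    cohort: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimConfig,
    expression: FeatureMatrix | None = None,
) -> pd.DataFrame:
    """Append exponential survival (time, event) to the cohort table.

    Hazard = baseline_hazard * exp(score_log_hr * standardized true score),
    where the true score is the effect-weighted sum of true-gene expression
    (recomputed from the expression matrix when given, else from the latent
    delta signal).  Censoring: independent uniform dropout plus an
    administrative horizon; times are strictly positive.
    """
    rng = _rng_streams(config.seed, _STREAMS)["survival"]
    n = len(cohort)
    if expression is not None:
        sub = expression.values
        score = np.zeros(n)
        for g, eff in truth.true_effects.items():
            score += eff * sub.loc[g].to_numpy()
    else:
        score = truth.delta.copy()
    sd = score.std(ddof=0)
    z = (score - score.mean()) / sd if sd > 0 else np.zeros(n)

    hazard = config.baseline_hazard * np.exp(config.score_log_hr * z)
    t_event = rng.exponential(1.0 / hazard)
    dropout = rng.uniform(0.5 * config.censor_horizon, 1.2 * config.censor_horizon, size=n)
    censor = np.minimum(dropout, config.censor_horizon)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    time = np.maximum(time, 1e-6)

    out = cohort.copy()
    out["time"] = time
    out["event"] = event
    return out


def generate_all(config: SimConfig) -> dict:
    """Generate every synthetic input for the full pipeline in one call."""
    cohort, truth = generate_cohort(config)
    expr = generate_expression(cohort, truth, config)
    meth, cpg_map = generate_methylation(cohort, truth, config)
    network = generate_network(truth, config)
    genesets = generate_genesets(truth, config)
    cohort = generate_survival(cohort, truth, config, expression=expr)
    return {
        "cohort": cohort,
        "truth": truth,
        "expression": expr,
        "methylation": meth,
        "cpg_map": cpg_map,
        "network": network,
        "genesets": genesets,
    }
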