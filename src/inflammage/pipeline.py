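"""End-to-end pipeline driver.

Stage order mirrors the analysis: biologic age / delta-age, expression scan,
expression score + mortality, pathway enrichment + prior-list overlap, PPI
dense-module subnetwork, methylation integration.  Each stage writes its
table under the output directory; a machine-readable ``summary.json``
collects the headline counts and thresholds, and ``run.log`` records the
versions, seed and every analysis flag in effect.  Reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assoc, enrich, io, kdage, methyl, netmod, score, synthcohort
from .config import PipelineConfig


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(config: PipelineConfig) -> dict:
    """Load user inputs, falling back to the synthetic generator."""
    if config.pheno_path is None:
        sim = config.sim
        data = synthcohort.generate_all(sim)
        return data
    data = {"truth": None}
    data["cohort"] = io.read_pheno(config.pheno_path)
    data["expression"] = io.read_matrix(config.expression_path)
    data["methylation"] = (
        io.read_matrix(config.methylation_path) if config.methylation_path else None
    )
    data["cpg_map"] = io.read_cpg_map(config.cpg_map_path) if config.cpg_map_path else None
    data["genesets"] = io.read_gmt(config.gmt_path) if config.gmt_path else None
    data["network"] = io.read_edge_list(config.network_path) if config.network_path else None
    if data["methylation"] is not None and data["cpg_map"] is not None:
        gm = data["cpg_map"].set_index("cpg_id")["gene_symbol"]
        data["methylation"].gene_map = gm.reindex(data["methylation"].values.index)
    return data


def run_pipeline(config: PipelineConfig) -> dict:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "version": __version__}
    log_lines = [f"inflammage {__version__}", f"seed={config.seed}",
                 f"alpha_policy={config.alpha_policy}",
                 f"covariates={','.join(config.covariates)}",
                 f"n_seeds={config.n_seeds}", f"n_perm={config.n_perm}"]

    def stage(name):
        log_lines.append(f"stage:{name}")

    try:
        stage("inputs")
        data = _load_inputs(config)
        cohort = data["cohort"]
        for col in list(config.biomarkers) + ["age"]:
            if col not in cohort.columns:
                raise KeyError(f"phenotype table lacks required column {col!r}")
    except Exception as e:  # noqa: BLE001
        raise StageError("inputs", e) from e

    # --- biologic age / delta-age -------------------------------------------
    try:
        stage("kdage")
        model = kdage.fit_kd(cohort, config.biomarkers)
        est = kdage.estimate_ba(model, cohort)
        indep = kdage.check_delta_independence(est)
        ba = est.to_frame()
        ba.to_csv(out_dir / "ba.tsv", sep="\t", index=False, float_format="%.6g")
        (out_dir / "kd_model.txt").write_text(model.to_text())
        summary["kd"] = {
            "m": model.m,
            "r_char": round(model.r_char, 6),
            "s2_ba": round(model.s2_ba, 4),
            "delta_mean": round(float(np.mean(est.delta_age)), 4),
            "delta_sd": round(float(np.std(est.delta_age, ddof=1)), 4),
            "delta_ca_r": None if indep["degenerate"] else round(indep["r"], 4),
            "delta_ca_p": None if indep["degenerate"] else round(indep["p"], 4),
        }
        log_lines.append(f"kdage: s2_BA={model.s2_ba:.4g} r_char={model.r_char:.4g}")
    except Exception as e:  # noqa: BLE001
        raise StageError("kdage", e) from e

    # --- expression scan -----------------------------------------------------
    try:
        stage("assoc")
        delta = pd.Series(est.delta_age, index=est.subject_id)
        covs = [c for c in config.covariates if c in cohort.columns]
        results, scan_sum = assoc.run_scan(
            data["expression"], delta, cohort, covs, family_col=config.family_col
        )
        results.to_csv(out_dir / "scan.tsv", sep="\t", index=False, float_format="%.6g")
        if config.alpha_policy == "bonferroni":
            alpha = scan_sum.alpha_bonferroni
        else:
            alpha = config.alpha_fixed
        sig = results[results["p"] < alpha]
        summary["scan"] = {
            "n_features": scan_sum.n_features,
            "alpha": float(f"{alpha:.6g}"),
            "n_significant": int(len(sig)),
            "n_positive": int((sig["beta"] > 0).sum()),
            "n_negative": int((sig["beta"] <= 0).sum()),
        }
        log_lines.append(
            f"assoc: alpha=0.05/{scan_sum.n_features}={scan_sum.alpha_bonferroni:.4g}"
            f" policy={config.alpha_policy} used={alpha:.4g}"
        )
        vol = assoc.volcano_table(results, alpha)
        vol.to_csv(out_dir / "volcano.tsv", sep="\t", index=False, float_format="%.6g")
        io.write_gene_list(sorted(sig["gene"].unique()), out_dir / "sig_genes.txt")
    except Exception as e:  # noqa: BLE001
        raise StageError("assoc", e) from e

    # --- expression score + mortality ---------------------------------------
    try:
        stage("score")
        if len(sig) and {"time", "event"} <= set(cohort.columns):
            scores = score.expression_score(sig, data["expression"])
            scores.rename("score").to_frame().assign(
                subject_id=scores.index
            )[["subject_id", "score"]].to_csv(
                out_dir / "score.tsv", sep="\t", index=False, float_format="%.6g"
            )
            sres = score.score_survival(scores, cohort, family_col=config.family_col)
            summary["score"] = {
                t.tier: {
                    "hr_per_sd": round(t.hr_per_sd, 4),
                    "ci": [round(t.ci_low, 4), round(t.ci_high, 4)],
                    "p": float(f"{t.p:.4g}"),
                    "n_events": t.n_events,
                }
                for t in sres.tiers
            }
        else:
            summary["score"] = None
            log_lines.append("score: skipped (no significant genes or no survival columns)")
    except Exception as e:  # noqa: BLE001
        raise StageError("score", e) from e

    # --- enrichment ----------------------------------------------------------
    try:
        stage("enrich")
        universe = list(data["expression"].gene_map.unique())
        if data.get("genesets"):
            enr = enrich.pathway_enrichment(sig["gene"], data["genesets"], universe)
            pd.DataFrame(
                [
                    {
                        "set": e.set_name, "n_set": e.n_set, "n_hit": e.n_hit,
                        "ratio": round(e.ratio, 4), "p": float(f"{e.p:.4g}"),
                        "fdr": float(f"{e.fdr:.4g}"), "hits": ";".join(e.hits),
                    }
                    for e in enr
                ]
            ).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
            summary["enrich"] = {
                "n_sets_tested": len(enr),
                "top_set": enr[0].set_name if enr else None,
                "top_fdr": float(f"{enr[0].fdr:.4g}") if enr else None,
            }
        else:
            summary["enrich"] = None
        prior = None
        if config.prior_genes_path:
            prior = io.read_gene_list(config.prior_genes_path)
        elif data.get("truth") is not None:
            # synthetic prior list: half the true genes plus random fillers
            rng = np.random.default_rng(config.seed + 17)
            truth = data["truth"]
            half = sorted(truth.true_gene_ids)[::2]
            fill = rng.choice(universe, size=min(100, len(universe)), replace=False)
            prior = sorted(set(half) | set(map(str, fill)))
        if prior is not None and len(sig):
            n_ov, p_ov = enrich.overlap_test(sig["gene"], prior, universe)
            summary["overlap"] = {"n_overlap": int(n_ov), "p": float(f"{p_ov:.4g}")}
        else:
            summary["overlap"] = None
    except Exception as e:  # noqa: BLE001
        raise StageError("enrich", e) from e

    # --- PPI subnetwork ------------------------------------------------------
    try:
        stage("netmod")
        if data.get("network") is not None:
            by_gene = results.drop_duplicates("gene")
            sub, modules = netmod.build_subnetwork(
                data["network"], by_gene, n_seeds=config.n_seeds
            )
            nodes, edges = netmod.subnetwork_tables(sub)
            nodes.to_csv(out_dir / "subnetwork_nodes.tsv", sep="\t", index=False,
                         float_format="%.6g")
            edges.to_csv(out_dir / "subnetwork_edges.tsv", sep="\t", index=False)
            pd.DataFrame(
                [
                    {"seed": m.seed, "k": m.k, "z_m": round(m.z_m, 4),
                     "members": ";".join(m.members)}
                    for m in modules
                ]
            ).to_csv(out_dir / "modules.tsv", sep="\t", index=False)
            summary["network"] = {
                "n_nodes": sub.number_of_nodes(),
                "n_edges": sub.number_of_edges(),
                "n_modules": len(modules),
            }
        else:
            summary["network"] = None
    except Exception as e:  # noqa: BLE001
        raise StageError("netmod", e) from e

    # --- methylation ---------------------------------------------------------
    try:
        stage("methyl")
        if data.get("methylation") is not None and data.get("cpg_map") is not None and len(sig):
            ewas, _ = methyl.ewas_scan(
                data["methylation"], delta, cohort, covs, family_col=config.family_col
            )
            ewas.to_csv(out_dir / "ewas.tsv", sep="\t", index=False, float_format="%.6g")
            sig_genes = sorted(sig["gene"].unique())
            calls = methyl.call_dmgs(ewas, data["cpg_map"], sig_genes)
            dmg_genes = [c.gene for c in calls if c.is_dmg]
            pd.DataFrame(
                [
                    {"gene": c.gene, "n_cpgs": c.n_cpgs, "min_p": c.min_p,
                     "cutoff": c.cutoff, "is_dmg": int(c.is_dmg),
                     "top_cpg": c.top_cpg or "", "direction": c.direction}
                    for c in calls
                ]
            ).to_csv(out_dir / "dmg_calls.tsv", sep="\t", index=False, float_format="%.6g")

            # permutation null over the scanned-gene universe
            all_calls = methyl.call_dmgs(ewas, data["cpg_map"], universe)
            all_dmgs = [c.gene for c in all_calls if c.is_dmg]
            perm = methyl.permutation_enrichment(
                universe, all_dmgs, observed=len(dmg_genes),
                set_size=len(sig_genes), n_perm=config.n_perm, seed=config.seed + 101,
            )
            atten = methyl.attenuation_analysis(
                data["expression"], data["methylation"], calls, delta, cohort,
                covs, family_col=config.family_col, scan_results=results,
            )
            frac = methyl.attenuated_fraction(atten)
            summary["methyl"] = {
                "n_dmgs": len(dmg_genes),
                "cutoff": float(f"{calls[0].cutoff:.6g}") if calls else None,
                "null_mean": round(perm.null_mean, 2),
                "null_min": perm.null_min,
                "null_max": perm.null_max,
                "empirical_p": perm.format_p(),
                "attenuated_fraction": None if np.isnan(frac) else round(frac, 4),
            }
            log_lines.append(
                f"methyl: cutoff=0.05/{int(round(0.05 / calls[0].cutoff))}"
                f"={calls[0].cutoff:.4g}" if calls else "methyl: no calls"
            )
        else:
            summary["methyl"] = None
    except Exception as e:  # noqa: BLE001
        raise StageError("methyl", e) from e

    # consistency guard mirrored in the summary
    sc = summary["scan"]
    assert sc["n_positive"] + sc["n_negative"] == sc["n_significant"]

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
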