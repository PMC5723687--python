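#!/usr/bin/env python
"""Methylation integration: EWAS, DMG calling, permutation null, attenuation.

Scans every CpG against delta-age with the same mixed model as the
expression scan; calls a significant gene a DMG when any of its CpGs passes
p < 0.05/N (N = CpGs mapped to the significant genes); compares the
observed DMG count with the count in random same-size gene sets (the
permutation null); and refits each DMG's expression model with its top CpG
as a covariate to measure attenuation.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from inflammage import io, methyl

BASE = Path(__file__).resolve().parent.parent / "results"
COVARIATES = ["age", "sex", "cell_neut", "cell_lymph", "tech_pc1"]
N_PERM = 100_000
SEED = 1


def main() -> None:
    pheno = io.read_pheno(BASE / "data" / "pheno.tsv")
    meth = io.read_matrix(BASE / "data" / "meth.tsv")
    cpg_map = io.read_cpg_map(BASE / "data" / "cpg_map.tsv")
    expr = io.read_matrix(BASE / "data" / "expr.tsv")
    sig = io.read_gene_list(BASE / "sig_genes.txt")
    scan = pd.read_csv(BASE / "scan.tsv", sep="\t")
    ba = pd.read_csv(BASE / "ba.tsv", sep="\t", dtype={"subject_id": str})
    delta = pd.Series(ba["delta_age"].to_numpy(), index=ba["subject_id"])

    ewas, _ = methyl.ewas_scan(meth, delta, pheno, COVARIATES)
    ewas.to_csv(BASE / "ewas.tsv", sep="\t", index=False, float_format="%.6g")

    calls = methyl.call_dmgs(ewas, cpg_map, sig)
    dmg_genes = [c.gene for c in calls if c.is_dmg]
    pd.DataFrame(
        [{"gene": c.gene, "n_cpgs": c.n_cpgs, "min_p": c.min_p,
          "cutoff": c.cutoff, "is_dmg": int(c.is_dmg),
          "top_cpg": c.top_cpg or "", "direction": c.direction}
         for c in calls]
    ).to_csv(BASE / "dmg_calls.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"{len(dmg_genes)}/{len(sig)} significant genes are DMGs "
          f"(cutoff 0.05/{int(round(0.05 / calls[0].cutoff))} = "
          f"{calls[0].cutoff:.2e})")

    universe = sorted(expr.gene_map.unique())
    all_calls = methyl.call_dmgs(ewas, cpg_map, universe)
    perm = methyl.permutation_enrichment(
        universe, [c.gene for c in all_calls if c.is_dmg],
        observed=len(dmg_genes), set_size=len(sig), n_perm=N_PERM, seed=SEED)
    print(f"random {len(sig)}-gene sets contain {perm.null_mean:.1f} DMGs on "
          f"average (min {perm.null_min}, max {perm.null_max}); observed "
          f"{perm.observed}; empirical p {perm.format_p()}")

    atten = methyl.attenuation_analysis(expr, meth, calls, delta, pheno,
                                        COVARIATES, scan_results=scan)
    frac = methyl.attenuated_fraction(atten)
    pd.DataFrame(
        [{"gene": a.gene, "beta_before": a.beta_before,
          "beta_after": a.beta_after, "attenuated": int(a.attenuated),
          "indeterminate": int(a.indeterminate)} for a in atten]
    ).to_csv(BASE / "attenuation.tsv", sep="\t", index=False, float_format="%.6g")
    n_att = sum(a.attenuated for a in atten)
    print(f"{n_att} of {len(atten)} DMG expression associations "
          f"({100 * frac:.0f}%) attenuated after adjusting for the top CpG")


if __name__ == "__main__":
    main()
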