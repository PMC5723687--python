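#!/usr/bin/env python
"""Transcriptome-wide delta-age association scan.

Fits, for every gene, a linear mixed model of expression on delta-age with
sex, age, imputed cell counts and a technical covariate as fixed effects and
a family random intercept, then applies the Bonferroni threshold
0.05/n_genes and splits the significant genes by effect sign.  Writes the
full results table, the significant-gene list, and volcano-plot data.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from inflammage import assoc, io

BASE = Path(__file__).resolve().parent.parent / "results"
COVARIATES = ["age", "sex", "cell_neut", "cell_lymph", "tech_pc1"]


def main() -> None:
    pheno = io.read_pheno(BASE / "data" / "pheno.tsv")
    expr = io.read_matrix(BASE / "data" / "expr.tsv")
    ba = pd.read_csv(BASE / "ba.tsv", sep="\t", dtype={"subject_id": str})
    delta = pd.Series(ba["delta_age"].to_numpy(), index=ba["subject_id"])

    results, summary = assoc.run_scan(expr, delta, pheno, COVARIATES)
    results.to_csv(BASE / "scan.tsv", sep="\t", index=False, float_format="%.6g")
    sig = results[results["p"] < summary.alpha_bonferroni]
    io.write_gene_list(sorted(sig["gene"].unique()), BASE / "sig_genes.txt")
    vol = assoc.volcano_table(results, summary.alpha_bonferroni)
    vol.to_csv(BASE / "volcano.tsv", sep="\t", index=False, float_format="%.6g")

    truth = pd.read_csv(BASE / "data" / "truth.tsv", sep="\t")
    recovered = len(set(sig["gene"]) & set(truth["gene"]))
    print(f"Bonferroni threshold: 0.05/{summary.n_features} = "
          f"{summary.alpha_bonferroni:.3g}")
    print(f"{summary.n_significant} genes significant "
          f"({summary.n_positive} positive, {summary.n_negative} negative)")
    print(f"{recovered}/{len(truth)} planted genes recovered; "
          f"{len(sig) - recovered} hits outside the planted set")
    print(f"top gene: {results.iloc[0]['gene']} "
          f"(beta={results.iloc[0]['beta']:.4f}, p={results.iloc[0]['p']:.2e})")


if __name__ == "__main__":
    main()
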