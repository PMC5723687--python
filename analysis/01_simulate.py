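#!/usr/bin/env python
"""Generate the synthetic study cohort and every downstream input.

Writes, under results/data/: the phenotype table (2,000 subjects in ~800
families, nine inflammatory biomarkers, survival follow-up), the gene
expression and CpG methylation matrices, the CpG-to-gene map, gene sets
(GMT), the PPI-style edge list, and the ground-truth table used only for
checking recovery.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from inflammage import io, synthcohort as sc
from inflammage.config import SimConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    data = sc.generate_all(cfg)
    io.write_pheno(data["cohort"], OUT / "pheno.tsv")
    io.write_matrix(data["expression"], OUT / "expr.tsv")
    io.write_matrix(data["methylation"], OUT / "meth.tsv")
    io.write_cpg_map(data["cpg_map"], OUT / "cpg_map.tsv")
    io.write_gmt(data["genesets"], OUT / "genesets.gmt")
    io.write_edge_list(data["network"], OUT / "network.tsv")
    io.write_truth(data["truth"], OUT / "truth.tsv")
    n_events = int(data["cohort"]["event"].sum())
    print(f"cohort: {len(data['cohort'])} subjects, {cfg.n_families} families")
    print(f"expression: {cfg.n_genes} genes ({cfg.n_true_genes} truly delta-age-associated)")
    print(f"methylation: {cfg.n_genes * cfg.n_cpg_per_gene} CpGs")
    print(f"survival: {n_events} deaths within {cfg.censor_horizon:.0f} years")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
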