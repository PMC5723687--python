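#!/usr/bin/env python
"""Weighted expression score and its association with 10-year mortality.

Builds Score_j = sum_i beta_i G_ij over the significant genes and fits Cox
proportional-hazards models of time to death on the standardized score with
family-clustered robust variance: first adjusted for age and sex, then
additionally for smoking, diabetes, hypertension treatment, lipid
treatment, prevalent cardiovascular disease and prevalent cancer.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from inflammage import assoc, io, score

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pheno = io.read_pheno(BASE / "data" / "pheno.tsv")
    expr = io.read_matrix(BASE / "data" / "expr.tsv")
    results = pd.read_csv(BASE / "scan.tsv", sep="\t")
    alpha = assoc.bonferroni_alpha(len(results))
    sig = results[results["p"] < alpha]

    scores = score.expression_score(sig, expr)
    pd.DataFrame({"subject_id": scores.index, "score": scores.to_numpy()}).to_csv(
        BASE / "score.tsv", sep="\t", index=False, float_format="%.6g")

    res = score.score_survival(scores, pheno)
    rows = []
    for t in res.tiers:
        rows.append({"tier": t.tier, "hr_per_sd": t.hr_per_sd,
                     "ci_low": t.ci_low, "ci_high": t.ci_high, "p": t.p,
                     "n": t.n, "n_events": t.n_events})
        print(f"tier {t.tier} ({', '.join(t.covariates)}): "
              f"HR per SD = {t.hr_per_sd:.2f} "
              f"(95% CI {t.ci_low:.2f}-{t.ci_high:.2f}), p = {t.p:.3g}, "
              f"{t.n_events} deaths / {t.n} subjects")
    pd.DataFrame(rows).to_csv(BASE / "score_survival.tsv", sep="\t",
                              index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
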