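"""Weighted expression score and its association with mortality.

The score for subject j is the effect-weighted sum over the significant
genes, Score_j = sum_i beta_i * G_ij, with beta_i the scan effect size and
G_ij the expression value.  Mortality association uses Cox proportional
hazards with Efron tie handling and a family-clustered (sandwich) variance,
fit on the standardized score in two adjustment tiers: age + sex, then
additionally smoking, diabetes, hypertension treatment, lipid treatment,
prevalent cardiovascular disease and prevalent cancer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthcohort import FeatureMatrix

TIER1 = ("age", "sex")
TIER2_EXTRA = (
    "smoking",
    "diabetes",
    "htn_treatment",
    "lipid_treatment",
    "prev_cvd",
    "prev_cancer",
)


@dataclass
class TierResult:
    tier: str
    covariates: tuple
    hr_per_sd: float
    ci_low: float
    ci_high: float
    p: float
    hr_per_unit: float
    n: int
    n_events: int
    ph_ok: Optional[bool] = None


@dataclass
class ScoreResult:
    scores: pd.Series
    tiers: list = field(default_factory=list)

    def tier(self, name: str) -> TierResult:
        for t in self.tiers:
            if t.tier == name:
                return t
        raise KeyError(name)


def expression_score(results: pd.DataFrame, matrix: FeatureMatrix) -> pd.Series:
    """Score_j = sum_i beta_i G_ij over the given (significant) features.

    ``results`` needs columns ``feature`` and ``beta``; every feature must be
    present in the matrix.
    """
    feats = results["feature"].tolist()
    missing = [f for f in feats if f not in matrix.values.index]
    if missing:
        raise KeyError(f"features absent from expression matrix: {missing[:10]}")
    betas = results.set_index("feature")["beta"].loc[feats].to_numpy(dtype=float)
    g = matrix.values.loc[feats].to_numpy(dtype=float)
    return pd.Series(betas @ g, index=matrix.subject_ids, name="score")


def score_survival(
    scores: pd.Series,
    cohort: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    family_col: Optional[str] = "family_id",
    adjustments: Sequence[str] = TIER1,
    extra_adjustments: Sequence[str] = TIER2_EXTRA,
    horizon: Optional[float] = 10.0,
    standardize: bool = True,
) -> ScoreResult:
    """Cox PH of time-to-death on the (standardized) expression score.

    Two tiers are fit: ``base`` (the ``adjustments`` covariates) and ``full``
    (additionally ``extra_adjustments``, restricted to columns present).
    ``horizon`` administratively censors follow-up (default 10 years).
    Raises if there are no events or non-positive follow-up times.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    df = cohort.set_index("subject_id") if "subject_id" in cohort.columns else cohort.copy()
    df = df.loc[df.index.intersection(scores.index)]
    sc = scores.loc[df.index]
    if (df[time_col] <= 0).any():
        raise ValueError("non-positive follow-up times")

    time = df[time_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=int)
    if horizon is not None:
        over = time > horizon
        event = np.where(over, 0, event)
        time = np.minimum(time, horizon)
    if event.sum() == 0:
        raise ValueError("no events observed; cannot fit Cox model")

    sd = float(sc.std(ddof=1))
    x = (sc - sc.mean()) / sd if standardize and sd > 0 else sc.astype(float)

    result = ScoreResult(scores=scores)
    tiers = [("base", list(adjustments))]
    extra = [c for c in extra_adjustments if c in df.columns]
    if extra:
        tiers.append(("full", list(adjustments) + extra))

    for name, covs in tiers:
        missing = [c for c in covs if c not in df.columns]
        if missing:
            raise KeyError(f"adjustment columns absent from cohort: {missing}")
        fit_df = pd.DataFrame({"time": time, "event": event, "score": x.to_numpy()},
                              index=df.index)
        for c in covs:
            fit_df[c] = df[c].to_numpy(dtype=float)
        cluster = None
        if family_col is not None and family_col in df.columns:
            fit_df["_cluster"] = df[family_col].to_numpy()
            cluster = "_cluster"
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col="time", event_col="event",
                    cluster_col=cluster, robust=cluster is not None,
                    fit_options={"precision": 1e-9, "max_steps": 500})
        b = float(cph.params_["score"])
        se = float(cph.standard_errors_["score"])
        pv = float(cph.summary.loc["score", "p"])
        ph_ok = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pht = proportional_hazard_test(cph, fit_df, time_transform="rank")
                ph_p = float(pht.summary.loc["score", "p"].min()
                             if hasattr(pht.summary.loc["score", "p"], "min")
                             else pht.summary.loc["score", "p"])
            ph_ok = ph_p >= 0.05
            if not ph_ok:
                warnings.warn(
                    f"proportional-hazards diagnostic failed for tier {name!r} "
                    f"(p={ph_p:.3g}); estimates reported anyway",
                    RuntimeWarning,
                    stacklevel=2,
                )
        except Exception:
            pass
        hr = float(np.exp(b))
        ci = (float(np.exp(b - 1.959963984540054 * se)),
              float(np.exp(b + 1.959963984540054 * se)))
        per_unit = float(np.exp(b / sd)) if standardize and sd > 0 else hr
        result.tiers.append(
            TierResult(tier=name, covariates=tuple(covs), hr_per_sd=hr,
                       ci_low=ci[0], ci_high=ci[1], p=pv, hr_per_unit=per_unit,
                       n=len(fit_df), n_events=int(event.sum()), ph_ok=ph_ok)
        )
    return result
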