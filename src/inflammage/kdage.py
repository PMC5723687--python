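"""Klemera-Doubal inflammatory biologic age.

The estimator regresses each biomarker on chronological age (CA), combines
the per-biomarker evidence by inverse-variance weights into a biologic-age
estimate BA_E, and then shrinks BA_E toward CA ("age included as one of the
biomarkers") using the estimated variance s2_BA of the true biologic-age
offset.  Delta-age is BA_EC - CA.

Formulas (m biomarkers, subject i):

    x_ij = q_j + k_j * age + e_j,   s_j = residual SD,  r_j = corr(x_j, CA)
    BA_E_i  = sum_j (x_ij - q_j) k_j / s_j^2  /  sum_j k_j^2 / s_j^2
    r_char  = sqrt( sum_j w_j r_j^2 / sum_j w_j ),  w_j = k_j^2 / s_j^2
    s2_BA   = Var_i(BA_E_i - CA_i)
              - ((1 - r_char^2)/r_char^2) * (ca_max - ca_min)^2 / (12 m)
    BA_EC_i = [ sum_j (x_ij - q_j) k_j/s_j^2 + CA_i/s2_BA ]
              / [ sum_j k_j^2/s_j^2 + 1/s2_BA ]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KDModel:
    """Fitted Klemera-Doubal model parameters."""

    biomarkers: list  # names, order fixed
    q: np.ndarray  # intercepts, biomarker units
    k: np.ndarray  # slopes, units / year
    s: np.ndarray  # residual SDs, units
    r: np.ndarray  # biomarker-age Pearson correlations
    r_char: float  # characteristic correlation
    s2_ba: float  # variance of the biologic-age offset, years^2
    ca_min: float
    ca_max: float
    log_transformed: list = field(default_factory=list)
    low_r_flagged: list = field(default_factory=list)
    s2_ba_fallback: bool = False

    @property
    def m(self) -> int:
        return len(self.biomarkers)

    def to_text(self) -> str:
        lines = [f"m\t{self.m}", f"r_char\t{self.r_char:.6g}", f"s2_ba\t{self.s2_ba:.6g}",
                 f"ca_min\t{self.ca_min:.6g}", f"ca_max\t{self.ca_max:.6g}",
                 f"s2_ba_fallback\t{int(self.s2_ba_fallback)}"]
        for j, name in enumerate(self.biomarkers):
            lines.append(
                f"biomarker\t{name}\tq={self.q[j]:.6g}\tk={self.k[j]:.6g}"
                f"\ts={self.s[j]:.6g}\tr={self.r[j]:.6g}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class AgeEstimates:
    """Per-subject biologic-age estimates."""

    subject_id: pd.Index
    ca: np.ndarray
    ba_e: np.ndarray
    ba_ec: np.ndarray

    @property
    def delta_age(self) -> np.ndarray:
        return self.ba_ec - self.ca

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": np.asarray(self.subject_id),
                "ca": self.ca,
                "ba_e": self.ba_e,
                "ba_ec": self.ba_ec,
                "delta_age": self.delta_age,
            }
        )


def characteristic_correlation(
    k: np.ndarray,
    s: np.ndarray,
    r: np.ndarray,
    var_ca: float,
    method: str = "precision",
) -> float:
    """Characteristic correlation r_char of the biomarker panel.

    ``method='precision'`` (default) defines r_char^2 = S / (m + S) with
    S = Var(CA) * sum_j k_j^2/s_j^2.  Under this choice the s2_BA noise
    penalty ((1-r^2)/r^2)(ca_max-ca_min)^2/(12m) equals the sampling
    variance 1/sum_j(k_j^2/s_j^2) of BA_E (for uniformly distributed ages),
    which is exactly the quantity the penalty is meant to subtract; for a
    single biomarker regressed on age it reduces to that biomarker's age
    correlation.  ``method='weighted_rms'`` is the alternative
    sqrt(sum w_j r_j^2 / sum w_j), w_j = k_j^2/s_j^2, which is simpler but
    understates the penalty when biomarker-age correlations are weak.
    """
    w = k**2 / s**2
    if method == "precision":
        s_stat = var_ca * float(np.sum(w))
        return float(np.sqrt(s_stat / (len(k) + s_stat)))
    if method == "weighted_rms":
        return float(np.sqrt(np.sum(w * r**2) / np.sum(w)))
    raise ValueError(f"unknown characteristic-correlation method: {method!r}")


def fit_kd(
    cohort: pd.DataFrame,
    biomarker_names: Sequence[str],
    age_col: str = "age",
    log_transform: Optional[Sequence[str]] = None,
    r_floor: float = 0.01,
    r_char_method: str = "precision",
) -> KDModel:
    """Fit per-biomarker OLS regressions on chronological age.

    Complete-case: subjects missing any biomarker or age are excluded from
    the fit.  Biomarkers with |r| below ``r_floor`` are flagged (retained).
    ``log_transform`` optionally names skewed biomarkers to log before
    fitting (default: none).
    """
    biomarker_names = list(biomarker_names)
    log_transform = list(log_transform or [])
    cols = [age_col] + biomarker_names
    data = cohort[cols].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 subjects with complete biomarkers and age")
    ca = data[age_col].to_numpy(dtype=float)
    if np.var(ca) == 0:
        raise ValueError("chronological age has zero variance")

    m = len(biomarker_names)
    q = np.empty(m)
    k = np.empty(m)
    s = np.empty(m)
    r = np.empty(m)
    flagged = []
    for j, name in enumerate(biomarker_names):
        x = data[name].to_numpy(dtype=float)
        if name in log_transform:
            if np.any(x <= 0):
                raise ValueError(f"log transform requested for {name!r} with non-positive values")
            x = np.log(x)
        slope, intercept, rv, _, _ = stats.linregress(ca, x)
        resid = x - (intercept + slope * ca)
        dof = max(len(data) - 2, 1)
        q[j] = intercept
        k[j] = slope
        s[j] = max(np.sqrt(np.sum(resid**2) / dof), 1e-12)
        r[j] = rv
        if abs(rv) < r_floor:
            flagged.append(name)

    w = k**2 / s**2
    if np.all(w == 0):
        raise ValueError("no biomarker tracks age (all slopes zero)")
    r_char = characteristic_correlation(
        k, s, r, float(np.var(ca, ddof=1)), method=r_char_method
    )
    ca_min, ca_max = float(ca.min()), float(ca.max())

    model = KDModel(
        biomarkers=biomarker_names,
        q=q,
        k=k,
        s=s,
        r=r,
        r_char=r_char,
        s2_ba=np.nan,
        ca_min=ca_min,
        ca_max=ca_max,
        log_transformed=log_transform,
        low_r_flagged=flagged,
    )

    # s2_BA from the fitting sample: spread of BA_E around CA, minus the
    # estimation-noise share implied by the characteristic correlation.
    ba_e = _ba_e(model, data, age_col=None)
    var_diff = float(np.var(ba_e - ca, ddof=1))
    penalty = ((1.0 - r_char**2) / r_char**2) * (ca_max - ca_min) ** 2 / (12.0 * m)
    s2_ba = var_diff - penalty
    if s2_ba <= 0:
        warnings.warn(
            "s2_BA non-positive after noise correction; falling back to Var(BA_E - CA)",
            RuntimeWarning,
            stacklevel=2,
        )
        s2_ba = var_diff if var_diff > 0 else 1e-6
        model.s2_ba_fallback = True
    model.s2_ba = float(s2_ba)
    return model


def _ba_e(model: KDModel, data: pd.DataFrame, age_col) -> np.ndarray:
    """Unshrunken inverse-variance estimate from the biomarkers alone."""
    num = np.zeros(len(data))
    den = 0.0
    for j, name in enumerate(model.biomarkers):
        x = data[name].to_numpy(dtype=float)
        if name in model.log_transformed:
            x = np.log(x)
        num += (x - model.q[j]) * model.k[j] / model.s[j] ** 2
        den += model.k[j] ** 2 / model.s[j] ** 2
    return num / den


def estimate_ba(
    model: KDModel,
    cohort: pd.DataFrame,
    age_col: str = "age",
    subject_col: str = "subject_id",
    missing: str = "drop",
) -> AgeEstimates:
    """Compute BA_E, BA_EC and delta-age for each subject.

    ``missing='drop'`` (default) excludes subjects with any missing biomarker;
    ``missing='renormalize'`` rescores such subjects using only their observed
    biomarkers (weights renormalized).
    """
    if missing not in ("drop", "renormalize"):
        raise ValueError(f"unknown missing-biomarker policy: {missing!r}")
    cols = [age_col] + model.biomarkers
    sub = cohort.dropna(subset=[age_col])
    if missing == "drop":
        sub = sub.dropna(subset=model.biomarkers)
        n_dropped = len(cohort) - len(sub)
        if n_dropped:
            warnings.warn(
                f"dropping {n_dropped} subjects with incomplete biomarkers "
                "(complete-case policy)",
                RuntimeWarning,
                stacklevel=2,
            )
    ca = sub[age_col].to_numpy(dtype=float)

    num = np.zeros(len(sub))
    den = np.zeros(len(sub))
    for j, name in enumerate(model.biomarkers):
        x = sub[name].to_numpy(dtype=float)
        obs = np.isfinite(x)
        xs = np.where(obs, x, 0.0)
        if name in model.log_transformed:
            xs = np.where(obs, np.log(np.where(obs, x, 1.0)), 0.0)
        num += np.where(obs, (xs - model.q[j]) * model.k[j] / model.s[j] ** 2, 0.0)
        den += np.where(obs, model.k[j] ** 2 / model.s[j] ** 2, 0.0)
    if np.any(den == 0):
        raise ValueError("subject with no observed biomarkers cannot be scored")
    ba_e = num / den
    ba_ec = (num + ca / model.s2_ba) / (den + 1.0 / model.s2_ba)

    subject = sub[subject_col] if subject_col in sub.columns else pd.Index(sub.index)
    return AgeEstimates(subject_id=pd.Index(subject), ca=ca, ba_e=ba_e, ba_ec=ba_ec)


def check_delta_independence(est: AgeEstimates) -> dict:
    """Pearson correlation of delta-age with chronological age.

    The shrinkage construction should leave delta-age uncorrelated with CA;
    a small p-value here flags a miscalibrated fit.  Degenerate (constant)
    delta-age is reported as such with no warning.
    """
    delta = est.delta_age
    if np.allclose(delta, delta[0]) or np.allclose(est.ca, est.ca[0]):
        return {"r": np.nan, "p": np.nan, "degenerate": True, "warn": False}
    r, p = stats.pearsonr(delta, est.ca)
    out = {"r": float(r), "p": float(p), "degenerate": False, "warn": bool(p < 0.05)}
    if out["warn"]:
        warnings.warn(
            f"delta-age correlates with chronological age (r={r:.3f}, p={p:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return out
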