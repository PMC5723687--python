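"""Per-feature association scan with a family/kinship random effect.

Model, for one feature y (gene expression or CpG beta-value):

    y = beta * delta_age + X gamma + u + e,
    u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I),

where K is either the exchangeable family-block matrix (K_ij = 1 when i and
j share a family, including the diagonal) or a user-supplied symmetric PSD
relatedness matrix.  Estimation follows the standard single-eigendecomposition
scheme: K = U diag(d) U' is computed once and shared across all features;
in the rotated basis the covariance is diagonal, sigma_e^2 (lambda d_i + 1)
with lambda = sigma_g^2/sigma_e^2, and each feature needs only a 1-D REML
profile optimization over lambda.  Wald tests give two-sided p-values with
a Student-t reference on the residual degrees of freedom (equivalent to the
normal-z reporting of kinship mixed-model packages at cohort-scale n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthcohort import FeatureMatrix

_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-3, 3, 25)])


@dataclass
class AssociationResult:
    feature: str
    gene: str
    beta: float
    se: float
    p: float
    n: int
    converged: bool
    lam: float = np.nan  # fitted variance ratio sigma_g^2 / sigma_e^2

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class ScanSummary:
    n_features: int
    alpha_bonferroni: float
    n_significant: int
    n_positive: int
    n_negative: int

    def __post_init__(self) -> None:
        assert self.n_positive + self.n_negative == self.n_significant


def bonferroni_alpha(n_features: int, family_alpha: float = 0.05) -> float:
    """Per-feature significance threshold controlling FWER at family_alpha."""
    if n_features <= 0:
        raise ValueError("n_features must be positive")
    return family_alpha / n_features


class KinshipEigen:
    """Eigendecomposition of the grouping covariance, shared across features."""

    def __init__(self, eigvals: np.ndarray, eigvecs: np.ndarray, subjects: pd.Index):
        self.d = eigvals
        self.u = eigvecs
        self.subjects = subjects

    @classmethod
    def from_families(cls, family_ids: Sequence, subjects: Optional[pd.Index] = None):
        fam = np.asarray(family_ids)
        codes, idx = np.unique(fam, return_inverse=True)
        z = np.zeros((len(fam), len(codes)))
        z[np.arange(len(fam)), idx] = 1.0
        k = z @ z.T  # exchangeable blocks, diag 1 within-family covariance
        return cls.from_matrix(k, subjects if subjects is not None else pd.RangeIndex(len(fam)))

    @classmethod
    def from_matrix(cls, k: np.ndarray, subjects: Optional[pd.Index] = None):
        k = np.asarray(k, dtype=float)
        if k.shape[0] != k.shape[1] or not np.allclose(k, k.T, atol=1e-10):
            raise ValueError("relatedness matrix must be square symmetric")
        d, u = np.linalg.eigh(k)
        d = np.clip(d, 0.0, None)  # PSD up to round-off
        return cls(d, u, subjects if subjects is not None else pd.RangeIndex(k.shape[0]))

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.u.T @ a


def _wald_p(z: float, dof: int) -> float:
    """Two-sided Wald p with a Student-t reference on the residual dof.

    The t reference keeps extreme-tail type-I error honest at desk-scale n;
    at cohort-scale n it is indistinguishable from the normal reference that
    kinship-LMM packages report.
    """
    return max(float(2.0 * stats.t.sf(abs(z), dof)), np.finfo(float).tiny)


def _design(delta_age, covariates) -> tuple[np.ndarray, list]:
    x = [np.asarray(delta_age, dtype=float)]
    names = ["delta_age"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            v = cov[c].to_numpy(dtype=float)
            if np.ptp(v) == 0:
                continue  # constant column; intercept covers it
            x.append(v)
            names.append(str(c))
    x.append(np.ones_like(x[0]))
    names.append("intercept")
    xm = np.column_stack(x)
    rank = np.linalg.matrix_rank(xm)
    if rank < xm.shape[1]:
        # identify an offending column by greedy removal
        for j in range(xm.shape[1] - 1):
            keep = [c for c in range(xm.shape[1]) if c != j]
            if np.linalg.matrix_rank(xm[:, keep]) == rank:
                raise ValueError(f"design matrix rank-deficient: column {names[j]!r} is collinear")
        raise ValueError("design matrix rank-deficient")
    return xm, names


def _reml_crit_grid(ytil: np.ndarray, xtil: np.ndarray, d: np.ndarray, lams: np.ndarray):
    """-2 REML log-likelihood (up to constant) on a lambda grid.

    ytil: (F, n) rotated features; xtil: (n, p) rotated design.
    Returns (crit (L, F), beta (L, F), se (L, F)) for the delta_age column 0.
    """
    n, p = xtil.shape
    crits, betas, ses = [], [], []
    for lam in lams:
        w = 1.0 / (lam * d + 1.0)
        xw = xtil * w[:, None]
        g = xtil.T @ xw  # p x p
        c = xw.T @ ytil.T  # p x F
        b = np.linalg.solve(g, c)  # p x F
        resid = ytil - (xtil @ b).T  # F x n
        rss = np.einsum("fn,n,fn->f", resid, w, resid)
        rss = np.maximum(rss, 1e-300)
        sign, logdet_g = np.linalg.slogdet(g)
        crit = (
            (n - p) * np.log(rss / (n - p))
            + np.sum(np.log(lam * d + 1.0))
            + logdet_g
        )
        sig2 = rss / (n - p)
        ginv00 = np.linalg.inv(g)[0, 0]
        crits.append(crit)
        betas.append(b[0])
        ses.append(np.sqrt(sig2 * ginv00))
    return np.array(crits), np.array(betas), np.array(ses)


def _fit_one(ytil: np.ndarray, xtil: np.ndarray, d: np.ndarray, lam_grid=_LAMBDA_GRID):
    """Grid bracket + Brent refinement of the 1-D REML profile for one feature."""
    crit, beta, se = _reml_crit_grid(ytil[None, :], xtil, d, lam_grid)
    crit = crit[:, 0]
    j = int(np.argmin(crit))

    def obj(log_lam):
        c, _, _ = _reml_crit_grid(ytil[None, :], xtil, d, np.array([np.exp(log_lam)]))
        return c[0, 0]

    if j == 0:
        # boundary lambda = 0 (no family variance)
        lam = 0.0
    else:
        lo = np.log(lam_grid[j - 1]) if j >= 2 else np.log(lam_grid[1]) - 3.0
        hi = np.log(lam_grid[min(j + 1, len(lam_grid) - 1)]) if j < len(lam_grid) - 1 else np.log(lam_grid[j]) + 3.0
        res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-4})
        lam = float(np.exp(res.x))
        if res.fun > crit[j]:  # safeguard: keep grid optimum
            lam = float(lam_grid[j])
    c, b, s = _reml_crit_grid(ytil[None, :], xtil, d, np.array([lam]))
    return float(b[0, 0]), float(s[0, 0]), lam


def fit_feature_lmm(
    y: np.ndarray,
    delta_age: np.ndarray,
    covariates=None,
    grouping=None,
    feature: str = "feature",
    gene: str = "",
) -> AssociationResult:
    """Fit the mixed model for a single feature.

    ``grouping`` may be a vector of family ids, a symmetric PSD relatedness
    matrix, a prebuilt :class:`KinshipEigen`, or None (independent subjects,
    reducing exactly to OLS).
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    xm, _ = _design(delta_age, covariates)
    eig = _as_eigen(grouping, len(y))
    if not mask.all():
        sub = _subset_eigen(grouping, mask, len(y))
        return _fit_feature(y[mask], xm[mask], sub, feature, gene)
    return _fit_feature(y, xm, eig, feature, gene)


def _as_eigen(grouping, n) -> KinshipEigen:
    if grouping is None:
        return KinshipEigen(np.ones(n), np.eye(n), pd.RangeIndex(n))
    if isinstance(grouping, KinshipEigen):
        return grouping
    arr = np.asarray(grouping)
    if arr.ndim == 2:
        return KinshipEigen.from_matrix(arr)
    return KinshipEigen.from_families(arr)


def _subset_eigen(grouping, mask, n) -> KinshipEigen:
    if grouping is None:
        return KinshipEigen(np.ones(mask.sum()), np.eye(mask.sum()), pd.RangeIndex(mask.sum()))
    if isinstance(grouping, KinshipEigen):
        k = (grouping.u * grouping.d) @ grouping.u.T
        return KinshipEigen.from_matrix(k[np.ix_(mask, mask)])
    arr = np.asarray(grouping)
    if arr.ndim == 2:
        return KinshipEigen.from_matrix(arr[np.ix_(mask, mask)])
    return KinshipEigen.from_families(arr[mask])


def _fit_feature(y, xm, eig: KinshipEigen, feature, gene) -> AssociationResult:
    n, p = xm.shape
    ytil = eig.rotate(y)
    xtil = eig.rotate(xm)
    try:
        beta, se, lam = _fit_one(ytil, xtil, eig.d)
        converged = True
    except np.linalg.LinAlgError:
        b, *_ = np.linalg.lstsq(xm, y, rcond=None)
        resid = y - xm @ b
        sig2 = resid @ resid / (n - p)
        cov = sig2 * np.linalg.inv(xm.T @ xm)
        beta, se, lam = float(b[0]), float(np.sqrt(cov[0, 0])), np.nan
        converged = False
    pval = _wald_p(beta / se, n - p)
    return AssociationResult(
        feature=feature, gene=gene, beta=beta, se=se, p=pval, n=n,
        converged=converged, lam=lam,
    )


def run_scan(
    matrix: FeatureMatrix,
    delta_age: pd.Series | np.ndarray,
    cohort: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    family_col: Optional[str] = "family_id",
    kinship: Optional[np.ndarray] = None,
    refine: bool = True,
) -> tuple[pd.DataFrame, ScanSummary]:
    """Scan every feature in the matrix against delta-age.

    delta_age may be a Series indexed by subject id or an array aligned to
    the cohort.  Returns a results table (feature, gene, beta, se, p, n,
    converged, lam) sorted by p, and a :class:`ScanSummary` with the
    Bonferroni threshold 0.05/n_features and the sign split of significant
    features.  ``refine=False`` stops at the (vectorized) lambda grid,
    skipping the per-feature Brent polish.
    """
    subjects = matrix.subject_ids.intersection(pd.Index(cohort["subject_id"]))
    if len(subjects) == 0:
        raise ValueError("no overlapping subjects between matrix and cohort")
    cohort_sub = cohort.set_index("subject_id").loc[subjects]
    if isinstance(delta_age, pd.Series):
        da = delta_age.reindex(subjects).to_numpy(dtype=float)
    else:
        da = pd.Series(np.asarray(delta_age, dtype=float),
                       index=cohort["subject_id"]).reindex(subjects).to_numpy()
    vals = matrix.values[subjects]

    cov_df = cohort_sub[list(covariate_names)] if covariate_names else None
    xm, _ = _design(da, cov_df)
    if kinship is not None:
        eig = KinshipEigen.from_matrix(np.asarray(kinship))
    elif family_col is not None and family_col in cohort_sub.columns:
        eig = KinshipEigen.from_families(cohort_sub[family_col].to_numpy())
    else:
        eig = _as_eigen(None, len(subjects))

    y_all = vals.to_numpy(dtype=float)
    complete = np.isfinite(y_all).all(axis=1)
    xtil = eig.rotate(xm)
    ytil = eig.rotate(y_all[complete].T).T  # (F, n)

    crit, beta_g, se_g = _reml_crit_grid(ytil, xtil, eig.d, _LAMBDA_GRID)
    best = np.argmin(crit, axis=0)

    rows = []
    feats = matrix.feature_ids[complete]
    genes = matrix.gene_map[complete]
    n, p = xm.shape
    for fi, (feat, gene) in enumerate(zip(feats, genes)):
        j = int(best[fi])
        if refine and j > 0:
            beta, se, lam = _fit_one(ytil[fi], xtil, eig.d)
        else:
            beta, se, lam = float(beta_g[j, fi]), float(se_g[j, fi]), float(_LAMBDA_GRID[j])
        pv = _wald_p(beta / se, n - p)
        rows.append((feat, gene, beta, se, pv, n, True, lam))

    # slow path: features with missing values, complete-case per feature
    for feat in matrix.feature_ids[~complete]:
        y = vals.loc[feat].to_numpy(dtype=float)
        res = fit_feature_lmm(
            y, da, cov_df,
            grouping=eig if np.isfinite(y).all() else _subset_eigen(eig, np.isfinite(y), len(y)),
            feature=feat, gene=str(matrix.gene_map.loc[feat]),
        )
        rows.append((res.feature, res.gene, res.beta, res.se, res.p, res.n,
                     res.converged, res.lam))

    results = pd.DataFrame(
        rows, columns=["feature", "gene", "beta", "se", "p", "n", "converged", "lam"]
    ).sort_values("p", kind="stable").reset_index(drop=True)

    n_features = len(results)
    alpha = bonferroni_alpha(n_features) if n_features else np.nan
    sig = results[results["p"] < alpha] if n_features else results
    summary = ScanSummary(
        n_features=n_features,
        alpha_bonferroni=alpha,
        n_significant=len(sig),
        n_positive=int((sig["beta"] > 0).sum()),
        n_negative=int((sig["beta"] <= 0).sum()),
    )
    return results, summary


def volcano_table(results: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Per-feature (beta, -log10 p, significant) plus the threshold line."""
    out = results[["feature", "gene", "beta", "p"]].copy()
    out["neg_log10_p"] = -np.log10(out["p"])
    out["significant"] = out["p"] < alpha
    out.attrs["threshold_line"] = -np.log10(alpha)
    return out
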