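"""Klemera-Doubal estimator: exact limits, invariances, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from inflammage import kdage
from inflammage import synthcohort as sc
from inflammage.config import BIOMARKERS, SimConfig


def _toy_cohort(n=200, seed=0):
    rng = np.random.default_rng(seed)
    ca = rng.uniform(40, 80, n)
    return pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)], "age": ca})


def test_exact_line_recovers_parameters():
    df = _toy_cohort()
    rng = np.random.default_rng(1)
    df["bm"] = 2.0 + 0.5 * df["age"] + rng.normal(0, 1e-8, len(df))
    model = kdage.fit_kd(df, ["bm"])
    assert model.q[0] == pytest.approx(2.0, abs=1e-5)
    assert model.k[0] == pytest.approx(0.5, abs=1e-6)
    assert model.r[0] == pytest.approx(1.0, abs=1e-6)


def test_noiseless_biomarkers_give_ba_equal_ca():
    """Markers exactly linear in CA: BA_E = CA, so delta-age is 0."""
    df = _toy_cohort()
    rng = np.random.default_rng(2)
    for j, slope in enumerate((0.5, -1.2, 2.0)):
        df[f"bm{j}"] = j + slope * df["age"] + rng.normal(0, 1e-9, len(df))
    model = kdage.fit_kd(df, ["bm0", "bm1", "bm2"])
    est = kdage.estimate_ba(model, df)
    np.testing.assert_allclose(est.ba_e, df["age"], atol=1e-4)
    np.testing.assert_allclose(est.delta_age, 0.0, atol=1e-4)


def test_shrinkage_limits(default_cohort):
    _, cohort, _ = default_cohort
    model = kdage.fit_kd(cohort, BIOMARKERS)
    est = kdage.estimate_ba(model, cohort)
    big = kdage.KDModel(**{**model.__dict__, "s2_ba": 1e12})
    small = kdage.KDModel(**{**model.__dict__, "s2_ba": 1e-9})
    est_big = kdage.estimate_ba(big, cohort)
    est_small = kdage.estimate_ba(small, cohort)
    np.testing.assert_allclose(est_big.ba_ec, est.ba_e, atol=1e-3)
    np.testing.assert_allclose(est_small.ba_ec, est.ca, atol=1e-3)


def test_ba_ec_is_convex_combination(default_cohort):
    _, cohort, _ = default_cohort
    model = kdage.fit_kd(cohort, BIOMARKERS)
    est = kdage.estimate_ba(model, cohort)
    lo = np.minimum(est.ba_e, est.ca) - 1e-9
    hi = np.maximum(est.ba_e, est.ca) + 1e-9
    assert np.all(est.ba_ec >= lo) and np.all(est.ba_ec <= hi)


def test_affine_equivariance_in_age(default_cohort):
    _, cohort, _ = default_cohort
    shifted = cohort.copy()
    shifted["age"] = shifted["age"] + 10.0
    m0 = kdage.fit_kd(cohort, BIOMARKERS)
    m1 = kdage.fit_kd(shifted, BIOMARKERS)
    e0 = kdage.estimate_ba(m0, cohort)
    e1 = kdage.estimate_ba(m1, shifted)
    np.testing.assert_allclose(e1.ba_e, e0.ba_e + 10.0, rtol=0, atol=1e-6)
    np.testing.assert_allclose(e1.ba_ec, e0.ba_ec + 10.0, rtol=0, atol=1e-6)


def test_scale_invariance_per_biomarker(default_cohort):
    _, cohort, _ = default_cohort
    scaled = cohort.copy()
    scaled["crp"] = scaled["crp"] * 1000.0
    e0 = kdage.estimate_ba(kdage.fit_kd(cohort, BIOMARKERS), cohort)
    e1 = kdage.estimate_ba(kdage.fit_kd(scaled, BIOMARKERS), scaled)
    np.testing.assert_allclose(e1.ba_e, e0.ba_e, atol=1e-8)


def test_null_biomarker_contributes_nothing():
    df = _toy_cohort(400)
    rng = np.random.default_rng(3)
    df["good"] = 0.8 * df["age"] + rng.normal(0, 3, len(df))
    df["null"] = rng.normal(0, 5, len(df))
    model = kdage.fit_kd(df, ["good", "null"])
    w = model.k**2 / model.s**2
    assert abs(model.r[1]) < 0.1
    assert w[1] / w[0] < 0.01
    assert "null" in model.low_r_flagged or abs(model.r[1]) >= 0.01


def test_fitted_slopes_match_generating_truth(default_cohort):
    cfg, cohort, truth = default_cohort
    model = kdage.fit_kd(cohort, BIOMARKERS)
    n = cfg.n_subjects
    for j in range(9):
        # OLS of x on CA targets k_j * (1 + 0) since delta is CA-orthogonal;
        # allow 4 standard errors of the marker regression
        se = model.s[j] / (np.std(cohort["age"]) * np.sqrt(n))
        assert abs(model.k[j] - truth.biomarker_slopes[j]) < 4 * se + 1e-9


def test_recovery_beats_chronological_age():
    """BA_EC tracks latent biologic age better than CA does (10 seeds)."""
    gains, means = [], []
    for seed in range(1, 11):
        cohort, truth = sc.generate_cohort(SimConfig(n_subjects=2000, seed=seed))
        model = kdage.fit_kd(cohort, BIOMARKERS)
        est = kdage.estimate_ba(model, cohort)
        gains.append(
            np.corrcoef(est.ba_ec, truth.true_ba)[0, 1]
            - np.corrcoef(est.ca, truth.true_ba)[0, 1]
        )
        means.append(est.delta_age.mean())
    assert np.mean(gains) > 0
    assert abs(np.mean(means)) < 0.5


def test_delta_age_shrinkage_consistent(default_cohort):
    """SD(delta-age) matches the analytic shrinkage prediction.

    delta-age = w (delta + e) with w = s2_BA/(s2_BA + Ve) and
    Ve = 1/sum(k^2/s^2) the BA_E noise variance, so its SD is
    sqrt(w * s2_BA) when s2_BA is well calibrated.
    """
    _, cohort, truth = default_cohort
    model = kdage.fit_kd(cohort, BIOMARKERS)
    est = kdage.estimate_ba(model, cohort)
    ve = 1.0 / np.sum(model.k**2 / model.s**2)
    w = model.s2_ba / (model.s2_ba + ve)
    predicted_sd = np.sqrt(w * model.s2_ba)
    assert est.delta_age.std(ddof=1) == pytest.approx(predicted_sd, rel=0.25)


def test_delta_independence_report(default_cohort):
    _, cohort, _ = default_cohort
    model = kdage.fit_kd(cohort, BIOMARKERS)
    est = kdage.estimate_ba(model, cohort)
    rep = kdage.check_delta_independence(est)
    assert not rep["degenerate"]
    assert rep["p"] > 0.05 and not rep["warn"]

    # adversarial: delta-age equal to CA itself must warn
    bad = kdage.AgeEstimates(est.subject_id, est.ca, est.ba_e, 2 * est.ca)
    with pytest.warns(RuntimeWarning):
        rep_bad = kdage.check_delta_independence(bad)
    assert rep_bad["r"] == pytest.approx(1.0)

    # degenerate: constant delta-age, reported as such without warning
    const = kdage.AgeEstimates(est.subject_id, est.ca, est.ba_e, est.ca + 3.0)
    rep_c = kdage.check_delta_independence(const)
    assert rep_c["degenerate"] and not rep_c["warn"]


def test_independence_holds_across_seeds():
    ok = 0
    for seed in range(20):
        cohort, _ = sc.generate_cohort(SimConfig(n_subjects=1000, seed=seed))
        model = kdage.fit_kd(cohort, BIOMARKERS)
        est = kdage.estimate_ba(model, cohort)
        rep = kdage.check_delta_independence(est)
        ok += rep["p"] > 0.05
    assert ok >= 18


def test_errors_and_fallbacks():
    df = _toy_cohort(50)
    df["flat"] = 5.0  # constant marker: slope exactly 0
    with pytest.raises(ValueError, match="tracks age"):
        kdage.fit_kd(df, ["flat"])
    df2 = df.iloc[:2]
    df2 = df2.assign(bm=1.0)
    with pytest.raises(ValueError, match="3 subjects"):
        kdage.fit_kd(df2, ["bm"])


def test_missing_biomarker_policies(default_cohort):
    _, cohort, _ = default_cohort
    model = kdage.fit_kd(cohort, BIOMARKERS)
    holed = cohort.copy()
    holed.loc[holed.index[:50], "crp"] = np.nan
    with pytest.warns(RuntimeWarning, match="complete-case"):
        dropped = kdage.estimate_ba(model, holed)
    assert len(dropped.ca) == len(cohort) - 50
    renorm = kdage.estimate_ba(model, holed, missing="renormalize")
    assert len(renorm.ca) == len(cohort)
    with pytest.raises(ValueError, match="policy"):
        kdage.estimate_ba(model, holed, missing="bogus")
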