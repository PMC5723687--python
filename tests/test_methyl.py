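"""DMG calling, permutation null against the hypergeometric oracle,
and CpG-adjusted attenuation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inflammage import assoc, kdage, methyl
from inflammage.config import BIOMARKERS, SimConfig
from inflammage import synthcohort as sc


def _ewas_table(cpgs, ps, betas=None):
    betas = betas if betas is not None else np.ones(len(cpgs))
    return pd.DataFrame({"feature": cpgs, "gene": "", "beta": betas, "p": ps})


def _map(cpgs, genes):
    return pd.DataFrame({"cpg_id": cpgs, "gene_symbol": genes,
                         "position": range(len(cpgs))})


def test_dmg_cutoff_forced_arithmetic():
    cpgs = [f"cg{i}" for i in range(1000)]
    genes = [f"G{i % 448}" for i in range(1000)]
    ewas = _ewas_table(cpgs, np.full(1000, 0.5))
    calls = methyl.call_dmgs(ewas, _map(cpgs, genes), [f"G{i}" for i in range(448)])
    assert calls[0].cutoff == pytest.approx(0.05 / 1000)
    assert not any(c.is_dmg for c in calls)


def test_dmg_gene_without_cpgs_and_top_cpg_ties():
    cpgs = ["cg1", "cg2", "cg3"]
    genes = ["GA", "GA", "GB"]
    ewas = _ewas_table(cpgs, [1e-6, 1e-6, 0.2], betas=[-1.0, 1.0, 1.0])
    calls = methyl.call_dmgs(ewas, _map(cpgs, genes), ["GA", "GB", "GC"])
    by_gene = {c.gene: c for c in calls}
    assert by_gene["GC"].n_cpgs == 0 and not by_gene["GC"].is_dmg
    # N counts only CpGs mapped to the tested genes (3 here)
    assert by_gene["GA"].cutoff == pytest.approx(0.05 / 3)
    assert by_gene["GA"].is_dmg
    # tie on p broken by lexicographic CpG id
    assert by_gene["GA"].top_cpg == "cg1"
    assert by_gene["GA"].direction == -1.0
    assert not by_gene["GB"].is_dmg


def test_dmg_invariant_to_cpg_order():
    rng = np.random.default_rng(0)
    cpgs = [f"cg{i}" for i in range(60)]
    genes = [f"G{i % 20}" for i in range(60)]
    ps = rng.uniform(1e-8, 1, 60)
    ewas = _ewas_table(cpgs, ps)
    perm = rng.permutation(60)
    ewas_shuf = ewas.iloc[perm].reset_index(drop=True)
    c1 = methyl.call_dmgs(ewas, _map(cpgs, genes), [f"G{i}" for i in range(20)])
    c2 = methyl.call_dmgs(ewas_shuf, _map(cpgs, genes), [f"G{i}" for i in range(20)])
    assert [(c.gene, c.is_dmg, c.top_cpg) for c in c1] == [
        (c.gene, c.is_dmg, c.top_cpg) for c in c2
    ]


def test_empty_map_errors():
    with pytest.raises(ValueError, match="empty"):
        methyl.call_dmgs(_ewas_table(["cg1"], [0.1]), _map([], []), ["G1"])


def test_permutation_null_matches_hypergeometric():
    """Null DMG-count mean matches the closed-form hypergeometric mean
    within 3 Monte-Carlo SEs (100-gene universe, 30 DMGs, sets of 10)."""
    universe = [f"G{i}" for i in range(100)]
    dmgs = universe[:30]
    n_perm = 100_000
    res = methyl.permutation_enrichment(universe, dmgs, observed=9,
                                        set_size=10, n_perm=n_perm, seed=5)
    expected = 10 * 30 / 100
    var = stats.hypergeom(100, 30, 10).var()
    se_mc = np.sqrt(var / n_perm)
    assert res.null_mean == pytest.approx(expected, abs=3 * se_mc)
    assert res.null_counts.max() <= 10


def test_permutation_empirical_p_bounds():
    universe = [f"G{i}" for i in range(50)]
    # saturated: every gene a DMG -> every null count = set size -> p = 1
    res = methyl.permutation_enrichment(universe, universe, observed=10,
                                        set_size=10, n_perm=500, seed=1)
    assert res.empirical_p == 1.0
    # observed above all null counts: p = 1/(n_perm+1), printed as a bound
    res2 = methyl.permutation_enrichment(universe, universe[:5], observed=6,
                                         set_size=5, n_perm=999, seed=2)
    assert res2.empirical_p == pytest.approx(1 / 1000)
    assert res2.format_p().startswith("<")
    # never zero; monotone in the observed count
    res3 = methyl.permutation_enrichment(universe, universe[:5], observed=0,
                                         set_size=5, n_perm=999, seed=2)
    assert 0 < res2.empirical_p <= res3.empirical_p <= 1


def test_permutation_reproducible_and_validated():
    universe = [f"G{i}" for i in range(30)]
    a = methyl.permutation_enrichment(universe, universe[:10], 3, 5, 2000, seed=9)
    b = methyl.permutation_enrichment(universe, universe[:10], 3, 5, 2000, seed=9)
    np.testing.assert_array_equal(a.null_counts, b.null_counts)
    with pytest.raises(ValueError, match="set_size"):
        methyl.permutation_enrichment(universe, [], 3, 50, 10, seed=0)
    with pytest.raises(ValueError, match="n_perm"):
        methyl.permutation_enrichment(universe, [], 3, 5, 0, seed=0)


@pytest.fixture(scope="module")
def mediated_pipeline():
    cfg = SimConfig(n_subjects=500, n_families=200, n_genes=150,
                    n_true_genes=30, mediation_fraction=0.5,
                    mediation_strength=0.6, seed=21)
    data = sc.generate_all(cfg)
    cohort = data["cohort"]
    model = kdage.fit_kd(cohort, BIOMARKERS)
    est = kdage.estimate_ba(model, cohort)
    delta = pd.Series(est.delta_age, index=est.subject_id)
    return cfg, data, delta


def test_mediated_genes_called_dmgs(mediated_pipeline):
    cfg, data, delta = mediated_pipeline
    truth = data["truth"]
    ewas, _ = methyl.ewas_scan(data["methylation"], delta, data["cohort"],
                               ["age", "sex"])
    calls = methyl.call_dmgs(ewas, data["cpg_map"], sorted(truth.true_gene_ids))
    dmg = {c.gene for c in calls if c.is_dmg}
    frac_med = len(dmg & truth.mediated_gene_ids) / len(truth.mediated_gene_ids)
    assert frac_med >= 0.9


def test_attenuation_mediated_vs_not(mediated_pipeline):
    """Mediated genes attenuate more often than non-mediated ones after
    adjusting for the top CpG."""
    cfg, data, delta = mediated_pipeline
    truth = data["truth"]
    cohort = data["cohort"]
    ewas, _ = methyl.ewas_scan(data["methylation"], delta, cohort, ["age", "sex"])
    scan, _ = assoc.run_scan(data["expression"], delta, cohort, ["age", "sex"])
    calls = methyl.call_dmgs(ewas, data["cpg_map"], sorted(truth.true_gene_ids))
    # force evaluation for every true gene (DMG or not) by marking them
    for c in calls:
        c.is_dmg = c.top_cpg is not None
    atten = methyl.attenuation_analysis(
        data["expression"], data["methylation"], calls, delta, cohort,
        ["age", "sex"], scan_results=scan,
    )
    med = [a for a in atten if a.gene in truth.mediated_gene_ids]
    non = [a for a in atten if a.gene not in truth.mediated_gene_ids]
    assert methyl.attenuated_fraction(med) > methyl.attenuated_fraction(non)


def test_attenuation_constant_cpg_indeterminate():
    n = 80
    rng = np.random.default_rng(3)
    subjects = [f"S{i}" for i in range(n)]
    cohort = pd.DataFrame({"subject_id": subjects,
                           "family_id": rng.integers(0, 30, n)})
    expr = sc.FeatureMatrix(
        values=pd.DataFrame(rng.normal(size=(1, n)), index=["G1"], columns=subjects),
        gene_map=pd.Series(["G1"], index=["G1"]))
    meth = sc.FeatureMatrix(
        values=pd.DataFrame(np.full((1, n), 0.5), index=["cg1"], columns=subjects),
        gene_map=pd.Series(["G1"], index=["cg1"]))
    call = methyl.DMGCall("G1", 1, 1e-9, 1e-3, True, "cg1", 1.0)
    delta = pd.Series(rng.normal(size=n), index=subjects)
    res = methyl.attenuation_analysis(expr, meth, [call], delta, cohort)
    assert res[0].indeterminate
    assert np.isnan(methyl.attenuated_fraction(res))


def test_null_cpg_attenuates_about_half_the_time():
    """A CpG independent of expression and delta-age flips |beta| up or down
    at random: the attenuated fraction is ~0.5 under the null."""
    rng = np.random.default_rng(8)
    n, reps = 300, 100
    subjects = [f"S{i}" for i in range(n)]
    hits = 0
    fam = rng.integers(0, 120, n)
    cohort = pd.DataFrame({"subject_id": subjects, "family_id": fam})
    delta = pd.Series(rng.normal(size=n), index=subjects)
    for r in range(reps):
        y = rng.normal(size=(1, n))
        cpg = np.clip(rng.normal(0.5, 0.1, size=(1, n)), 0, 1)
        expr = sc.FeatureMatrix(
            values=pd.DataFrame(y, index=["G1"], columns=subjects),
            gene_map=pd.Series(["G1"], index=["G1"]))
        meth = sc.FeatureMatrix(
            values=pd.DataFrame(cpg, index=["cg1"], columns=subjects),
            gene_map=pd.Series(["G1"], index=["cg1"]))
        call = methyl.DMGCall("G1", 1, 1e-9, 1e-3, True, "cg1", 1.0)
        res = methyl.attenuation_analysis(expr, meth, [call], delta, cohort)
        hits += res[0].attenuated
    lo, hi = stats.binom.interval(0.999, reps, 0.5)
    assert lo <= hits <= hi
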