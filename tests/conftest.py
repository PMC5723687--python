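import numpy as np
import pandas as pd
import pytest

from inflammage import synthcohort as sc
from inflammage.config import SimConfig


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale cohort used by most integration-style tests."""
    return SimConfig(
        n_subjects=600,
        n_families=240,
        n_genes=400,
        n_true_genes=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return sc.generate_all(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort (n=2000) for estimator-recovery checks."""
    cfg = SimConfig(seed=1)
    cohort, truth = sc.generate_cohort(cfg)
    return cfg, cohort, truth


def make_family_feature(rng, fam, sigma_f=1.0, sigma_e=1.0):
    """One null feature with a shared family intercept."""
    n_fam = fam.max() + 1
    return rng.normal(0, sigma_f, n_fam)[fam] + rng.normal(0, sigma_e, len(fam))
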