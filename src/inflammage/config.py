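"""Configuration objects for the synthetic cohort and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

#: Column names of the nine inflammatory biomarkers, in panel order:
#: C-reactive protein, ICAM-1, interleukin-6, Lp-PLA2 mass, Lp-PLA2 activity,
#: MCP-1, osteoprotegerin, P-selectin, TNF receptor II.
BIOMARKERS = (
    "crp",
    "icam1",
    "il6",
    "lppla2_mass",
    "lppla2_act",
    "mcp1",
    "opg",
    "pselectin",
    "tnfr2",
)

#: Default target correlations of each biomarker with chronological age.
#: Seven of nine markers track age; the last two are essentially age-independent.
DEFAULT_BIOMARKER_AGE_R = (0.30, 0.25, 0.35, 0.20, 0.15, 0.22, 0.28, 0.03, 0.02)

#: Default binary-covariate prevalences used for the mortality-adjustment tier.
SURVIVAL_COVARIATES = {
    "smoking": 0.083,
    "diabetes": 0.17,
    "htn_treatment": 0.49,
    "lipid_treatment": 0.44,
    "prev_cvd": 0.089,
    "prev_cancer": 0.10,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The defaults define the generator's study conditions: a cohort of older
    adults with a latent biologic age ``BA_true = CA + delta`` (delta i.i.d.
    mean-0, SD ``delta_sd`` years), nine biomarkers linear in BA_true with
    noise calibrated to hit the target biomarker-age correlations, a minority
    of expression features truly associated with delta-age (roughly 2:1
    positive:negative), CpGs partially mediating a subset of those genes,
    family clustering, and mortality whose hazard depends on the true
    expression score.
    """

    n_subjects: int = 2000
    n_families: int = 800
    age_range: tuple[float, float] = (50.0, 85.0)
    delta_sd: float = 7.0

    n_biomarkers: int = 9
    biomarker_age_r: Sequence[float] = DEFAULT_BIOMARKER_AGE_R
    #: Range the modest pairwise biomarker correlations should fall in (the
    #: shared latent-BA factor induces them); documented target, not enforced.
    biomarker_cross_r: tuple[float, float] = (0.06, 0.27)
    #: One designated pair is more strongly correlated than the rest
    #: (CRP and IL-6 in the panel order), with this target correlation.
    high_pair: tuple[int, int] = (0, 2)
    high_pair_r: float = 0.52

    n_genes: int = 1000
    n_true_genes: int = 50
    frac_positive: float = 2.0 / 3.0
    #: Scale (expression units per year of delta-age) of planted effect
    #: magnitudes; magnitudes are drawn uniformly in [0.5, 1.5] x this value.
    effect_size_sd: float = 0.08
    expr_noise_sd: float = 1.0
    family_sd: float = 0.5

    n_cpg_per_gene: int = 3
    mediation_fraction: float = 0.5
    mediation_strength: float = 0.6
    cpg_noise_sd: float = 0.45

    baseline_hazard: float = 0.012
    score_log_hr: float = 0.4
    censor_horizon: float = 10.0

    net_mean_degree: float = 4.0
    planted_cluster_size: int = 20
    n_gene_sets: int = 30

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_genes > self.n_genes:
            raise ValueError("n_true_genes must be <= n_genes")
        if not 0.0 <= self.frac_positive <= 1.0:
            raise ValueError("frac_positive must lie in [0, 1]")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy low < high")
        self.biomarker_age_r = rs = tuple(self.biomarker_age_r)
        if len(rs) != self.n_biomarkers:
            raise ValueError(
                f"biomarker_age_r has {len(rs)} entries for {self.n_biomarkers} biomarkers"
            )
        for j, r in enumerate(rs):
            if not -1.0 < r < 1.0:
                raise ValueError(f"biomarker_age_r[{j}]={r} not in (-1, 1)")
        if not -1.0 < self.high_pair_r < 1.0:
            raise ValueError("high_pair_r must lie in (-1, 1)")
        if self.planted_cluster_size > self.n_genes:
            raise ValueError("planted cluster larger than graph")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["biomarker_age_r"] = list(self.biomarker_age_r)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "high_pair" in d:
            d["high_pair"] = tuple(d["high_pair"])
        if "biomarker_cross_r" in d:
            d["biomarker_cross_r"] = tuple(d["biomarker_cross_r"])
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (file paths, columns, knobs)."""

    out_dir: str = "results/pipeline"
    seed: int = 0

    # Input paths; when None the synthetic generator provides the stage inputs.
    pheno_path: Optional[str] = None
    expression_path: Optional[str] = None
    methylation_path: Optional[str] = None
    cpg_map_path: Optional[str] = None
    gmt_path: Optional[str] = None
    network_path: Optional[str] = None
    prior_genes_path: Optional[str] = None

    biomarkers: Sequence[str] = BIOMARKERS
    covariates: Sequence[str] = ("age", "sex", "cell_neut", "cell_lymph", "tech_pc1")
    family_col: str = "family_id"
    alpha_policy: str = "bonferroni"  # "bonferroni" | "fixed"
    alpha_fixed: float = 5e-5
    n_seeds: int = 25
    n_perm: int = 100_000
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.alpha_policy not in ("bonferroni", "fixed"):
            raise ValueError(f"unrecognized alpha policy: {self.alpha_policy!r}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["biomarkers"] = list(self.biomarkers)
        d["covariates"] = list(self.covariates)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
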