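"""Configuration objects for the simulator and the end-to-end pipeline.

All knobs that the analysis exposes (sparsity grid, negative-weight policy,
clustering conventions, mixed-model covariates, NBS settings, amyloid window)
live here so a run is fully described by one validated object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass
class CovariateParams:
    """Per-sex covariate distributions (age/education in years)."""

    age_mean_men: float = 72.2
    age_sd_men: float = 4.3
    age_mean_women: float = 72.6
    age_sd_women: float = 4.5
    edu_mean_men: float = 17.7
    edu_sd_men: float = 2.2
    edu_mean_women: float = 16.3
    edu_sd_women: float = 2.3
    adas_mean_men: float = 5.7
    adas_sd_men: float = 2.3
    adas_mean_women: float = 5.5
    adas_sd_women: float = 2.2
    left_handed_prob_men: float = 5 / 48
    left_handed_prob_women: float = 11 / 74
    apoe4_prob_men: float = 12 / 48
    apoe4_prob_women: float = 27 / 74
    age_max: float = 80.0
    adas_max: float = 10.0

    def validate(self) -> None:
        for name, val in dataclasses.asdict(self).items():
            if name.endswith("_sd_men") or name.endswith("_sd_women"):
                if val <= 0:
                    raise ConfigError(f"{name} must be > 0, got {val}")
            if "prob" in name and not 0 <= val <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {val}")


@dataclass
class SuvrParams:
    """Two-component amyloid-PET SUVR mixture straddling the 1.11 cutoff.

    APOE4 carriers draw the high component with higher probability; a
    configurable fraction of sessions has no PET scan close enough to the
    MRI date, yielding unknown amyloid status downstream.
    """

    negative_mean: float = 1.00
    negative_sd: float = 0.05
    positive_mean: float = 1.26
    positive_sd: float = 0.08
    p_positive_carrier: float = 0.55
    p_positive_noncarrier: float = 0.32
    unknown_frac: float = 23 / 207

    def validate(self) -> None:
        if self.negative_sd <= 0 or self.positive_sd <= 0:
            raise ConfigError("SUVR component SDs must be > 0")
        for p in (self.p_positive_carrier, self.p_positive_noncarrier, self.unknown_frac):
            if not 0 <= p <= 1:
                raise ConfigError(f"SUVR probabilities must be in [0, 1], got {p}")


@dataclass
class CognitionLink:
    """Affine link from a global network metric (z-scored) to a score.

    score = intercept_<sex> + slope_<sex> * metric + N(0, noise_sd).
    Defaults emulate a negative clustering/percent-forgetting association in
    women and none in men.
    """

    score: str = "ravlt_forgetting"
    metric: str = "clustering"
    slope_men: float = 0.0
    slope_women: float = -3.0
    intercept_men: float = 35.0
    intercept_women: float = 35.0
    noise_sd: float = 12.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("cognition noise_sd must be >= 0")


@dataclass
class BaseCovParams:
    """Community-structured baseline correlation for the male group."""

    n_blocks: int = 4
    r_within: float = 0.35
    r_between: float = 0.12

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if not (-1 < self.r_between <= self.r_within < 1):
            raise ConfigError("require -1 < r_between <= r_within < 1")


@dataclass
class SimConfig:
    """Parameters of the synthetic resting-state cohort generator.

    ``sex_effect_scale`` multiplies the women's between-region covariance:
    values below 1 implant globally lower connectivity in women, except for
    ``reversal_regions`` (emulating thalamus/dorsal striatum) where the
    factor is inverted. ``deficit_regions``, when set, confines the scaling
    to edges within that node set (a spatially localized deficit).
    ``subject_cov_sd`` is the SD (correlation units) of a per-subject
    perturbation of the group covariance shared by all of that subject's
    sessions — the subject random effect that makes repeated sessions
    correlated.
    """

    n_men: int = 48
    n_women: int = 74
    sessions_per_subject: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.35, 3: 0.15}
    )
    n_regions: int = 94
    n_timepoints: int = 192
    sex_effect_scale: float = 0.9
    reversal_regions: Optional[Sequence[int]] = None
    deficit_regions: Optional[Sequence[int]] = None
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    suvr_params: SuvrParams = field(default_factory=SuvrParams)
    cognition_links: list[CognitionLink] = field(default_factory=lambda: [CognitionLink()])
    base_cov: BaseCovParams = field(default_factory=BaseCovParams)
    ar1_coef: float = 0.3
    subject_cov_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_men <= 0 or self.n_women <= 0:
            raise ConfigError("subject counts must be positive")
        if self.n_regions < 3:
            raise ConfigError("n_regions must be >= 3")
        if self.n_timepoints < 3:
            raise ConfigError("n_timepoints must be >= 3")
        if self.sex_effect_scale <= 0:
            raise ConfigError("sex_effect_scale must be > 0")
        if not 0 <= self.ar1_coef < 1:
            raise ConfigError("ar1_coef must be in [0, 1)")
        if self.subject_cov_sd < 0:
            raise ConfigError("subject_cov_sd must be >= 0")
        probs = self.sessions_per_subject
        if not probs or any(k not in (1, 2, 3) for k in probs):
            raise ConfigError("sessions_per_subject keys must be in {1, 2, 3}")
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-9:
            raise ConfigError("sessions_per_subject must be a distribution summing to 1")
        for idx_set in (self.reversal_regions, self.deficit_regions):
            if idx_set is not None and any(
                not 0 <= i < self.n_regions for i in idx_set
            ):
                raise ConfigError("region indices out of range")
        self.covariate_params.validate()
        self.suvr_params.validate()
        self.base_cov.validate()
        for link in self.cognition_links:
            link.validate()


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (simulate -> connectome -> metrics -> stats -> nbs)."""

    sim: SimConfig = field(default_factory=SimConfig)
    sparsity_min: float = 0.05
    sparsity_max: float = 0.50
    sparsity_step: float = 0.01
    negative_weights: Literal["exclude", "absolute", "keep"] = "exclude"
    clustering_denominator: Literal["degree", "strength"] = "degree"
    clustering_normalize: Literal["max", "none"] = "max"
    edge_length: Literal["inverse", "neglog"] = "inverse"
    integration: Literal["mean", "trapezoid"] = "mean"
    global_aggregate: Literal["mean", "sum"] = "mean"
    covariates: tuple[str, ...] = ("age", "education", "handedness", "apoe4")
    bonferroni_global: int = 3
    bonferroni_regional: int = 94
    nbs_threshold: float = 0.005
    nbs_n_perm: int = 10_000
    nbs_direction: Literal["women_lt_men", "women_gt_men"] = "women_lt_men"
    nbs_statistic: Literal["extent", "intensity"] = "extent"
    amyloid_threshold: float = 1.11
    amyloid_window_days: int = 365
    age_cutoff: float = 80.0
    adas_cutoff: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        if not 0 < self.sparsity_min <= self.sparsity_max <= 1:
            raise ConfigError("sparsity bounds must satisfy 0 < min <= max <= 1")
        if self.sparsity_step <= 0:
            raise ConfigError("sparsity_step must be > 0")
        if not 0 < self.nbs_threshold < 1:
            raise ConfigError("nbs_threshold must be in (0, 1)")
        if self.nbs_n_perm < 100:
            raise ConfigError("nbs_n_perm must be >= 100")
        for name in ("negative_weights", "clustering_denominator", "clustering_normalize",
                     "edge_length", "integration", "global_aggregate",
                     "nbs_direction", "nbs_statistic"):
            allowed = _ALLOWED[name]
            if getattr(self, name) not in allowed:
                raise ConfigError(f"{name} must be one of {allowed}")


_ALLOWED = {
    "negative_weights": ("exclude", "absolute", "keep"),
    "clustering_denominator": ("degree", "strength"),
    "clustering_normalize": ("max", "none"),
    "edge_length": ("inverse", "neglog"),
    "integration": ("mean", "trapezoid"),
    "global_aggregate": ("mean", "sum"),
    "nbs_direction": ("women_lt_men", "women_gt_men"),
    "nbs_statistic": ("extent", "intensity"),
}


def load_config(path: str) -> PipelineConfig:
    """Load a PipelineConfig from a YAML (or JSON) file and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", {})
    sim_kwargs = dict(sim_raw)
    if "covariate_params" in sim_kwargs:
        sim_kwargs["covariate_params"] = CovariateParams(**sim_kwargs["covariate_params"])
    if "suvr_params" in sim_kwargs:
        sim_kwargs["suvr_params"] = SuvrParams(**sim_kwargs["suvr_params"])
    if "base_cov" in sim_kwargs:
        sim_kwargs["base_cov"] = BaseCovParams(**sim_kwargs["base_cov"])
    if "cognition_links" in sim_kwargs:
        sim_kwargs["cognition_links"] = [
            CognitionLink(**d) for d in sim_kwargs["cognition_links"]
        ]
    if "sessions_per_subject" in sim_kwargs:
        sim_kwargs["sessions_per_subject"] = {
            int(k): float(v) for k, v in sim_kwargs["sessions_per_subject"].items()
        }
    cfg = PipelineConfig(sim=SimConfig(**sim_kwargs), **raw)
    cfg.validate()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the full configuration, for provenance manifests."""
    canon = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
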