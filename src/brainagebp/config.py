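"""Configuration objects and seeded random-number streams.

``SimulationConfig`` collects every parameter of the synthetic longitudinal
cohort: cohort sizes, baseline-age windows, the blood-pressure baseline and
slope distributions, the generating fixed effects of the outcome model, the
covariate prevalences, feature-simulation settings and attrition. Defaults
describe a two-cohort study (middle-age 44-46 and older-age 60-64 at
baseline) followed for up to four waves roughly four years apart.

Randomness is organised as one named stream per generator stage: every stage
derives its own ``numpy`` Generator from ``(seed, stage key)``, so adding or
re-running a stage never shifts the draws of another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """A configuration field is invalid; the message names the field."""


#: stable keys for the per-stage random streams
_STAGE_KEYS = {
    "design": 11,
    "bp": 23,
    "features": 37,
    "outcome": 53,
    "pipeline": 71,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return the dedicated Generator for ``stage`` under the master ``seed``."""
    if stage not in _STAGE_KEYS:
        raise KeyError(f"unknown RNG stage {stage!r}; known: {sorted(_STAGE_KEYS)}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_KEYS[stage],))
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Blood pressure is generated per subject as a latent linear trajectory:
    baseline systolic/diastolic pressures are drawn from cohort- and
    sex-specific normal distributions; the per-subject annual slopes of mean
    arterial pressure (MAP) and systolic pressure (SBP) are drawn from the
    configured slope distributions, with the diastolic trajectory implied by
    MAP = (SBP + 2 DBP) / 3. Two readings per measure per visit add
    independent ``reading_noise_sd`` noise.
    """

    # cohort structure
    n_ma: int = 335
    n_oa: int = 351
    baseline_age_range_ma: tuple[float, float] = (44.0, 46.0)
    baseline_age_range_oa: tuple[float, float] = (60.0, 64.0)
    n_waves: int = 4
    wave_interval: float = 4.0            # years
    wave_jitter_mean: float = -0.16       # years, per interval
    wave_jitter_sd: float = 0.97          # years, per interval
    female_prob_ma: float = 0.52
    female_prob_oa: float = 0.46

    # baseline blood pressure (mmHg); cohort means with an additive
    # male-minus-female gap split symmetrically around the cohort mean
    sbp_baseline_mean: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 125.41, "OA": 137.90})
    sbp_baseline_sd: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 16.83, "OA": 17.45})
    dbp_baseline_mean: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 80.83, "OA": 82.53})
    dbp_baseline_sd: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 9.89, "OA": 10.09})
    sbp_sex_gap: float = 8.04             # male minus female, mmHg
    dbp_sex_gap: float = 5.02

    # annual blood-pressure change (mmHg/year), per-subject random slopes
    map_slope_mean: float = 0.8
    map_slope_sd: float = 0.92
    sbp_slope_mean: float = 1.41
    sbp_slope_sd: float = 1.49
    dbp_slope_mean: float = 0.61          # reference value; DBP trajectory is
    dbp_slope_sd: float = 0.78            # implied by the MAP identity
    slope_corr: float = 0.7               # corr(MAP slope, SBP slope); keeps
                                          # pulse pressure from drifting apart
    reading_noise_sd: float = 3.0         # within-visit duplicate-reading noise

    # generating fixed effects of the BrainAGE outcome model
    beta_map: float = 0.019               # years per mmHg above the MAP center
    beta_time: float = 0.035              # years per year in study
    beta_cohort: float = -0.402           # OA relative to MA, years
    beta_sex: float = -0.837              # female relative to male, years
    outcome_intercept: float = 0.073      # years
    map_center: float = 90.0              # mmHg
    random_intercept_sd: float = 3.633    # years
    residual_sd: float = 1.590            # years

    # covariates (prevalences are proportions; keyed maps are per cohort)
    smoker_prev: float = 0.4446
    apoe4_prev: float = 0.2974
    diabetes_prev: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 0.0627, "OA": 0.1852})
    bp_med_baseline_prev: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 0.0866, "OA": 0.2963})
    bp_med_onset_per_wave: float = 0.05
    education_mean: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 14.89, "OA": 14.11})
    education_sd: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 2.24, "OA": 2.65})
    bmi_mean: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 27.22, "OA": 26.61})
    bmi_sd: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 4.61, "OA": 4.23})
    activity_mean: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 37.79, "OA": 40.44})  # METs/day
    activity_sd: Mapping[str, float] = field(
        default_factory=lambda: {"MA": 31.78, "OA": 37.72})
    depression_mean: float = 2.0          # symptom count
    depression_sd: float = 1.8
    alcohol_mean: float = 8.0             # g/day
    alcohol_sd: float = 7.0

    # cognition / neurological screening
    mmse_mean: float = 28.8
    mmse_sd: float = 0.9
    neuro_rate: float = 0.0

    # feature simulation
    feature_dim: int = 100
    n_latent: int = 5
    latent_nuisance_sd: float = 5.0
    scanner_effect_size: float = 0.5
    feature_noise_sd: float = 1.0
    scanner_change_wave: int = 2          # first wave on the second scanner

    # attrition and missingness; per-wave dropout hazards are the probability
    # of leaving before wave w+1 given wave w was attended (MCAR). Defaults
    # produce 2/3/4-scan proportions of about 26/42/32%.
    dropout_hazard: Sequence[float] = (0.0, 0.26, 0.42 / 0.74)
    scan_missing_rate: float = 0.0
    covariate_missing_rate: float = 0.0

    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> "SimulationConfig":
        """Raise :class:`ConfigurationError` naming the first offending field."""
        def _check(cond: bool, fieldname: str, why: str) -> None:
            if not cond:
                raise ConfigurationError(f"{fieldname}: {why}")

        _check(self.n_ma >= 0 and self.n_oa >= 0, "n_ma/n_oa", "must be non-negative")
        _check(self.n_ma + self.n_oa >= 1, "n_ma/n_oa", "need at least one subject")
        _check(self.n_waves in (2, 3, 4), "n_waves", "must be 2, 3 or 4")
        for name in ("baseline_age_range_ma", "baseline_age_range_oa"):
            lo, hi = getattr(self, name)
            _check(lo <= hi, name, "range must be ordered (lo <= hi)")
        _check(self.wave_interval > 0, "wave_interval", "must be positive")
        for name in (
            "map_slope_sd", "sbp_slope_sd", "dbp_slope_sd", "reading_noise_sd",
            "random_intercept_sd", "residual_sd", "wave_jitter_sd", "mmse_sd",
            "latent_nuisance_sd", "feature_noise_sd", "depression_sd",
            "alcohol_sd",
        ):
            _check(getattr(self, name) >= 0, name, "SD must be non-negative")
        for name, val in (
            ("female_prob_ma", self.female_prob_ma),
            ("female_prob_oa", self.female_prob_oa),
            ("smoker_prev", self.smoker_prev),
            ("apoe4_prev", self.apoe4_prev),
            ("bp_med_onset_per_wave", self.bp_med_onset_per_wave),
            ("scan_missing_rate", self.scan_missing_rate),
            ("covariate_missing_rate", self.covariate_missing_rate),
            ("neuro_rate", self.neuro_rate),
        ):
            _check(0.0 <= val <= 1.0, name, "probability must lie in [0, 1]")
        for name in ("diabetes_prev", "bp_med_baseline_prev"):
            for cohort, val in getattr(self, name).items():
                _check(0.0 <= val <= 1.0, f"{name}[{cohort}]",
                       "probability must lie in [0, 1]")
        for name in ("sbp_baseline_sd", "dbp_baseline_sd", "education_sd",
                     "bmi_sd", "activity_sd"):
            for cohort, val in getattr(self, name).items():
                _check(val >= 0, f"{name}[{cohort}]", "SD must be non-negative")
        _check(len(self.dropout_hazard) >= self.n_waves - 1, "dropout_hazard",
               f"needs at least n_waves-1={self.n_waves - 1} entries")
        for i, h in enumerate(self.dropout_hazard):
            _check(0.0 <= h <= 1.0, f"dropout_hazard[{i}]",
                   "hazard must lie in [0, 1]")
        _check(-1.0 <= self.slope_corr <= 1.0, "slope_corr",
               "correlation must lie in [-1, 1]")
        _check(self.n_latent >= 1, "n_latent", "must be at least 1")
        _check(self.feature_dim >= self.n_latent, "feature_dim",
               "must be at least n_latent")
        _check(0 <= self.scanner_change_wave, "scanner_change_wave",
               "must be non-negative")
        return self

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_age_range_ma"] = list(d["baseline_age_range_ma"])
        d["baseline_age_range_oa"] = list(d["baseline_age_range_oa"])
        d["dropout_hazard"] = list(d["dropout_hazard"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown field(s): {sorted(unknown)}")
        kwargs = dict(d)
        for name in ("baseline_age_range_ma", "baseline_age_range_oa"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        if "dropout_hazard" in kwargs:
            kwargs["dropout_hazard"] = tuple(kwargs["dropout_hazard"])
        return cls(**kwargs).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable short hash of the configuration (for artifact stamping)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def no_attrition(config: SimulationConfig) -> SimulationConfig:
    """Copy of ``config`` with dropout, scan loss and covariate loss disabled."""
    return dataclasses.replace(
        config,
        dropout_hazard=tuple(0.0 for _ in config.dropout_hazard),
        scan_missing_rate=0.0,
        covariate_missing_rate=0.0,
    )
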