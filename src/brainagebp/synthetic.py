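"""Synthetic longitudinal cohort generator.

Builds cohorts with the statistical structure the downstream analysis
assumes: two age cohorts followed for up to four waves, per-subject latent
blood-pressure trajectories with random slopes, covariates at realistic
prevalences, scanner changes between waves, gray-matter-like feature
vectors whose latent structure encodes age, and a BrainAGE outcome generated
from a linear mixed model (random intercept per subject).

All operations are deterministic given ``(config, seed)`` and each stage
draws from its own named random stream (see :mod:`brainagebp.config`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig, stage_rng
from . import bp as bp_metrics

SUBJECT_COLUMNS = [
    "subject_id", "cohort", "sex", "baseline_age", "education", "apoe4",
    "smoker", "diabetes", "bmi", "physical_activity", "depression_score",
    "alcohol_intake",
]
VISIT_COLUMNS = [
    "subject_id", "wave", "time_in_study", "age_at_visit", "on_bp_med",
    "mmse", "neuro_flag", "scan_available",
    "sbp_reading_1", "sbp_reading_2", "dbp_reading_1", "dbp_reading_2",
]


@dataclass
class FeatureMatrix:
    """Per-scan feature vectors plus the metadata the estimator needs.

    ``data`` is indexed by scan id (``<subject>_w<wave>``); ``scanner``,
    ``subject_id`` and ``age`` are aligned to the same index.
    """

    data: pd.DataFrame
    scanner: pd.Series
    subject_id: pd.Series
    age: pd.Series

    def __post_init__(self) -> None:
        for name in ("scanner", "subject_id", "age"):
            s = getattr(self, name)
            if not s.index.equals(self.data.index):
                raise ValueError(f"{name} index does not match feature index")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "scanner", self.scanner)
        out.insert(1, "subject_id", self.subject_id)
        out.insert(2, "age_at_scan", self.age)
        out.to_csv(path, sep="\t", index_label="scan_id")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="scan_id")
        meta = ["scanner", "subject_id", "age_at_scan"]
        return cls(
            data=df.drop(columns=meta),
            scanner=df["scanner"],
            subject_id=df["subject_id"],
            age=df["age_at_scan"].rename("age"),
        )

    def subset(self, mask) -> "FeatureMatrix":
        return FeatureMatrix(
            data=self.data.loc[mask],
            scanner=self.scanner.loc[mask],
            subject_id=self.subject_id.loc[mask],
            age=self.age.loc[mask],
        )


def _cohort_arrays(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    cohort = np.array(["MA"] * config.n_ma + ["OA"] * config.n_oa)
    ids = np.array([f"S{i:05d}" for i in range(config.n_ma + config.n_oa)])
    return ids, cohort


def build_design(config: SimulationConfig, seed: int | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the subject table and the visit skeleton (no BP readings yet).

    Subjects are assigned a cohort, sex, baseline age (uniform within the
    cohort window) and time-fixed covariates; visits get wave indices,
    jittered visit times, MMSE scores, neurological flags, per-wave
    anti-hypertensive medication status and scan availability. Attrition is
    missing-completely-at-random: after each attended wave a subject drops
    out for good with the configured hazard.
    """
    config.validate()
    rng = stage_rng(config.seed if seed is None else seed, "design")
    ids, cohort = _cohort_arrays(config)
    n = len(ids)
    is_oa = cohort == "OA"

    female_prob = np.where(is_oa, config.female_prob_oa, config.female_prob_ma)
    female = rng.random(n) < female_prob
    lo = np.where(is_oa, config.baseline_age_range_oa[0],
                  config.baseline_age_range_ma[0])
    hi = np.where(is_oa, config.baseline_age_range_oa[1],
                  config.baseline_age_range_ma[1])
    baseline_age = lo + (hi - lo) * rng.random(n)

    def per_cohort(mapping):
        return np.where(is_oa, mapping["OA"], mapping["MA"])

    education = np.clip(rng.normal(per_cohort(config.education_mean),
                                   per_cohort(config.education_sd)), 6.0, None)
    bmi = np.clip(rng.normal(per_cohort(config.bmi_mean),
                             per_cohort(config.bmi_sd)), 14.0, None)
    # activity and alcohol are right-skewed; gamma with matched mean/SD
    act_mean = per_cohort(config.activity_mean)
    act_sd = np.maximum(per_cohort(config.activity_sd), 1e-9)
    shape = (act_mean / act_sd) ** 2
    activity = rng.gamma(shape, act_sd ** 2 / act_mean)
    if config.alcohol_sd > 0:
        a_shape = (config.alcohol_mean / config.alcohol_sd) ** 2
        alcohol = rng.gamma(a_shape, config.alcohol_sd ** 2 / config.alcohol_mean, n)
    else:
        alcohol = np.full(n, config.alcohol_mean)
    depression = np.clip(rng.normal(config.depression_mean,
                                    config.depression_sd, n), 0.0, None)

    subjects = pd.DataFrame({
        "subject_id": ids,
        "cohort": cohort,
        "sex": np.where(female, "female", "male"),
        "baseline_age": baseline_age,
        "education": education,
        "apoe4": rng.random(n) < config.apoe4_prev,
        "smoker": rng.random(n) < config.smoker_prev,
        "diabetes": rng.random(n) < per_cohort(config.diabetes_prev),
        "bmi": bmi,
        "physical_activity": activity,
        "depression_score": depression,
        "alcohol_intake": alcohol,
    })

    # attrition: monotone dropout after each wave
    attended = np.ones((n, config.n_waves), dtype=bool)
    for w in range(1, config.n_waves):
        hazard = config.dropout_hazard[w - 1]
        dropped = attended[:, w - 1] & (rng.random(n) < hazard)
        attended[:, w:] &= ~dropped[:, None]
        attended[:, w] &= attended[:, w - 1]

    # visit times: wave_interval plus jitter per interval, cumulative
    intervals = np.clip(
        config.wave_interval
        + rng.normal(config.wave_jitter_mean, config.wave_jitter_sd,
                     (n, max(config.n_waves - 1, 1))),
        0.5, None)
    times = np.zeros((n, config.n_waves))
    if config.n_waves > 1:
        times[:, 1:] = np.cumsum(intervals[:, :config.n_waves - 1], axis=1)

    mmse = np.minimum(
        rng.normal(config.mmse_mean, config.mmse_sd, (n, config.n_waves)),
        30.0).round(0)
    neuro = rng.random((n, config.n_waves)) < config.neuro_rate
    scan_ok = rng.random((n, config.n_waves)) >= config.scan_missing_rate

    on_med = np.zeros((n, config.n_waves), dtype=bool)
    on_med[:, 0] = rng.random(n) < per_cohort(config.bp_med_baseline_prev)
    for w in range(1, config.n_waves):
        onset = rng.random(n) < config.bp_med_onset_per_wave
        on_med[:, w] = on_med[:, w - 1] | onset  # once treated, stays treated

    rows = attended.ravel()
    sub_idx = np.repeat(np.arange(n), config.n_waves)[rows]
    wave_idx = np.tile(np.arange(config.n_waves), n)[rows]
    visits = pd.DataFrame({
        "subject_id": ids[sub_idx],
        "wave": wave_idx,
        "time_in_study": times[sub_idx, wave_idx],
        "age_at_visit": baseline_age[sub_idx] + times[sub_idx, wave_idx],
        "on_bp_med": on_med[sub_idx, wave_idx],
        "mmse": mmse[sub_idx, wave_idx],
        "neuro_flag": neuro[sub_idx, wave_idx],
        "scan_available": scan_ok[sub_idx, wave_idx],
        "sbp_reading_1": np.nan,
        "sbp_reading_2": np.nan,
        "dbp_reading_1": np.nan,
        "dbp_reading_2": np.nan,
    })
    return subjects, visits


def simulate_bp(subjects: pd.DataFrame, visits: pd.DataFrame,
                config: SimulationConfig, seed: int | None = None
                ) -> pd.DataFrame:
    """Fill the four BP reading columns from latent linear trajectories.

    Baseline SBP/DBP are cohort- and sex-specific; each subject gets an
    annual MAP slope and an annual SBP slope drawn from the configured
    distributions, with DBP implied by MAP = (SBP + 2 DBP)/3 so that the
    configured MAP trend is exactly the trend of the derived per-visit MAP.
    Both readings of a measure are the latent value plus independent noise.
    """
    config.validate()
    if visits.empty:
        raise ValueError("no visits to simulate blood pressure for")
    rng = stage_rng(config.seed if seed is None else seed, "bp")
    subs = subjects.set_index("subject_id")
    n = len(subs)
    is_oa = (subs["cohort"] == "OA").to_numpy()
    female = (subs["sex"] == "female").to_numpy()
    sex_sign = np.where(female, -0.5, 0.5)

    def pick(mapping):
        return np.where(is_oa, mapping["OA"], mapping["MA"])

    sbp0 = rng.normal(pick(config.sbp_baseline_mean) + sex_sign * config.sbp_sex_gap,
                      pick(config.sbp_baseline_sd))
    dbp0 = rng.normal(pick(config.dbp_baseline_mean) + sex_sign * config.dbp_sex_gap,
                      pick(config.dbp_baseline_sd))
    map0 = (sbp0 + 2.0 * dbp0) / 3.0
    # correlated slope draws; marginals keep the configured means and SDs
    z1 = rng.normal(0.0, 1.0, n)
    z2 = rng.normal(0.0, 1.0, n)
    rho = config.slope_corr
    map_slope = config.map_slope_mean + config.map_slope_sd * z1
    sbp_slope = config.sbp_slope_mean + config.sbp_slope_sd * (
        rho * z1 + math.sqrt(1.0 - rho ** 2) * z2)

    per_sub = pd.DataFrame(
        {"map0": map0, "sbp0": sbp0, "map_slope": map_slope,
         "sbp_slope": sbp_slope}, index=subs.index)
    v = visits.merge(per_sub, left_on="subject_id", right_index=True, how="left")
    if v[["map0"]].isna().any().any():
        missing = v.loc[v["map0"].isna(), "subject_id"].unique()
        raise ValueError(f"visits reference unknown subjects: {missing[:5]}")

    t = v["time_in_study"].to_numpy()
    map_true = v["map0"].to_numpy() + v["map_slope"].to_numpy() * t
    sbp_true = v["sbp0"].to_numpy() + v["sbp_slope"].to_numpy() * t
    dbp_true = (3.0 * map_true - sbp_true) / 2.0

    out = visits.copy()
    m = len(out)
    noise = lambda: rng.normal(0.0, config.reading_noise_sd, m)  # noqa: E731
    out["sbp_reading_1"] = np.clip(sbp_true + noise(), 5.0, None)
    out["sbp_reading_2"] = np.clip(sbp_true + noise(), 5.0, None)
    out["dbp_reading_1"] = np.clip(dbp_true + noise(), 5.0, None)
    out["dbp_reading_2"] = np.clip(dbp_true + noise(), 5.0, None)
    return out


def simulate_brainage_outcome(subjects: pd.DataFrame, visits: pd.DataFrame,
                              config: SimulationConfig,
                              seed: int | None = None) -> pd.DataFrame:
    """Add a ``brainage_true`` column generated from the mixed-model equation.

    BrainAGE_ij = intercept + b_map (MAP_ij - center) + b_time t_ij
    + b_cohort 1[OA] + b_sex 1[female] + u_i + e_ij with u_i ~ N(0, s_u^2)
    per subject and e_ij ~ N(0, s_e^2) per visit. MAP is computed from the
    averaged readings, exactly as the analysis will see it.
    """
    config.validate()
    if visits[["sbp_reading_1", "dbp_reading_1"]].isna().any().any():
        raise ValueError("blood pressure must be simulated before the outcome "
                         "(run simulate_bp first)")
    rng = stage_rng(config.seed if seed is None else seed, "outcome")

    sbp = bp_metrics.average_readings(visits["sbp_reading_1"].to_numpy(),
                                      visits["sbp_reading_2"].to_numpy())
    dbp = bp_metrics.average_readings(visits["dbp_reading_1"].to_numpy(),
                                      visits["dbp_reading_2"].to_numpy())
    map_ = bp_metrics.mean_arterial_pressure(sbp, dbp)

    subs = subjects.set_index("subject_id")
    is_oa = (subs.loc[visits["subject_id"], "cohort"] == "OA").to_numpy()
    female = (subs.loc[visits["subject_id"], "sex"] == "female").to_numpy()

    linpred = (config.outcome_intercept
               + config.beta_map * (map_ - config.map_center)
               + config.beta_time * visits["time_in_study"].to_numpy()
               + config.beta_cohort * is_oa
               + config.beta_sex * female)
    u = pd.Series(rng.normal(0.0, config.random_intercept_sd, len(subs)),
                  index=subs.index)
    e = rng.normal(0.0, config.residual_sd, len(visits))
    out = visits.copy()
    out["brainage_true"] = linpred + u.loc[visits["subject_id"]].to_numpy() + e
    return out


def simulate_features(visits: pd.DataFrame, config: SimulationConfig,
                      seed: int | None = None) -> FeatureMatrix:
    """Generate per-scan feature vectors with a recoverable age signal.

    Features are a linear mix of latent factors plus scanner offset plus
    isotropic noise. The first latent factor is the scan's latent brain age
    (chronological age plus the ``brainage_true`` deviation when present);
    the remaining ``n_latent - 1`` factors are age-independent nuisance
    structure. Scans from waves at or beyond ``scanner_change_wave`` get a
    constant per-feature offset of ``scanner_effect_size``, emulating a
    scanner change mid-study.
    """
    config.validate()
    if config.feature_dim < config.n_latent:
        raise ConfigurationError("feature_dim: must be at least n_latent")
    scans = visits.loc[visits["scan_available"]].copy()
    if scans.empty:
        raise ValueError("no scans available in the visit table")
    rng = stage_rng(config.seed if seed is None else seed, "features")

    scan_id = scans["subject_id"] + "_w" + scans["wave"].astype(str)
    n, k, p = len(scans), config.n_latent, config.feature_dim

    latent_age = scans["age_at_visit"].to_numpy(dtype=float)
    if "brainage_true" in scans.columns:
        latent_age = latent_age + scans["brainage_true"].to_numpy(dtype=float)
    latent = np.empty((n, k))
    latent[:, 0] = latent_age
    if k > 1:
        latent[:, 1:] = rng.normal(0.0, config.latent_nuisance_sd, (n, k - 1))

    loadings = rng.normal(0.0, 1.0, (k, p)) / np.sqrt(k)
    scanner_b = (scans["wave"] >= config.scanner_change_wave).to_numpy()
    features = (latent @ loadings
                + np.where(scanner_b, config.scanner_effect_size, 0.0)[:, None]
                + rng.normal(0.0, config.feature_noise_sd, (n, p)))

    idx = pd.Index(scan_id, name="scan_id")
    return FeatureMatrix(
        data=pd.DataFrame(features, index=idx,
                          columns=[f"f{j:04d}" for j in range(p)]),
        scanner=pd.Series(np.where(scanner_b, "scanner_b", "scanner_a"),
                          index=idx, name="scanner"),
        subject_id=pd.Series(scans["subject_id"].to_numpy(), index=idx,
                             name="subject_id"),
        age=pd.Series(scans["age_at_visit"].to_numpy(), index=idx, name="age"),
    )


def simulate_cohort(config: SimulationConfig, seed: int | None = None,
                    with_features: bool = True
                    ) -> tuple[pd.DataFrame, pd.DataFrame, FeatureMatrix | None]:
    """Run design -> blood pressure -> outcome (-> features) in one call."""
    subjects, visits = build_design(config, seed)
    visits = simulate_bp(subjects, visits, config, seed)
    visits = simulate_brainage_outcome(subjects, visits, config, seed)
    fm = simulate_features(visits, config, seed) if with_features else None
    return subjects, visits, fm
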