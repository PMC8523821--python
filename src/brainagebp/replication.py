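"""Study-scale replication experiments.

These functions re-run the generative model at the published design size
(686 subjects, up to four waves) and summarise what the analysis recovers:
the MAP fixed effect of the random-intercept mixed model over many
simulated replicates, the mean within-subject annual MAP slope, and the
type-I error of the Wald test under a null generator. They are the
computational backbone of the acceptance checks and the worked examples.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import association, bp, synthetic
from .config import SimulationConfig


def _analysis_table(cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    subjects, visits = synthetic.build_design(cfg, seed)
    visits = synthetic.simulate_bp(subjects, visits, cfg, seed)
    visits = synthetic.simulate_brainage_outcome(subjects, visits, cfg, seed)
    return association.build_analysis_table(subjects, bp.add_bp_columns(visits))


def recover_map_coefficient(n_replicates: int = 200, seed: int = 0,
                            config: SimulationConfig | None = None) -> dict:
    """Simulate-and-refit replicates of the base mixed model.

    Each replicate draws a fresh cohort from the generating equation
    (default: the published base-model coefficients and variance
    components), fits the random-intercept model by ML, and records the MAP
    coefficient. Returns the replicate mean, its Monte-Carlo standard error,
    the generating value and the mean number of observations per replicate.
    """
    cfg = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    estimates, n_obs = [], []
    for rs in rep_seeds:
        table = _analysis_table(cfg, int(rs))
        fit = association.fit_lmm(association.MixedModelSpec(), table)
        estimates.append(fit.coef("centered_map"))
        n_obs.append(fit.n_obs)
    estimates = np.asarray(estimates)
    return {
        "mean": float(estimates.mean()),
        "mc_se": float(estimates.std(ddof=1) / np.sqrt(n_replicates)),
        "generating": cfg.beta_map,
        "n_replicates": n_replicates,
        "mean_n_obs": float(np.mean(n_obs)),
    }


def mean_map_slope(seed: int = 0,
                   config: SimulationConfig | None = None) -> dict:
    """Per-subject OLS slopes of derived MAP on time in study, averaged.

    Uses the default cohort size (686 subjects); subjects with a single
    visit cannot contribute a slope and are skipped.
    """
    cfg = config if config is not None else SimulationConfig()
    subjects, visits = synthetic.build_design(cfg, seed)
    visits = synthetic.simulate_bp(subjects, visits, cfg, seed)
    vb = bp.add_bp_columns(visits)
    slopes = []
    for _, g in vb.groupby("subject_id"):
        if len(g) >= 2:
            slopes.append(np.polyfit(g["time_in_study"].to_numpy(),
                                     g["map"].to_numpy(), 1)[0])
    slopes = np.asarray(slopes)
    return {
        "mean": float(slopes.mean()),
        "se": float(slopes.std(ddof=1) / np.sqrt(len(slopes))),
        "generating": cfg.map_slope_mean,
        "n_subjects": int(len(slopes)),
    }


def type_one_error(n_replicates: int = 500, seed: int = 0,
                   n_ma: int = 75, n_oa: int = 75,
                   alpha: float = 0.05) -> dict:
    """Wald-test rejection rate for the MAP coefficient under a null
    generator (beta_MAP = 0)."""
    cfg = dataclasses.replace(SimulationConfig(n_ma=n_ma, n_oa=n_oa),
                              beta_map=0.0)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    rejections = 0
    for rs in rep_seeds:
        table = _analysis_table(cfg, int(rs))
        fit = association.fit_lmm(association.MixedModelSpec(), table)
        rejections += bool(
            fit.coefficients.loc["centered_map", "p"] < alpha)
    return {
        "rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "nominal": alpha,
    }
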