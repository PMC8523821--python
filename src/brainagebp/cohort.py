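"""Cohort eligibility filtering and EM-based covariate imputation.

``apply_eligibility`` reproduces the study's participant flow: keep subjects
with at least two brain scans, drop subjects with a neurological exclusion or
an MMSE below 25 at any visit, drop baseline blood-pressure outliers (beyond
3 SD of the per-cohort baseline sample), then drop subjects missing key
baseline covariates. ``em_impute`` completes a covariate table under a
multivariate-normal working model fitted by expectation-maximisation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import bp as bp_metrics

logger = logging.getLogger(__name__)

#: baseline covariates required for the fully adjusted model
DEFAULT_KEY_COVARIATES = (
    "education", "diabetes", "bmi", "smoker", "depression_score",
    "physical_activity", "alcohol_intake", "apoe4",
)


class SchemaError(KeyError):
    """An input table is missing a required column; the message names it."""


@dataclass
class EligibilityStage:
    name: str
    entering: int
    excluded: int


@dataclass
class EligibilityReport:
    """Per-stage accounting of the participant flow."""

    stages: list[EligibilityStage] = field(default_factory=list)
    final_n: dict[str, int] = field(default_factory=dict)

    def add(self, name: str, entering: int, excluded: int) -> None:
        if excluded < 0 or excluded > entering:
            raise ValueError("excluded count must lie in [0, entering]")
        self.stages.append(EligibilityStage(name, entering, excluded))

    @property
    def total_excluded(self) -> int:
        return sum(s.excluded for s in self.stages)

    def to_dict(self) -> dict:
        return {
            "stages": [vars(s) for s in self.stages],
            "final_n": dict(self.final_n),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _require(df: pd.DataFrame, columns: Sequence[str], table: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing required column {col!r}")


def apply_eligibility(
    subjects: pd.DataFrame,
    visits: pd.DataFrame,
    min_scans: int = 2,
    mmse_cutoff: float = 25.0,
    outlier_k: float = 3.0,
    outlier_measure: str = "map",
    per_cohort: bool = True,
    key_covariates: Sequence[str] = DEFAULT_KEY_COVARIATES,
) -> tuple[pd.DataFrame, pd.DataFrame, EligibilityReport]:
    """Apply the eligibility stages in order and report per-stage counts.

    Stages: (1) fewer than ``min_scans`` available scans; (2) neurological
    flag at any visit or MMSE < ``mmse_cutoff`` at any visit; (3) baseline
    blood pressure beyond ``outlier_k`` SD of the (per-cohort) baseline
    sample of remaining subjects; (4) missing key baseline covariates.
    Returns filtered copies of both tables plus the report.
    """
    _require(subjects, ["subject_id", "cohort"], "subject")
    _require(visits, ["subject_id", "wave", "scan_available", "mmse",
                      "neuro_flag", "sbp_reading_1", "sbp_reading_2",
                      "dbp_reading_1", "dbp_reading_2"], "visit")
    report = EligibilityReport()
    keep = subjects.set_index("subject_id")

    # stage 1: minimum number of scans
    n_scans = (visits.loc[visits["scan_available"]]
               .groupby("subject_id").size())
    n_scans = n_scans.reindex(keep.index, fill_value=0)
    drop = n_scans < min_scans
    report.add("fewer_than_min_scans", len(keep), int(drop.sum()))
    keep = keep.loc[~drop]

    # stage 2: neurological exclusion or low MMSE at any visit
    v = visits[visits["subject_id"].isin(keep.index)]
    bad = v.groupby("subject_id").apply(
        lambda g: bool(g["neuro_flag"].any() or (g["mmse"] < mmse_cutoff).any()),
        include_groups=False)
    bad = bad.reindex(keep.index, fill_value=False)
    report.add("neurological_or_mmse", len(keep), int(bad.sum()))
    keep = keep.loc[~bad]

    # stage 3: baseline BP outliers (per cohort by default)
    v = visits[visits["subject_id"].isin(keep.index)]
    baseline = (v.sort_values("wave").groupby("subject_id", as_index=True)
                .first())
    sbp = bp_metrics.average_readings(baseline["sbp_reading_1"],
                                      baseline["sbp_reading_2"])
    dbp = bp_metrics.average_readings(baseline["dbp_reading_1"],
                                      baseline["dbp_reading_2"])
    measure = {"map": bp_metrics.mean_arterial_pressure(sbp, dbp),
               "sbp": sbp, "dbp": dbp}[outlier_measure.lower()]
    measure = pd.Series(np.asarray(measure), index=baseline.index)
    flags = pd.Series(False, index=baseline.index)
    groups = (keep.loc[baseline.index, "cohort"] if per_cohort
              else pd.Series("all", index=baseline.index))
    for _, idx in measure.groupby(groups).groups.items():
        flags.loc[idx] = bp_metrics.flag_bp_outliers(measure.loc[idx], k=outlier_k)
    flags = flags.reindex(keep.index, fill_value=False)
    report.add("bp_outlier", len(keep), int(flags.sum()))
    keep = keep.loc[~flags]

    # stage 4: missing key baseline covariates
    present = [c for c in key_covariates if c in keep.columns]
    missing = keep[present].isna().any(axis=1) if present else \
        pd.Series(False, index=keep.index)
    report.add("missing_key_covariates", len(keep), int(missing.sum()))
    keep = keep.loc[~missing]

    subjects_out = subjects[subjects["subject_id"].isin(keep.index)].copy()
    visits_out = visits[visits["subject_id"].isin(keep.index)].copy()
    report.final_n = (subjects_out.groupby("cohort")["subject_id"]
                      .nunique().to_dict())
    report.final_n["total"] = int(subjects_out["subject_id"].nunique())
    return subjects_out, visits_out, report


# ---------------------------------------------------------------------------
# EM imputation under a multivariate-normal working model


def _em_loglik(X: np.ndarray, obs: np.ndarray, mu: np.ndarray,
               sigma: np.ndarray) -> float:
    """Observed-data log-likelihood, summed over missingness patterns."""
    ll = 0.0
    patterns = {}
    for i in range(X.shape[0]):
        patterns.setdefault(tuple(obs[i]), []).append(i)
    for pat, rows in patterns.items():
        o = np.array(pat)
        if not o.any():
            continue
        mu_o = mu[o]
        s_oo = sigma[np.ix_(o, o)]
        xo = X[np.ix_(rows, o)]
        sign, logdet = np.linalg.slogdet(s_oo)
        if sign <= 0:
            s_oo = s_oo + 1e-10 * np.eye(o.sum())
            sign, logdet = np.linalg.slogdet(s_oo)
        diff = xo - mu_o
        sol = np.linalg.solve(s_oo, diff.T)
        quad = np.einsum("ij,ji->i", diff, sol)
        k = int(o.sum())
        ll += -0.5 * (len(rows) * (k * np.log(2 * np.pi) + logdet) + quad.sum())
    return float(ll)


def em_impute(
    table: pd.DataFrame,
    max_iter: int = 200,
    tol: float = 1e-8,
    binary_cols: Sequence[str] | None = None,
    max_missing_frac: float = 0.10,
) -> pd.DataFrame:
    """Complete missing entries via EM under a multivariate normal model.

    Observed cells are never altered. Missing cells are replaced by their
    conditional means given the row's observed cells under the converged
    (mu, Sigma). Columns listed in ``binary_cols`` (or detected as 0/1) are
    thresholded at 0.5 after imputation. The observed-data log-likelihood is
    non-decreasing across iterations; convergence is declared when its change
    falls below ``tol`` (relative), else after ``max_iter`` (logged).
    """
    numeric = table.select_dtypes(include=[np.number, bool]).columns.tolist()
    if not numeric:
        raise ValueError("no numeric columns to impute")
    X = table[numeric].astype(float).to_numpy().copy()
    obs = ~np.isnan(X)
    n, p = X.shape
    for j, col in enumerate(numeric):
        if not obs[:, j].any():
            raise ValueError(f"column {col!r} is entirely missing")
        frac = 1.0 - obs[:, j].mean()
        if frac > max_missing_frac:
            raise ValueError(
                f"column {col!r} has {frac:.1%} missing, above the "
                f"{max_missing_frac:.0%} cap")

    if binary_cols is None:
        binary_cols = [c for c in numeric
                       if set(np.unique(X[obs[:, numeric.index(c)],
                                          numeric.index(c)])) <= {0.0, 1.0}]

    if obs.all():
        return table.copy()

    # init: observed means, diagonal covariance
    mu = np.array([X[obs[:, j], j].mean() for j in range(p)])
    var = np.array([X[obs[:, j], j].var() + 1e-6 for j in range(p)])
    sigma = np.diag(var)

    Xf = X.copy()
    ll_old = -np.inf
    ll_history: list[float] = []
    converged = False
    patterns: dict[tuple, list[int]] = {}
    for i in range(n):
        patterns.setdefault(tuple(obs[i]), []).append(i)

    for _ in range(max_iter):
        # E-step: conditional means and the conditional covariance correction
        cov_corr = np.zeros((p, p))
        for pat, rows in patterns.items():
            o = np.array(pat)
            m = ~o
            if not m.any():
                continue
            rows = np.asarray(rows)
            if o.any():
                s_oo = sigma[np.ix_(o, o)]
                s_mo = sigma[np.ix_(m, o)]
                try:
                    gain = np.linalg.solve(s_oo, s_mo.T).T
                except np.linalg.LinAlgError:
                    gain = s_mo @ np.linalg.pinv(s_oo)
                cond_mean = mu[m] + (X[np.ix_(rows, o)] - mu[o]) @ gain.T
                cond_cov = sigma[np.ix_(m, m)] - gain @ s_mo.T
            else:
                cond_mean = np.tile(mu[m], (len(rows), 1))
                cond_cov = sigma[np.ix_(m, m)]
            for r_i, r in enumerate(rows):
                Xf[r, m] = cond_mean[r_i]
            cov_corr[np.ix_(m, m)] += len(rows) * cond_cov

        # M-step
        mu = Xf.mean(axis=0)
        centered = Xf - mu
        sigma = (centered.T @ centered + cov_corr) / n
        sigma += 1e-10 * np.eye(p)

        ll = _em_loglik(X, obs, mu, sigma)
        ll_history.append(ll)
        if np.isfinite(ll_old) and ll - ll_old < tol * (1.0 + abs(ll_old)):
            converged = True
            break
        ll_old = ll
    if not converged:
        logger.info("em_impute reached max_iter=%d without meeting tol", max_iter)

    out = table.copy()
    completed = pd.DataFrame(Xf, columns=numeric, index=table.index)
    for j, col in enumerate(numeric):
        vals = completed[col]
        if col in binary_cols:
            vals = (vals >= 0.5).astype(float)
        mask = ~obs[:, j]
        if mask.any():
            col_out = out[col].astype(float)
            col_out[mask] = vals[mask]
            if pd.api.types.is_bool_dtype(table[col]):
                col_out = col_out.astype(bool)
            out[col] = col_out
    out.attrs["em_loglik"] = ll_history
    out.attrs["em_converged"] = converged
    return out
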