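"""Blood-pressure derived measures, classification rules and centering.

All functions are pure and accept scalars or numpy arrays / pandas Series.
Rules follow the study's clinical conventions:

* each visit's SBP/DBP is the mean of two readings;
* mean arterial pressure MAP = (SBP + 2 DBP) / 3;
* hypertensive: SBP > 140 or DBP > 90 (strictly) or on anti-hypertensive
  medication;
* optimal BP: SBP < 115 and DBP < 75 (strictly), i.e. MAP of 90 or below;
* model inputs are centered at 90 (MAP), 114 (SBP), 74 (DBP) mmHg;
* values more than k = 3 sample SDs from the sample mean are outliers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: centering thresholds, mmHg above which each measure enters the models
CENTERS = {"MAP": 90.0, "SBP": 114.0, "DBP": 74.0}

HYPERTENSION_SBP = 140.0
HYPERTENSION_DBP = 90.0
OPTIMAL_SBP = 115.0
OPTIMAL_DBP = 75.0


def _validate_positive(name, value):
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isnan(arr) & (arr <= 0)):
        raise ValueError(f"{name} must be positive (mmHg)")


def average_readings(r1, r2):
    """Arithmetic mean of the two readings taken at a visit (mmHg)."""
    _validate_positive("reading 1", r1)
    _validate_positive("reading 2", r2)
    return (np.asarray(r1, dtype=float) + np.asarray(r2, dtype=float)) / 2.0


def mean_arterial_pressure(sbp, dbp):
    """MAP = 1/3 SBP + 2/3 DBP (mmHg)."""
    return (np.asarray(sbp, dtype=float) + 2.0 * np.asarray(dbp, dtype=float)) / 3.0


def classify_hypertension(sbp, dbp, on_med):
    """True iff SBP > 140 or DBP > 90 (strict) or on anti-hypertensive meds."""
    return ((np.asarray(sbp, dtype=float) > HYPERTENSION_SBP)
            | (np.asarray(dbp, dtype=float) > HYPERTENSION_DBP)
            | np.asarray(on_med, dtype=bool))


def classify_optimal_bp(sbp, dbp):
    """True iff SBP < 115 and DBP < 75 (both strict)."""
    return ((np.asarray(sbp, dtype=float) < OPTIMAL_SBP)
            & (np.asarray(dbp, dtype=float) < OPTIMAL_DBP))


def center_bp(value, measure: str):
    """Subtract the measure's centering threshold (90/114/74 mmHg)."""
    key = measure.upper()
    if key not in CENTERS:
        raise ValueError(f"unknown BP measure {measure!r}; expected one of "
                         f"{sorted(CENTERS)}")
    return np.asarray(value, dtype=float) - CENTERS[key]


def flag_bp_outliers(values, k: float = 3.0) -> np.ndarray:
    """Flag values more than ``k`` sample SDs from the sample mean.

    The mean and SD are computed over the supplied sample itself. A sample
    with zero spread yields no flags (a warning is logged); ``k = inf``
    flags nothing.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < 2:
        logger.warning("outlier flagging on fewer than 2 values; no flags")
        return np.zeros(arr.shape, dtype=bool)
    if math.isinf(k):
        return np.zeros(arr.shape, dtype=bool)
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        logger.warning("all values identical; no outliers flagged")
        return np.zeros(arr.shape, dtype=bool)
    return np.abs(arr - arr.mean()) > k * sd


@dataclass
class BPVisitMeasure:
    """Derived blood-pressure quantities for a single visit."""

    sbp: float
    dbp: float
    map: float
    on_med: bool
    hypertensive: bool
    optimal: bool
    centered_map: float
    centered_sbp: float
    centered_dbp: float

    @classmethod
    def from_readings(cls, sbp_1, sbp_2, dbp_1, dbp_2,
                      on_med: bool = False) -> "BPVisitMeasure":
        sbp = float(average_readings(sbp_1, sbp_2))
        dbp = float(average_readings(dbp_1, dbp_2))
        map_ = float(mean_arterial_pressure(sbp, dbp))
        return cls(
            sbp=sbp, dbp=dbp, map=map_, on_med=bool(on_med),
            hypertensive=bool(classify_hypertension(sbp, dbp, on_med)),
            optimal=bool(classify_optimal_bp(sbp, dbp)),
            centered_map=float(center_bp(map_, "MAP")),
            centered_sbp=float(center_bp(sbp, "SBP")),
            centered_dbp=float(center_bp(dbp, "DBP")),
        )


def add_bp_columns(visits, med_col: str = "on_bp_med"):
    """Append derived BP columns to a visit table with the four readings.

    Adds sbp, dbp, map, hypertensive, optimal, centered_map/sbp/dbp.
    """
    required = ["sbp_reading_1", "sbp_reading_2", "dbp_reading_1",
                "dbp_reading_2"]
    for col in required:
        if col not in visits.columns:
            raise KeyError(f"visit table is missing column {col!r}")
    out = visits.copy()
    out["sbp"] = average_readings(visits["sbp_reading_1"], visits["sbp_reading_2"])
    out["dbp"] = average_readings(visits["dbp_reading_1"], visits["dbp_reading_2"])
    out["map"] = mean_arterial_pressure(out["sbp"], out["dbp"])
    on_med = visits[med_col] if med_col in visits.columns else False
    out["hypertensive"] = classify_hypertension(out["sbp"], out["dbp"], on_med)
    out["optimal"] = classify_optimal_bp(out["sbp"], out["dbp"])
    for measure in ("map", "sbp", "dbp"):
        out[f"centered_{measure}"] = center_bp(out[measure], measure)
    return out
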