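"""Longitudinal association analysis and summary-statistic inference.

The central model is a random-intercept linear mixed model of BrainAGE on a
centered blood-pressure measure, with age decomposed into time-in-study
(years from baseline, within-person change) and cohort (baseline age group,
between-person difference), plus sex; the adjusted model adds education,
diabetes, BMI, smoking, depression, physical activity, alcohol intake,
APOE e4 and hypertension/medication terms. Fitting is by maximum likelihood
(so nested-model likelihood comparisons are valid), with an REML option.

Also provided: Welch's t-test and Pearson's chi-square directly from printed
summary statistics (for comparisons against published cohort tables), and
the conversion of a coefficient in years per mmHg to days of brain ageing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

BASE_TERMS = ("time_in_study", "cohort_oa", "female")
ADJUSTED_EXTRA_TERMS = (
    "education", "diabetes", "bmi", "smoker", "depression_score",
    "physical_activity", "alcohol_intake", "apoe4",
    "unmedicated_hypertension", "on_bp_med",
)


@dataclass
class MixedModelSpec:
    """Specification of one mixed-effects analysis."""

    outcome: str = "brainage"
    bp_measure: str = "map"                  # map | sbp | dbp
    model: str = "base"                      # base | adjusted
    extra_terms: Sequence[str] = ()
    interactions: Sequence[str] = ()         # terms interacted with the BP term
    method: str = "ml"                       # ml | reml
    random_bp_slope: bool = False
    subset: str | None = None                # pandas query string

    @property
    def bp_term(self) -> str:
        return f"centered_{self.bp_measure.lower()}"

    def fixed_terms(self) -> list[str]:
        terms = [self.bp_term, *BASE_TERMS]
        if self.model == "adjusted":
            terms += list(ADJUSTED_EXTRA_TERMS)
        elif self.model != "base":
            raise ValueError("model must be 'base' or 'adjusted'")
        terms += [t for t in self.extra_terms if t not in terms]
        terms += [f"{self.bp_term}:{t}" for t in self.interactions]
        return terms

    def formula(self) -> str:
        return f"{self.outcome} ~ " + " + ".join(self.fixed_terms())


@dataclass
class MixedModelFit:
    """Fixed effects, variance components and fit statistics of one model."""

    spec: MixedModelSpec
    coefficients: pd.DataFrame     # estimate, se, ci_low, ci_high, p per term
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_subjects: int
    loglik: float
    aic: float
    bic: float
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def to_dict(self) -> dict:
        return {
            "formula": self.spec.formula(),
            "method": self.spec.method,
            "coefficients": self.coefficients.reset_index()
            .rename(columns={"index": "term"}).to_dict(orient="records"),
            "random_intercept_sd": self.random_intercept_sd,
            "residual_sd": self.residual_sd,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "warnings": self.warnings,
        }


def build_analysis_table(subjects: pd.DataFrame,
                         visits_bp: pd.DataFrame,
                         estimates: pd.DataFrame | None = None,
                         outcome_col: str = "brainage_true") -> pd.DataFrame:
    """Merge subject covariates, per-visit BP and the outcome into one
    long-format table ready for :func:`fit_lmm`.

    When an estimate frame (from the BrainAGE pipeline) is given, its
    ``brainage`` column becomes the outcome; otherwise ``outcome_col`` from
    the visit table is used (renamed to ``brainage``).
    """
    df = visits_bp.merge(subjects, on="subject_id", how="inner")
    df["cohort_oa"] = (df["cohort"] == "OA").astype(float)
    df["female"] = (df["sex"] == "female").astype(float)
    for col in ("apoe4", "smoker", "diabetes", "on_bp_med", "hypertensive"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    if "hypertensive" in df.columns and "on_bp_med" in df.columns:
        df["unmedicated_hypertension"] = (
            (df["hypertensive"] > 0) & (df["on_bp_med"] == 0)).astype(float)
    if estimates is not None:
        scan_id = df["subject_id"] + "_w" + df["wave"].astype(str)
        df["brainage"] = estimates["brainage"].reindex(scan_id).to_numpy()
        df = df.dropna(subset=["brainage"])
    elif outcome_col in df.columns:
        df = df.rename(columns={outcome_col: "brainage"})
    else:
        raise KeyError(f"no outcome available: column {outcome_col!r} absent "
                       "and no estimate frame supplied")
    return df


def fit_lmm(spec: MixedModelSpec, data: pd.DataFrame) -> MixedModelFit:
    """Fit the specified random-intercept mixed model.

    Rows with missing values in the model variables are dropped (complete-case
    within the model). Non-convergence and singular random effects are
    reported on the returned fit, never silently discarded.
    """
    df = data.query(spec.subset) if spec.subset else data
    base_terms = [t for t in spec.fixed_terms() if ":" not in t]
    needed = [spec.outcome, "subject_id", *base_terms]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise KeyError(f"analysis table is missing column(s) {missing_cols}")
    df = df.dropna(subset=needed)
    if df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")

    # constant columns (e.g. the cohort term in a cohort-stratified subset)
    # carry no information and make the design singular; drop them
    dropped = [t for t in base_terms if df[t].nunique() <= 1]
    terms = [t for t in spec.fixed_terms() if t not in dropped
             and not any(d in t.split(":") for d in dropped)]
    formula = f"{spec.outcome} ~ " + " + ".join(terms)

    re_formula = f"1 + {spec.bp_term}" if spec.random_bp_slope else "1"
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=df["subject_id"],
                            re_formula=re_formula)
        result = model.fit(reml=(spec.method.lower() == "reml"))
        caught = [str(w.message) for w in wlist
                  if issubclass(w.category, (ConvergenceWarning, UserWarning))]
    if dropped:
        caught.append(f"dropped constant term(s) {dropped} from the design")

    fe_names = [n for n in result.fe_params.index]
    ci = result.conf_int().loc[fe_names]
    coeffs = pd.DataFrame({
        "estimate": result.fe_params,
        "se": result.bse.loc[fe_names],
        "ci_low": ci[0],
        "ci_high": ci[1],
        "p": result.pvalues.loc[fe_names],
    })
    converged = bool(result.converged) and not any(
        "did not converge" in w.lower() for w in caught)
    return MixedModelFit(
        spec=spec,
        coefficients=coeffs,
        random_intercept_sd=float(np.sqrt(result.cov_re.iloc[0, 0])),
        residual_sd=float(np.sqrt(result.scale)),
        n_obs=int(result.nobs),
        n_subjects=int(df["subject_id"].nunique()),
        loglik=float(result.llf),
        aic=float(result.aic),
        bic=float(result.bic),
        converged=converged,
        warnings=caught,
    )


def likelihood_ratio_test(fit_null: MixedModelFit,
                          fit_alt: MixedModelFit) -> dict[str, float]:
    """LR test of nested ML fits (df = difference in fixed-effect count)."""
    if fit_null.spec.method != "ml" or fit_alt.spec.method != "ml":
        raise ValueError("likelihood-ratio comparison requires ML fits")
    if fit_null.n_obs != fit_alt.n_obs:
        raise ValueError("fits use different rows; refit on identical data")
    lr = 2.0 * (fit_alt.loglik - fit_null.loglik)
    df = len(fit_alt.coefficients) - len(fit_null.coefficients)
    if df <= 0:
        raise ValueError("alternative model must have more fixed effects")
    return {"lr": lr, "df": df, "p": float(stats.chi2.sf(max(lr, 0.0), df))}


# ---------------------------------------------------------------------------
# reporting conversions and summary-statistic inference


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def coef_to_days(coef: float, delta: float = 1.0,
                 days_per_year: float = 365.25,
                 sig_figs: int | None = 3) -> float:
    """Convert a coefficient in years/mmHg into days per ``delta`` mmHg.

    With the default 3-significant-figure rounding this matches the
    convention used when reporting brain-age differences in days.
    """
    if not (math.isfinite(coef) and math.isfinite(delta)):
        raise ValueError("inputs must be finite")
    days = coef * delta * days_per_year
    return round_sig(days, sig_figs) if sig_figs else days


@dataclass
class GroupSummary:
    """Summary statistics (n, mean, SD) of one group for one measure."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(n=len(arr), mean=float(arr.mean()),
                   sd=float(arr.std(ddof=1)))


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary,
                         pooled: bool = False) -> dict[str, float]:
    """Two-sample t-test from summary statistics.

    Default is Welch's unequal-variance form with Welch-Satterthwaite
    degrees of freedom; ``pooled=True`` gives the classical equal-variance
    test. Returns t, df and the two-sided p-value.
    """
    if g1.sd <= 0 or g2.sd <= 0:
        raise ValueError("SDs must be positive for a t-test")
    v1, v2 = g1.sd ** 2 / g1.n, g2.sd ** 2 / g2.n
    if pooled:
        sp2 = (((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2)
               / (g1.n + g2.n - 2))
        se = math.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
        df = g1.n + g2.n - 2
    else:
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    t = (g1.mean - g2.mean) / se
    return {"t": t, "df": df, "p": float(2.0 * stats.t.sf(abs(t), df))}


def chisq_from_counts(table) -> dict[str, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(arr, correction=False)
    if (res.expected_freq <= 0).any():
        raise ValueError("expected counts must be positive")
    return {"chi2": float(res.statistic), "df": int(res.dof),
            "p": float(res.pvalue)}
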