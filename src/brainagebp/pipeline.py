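"""Pipeline orchestration: simulate -> BP metrics -> filter -> BrainAGE ->
association -> report, with every artifact stamped by seed and config hash.

All randomness flows from the single top-level seed; rerunning a pipeline
with the same configuration and seed regenerates byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import association, bp, brainage, cohort, synthetic
from .config import SimulationConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    outdir: str = "pipeline_out"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    pca_k: float | int = 0.95
    kernel: str = "linear"
    rvr_tol: float = 1e-6
    measures: Sequence[str] = ("map", "sbp", "dbp")
    models: Sequence[str] = ("base", "adjusted")
    stratify: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["measures"] = list(self.measures)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = dict(d)
        if "sim" in kwargs:
            kwargs["sim"] = SimulationConfig.from_dict(kwargs["sim"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> str:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return a manifest of artifacts.

    Any stage failure raises with the stage name; artifacts written before
    the failure are left in place for inspection.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "artifacts": {},
        "timings_s": {},
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        subjects, visits = synthetic.build_design(sim, config.seed)
        visits = synthetic.simulate_bp(subjects, visits, sim, config.seed)
        visits = synthetic.simulate_brainage_outcome(subjects, visits, sim,
                                                     config.seed)
        fm = synthetic.simulate_features(visits, sim, config.seed)
        manifest["artifacts"]["subjects.tsv"] = _write_tsv(
            subjects, outdir / "subjects.tsv")
        fm.to_tsv(outdir / "features.tsv")
        manifest["artifacts"]["features.tsv"] = hashlib.sha256(
            (outdir / "features.tsv").read_bytes()).hexdigest()[:12]
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "bp_metrics"
        t0 = time.perf_counter()
        visits = bp.add_bp_columns(visits)
        manifest["artifacts"]["visits.tsv"] = _write_tsv(
            visits, outdir / "visits.tsv")
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "filter"
        t0 = time.perf_counter()
        subjects_f, visits_f, report = cohort.apply_eligibility(subjects, visits)
        report.to_json(outdir / "eligibility.json")
        manifest["artifacts"]["eligibility.json"] = "-"
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "brainage"
        t0 = time.perf_counter()
        keep_scans = fm.subject_id.isin(subjects_f["subject_id"])
        fm_f = fm.subset(keep_scans)
        fm_o = brainage.orthogonalize_scanner(fm_f)
        estimates = brainage.estimate_brainage_loso(
            fm_o, pca_k=config.pca_k, kernel=config.kernel, tol=config.rvr_tol)
        estimates = brainage.bias_correct(estimates)
        diagnostics = brainage.brainage_diagnostics(estimates)
        manifest["artifacts"]["estimates.tsv"] = _write_tsv(
            estimates, outdir / "estimates.tsv", index=True)
        manifest["brainage_diagnostics"] = diagnostics
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "associate"
        t0 = time.perf_counter()
        table = association.build_analysis_table(subjects_f, visits_f, estimates)
        fits = []
        for measure in config.measures:
            for model in config.models:
                spec = association.MixedModelSpec(
                    bp_measure=measure, model=model, subset=config.stratify)
                fits.append(association.fit_lmm(spec, table))
        with open(outdir / "fits.json", "w") as fh:
            json.dump([f.to_dict() for f in fits], fh, indent=2)
        manifest["artifacts"]["fits.json"] = "-"
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "report"
        t0 = time.perf_counter()
        table1, table2 = render_tables(subjects_f, visits_f, fits)
        manifest["artifacts"]["table1.tsv"] = _write_tsv(table1,
                                                         outdir / "table1.tsv")
        manifest["artifacts"]["table2.tsv"] = _write_tsv(table2,
                                                         outdir / "table2.tsv")
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


CONTINUOUS_ROWS = (
    ("baseline_age", "Age, years"),
    ("education", "Education, years"),
    ("bmi", "BMI, kg/m2"),
    ("physical_activity", "Physical activity, METs/day"),
)
CATEGORICAL_ROWS = (
    ("smoker", "Smoker"),
    ("diabetes", "Diabetes"),
    ("apoe4", "APOE e4"),
)


def render_tables(subjects: pd.DataFrame, visits_bp: pd.DataFrame,
                  fits: Sequence[association.MixedModelFit]
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build demographic-summary and model-coefficient tables.

    The first table reports mean (SD) for continuous measures and n (%) for
    categorical ones, by whole sample and by cohort, with Welch t or Pearson
    chi-square comparisons; baseline BP columns are merged in from the visit
    table. The second stacks coefficient (95% CI) columns per fitted model
    plus variance components and fit statistics.
    """
    baseline = (visits_bp.sort_values("wave").groupby("subject_id").first()
                .reset_index())
    subj = subjects.merge(
        baseline[["subject_id", "sbp", "dbp", "map", "hypertensive",
                  "on_bp_med"]],
        on="subject_id", how="left")

    rows = []
    groups = {"whole": subj, "MA": subj[subj["cohort"] == "MA"],
              "OA": subj[subj["cohort"] == "OA"]}
    cont = list(CONTINUOUS_ROWS) + [("sbp", "SBP, mmHg"), ("dbp", "DBP, mmHg"),
                                    ("map", "MAP, mmHg")]
    for col, label in cont:
        if col not in subj.columns:
            continue
        cells = {}
        for gname, g in groups.items():
            vals = g[col].dropna()
            if len(vals) == 0:
                logger.warning("empty stratum for %s in %s; row cell omitted",
                               col, gname)
                cells[gname] = ""
                continue
            cells[gname] = f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})"
        try:
            t = association.welch_t_from_summary(
                association.GroupSummary.from_values(groups["MA"][col].dropna()),
                association.GroupSummary.from_values(groups["OA"][col].dropna()))
            test = f"t={t['t']:.2f} (p={t['p']:.3g})"
        except ValueError:
            test = ""
        rows.append({"measure": label, "type": "continuous", **cells,
                     "test": test})
    cat = list(CATEGORICAL_ROWS) + [("hypertensive", "Hypertension"),
                                    ("on_bp_med", "BP medication")]
    for col, label in cat:
        if col not in subj.columns:
            continue
        cells = {}
        for gname, g in groups.items():
            vals = g[col].dropna().astype(bool)
            n_pos = int(vals.sum())
            pct = 100.0 * n_pos / len(vals) if len(vals) else float("nan")
            cells[gname] = f"{n_pos} ({pct:.2f}%)"
        counts = [[int(groups[g][col].dropna().astype(bool).sum()),
                   int((~groups[g][col].dropna().astype(bool)).sum())]
                  for g in ("MA", "OA")]
        try:
            c = association.chisq_from_counts(counts)
            test = f"chi2={c['chi2']:.2f} (p={c['p']:.3g})"
        except ValueError:
            test = ""
        rows.append({"measure": label, "type": "categorical", **cells,
                     "test": test})
    table1 = pd.DataFrame(rows)

    t2_rows: dict[str, dict] = {}
    colnames = []
    for fit in fits:
        cname = f"{fit.spec.bp_measure}_{fit.spec.model}"
        colnames.append(cname)
        for term, row in fit.coefficients.iterrows():
            t2_rows.setdefault(term, {})[cname] = (
                f"{row['estimate']:.3f} ({row['ci_low']:.3f}, "
                f"{row['ci_high']:.3f})")
        t2_rows.setdefault("random_intercept_sd", {})[cname] = \
            f"{fit.random_intercept_sd:.3f}"
        t2_rows.setdefault("residual_sd", {})[cname] = f"{fit.residual_sd:.3f}"
        t2_rows.setdefault("n_obs", {})[cname] = str(fit.n_obs)
        t2_rows.setdefault("loglik", {})[cname] = f"{fit.loglik:.3f}"
        t2_rows.setdefault("aic", {})[cname] = f"{fit.aic:.3f}"
        t2_rows.setdefault("bic", {})[cname] = f"{fit.bic:.3f}"
    table2 = pd.DataFrame(t2_rows).T.reindex(columns=colnames)
    table2.insert(0, "term", table2.index)
    table2 = table2.reset_index(drop=True)
    return table1, table2
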