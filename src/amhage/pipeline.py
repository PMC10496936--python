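"""Config-driven end-to-end analysis: load or simulate two cohorts, filter,
fit the power model per group, predict menopause ages, and export a table and
decline curves.

The run is fully deterministic given the config: every stochastic stage
(cohort generation, bootstrap) is seeded from values stored in the config, and
the report carries a SHA-256 hash of the canonicalized config for provenance.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from importlib import metadata as _im
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model as mdl
from .cohort import (
    Cohort,
    CohortSummary,
    EligibilityCriteria,
    ExclusionLog,
    apply_eligibility,
    read_cohort,
    study_criteria,
    summarize,
    write_cohort,
)
from .errors import PipelineStageError, UsageError
from .simulate import GenParams, default_params, generate_cohort, sidecar_metadata_text

log = logging.getLogger("amhage.pipeline")

try:
    __version__ = _im.version("amhage")
except _im.PackageNotFoundError:  # pragma: no cover - editable corner case
    __version__ = "unknown"


@dataclass(frozen=True)
class BootstrapConfig:
    enabled: bool = False
    n_boot: int = 1000
    level: float = 0.95
    seed: int = 0


@dataclass(frozen=True)
class CurveConfig:
    age_start: float = 30.0
    age_end: float = 55.0
    n_points: int = 51


@dataclass(frozen=True)
class GroupConfig:
    """One group's input: either a CSV path or generator parameters."""

    group: str
    csv_path: str | None = None
    gen_params: GenParams | None = None
    eligibility: EligibilityCriteria | None = None

    def __post_init__(self):
        if (self.csv_path is None) == (self.gen_params is None):
            raise UsageError(
                f"group {self.group!r}: configure exactly one of csv_path or gen_params"
            )


@dataclass(frozen=True)
class AnalysisConfig:
    groups: tuple[GroupConfig, GroupConfig]
    cutoff: float = mdl.DEFAULT_CUTOFF_NG_ML
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    curve: CurveConfig = field(default_factory=CurveConfig)

    def __post_init__(self):
        if len(self.groups) != 2:
            raise UsageError(f"exactly two groups must be configured, got {len(self.groups)}")
        if self.groups[0].group == self.groups[1].group:
            raise UsageError("the two configured groups must have distinct labels")
        if self.cutoff <= 0:
            raise UsageError(f"cutoff must be > 0 ng/mL, got {self.cutoff}")

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        groups = []
        for gd in d["groups"]:
            gp = None
            if "gen_params" in gd and gd["gen_params"] is not None:
                gen = dict(gd["gen_params"])
                base = default_params(gd["group"])
                for k in ("age_range", "amh_range", "bmi_range"):
                    if k in gen:
                        gen[k] = tuple(gen[k])
                gp = GenParams(**{**base.__dict__, **gen, "group": gd["group"]})
            elig = None
            ed = gd.get("eligibility")
            if ed == "study":
                elig = study_criteria(gd["group"])
            elif isinstance(ed, dict):
                for k in ("age_range", "bmi_range", "fsh_range", "cycle_length_range"):
                    if ed.get(k) is not None:
                        ed[k] = tuple(ed[k])
                if ed.get("required_menstrual_status") is not None:
                    ed["required_menstrual_status"] = frozenset(ed["required_menstrual_status"])
                elig = EligibilityCriteria(group=gd["group"], **ed)
            groups.append(
                GroupConfig(
                    group=gd["group"],
                    csv_path=gd.get("csv_path"),
                    gen_params=gp,
                    eligibility=elig,
                )
            )
        boot = BootstrapConfig(**d.get("bootstrap", {}))
        curve = CurveConfig(**d.get("curve", {}))
        return cls(
            groups=tuple(groups),
            cutoff=float(d.get("cutoff", mdl.DEFAULT_CUTOFF_NG_ML)),
            bootstrap=boot,
            curve=curve,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        groups = []
        for g in self.groups:
            gd: dict = {"group": g.group, "csv_path": g.csv_path}
            if g.gen_params is not None:
                gd["gen_params"] = {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in g.gen_params.__dict__.items()
                }
            if g.eligibility is not None:
                e = g.eligibility
                gd["eligibility"] = {
                    "age_range": list(e.age_range) if e.age_range else None,
                    "bmi_range": list(e.bmi_range) if e.bmi_range else None,
                    "fsh_range": list(e.fsh_range) if e.fsh_range else None,
                    "cycle_length_range": list(e.cycle_length_range)
                    if e.cycle_length_range
                    else None,
                    "required_menstrual_status": sorted(e.required_menstrual_status)
                    if e.required_menstrual_status
                    else None,
                }
            groups.append(gd)
        return {
            "groups": groups,
            "cutoff": self.cutoff,
            "bootstrap": self.bootstrap.__dict__,
            "curve": self.curve.__dict__,
        }

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass(frozen=True)
class GroupResult:
    group: str
    n_input: int
    n_kept: int
    exclusions: ExclusionLog
    cohort: Cohort
    summary: CohortSummary
    fit: mdl.PowerFit
    prediction: mdl.MenopausePrediction
    curve: mdl.DeclineCurve


@dataclass(frozen=True)
class Report:
    """Everything a run produced, with provenance; every number is a stage output."""

    groups: tuple[GroupResult, GroupResult]
    comparison: mdl.DeclineComparison
    config: AnalysisConfig
    config_hash: str
    version: str

    def group_result(self, group: str) -> GroupResult:
        for g in self.groups:
            if g.group == group:
                return g
        raise UsageError(f"no result for group {group!r}")


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc
    log.info("stage=%s elapsed=%.3fs", name, time.perf_counter() - t0)
    return out


def _load_group(gc: GroupConfig) -> Cohort:
    if gc.csv_path is not None:
        path = Path(gc.csv_path)
        if not path.exists():
            raise FileNotFoundError(f"cohort CSV not found: {path}")
        return read_cohort(path, gc.group)
    return generate_cohort(gc.gen_params)


def run_analysis(config: AnalysisConfig) -> Report:
    """Execute load/generate → filter → summarize → fit → predict → curves → compare."""
    results: list[GroupResult] = []
    for gc in config.groups:
        cohort = _stage(f"load[{gc.group}]", _load_group, gc)
        n_in = len(cohort)
        if gc.eligibility is not None:
            cohort, exclusions = _stage(
                f"filter[{gc.group}]", apply_eligibility, cohort, gc.eligibility
            )
        else:
            exclusions = ExclusionLog(records=())
        log.info("stage=filter[%s] n_in=%d n_out=%d", gc.group, n_in, len(cohort))
        summary = _stage(f"summarize[{gc.group}]", summarize, cohort)
        fit = _stage(
            f"fit[{gc.group}]", mdl.fit_power_model, cohort.ages(), cohort.amh(), gc.group
        )
        if config.bootstrap.enabled:
            prediction = _stage(
                f"predict[{gc.group}]",
                mdl.bootstrap_menopause_ci,
                cohort.ages(),
                cohort.amh(),
                gc.group,
                config.cutoff,
                config.bootstrap.n_boot,
                config.bootstrap.level,
                config.bootstrap.seed,
            )
        else:
            prediction = _stage(
                f"predict[{gc.group}]", mdl.predict_menopause_age, fit, config.cutoff
            )
        curve = _stage(
            f"curve[{gc.group}]",
            mdl.decline_curve,
            fit,
            config.curve.age_start,
            config.curve.age_end,
            config.curve.n_points,
        )
        results.append(
            GroupResult(
                group=gc.group,
                n_input=n_in,
                n_kept=len(cohort),
                exclusions=exclusions,
                cohort=cohort,
                summary=summary,
                fit=fit,
                prediction=prediction,
                curve=curve,
            )
        )
    grid = np.linspace(config.curve.age_start, config.curve.age_end, config.curve.n_points)
    comparison = _stage("compare", mdl.compare_decline, results[0].fit, results[1].fit, grid)
    return Report(
        groups=(results[0], results[1]),
        comparison=comparison,
        config=config,
        config_hash=config.config_hash(),
        version=__version__,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = (
    "group",
    "log_beta0",
    "beta0",
    "beta1",
    "cutoff",
    "predicted_menopause_age",
    "ci_low",
    "ci_high",
)


def report_table_frame(report: Report) -> pd.DataFrame:
    """Coefficients at 2 d.p., ages at 1 d.p.; CI columns blank when absent."""
    rows = []
    for g in report.groups:
        p = g.prediction
        rows.append(
            {
                "group": g.group,
                "log_beta0": f"{g.fit.log_beta0:.2f}",
                "beta0": f"{g.fit.beta0:.2f}",
                "beta1": f"{g.fit.beta1:.2f}",
                "cutoff": f"{p.cutoff:g}",
                "predicted_menopause_age": f"{p.predicted_age:.1f}",
                "ci_low": "" if p.ci_low is None else f"{p.ci_low:.1f}",
                "ci_high": "" if p.ci_high is None else f"{p.ci_high:.1f}",
            }
        )
    return pd.DataFrame(rows, columns=list(_TABLE_COLUMNS))


def render_table(report: Report) -> tuple[str, str]:
    """Return (csv_text, aligned_text) for the per-group results table."""
    df = report_table_frame(report)
    buf = StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue(), df.to_string(index=False)


def render_decline_curves(report: Report, out_dir: str | Path, plot: bool = False) -> list[Path]:
    """Write one (age, amh, rate) CSV per group; optionally a PNG per group.

    Plotting is a thin layer over the exported CSVs and needs matplotlib only
    when requested.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for g in report.groups:
        path = out_dir / f"decline_curve_{g.group}.csv"
        g.curve.to_frame().to_csv(path, index=False)
        paths.append(path)
        if plot:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            df = pd.read_csv(path)
            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.plot(df["age"], df["amh"])
            ax.set_xlabel("age (years)")
            ax.set_ylabel("AMH (ng/mL)")
            ax.set_title(f"Modelled AMH decline, {g.group}")
            png = out_dir / f"decline_curve_{g.group}.png"
            fig.savefig(png, dpi=120, bbox_inches="tight")
            plt.close(fig)
            paths.append(png)
    return paths


def write_manifest(report: Report, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [
        f"config_hash={report.config_hash}",
        f"version={report.version}",
        f"cutoff={report.config.cutoff:g}",
        f"bootstrap_enabled={report.config.bootstrap.enabled}",
        f"bootstrap_seed={report.config.bootstrap.seed}",
    ]
    for g in report.groups:
        gc = next(c for c in report.config.groups if c.group == g.group)
        seed = gc.gen_params.seed if gc.gen_params is not None else ""
        lines.append(f"group.{g.group}.seed={seed}")
        lines.append(f"group.{g.group}.n_input={g.n_input}")
        lines.append(f"group.{g.group}.n_kept={g.n_kept}")
    path = out_dir / "run_manifest.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


def run_and_export(config: AnalysisConfig, out_dir: str | Path) -> Report:
    """Full pipeline plus file outputs; nothing is written if any stage fails."""
    report = run_analysis(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_text, txt_text = render_table(report)
    (out_dir / "table.csv").write_text(csv_text)
    (out_dir / "table.txt").write_text(txt_text + "\n")
    render_decline_curves(report, out_dir)
    report.comparison.table.to_csv(out_dir / "decline_comparison.csv", index=False)
    for g in report.groups:
        write_cohort(g.cohort, out_dir / f"cohort_{g.group}.csv")
        g.exclusions.write_csv(out_dir / f"exclusions_{g.group}.csv")
        if g.cohort.metadata:
            (out_dir / f"cohort_{g.group}.meta.txt").write_text(
                sidecar_metadata_text(g.cohort)
            )
    write_manifest(report, out_dir)
    return report
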