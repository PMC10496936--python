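"""Subject-level cohort data model, CSV I/O, eligibility filtering and unit conversion.

The canonical concentration unit throughout the package is ng/mL; the ELISA
sensitivity quoted in pmol/L is converted with the standard molar factor
7.14 pmol/L per ng/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import pandas as pd

from .errors import CohortFormatError, CohortValidationError, UsageError

GROUPS = ("pcos", "eumenorrheic")
MENSTRUAL_STATUSES = ("regular", "oligomenorrhea", "amenorrhea")

#: pmol/L per ng/mL for AMH (140 kDa dimeric glycoprotein, standard conversion).
PMOL_PER_NG_ML = 7.14

#: Canonical CSV column order written by :func:`write_cohort`.
CANONICAL_COLUMNS = (
    "subject_id",
    "group",
    "age_years",
    "bmi",
    "amh_ng_ml",
    "fsh_iu_l",
    "cycle_length_days",
    "menstrual_status",
)

_MANDATORY_COLUMNS = ("subject_id", "age_years", "bmi", "amh_ng_ml")


@dataclass(frozen=True)
class Subject:
    """One woman's record: age (years), BMI (kg/m²), serum AMH (ng/mL).

    FSH (IU/L), cycle length (days) and menstrual status are optional; they are
    consumed only by eligibility filtering, never by the model fit.
    """

    subject_id: str
    group: str
    age: float
    bmi: float
    amh: float
    fsh: float | None = None
    cycle_length_days: int | None = None
    menstrual_status: str | None = None

    def invariant_violations(self) -> list[str]:
        """Return human-readable descriptions of every violated invariant."""
        problems: list[str] = []
        if not self.subject_id:
            problems.append("subject_id must be non-empty")
        if self.group not in GROUPS:
            problems.append(f"group must be one of {GROUPS}, got {self.group!r}")
        if not (isinstance(self.age, (int, float)) and math.isfinite(self.age) and self.age > 0):
            problems.append(f"age must be a finite number > 0, got {self.age!r}")
        if not (isinstance(self.bmi, (int, float)) and math.isfinite(self.bmi) and self.bmi > 0):
            problems.append(f"bmi must be a finite number > 0, got {self.bmi!r}")
        if not (isinstance(self.amh, (int, float)) and math.isfinite(self.amh) and self.amh >= 0):
            problems.append(f"amh must be a finite number >= 0, got {self.amh!r}")
        if self.fsh is not None and not (math.isfinite(self.fsh) and self.fsh >= 0):
            problems.append(f"fsh must be >= 0 when present, got {self.fsh!r}")
        if self.cycle_length_days is not None and self.cycle_length_days <= 0:
            problems.append("cycle_length_days must be > 0 when present")
        if self.menstrual_status is not None and self.menstrual_status not in MENSTRUAL_STATUSES:
            problems.append(
                f"menstrual_status must be one of {MENSTRUAL_STATUSES}, "
                f"got {self.menstrual_status!r}"
            )
        return problems


@dataclass(frozen=True)
class Cohort:
    """A validated, ordered collection of subjects sharing one group label."""

    subjects: tuple[Subject, ...]
    group: str
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise UsageError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        object.__setattr__(self, "subjects", tuple(self.subjects))
        seen: set[str] = set()
        for s in self.subjects:
            if s.group != self.group:
                raise UsageError(
                    f"subject {s.subject_id!r} has group {s.group!r}, cohort is {self.group!r}"
                )
            if s.subject_id in seen:
                raise UsageError(f"duplicate subject_id {s.subject_id!r}")
            seen.add(s.subject_id)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)

    def ages(self) -> list[float]:
        return [s.age for s in self.subjects]

    def amh(self) -> list[float]:
        return [s.amh for s in self.subjects]

    def to_frame(self) -> pd.DataFrame:
        """Return the cohort as a DataFrame with the canonical columns."""
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age_years": [s.age for s in self.subjects],
                "bmi": [s.bmi for s in self.subjects],
                "amh_ng_ml": [s.amh for s in self.subjects],
                "fsh_iu_l": [s.fsh for s in self.subjects],
                "cycle_length_days": [s.cycle_length_days for s in self.subjects],
                "menstrual_status": [s.menstrual_status for s in self.subjects],
            }
        )


@dataclass(frozen=True)
class CohortSummary:
    """Arithmetic means of the quantities the study reports per group."""

    n: int
    mean_age: float
    mean_bmi: float
    mean_amh: float


@dataclass(frozen=True)
class EligibilityCriteria:
    """Closed-interval inclusion windows; every boundary is inclusive.

    A criterion left as None is not applied. ``required_menstrual_status`` is a
    set of admissible status values; a subject with no recorded status fails it.
    """

    group: str
    age_range: tuple[float, float] | None = None
    bmi_range: tuple[float, float] | None = None
    fsh_range: tuple[float, float] | None = None
    cycle_length_range: tuple[int, int] | None = None
    required_menstrual_status: frozenset[str] | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise UsageError(f"unknown group {self.group!r}")
        for name in ("age_range", "bmi_range", "fsh_range", "cycle_length_range"):
            rng = getattr(self, name)
            if rng is not None and rng[0] > rng[1]:
                raise UsageError(f"{name} lower bound {rng[0]} exceeds upper bound {rng[1]}")
        if self.required_menstrual_status is not None:
            object.__setattr__(
                self, "required_menstrual_status", frozenset(self.required_menstrual_status)
            )


@dataclass(frozen=True)
class ExclusionLog:
    """Excluded subject ids paired with the first violated criterion."""

    records: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["subject_id", "reason"])

    def write_csv(self, dest: str | Path | IO[str]) -> None:
        self.to_frame().to_csv(dest, index=False)


def study_criteria(group: str) -> EligibilityCriteria:
    """The study's published inclusion windows for each group.

    PCOS: age 30–35 y, BMI 24–31 kg/m², FSH within normal limits (1–10 IU/L),
    oligomenorrhea or amenorrhea. Eumenorrheic: age 30–35 y, BMI 22–28 kg/m²,
    regular cycles of 26–35 days.
    """
    if group == "pcos":
        return EligibilityCriteria(
            group="pcos",
            age_range=(30.0, 35.0),
            bmi_range=(24.0, 31.0),
            fsh_range=(1.0, 10.0),
            required_menstrual_status=frozenset({"oligomenorrhea", "amenorrhea"}),
        )
    if group == "eumenorrheic":
        return EligibilityCriteria(
            group="eumenorrheic",
            age_range=(30.0, 35.0),
            bmi_range=(22.0, 28.0),
            cycle_length_range=(26, 35),
            required_menstrual_status=frozenset({"regular"}),
        )
    raise UsageError(f"unknown group {group!r}; expected one of {GROUPS}")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_float(raw: str, column: str, errors: list[str]) -> float | None:
    if raw is None or raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        errors.append(f"non-numeric {column}: {raw!r}")
        return None


def read_cohort(source: str | Path | IO[str], group: str) -> Cohort:
    """Read a subject CSV into a validated Cohort.

    The file must carry a header row with at least ``subject_id``, ``age_years``,
    ``bmi`` and ``amh_ng_ml``; unknown columns are ignored. A ``group`` column,
    if present, must agree with the requested group on every row. Any row
    violating a subject invariant is reported (with its 0-based data-row index)
    in a single :class:`CohortValidationError`.
    """
    if group not in GROUPS:
        raise UsageError(f"unknown group {group!r}; expected one of {GROUPS}")
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing mandatory column(s): {', '.join(missing)}")

    subjects: list[Subject] = []
    row_errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        errs: list[str] = []
        if "group" in df.columns and rec["group"] not in ("", group):
            errs.append(f"group column reads {rec['group']!r}, expected {group!r}")
        age = _parse_float(rec["age_years"], "age_years", errs)
        bmi = _parse_float(rec["bmi"], "bmi", errs)
        amh = _parse_float(rec["amh_ng_ml"], "amh_ng_ml", errs)
        fsh = _parse_float(rec.get("fsh_iu_l", ""), "fsh_iu_l", errs)
        cycle_raw = rec.get("cycle_length_days", "")
        cycle: int | None = None
        if cycle_raw != "":
            try:
                cycle = int(float(cycle_raw))
            except ValueError:
                errs.append(f"non-numeric cycle_length_days: {cycle_raw!r}")
        status = rec.get("menstrual_status", "") or None
        if not errs:
            subj = Subject(
                subject_id=rec["subject_id"],
                group=group,
                age=age,
                bmi=bmi,
                amh=amh,
                fsh=fsh,
                cycle_length_days=cycle,
                menstrual_status=status,
            )
            errs.extend(subj.invariant_violations())
            if not errs:
                subjects.append(subj)
        for msg in errs:
            row_errors.append((i, msg))
    if row_errors:
        raise CohortValidationError(row_errors)
    src = str(source) if isinstance(source, (str, Path)) else "<stream>"
    return Cohort(subjects=tuple(subjects), group=group, metadata={"source": src})


def write_cohort(cohort: Cohort, dest: str | Path | IO[str]) -> None:
    """Write a cohort CSV with the canonical header; optional fields left blank.

    Floats are written at full (shortest round-trip) precision so that
    ``read_cohort(write_cohort(c))`` reproduces every field exactly.
    """
    df = cohort.to_frame()
    df["cycle_length_days"] = df["cycle_length_days"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    for col in ("fsh_iu_l", "menstrual_status"):
        df[col] = df[col].map(lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else v)
    df.to_csv(dest, index=False, columns=list(CANONICAL_COLUMNS))


# ---------------------------------------------------------------------------
# Eligibility and summaries
# ---------------------------------------------------------------------------

def _first_violation(s: Subject, c: EligibilityCriteria) -> str | None:
    # Fixed evaluation order for deterministic logs: age, BMI, FSH, cycle, status.
    if c.age_range is not None and not (c.age_range[0] <= s.age <= c.age_range[1]):
        return "age"
    if c.bmi_range is not None and not (c.bmi_range[0] <= s.bmi <= c.bmi_range[1]):
        return "bmi"
    if c.fsh_range is not None and (
        s.fsh is None or not (c.fsh_range[0] <= s.fsh <= c.fsh_range[1])
    ):
        return "fsh"
    if c.cycle_length_range is not None and (
        s.cycle_length_days is None
        or not (c.cycle_length_range[0] <= s.cycle_length_days <= c.cycle_length_range[1])
    ):
        return "cycle_length"
    if c.required_menstrual_status is not None and (
        s.menstrual_status not in c.required_menstrual_status
    ):
        return "menstrual_status"
    return None


def apply_eligibility(
    cohort: Cohort, criteria: EligibilityCriteria
) -> tuple[Cohort, ExclusionLog]:
    """Filter a cohort by closed-interval inclusion criteria.

    Returns the kept subjects (order preserved) and a log pairing each excluded
    subject with the first violated criterion. Kept + excluded always sum to
    the input count, and re-filtering the kept cohort excludes nothing.
    """
    if criteria.group != cohort.group:
        raise UsageError(
            f"criteria are for group {criteria.group!r} but cohort is {cohort.group!r}"
        )
    kept: list[Subject] = []
    excluded: list[tuple[str, str]] = []
    for s in cohort:
        reason = _first_violation(s, criteria)
        if reason is None:
            kept.append(s)
        else:
            excluded.append((s.subject_id, reason))
    filtered = Cohort(subjects=tuple(kept), group=cohort.group, metadata=dict(cohort.metadata))
    return filtered, ExclusionLog(records=tuple(excluded))


def summarize(cohort: Cohort) -> CohortSummary:
    """Arithmetic means of age, BMI and AMH over all subjects."""
    n = len(cohort)
    if n == 0:
        raise UsageError("cannot summarize an empty cohort")
    return CohortSummary(
        n=n,
        mean_age=sum(s.age for s in cohort) / n,
        mean_bmi=sum(s.bmi for s in cohort) / n,
        mean_amh=sum(s.amh for s in cohort) / n,
    )


def convert_amh_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an AMH concentration between ng/mL and pmol/L (factor 7.14)."""
    units = {"ng_ml", "pmol_l"}
    if from_unit not in units or to_unit not in units:
        raise UsageError(f"units must be in {sorted(units)}")
    if value < 0:
        raise UsageError(f"concentration must be >= 0, got {value}")
    if from_unit == to_unit:
        return value
    if from_unit == "ng_ml":
        return value * PMOL_PER_NG_ML
    return value / PMOL_PER_NG_ML
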