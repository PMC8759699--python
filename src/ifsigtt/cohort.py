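"""Cohort data model and tidy-CSV input/output for I-FSIGTT time series.

The atomic unit is a :class:`SubjectSeries`: one animal's paired glucose and
insulin concentrations over the test, on a clock whose zero is the dextrose
bolus.  A :class:`Cohort` bundles subjects with the :class:`ProtocolSpec`
(doses and canonical sampling schedule) that produced them.

On-disk format is a tidy long CSV, one row per subject x time::

    subject_id,group,age_hours,time_min,glucose_mg_dl,insulin_uIU_ml

Missing measurements are empty cells; they are preserved as NaN and never
imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    IntegrityError,
    ParseError,
    SchemaError,
    ValidationError,
)

#: Sampling schedule of the insulin-modified FSIGT protocol, minutes relative
#: to the dextrose bolus.  Two baseline draws (-60 and 0), dense sampling
#: around the dextrose (t=0) and insulin (t=20) boluses, sparse to 180 min.
DEFAULT_SAMPLE_TIMES = (
    -60.0, 0.0, 2.0, 5.0, 7.0, 10.0, 15.0, 19.0, 22.0, 25.0,
    30.0, 35.0, 40.0, 50.0, 60.0, 75.0, 90.0, 120.0, 150.0, 180.0,
)

#: Basal insulin above this concentration (uIU/mL) marks a subject as not
#: metabolically fasted/healthy and excludes it from analysis.
ENROLLMENT_INSULIN_CUTOFF = 20.0

GROUPS = ("foal", "horse")

CSV_COLUMNS = (
    "subject_id", "group", "age_hours", "time_min",
    "glucose_mg_dl", "insulin_uIU_ml",
)
REQUIRED_COLUMNS = tuple(c for c in CSV_COLUMNS if c != "age_hours")


@dataclass(frozen=True)
class ProtocolSpec:
    """Doses and sampling schedule of an insulin-modified FSIGT.

    Parameters
    ----------
    dextrose_dose_mg_kg
        Dextrose bolus, mg glucose per kg body mass, given at
        ``dextrose_time_min`` (the clock zero).
    insulin_dose_iu_kg
        Regular insulin bolus, IU per kg, given at ``insulin_time_min``.
    sample_times_min
        Strictly increasing sampling times in minutes.  Exactly two samples
        must be pre-dextrose (time <= 0): the -60 min and time-0 baselines.
    """

    dextrose_dose_mg_kg: float = 300.0
    insulin_dose_iu_kg: float = 0.02
    dextrose_time_min: float = 0.0
    insulin_time_min: float = 20.0
    sample_times_min: tuple[float, ...] = DEFAULT_SAMPLE_TIMES

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times_min, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValidationError("sample_times_min must be strictly increasing")
        if not self.insulin_time_min > self.dextrose_time_min:
            raise ValidationError("insulin bolus must follow the dextrose bolus")
        n_baseline = int(np.sum(t <= self.dextrose_time_min))
        if n_baseline != 2:
            raise ValidationError(
                f"protocol requires exactly two pre-dextrose samples, got {n_baseline}"
            )

    @property
    def post_dextrose_times(self) -> np.ndarray:
        t = np.asarray(self.sample_times_min, dtype=float)
        return t[t > self.dextrose_time_min]


@dataclass
class SubjectSeries:
    """One animal's glucose/insulin time course through the test.

    ``times`` are minutes relative to the dextrose bolus (so the -60 min
    baseline is negative).  ``glucose`` (mg/dL) and ``insulin`` (uIU/mL) are
    aligned with ``times``; NaN marks a missing measurement.  ``age`` is in
    hours for foals and years for horses, or None when unknown.
    """

    subject_id: str
    group: str
    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray
    age: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.insulin = np.asarray(self.insulin, dtype=float)
        if self.group not in GROUPS:
            raise ValidationError(
                f"{self.subject_id}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValidationError(f"{self.subject_id}: times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self.subject_id}: times must be strictly increasing")
        for name, arr in (("glucose", self.glucose), ("insulin", self.insulin)):
            if arr.shape != self.times.shape:
                raise ValidationError(
                    f"{self.subject_id}: {name} length {arr.size} != times length {self.times.size}"
                )
        if np.any(self.glucose[np.isfinite(self.glucose)] <= 0):
            raise ValidationError(f"{self.subject_id}: glucose values must be positive")
        if np.any(self.insulin[np.isfinite(self.insulin)] < 0):
            raise ValidationError(f"{self.subject_id}: insulin values must be non-negative")

    def value_at(self, channel: str, t: float) -> float:
        """Measured value of ``channel`` at exactly time ``t`` (NaN if absent)."""
        arr = getattr(self, channel)
        idx = np.flatnonzero(self.times == t)
        return float(arr[idx[0]]) if idx.size else math.nan

    def baseline_pair(self) -> tuple[float, float]:
        """Time-0 (glucose, insulin); raises if either is missing."""
        g = self.value_at("glucose", 0.0)
        i = self.value_at("insulin", 0.0)
        if not math.isfinite(g) or not math.isfinite(i):
            raise ValidationError(
                f"{self.subject_id}: time-0 glucose and insulin are required"
            )
        return g, i


@dataclass
class ParseReport:
    """Non-fatal findings from reading a cohort CSV."""

    missing_cells: list[tuple[str, float, str]] = field(default_factory=list)
    n_rows: int = 0
    n_subjects: int = 0


@dataclass
class Cohort:
    """All subjects of one study plus the protocol they were run under."""

    subjects: list[SubjectSeries]
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    parse_report: ParseReport | None = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def by_group(self, group: str) -> list[SubjectSeries]:
        return [s for s in self.subjects if s.group == group]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return seen


@dataclass
class ValidationIssue:
    kind: str  # "missing_time" | "unscheduled_time" | "missing_measurement"
    time_min: float
    channel: str | None = None


def read_cohort_csv(path, protocol: ProtocolSpec | None = None) -> Cohort:
    """Read the tidy cohort CSV into a :class:`Cohort`.

    Rows are grouped by ``subject_id`` and stably sorted by ``time_min``
    within each subject; subject order follows first appearance in the file.
    Empty measurement cells become NaN and are listed in the attached
    :class:`ParseReport`; malformed cells raise :class:`ParseError` naming
    the row.
    """
    protocol = protocol or ProtocolSpec()
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    report = ParseReport(n_rows=len(df))

    def _num(raw: str, row: int, col: str, subject: str, allow_blank: bool) -> float:
        raw = raw.strip()
        if raw == "" or raw.upper() in ("NA", "NAN"):
            if allow_blank:
                return math.nan
            raise ParseError(f"row {row}: {col} may not be blank")
        try:
            return float(raw)
        except ValueError as exc:
            raise ParseError(
                f"row {row} (subject {subject}): non-numeric {col} value {raw!r}"
            ) from exc

    subjects: list[SubjectSeries] = []
    for sid, grp_df in df.groupby("subject_id", sort=False):
        rows = []
        for row_idx, rec in grp_df.iterrows():
            t = _num(rec["time_min"], row_idx, "time_min", sid, allow_blank=False)
            g = _num(rec["glucose_mg_dl"], row_idx, "glucose_mg_dl", sid, allow_blank=True)
            i = _num(rec["insulin_uIU_ml"], row_idx, "insulin_uIU_ml", sid, allow_blank=True)
            if math.isnan(g):
                report.missing_cells.append((sid, t, "glucose_mg_dl"))
            if math.isnan(i):
                report.missing_cells.append((sid, t, "insulin_uIU_ml"))
            rows.append((t, g, i))
        times = np.array([r[0] for r in rows])
        if np.unique(times).size != times.size:
            dup = sorted({t for t in times.tolist() if times.tolist().count(t) > 1})
            raise IntegrityError(f"subject {sid}: duplicate times {dup}")
        order = np.argsort(times, kind="stable")
        group = str(grp_df["group"].iloc[0]).strip()
        age: float | None = None
        if "age_hours" in grp_df.columns:
            raw_age = str(grp_df["age_hours"].iloc[0]).strip()
            if raw_age not in ("", "NA", "nan", "NaN"):
                age = _num(raw_age, int(grp_df.index[0]), "age_hours", sid, allow_blank=True)
        subjects.append(
            SubjectSeries(
                subject_id=str(sid),
                group=group,
                times=times[order],
                glucose=np.array([r[1] for r in rows])[order],
                insulin=np.array([r[2] for r in rows])[order],
                age=age,
            )
        )
    report.n_subjects = len(subjects)
    return Cohort(subjects=subjects, protocol=protocol, parse_report=report)


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort back to the tidy CSV schema at full float precision."""
    rows = []
    for s in cohort.subjects:
        for t, g, i in zip(s.times, s.glucose, s.insulin):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "age_hours": "" if s.age is None else repr(float(s.age)),
                    "time_min": repr(float(t)),
                    "glucose_mg_dl": "" if math.isnan(g) else repr(float(g)),
                    "insulin_uIU_ml": "" if math.isnan(i) else repr(float(i)),
                }
            )
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def apply_enrollment_filter(cohort: Cohort) -> tuple[Cohort, list[str]]:
    """Drop subjects whose time-0 insulin exceeds the enrollment cutoff.

    The cutoff is strict: a subject at exactly 20 uIU/mL is retained.
    Returns the filtered cohort and the excluded subject ids.  A subject with
    no time-0 insulin measurement cannot be screened and raises
    :class:`ValidationError`.
    """
    kept: list[SubjectSeries] = []
    excluded: list[str] = []
    for s in cohort.subjects:
        i0 = s.value_at("insulin", 0.0)
        if math.isnan(i0):
            raise ValidationError(
                f"{s.subject_id}: missing time-0 insulin; cannot apply enrollment filter"
            )
        if i0 > ENROLLMENT_INSULIN_CUTOFF:
            excluded.append(s.subject_id)
        else:
            kept.append(s)
    return replace(cohort, subjects=kept, parse_report=None), excluded


def validate_protocol(series: SubjectSeries, protocol: ProtocolSpec) -> list[ValidationIssue]:
    """Report (never fix) deviations of a series from the sampling schedule.

    Issues: scheduled times absent from the series, unscheduled extra times,
    and NaN measurements at scheduled times.
    """
    issues: list[ValidationIssue] = []
    scheduled = np.asarray(protocol.sample_times_min, dtype=float)
    have = set(series.times.tolist())
    for t in scheduled:
        if t not in have:
            issues.append(ValidationIssue("missing_time", float(t)))
    sched_set = set(scheduled.tolist())
    for t in series.times:
        if float(t) not in sched_set:
            issues.append(ValidationIssue("unscheduled_time", float(t)))
    for t, g, i in zip(series.times, series.glucose, series.insulin):
        if float(t) in sched_set:
            if math.isnan(g):
                issues.append(ValidationIssue("missing_measurement", float(t), "glucose"))
            if math.isnan(i):
                issues.append(ValidationIssue("missing_measurement", float(t), "insulin"))
    return issues


def convert_supplementary(glucose_xlsx, insulin_xlsx, subjects_xlsx, out_csv,
                          protocol: ProtocolSpec | None = None) -> Cohort:
    """Convert wide per-analyte workbooks into the tidy cohort CSV.

    Expected workbook layout (one sheet each): first column subject id, the
    remaining column headers sampling times in minutes; the subjects workbook
    has columns ``subject_id``, ``group`` and optionally ``age_hours``.
    Writes ``out_csv`` and returns the parsed :class:`Cohort`.
    """
    protocol = protocol or ProtocolSpec()
    glu = pd.read_excel(glucose_xlsx)
    ins = pd.read_excel(insulin_xlsx)
    info = pd.read_excel(subjects_xlsx)
    if "subject_id" not in info.columns or "group" not in info.columns:
        raise SchemaError("subjects workbook must have subject_id and group columns")

    def _wide_to_map(df: pd.DataFrame, label: str) -> dict[str, dict[float, float]]:
        id_col = df.columns[0]
        out: dict[str, dict[float, float]] = {}
        times = []
        for c in df.columns[1:]:
            try:
                times.append(float(c))
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{label} workbook: column header {c!r} is not a time in minutes"
                ) from exc
        for _, rec in df.iterrows():
            sid = str(rec[id_col])
            out[sid] = {
                t: float(rec[c]) if pd.notna(rec[c]) else math.nan
                for t, c in zip(times, df.columns[1:])
            }
        return out

    gmap = _wide_to_map(glu, "glucose")
    imap = _wide_to_map(ins, "insulin")
    rows = []
    for _, rec in info.iterrows():
        sid = str(rec["subject_id"])
        if sid not in gmap or sid not in imap:
            raise IntegrityError(f"subject {sid} absent from glucose or insulin workbook")
        times = sorted(set(gmap[sid]) | set(imap[sid]))
        age = rec.get("age_hours")
        for t in times:
            rows.append(
                {
                    "subject_id": sid,
                    "group": str(rec["group"]),
                    "age_hours": "" if pd.isna(age) else float(age),
                    "time_min": t,
                    "glucose_mg_dl": gmap[sid].get(t, math.nan),
                    "insulin_uIU_ml": imap[sid].get(t, math.nan),
                }
            )
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    for col in ("glucose_mg_dl", "insulin_uIU_ml"):
        df[col] = df[col].map(lambda v: "" if isinstance(v, float) and math.isnan(v) else v)
    df.to_csv(out_csv, index=False)
    return read_cohort_csv(out_csv, protocol)
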