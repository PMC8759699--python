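"""Per-subject response summaries: trapezoidal AUCs and glucose nadir.

AUCs are total (not baseline-subtracted) areas over the post-dextrose window
[0, 180] min by the composite trapezoid rule on the sampled points; missing
interior samples simply widen a trapezoid (linear interpolation across the
gap), and nothing is extrapolated outside the sampled range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import ProtocolSpec, SubjectSeries
from .errors import ValidationError

AUC_WINDOW = (0.0, 180.0)


@dataclass(frozen=True)
class ResponseSummary:
    subject_id: str
    auc_glucose: float       # mg/dL * min over [0, 180]
    auc_insulin: float       # uIU/mL * min over [0, 180]
    glucose_nadir: float     # mg/dL, minimum after the insulin bolus
    nadir_time: float        # minutes
    baseline_glucose: float  # mg/dL at time 0
    baseline_insulin: float  # uIU/mL at time 0


def auc_trapezoid(times, values, t_start: float, t_end: float) -> float:
    """Composite trapezoid area of ``values`` over samples in [t_start, t_end].

    Only samples with finite values inside the window contribute; fewer than
    two is an error rather than a silent zero.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValidationError("times and values must be matching 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    mask = (t >= t_start) & (t <= t_end) & np.isfinite(v)
    if int(mask.sum()) < 2:
        raise ValidationError(
            f"need >= 2 samples in [{t_start}, {t_end}], have {int(mask.sum())}"
        )
    return float(np.trapezoid(v[mask], t[mask]))


def glucose_nadir(series: SubjectSeries,
                  insulin_time: float = 20.0) -> tuple[float, float]:
    """(time, value) of the glucose minimum after the insulin bolus.

    Only samples strictly after ``insulin_time`` are scanned; ties go to the
    earliest time.
    """
    mask = (series.times > insulin_time) & np.isfinite(series.glucose)
    if not np.any(mask):
        raise ValidationError(
            f"{series.subject_id}: no post-insulin glucose samples"
        )
    t = series.times[mask]
    g = series.glucose[mask]
    i = int(np.argmin(g))  # argmin returns the first minimum; times increase
    return float(t[i]), float(g[i])


def summarize_subject(series: SubjectSeries,
                      protocol: ProtocolSpec | None = None) -> ResponseSummary:
    """Bundle time-0 baselines, both AUCs on [0, 180], and nadir descriptors."""
    protocol = protocol or ProtocolSpec()
    g0 = series.value_at("glucose", 0.0)
    i0 = series.value_at("insulin", 0.0)
    if not (math.isfinite(g0) and math.isfinite(i0)):
        raise ValidationError(f"{series.subject_id}: time-0 baselines required")
    nadir_t, nadir_g = glucose_nadir(series, protocol.insulin_time_min)
    return ResponseSummary(
        subject_id=series.subject_id,
        auc_glucose=auc_trapezoid(series.times, series.glucose, *AUC_WINDOW),
        auc_insulin=auc_trapezoid(series.times, series.insulin, *AUC_WINDOW),
        glucose_nadir=nadir_g,
        nadir_time=nadir_t,
        baseline_glucose=g0,
        baseline_insulin=i0,
    )
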