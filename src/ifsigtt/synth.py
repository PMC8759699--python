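"""Synthetic I-FSIGTT cohorts with foal-like and horse-like phenotypes.

Each synthetic subject is built forward through the same model the analysis
fits: subject-level parameters are drawn log-normally around preset centers,
a parametric two-peak insulin curve plays the role of the measured input,

    I(t) = Ib + A1 * t * exp(-k1 t) + A2 * exp(-k2 (t - 20)) * 1[t >= 20],

(endogenous first phase after the dextrose bolus, exogenous insulin bolus at
20 min), glucose is obtained by integrating the minimal model with G0 = Gb
plus a dose-scaled mixing jump, and both channels are read off at the
protocol's 20 sampling times with multiplicative Gaussian measurement noise.

The foal preset centers basal glucose at 166 mg/dL with reporting-scale
insulin sensitivity 18.3 (deep insulin-induced nadir, rebound toward basal
by 180 min); the horse preset centers at 104 mg/dL with SI 0.9, a slower
glucose decay and a much larger insulin excursion.  Basal setpoints (Gb, Ib)
vary between subjects with 0.3x the kinetic between-subject CV, since
homeostatic baselines are far tighter than kinetic parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cohort import Cohort, ProtocolSpec, SubjectSeries
from .errors import ValidationError
from .minimal_model import InsulinForcing, MinimalModelParams, SI_REPORT_SCALE, simulate

#: Floors applied to noisy samples; assay reporting limits, not physiology.
GLUCOSE_FLOOR = 20.0   # mg/dL
INSULIN_FLOOR = 0.5    # uIU/mL

#: Glucose distribution space used to convert the dextrose dose (mg/kg) into
#: the instantaneous mixing jump in G0, dL per kg.
GLUCOSE_SPACE_DL_KG = 1.875


@dataclass(frozen=True)
class CohortPreset:
    """Generating distribution for one phenotype."""

    label: str                       # "foal_like" | "horse_like"
    gb_center: float                 # mg/dL
    ib_center: float                 # uIU/mL
    si_center: float                 # reporting scale (x 1e4)
    sg_center: float                 # min^-1
    p2_center: float                 # min^-1
    first_phase_amplitude: float     # A1, uIU/mL per min
    first_phase_decay: float         # k1, min^-1
    bolus_amplitude: float           # A2, uIU/mL
    bolus_decay: float               # k2, min^-1
    between_subject_cv: float = 0.25
    measurement_cv: float = 0.03             # glucose
    measurement_cv_insulin: float = 0.08

    def __post_init__(self) -> None:
        for name in ("gb_center", "ib_center", "si_center", "sg_center",
                     "p2_center", "first_phase_amplitude", "first_phase_decay",
                     "bolus_amplitude", "bolus_decay"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("between_subject_cv", "measurement_cv",
                     "measurement_cv_insulin"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValidationError(f"{name} must lie in [0, 0.5]")


FOAL_PRESET = CohortPreset(
    label="foal_like", gb_center=166.0, ib_center=8.3, si_center=18.3,
    sg_center=0.02, p2_center=0.10,
    first_phase_amplitude=173.0, first_phase_decay=0.5,
    bolus_amplitude=55.0, bolus_decay=0.06,
)

HORSE_PRESET = CohortPreset(
    label="horse_like", gb_center=104.0, ib_center=8.0, si_center=0.9,
    sg_center=0.01, p2_center=0.03,
    first_phase_amplitude=19.4, first_phase_decay=0.15,
    bolus_amplitude=130.0, bolus_decay=0.02,
)

PRESETS = {"foal_like": FOAL_PRESET, "horse_like": HORSE_PRESET}

#: Fraction of the kinetic between-subject CV applied to basal setpoints.
BASAL_CV_FRACTION = 0.3


def _lognormal(rng: np.random.Generator, center: float, cv: float) -> float:
    """Mean-preserving log-normal draw around ``center`` with the given CV."""
    sigma2 = math.log1p(cv * cv)
    mu = math.log(center) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _insulin_curve(t: np.ndarray, ib: float, a1: float, k1: float,
                   a2: float, k2: float, bolus_time: float) -> np.ndarray:
    first = a1 * np.maximum(t, 0.0) * np.exp(-k1 * np.maximum(t, 0.0))
    bolus = np.where(t >= bolus_time, a2 * np.exp(-k2 * (t - bolus_time)), 0.0)
    return ib + np.where(t >= 0, first, 0.0) + bolus


@dataclass(frozen=True)
class SubjectTruth:
    """Generating ground-truth values attached to a synthetic subject."""

    params: MinimalModelParams
    a1: float
    k1: float
    a2: float
    k2: float


def generate_subject(preset: CohortPreset, seed,
                     protocol: ProtocolSpec | None = None,
                     subject_id: str | None = None,
                     age: float | None = None,
                     ) -> tuple[SubjectSeries, SubjectTruth]:
    """Simulate one subject; returns the noisy series plus its ground truth.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; identical
    (preset, seed) give bit-identical output.
    """
    protocol = protocol or ProtocolSpec()
    for attempt in range(5):
        rng = np.random.default_rng(
            seed if attempt == 0 else np.random.SeedSequence(
                entropy=(seed if isinstance(seed, int) else 0) + 10_000_019 * attempt)
        )
        series, truth = _generate_once(preset, rng, protocol, subject_id, age)
        if np.all(series.glucose > 0) and np.all(series.insulin >= 0):
            return series, truth
    raise ValidationError("could not draw a positive series in 5 attempts")


def _generate_once(preset, rng, protocol, subject_id, age):
    cv = preset.between_subject_cv
    basal_cv = cv * BASAL_CV_FRACTION
    gb = _lognormal(rng, preset.gb_center, basal_cv)
    ib = _lognormal(rng, preset.ib_center, basal_cv)
    si = _lognormal(rng, preset.si_center, cv)
    sg = _lognormal(rng, preset.sg_center, cv)
    p2 = _lognormal(rng, preset.p2_center, cv)
    a1 = _lognormal(rng, preset.first_phase_amplitude, cv)
    a2 = _lognormal(rng, preset.bolus_amplitude, cv)
    k1 = preset.first_phase_decay
    k2 = preset.bolus_decay

    jump = protocol.dextrose_dose_mg_kg / GLUCOSE_SPACE_DL_KG
    params = MinimalModelParams(
        sg=sg, p2=p2, p3=(si / SI_REPORT_SCALE) * p2, g0=gb + jump, gb=gb, ib=ib,
    )
    times = np.asarray(protocol.sample_times_min, dtype=float)
    post = times[times > 0]

    # Glucose is driven by the insulin curve as the analysis will see it:
    # piecewise linear through the protocol's sampled values.  Denser knots
    # would generate glucose no fit on sampled insulin could reproduce.
    t_knots = np.concatenate([[0.0], post])
    i_knots = _insulin_curve(t_knots, ib, a1, k1, a2, k2, protocol.insulin_time_min)
    forcing = InsulinForcing(t_knots, i_knots)

    g_post = simulate(params, forcing, np.concatenate([[0.0], post]))[1:]
    glucose = np.where(times > 0, np.interp(times, post, g_post,
                                            left=np.nan, right=np.nan), gb)
    glucose[times <= 0] = gb
    insulin = _insulin_curve(times, ib, a1, k1, a2, k2, protocol.insulin_time_min)
    insulin[times <= 0] = ib

    glucose = glucose * (1.0 + preset.measurement_cv * rng.standard_normal(times.size))
    insulin = insulin * (1.0 + preset.measurement_cv_insulin
                         * rng.standard_normal(times.size))
    glucose = np.maximum(glucose, GLUCOSE_FLOOR)
    insulin = np.maximum(insulin, INSULIN_FLOOR)

    series = SubjectSeries(
        subject_id=subject_id or f"{preset.label}_subject",
        group="foal" if preset.label.startswith("foal") else "horse",
        times=times, glucose=glucose, insulin=insulin, age=age,
    )
    return series, SubjectTruth(params=params, a1=a1, k1=k1, a2=a2, k2=k2)


def generate_cohort(n_foal: int = 12, n_horse: int = 8, seed: int = 0,
                    protocol: ProtocolSpec | None = None,
                    foal_preset: CohortPreset = FOAL_PRESET,
                    horse_preset: CohortPreset = HORSE_PRESET) -> Cohort:
    """Generate a two-group cohort with independent per-subject seed streams.

    Foal ages (hours, uniform 24-60) and horse ages (years, uniform 3-14) are
    drawn independently of the kinetic parameters.  Default sizes 12 and 8
    match the study design being emulated.
    """
    if n_foal < 0 or n_horse < 0:
        raise ValidationError("cohort sizes must be >= 0")
    protocol = protocol or ProtocolSpec()
    master = np.random.SeedSequence(entropy=seed)
    children = master.spawn(n_foal + n_horse)
    age_rng = np.random.default_rng(master.spawn(1)[0])
    subjects = []
    for i in range(n_foal):
        age = float(age_rng.uniform(24.0, 60.0))
        s, _ = generate_subject(foal_preset, children[i], protocol,
                                subject_id=f"foal_{i + 1:02d}", age=age)
        subjects.append(s)
    for j in range(n_horse):
        age = float(age_rng.uniform(3.0, 14.0))
        s, _ = generate_subject(horse_preset, children[n_foal + j], protocol,
                                subject_id=f"horse_{j + 1:02d}", age=age)
        subjects.append(s)
    return Cohort(subjects=subjects, protocol=protocol)
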