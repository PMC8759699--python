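"""Fasting proxy indices of insulin sensitivity and beta-cell function.

All five indices are computed from a single fasted baseline pair: glucose in
mg/dL and insulin in uIU/mL, taken at time 0 (immediately before the dextrose
bolus).  HOMA indices convert glucose to mmol/L first; QUICKI and MIRG use
their canonical mg/dL forms (their printed constants 30 and the customary
magnitudes assume mg/dL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import SubjectSeries
from .errors import DomainError

#: mg/dL per mmol/L for glucose (molar mass 180.16 g/mol).
MGDL_PER_MMOLL = 18.016

#: HOMA-BC% glucose offset, mmol/L (the mg/dL rendering is 63).
HOMA_BC_OFFSET_MMOLL = 3.5


def mgdl_to_mmoll(glucose: float) -> float:
    """Convert glucose from mg/dL to mmol/L."""
    if glucose < 0:
        raise DomainError(f"glucose must be >= 0, got {glucose}")
    return glucose / MGDL_PER_MMOLL


def homa_ir(glucose: float, insulin: float) -> float:
    """HOMA insulin resistance: (glucose_mmol * insulin) / 22.5."""
    if glucose < 0 or insulin < 0:
        raise DomainError("glucose and insulin must be >= 0")
    return mgdl_to_mmoll(glucose) * insulin / 22.5


def homa_bc_pct(glucose: float, insulin: float, variant: str = "mmol") -> float:
    """HOMA beta-cell function (%), 20 * insulin / (glucose - offset).

    ``variant="mmol"`` (default) uses glucose in mmol/L with offset 3.5;
    ``variant="mgdl"`` uses mg/dL with offset 63 (the same formula before
    unit conversion, differing by the factor 18.016 in the result).  The
    denominator must be positive: glucose at or below the offset is outside
    the index's domain.
    """
    if variant == "mmol":
        denom = mgdl_to_mmoll(glucose) - HOMA_BC_OFFSET_MMOLL
    elif variant == "mgdl":
        denom = glucose - 63.0
    else:
        raise DomainError(f"unknown HOMA-BC% variant {variant!r}")
    if denom <= 0:
        raise DomainError(
            f"HOMA-BC% undefined: glucose {glucose} mg/dL at or below the offset"
        )
    return 20.0 * insulin / denom


def quicki(glucose: float, insulin: float) -> float:
    """QUICKI: 1 / (log10 insulin + log10 glucose), glucose in mg/dL."""
    if glucose <= 0 or insulin <= 0:
        raise DomainError("glucose and insulin must be > 0 for QUICKI")
    s = math.log10(insulin) + math.log10(glucose)
    if s == 0:
        raise DomainError("QUICKI undefined: log terms sum to zero")
    return 1.0 / s


def risqi(insulin: float) -> float:
    """RISQI: reciprocal square root of fasting insulin."""
    if insulin <= 0:
        raise DomainError("insulin must be > 0 for RISQI")
    return insulin ** -0.5


def mirg(glucose: float, insulin: float) -> float:
    """Modified insulin-to-glucose ratio (beta-cell proxy), glucose in mg/dL:

        (800 - 0.3 * (insulin - 50)^2) / (glucose - 30)
    """
    if glucose <= 30.0:
        raise DomainError(f"MIRG undefined: glucose {glucose} <= 30 mg/dL")
    return (800.0 - 0.3 * (insulin - 50.0) ** 2) / (glucose - 30.0)


@dataclass(frozen=True)
class ProxyPanel:
    """The five fasting indices for one subject plus the baseline pair used."""

    subject_id: str
    baseline_glucose: float
    baseline_insulin: float
    homa_ir: float
    homa_bc_pct: float
    quicki: float
    risqi: float
    mirg: float


def proxy_panel(series: SubjectSeries, homa_bc_variant: str = "mmol") -> ProxyPanel:
    """All five indices from the subject's time-0 glucose/insulin pair.

    The time-0 sample (not the mean of the two baselines) is the fasted pair,
    matching how the basal state is snapshotted immediately before dosing.
    Domain errors from individual indices propagate with the index named.
    """
    g0, i0 = series.baseline_pair()
    values = {}
    for name, func in (
        ("homa_ir", lambda: homa_ir(g0, i0)),
        ("homa_bc_pct", lambda: homa_bc_pct(g0, i0, homa_bc_variant)),
        ("quicki", lambda: quicki(g0, i0)),
        ("risqi", lambda: risqi(i0)),
        ("mirg", lambda: mirg(g0, i0)),
    ):
        try:
            values[name] = func()
        except DomainError as exc:
            raise DomainError(f"{series.subject_id}: {name}: {exc}") from exc
    return ProxyPanel(
        subject_id=series.subject_id,
        baseline_glucose=g0,
        baseline_insulin=i0,
        **values,
    )
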