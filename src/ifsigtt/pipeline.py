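"""End-to-end analysis: read -> filter -> fit/proxy/summarize -> compare.

The report mirrors how an I-FSIGTT study is written up: per-subject tables
(minimal-model fits, proxy panels, response summaries), a between-group
comparison for every endpoint (rank tests for model parameters and proxies,
t tests for AUCs), and within-group Friedman/Dunn time tests for glucose and
insulin.  Individual subject failures (non-converging fit, domain error in a
proxy) are quarantined with a reason and excluded from group statistics
rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    Cohort,
    ProtocolSpec,
    apply_enrollment_filter,
    read_cohort_csv,
)
from .errors import FitError, IfsigttError, PipelineError
from .minimal_model import FitSettings, MinimalModelFit, fit
from .proxies import ProxyPanel, proxy_panel
from .stats import (
    CohortComparison,
    FriedmanDunnsReport,
    friedman_with_dunns,
    mann_whitney_u,
    spearman,
    students_t,
)
from .summaries import ResponseSummary, summarize_subject

logger = logging.getLogger("ifsigtt")

#: Endpoint -> (source table, column); rank-compared endpoints.
RANK_ENDPOINTS = (
    "si", "sg", "airg", "di",
    "homa_ir", "homa_bc_pct", "quicki", "risqi", "mirg",
    "baseline_glucose", "baseline_insulin",
)
#: Normally-distributed endpoints compared by t test.
T_ENDPOINTS = ("auc_glucose", "auc_insulin")


@dataclass(frozen=True)
class AnalysisConfig:
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    fit_settings: FitSettings = field(default_factory=FitSettings)
    homa_bc_variant: str = "mmol"
    group_labels: tuple[str, str] = ("foal", "horse")

    def provenance_hash(self) -> str:
        payload = json.dumps(
            {"protocol": asdict(self.protocol),
             "fit": asdict(self.fit_settings),
             "homa_bc_variant": self.homa_bc_variant,
             "groups": list(self.group_labels)},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    fits: dict[str, MinimalModelFit]
    proxies: dict[str, ProxyPanel]
    summaries: dict[str, ResponseSummary]
    comparisons: list[CohortComparison]
    time_tests: dict[tuple[str, str], FriedmanDunnsReport]   # (group, channel)
    age_si_correlation: CohortComparison | None
    excluded_by_filter: list[str]
    quarantined: dict[str, str]          # subject_id -> reason
    group_sizes: dict[str, int]
    provenance: dict


def _endpoint_value(subject_id: str, endpoint: str, fits, proxies, summaries):
    if endpoint in ("si", "sg", "airg", "di"):
        f = fits.get(subject_id)
        return getattr(f, endpoint) if f is not None else None
    if endpoint in ("homa_ir", "homa_bc_pct", "quicki", "risqi", "mirg"):
        p = proxies.get(subject_id)
        return getattr(p, endpoint) if p is not None else None
    s = summaries.get(subject_id)
    return getattr(s, endpoint) if s is not None else None


def run_analysis(cohort: Cohort, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full analysis on an in-memory cohort."""
    config = config or AnalysisConfig()
    ga, gb_label = config.group_labels

    filtered, excluded = apply_enrollment_filter(cohort)
    for g in config.group_labels:
        if not filtered.by_group(g):
            raise PipelineError(f"group {g!r} is empty after the enrollment filter")

    fits: dict[str, MinimalModelFit] = {}
    proxies: dict[str, ProxyPanel] = {}
    summaries: dict[str, ResponseSummary] = {}
    quarantined: dict[str, str] = {}
    for s in filtered.subjects:
        try:
            fits[s.subject_id] = fit(s, config.fit_settings)
        except (FitError, IfsigttError) as exc:
            quarantined[s.subject_id] = f"fit: {exc}"
            logger.warning("quarantined %s: %s", s.subject_id, exc)
        try:
            proxies[s.subject_id] = proxy_panel(s, config.homa_bc_variant)
        except IfsigttError as exc:
            quarantined.setdefault(s.subject_id, f"proxy: {exc}")
        try:
            summaries[s.subject_id] = summarize_subject(s, config.protocol)
        except IfsigttError as exc:
            quarantined.setdefault(s.subject_id, f"summary: {exc}")

    comparisons: list[CohortComparison] = []
    for endpoint in RANK_ENDPOINTS + T_ENDPOINTS:
        xa, xb = [], []
        for s in filtered.by_group(ga):
            v = _endpoint_value(s.subject_id, endpoint, fits, proxies, summaries)
            if v is not None and math.isfinite(v):
                xa.append(v)
        for s in filtered.by_group(gb_label):
            v = _endpoint_value(s.subject_id, endpoint, fits, proxies, summaries)
            if v is not None and math.isfinite(v):
                xb.append(v)
        try:
            if endpoint in T_ENDPOINTS:
                comparisons.append(students_t(xa, xb, endpoint, config.group_labels))
            else:
                comparisons.append(mann_whitney_u(xa, xb, endpoint, config.group_labels))
        except IfsigttError as exc:
            logger.warning("endpoint %s failed: %s", endpoint, exc)
            comparisons.append(CohortComparison(
                endpoint=endpoint, statistic_name="failed",
                statistic=math.nan, p_value=math.nan,
                warnings=[f"comparison failed: {exc}"],
            ))

    # within-group glucose/insulin time courses vs baseline (time 0)
    sched = [t for t in config.protocol.sample_times_min if t >= 0]
    time_tests: dict[tuple[str, str], FriedmanDunnsReport] = {}
    for g in config.group_labels:
        members = filtered.by_group(g)
        for channel in ("glucose", "insulin"):
            matrix = np.full((len(members), len(sched)), np.nan)
            for i, s in enumerate(members):
                for j, t in enumerate(sched):
                    matrix[i, j] = s.value_at(channel, t)
            try:
                time_tests[(g, channel)] = friedman_with_dunns(
                    matrix, sched, baseline_index=0)
            except IfsigttError as exc:
                logger.warning("time test %s/%s failed: %s", g, channel, exc)

    # SI vs foal age (hours); informative only when ages are present
    foal_pairs = [(s.age, fits[s.subject_id].si)
                  for s in filtered.by_group(ga)
                  if s.age is not None and s.subject_id in fits]
    age_corr = None
    if len(foal_pairs) >= 3:
        try:
            age_corr = spearman([p[0] for p in foal_pairs],
                                [p[1] for p in foal_pairs],
                                endpoint="foal_age_vs_si")
        except IfsigttError as exc:
            logger.warning("age correlation failed: %s", exc)

    return AnalysisReport(
        fits=fits, proxies=proxies, summaries=summaries,
        comparisons=comparisons, time_tests=time_tests,
        age_si_correlation=age_corr,
        excluded_by_filter=excluded, quarantined=quarantined,
        group_sizes={g: len(filtered.by_group(g)) for g in config.group_labels},
        provenance={"config_hash": config.provenance_hash(),
                    "version": __version__,
                    "n_input": len(cohort),
                    "n_retained": len(filtered) - len(quarantined),
                    "n_filter_excluded": len(excluded),
                    "n_fit_failed": len(quarantined)},
    )


def run_analysis_csv(cohort_csv, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Read the tidy cohort CSV and run the full analysis."""
    config = config or AnalysisConfig()
    cohort = read_cohort_csv(cohort_csv, config.protocol)
    return run_analysis(cohort, config)


def _fits_frame(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for sid, f in sorted(report.fits.items()):
        rows.append({
            "subject_id": sid, "si": f.si, "sg": f.sg, "airg": f.airg,
            "di": f.di, "p2": f.params.p2, "p3": f.params.p3,
            "g0": f.params.g0, "gb": f.params.gb, "ib": f.params.ib,
            "residual_sse": f.residual_sse, "n_points_fit": f.n_points_fit,
            "converged": f.converged, "at_bound": f.at_bound,
        })
    return pd.DataFrame(rows)


def _comparisons_frame(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for c in report.comparisons:
        row = {"endpoint": c.endpoint, "statistic_name": c.statistic_name,
               "statistic": c.statistic, "df": c.df, "p_value": c.p_value}
        for gs in c.group_summaries:
            row[f"{gs.label}_n"] = gs.n
            row[f"{gs.label}_center"] = gs.center
            row[f"{gs.label}_low"] = gs.low
            row[f"{gs.label}_high"] = gs.high
            row[f"{gs.label}_kind"] = gs.kind
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: AnalysisReport, out_dir) -> list[Path]:
    """Write the report tables; returns the manifest of files written.

    Emits five files with stable names: fits.csv, proxies.csv, summaries.csv,
    comparisons.csv and comparisons.json.  Payloads are deterministic for
    identical inputs (no timestamps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []

    f = out / "fits.csv"
    _fits_frame(report).to_csv(f, index=False)
    manifest.append(f)

    f = out / "proxies.csv"
    pd.DataFrame([asdict(p) for _, p in sorted(report.proxies.items())]).to_csv(
        f, index=False)
    manifest.append(f)

    f = out / "summaries.csv"
    pd.DataFrame([asdict(s) for _, s in sorted(report.summaries.items())]).to_csv(
        f, index=False)
    manifest.append(f)

    f = out / "comparisons.csv"
    _comparisons_frame(report).to_csv(f, index=False)
    manifest.append(f)

    payload = {
        "provenance": report.provenance,
        "group_sizes": report.group_sizes,
        "excluded_by_filter": report.excluded_by_filter,
        "quarantined": report.quarantined,
        "comparisons": [
            {"endpoint": c.endpoint, "statistic_name": c.statistic_name,
             "statistic": c.statistic, "df": c.df, "p_value": c.p_value,
             "groups": [asdict(gs) for gs in c.group_summaries],
             "warnings": c.warnings}
            for c in report.comparisons
        ],
        "time_tests": {
            f"{g}_{ch}": {
                "statistic": tt.statistic, "p_value": tt.p_value, "df": tt.df,
                "n_subjects": tt.n_subjects, "n_dropped": tt.n_dropped,
                "significant_times": [d.time_label for d in tt.dunns if d.significant],
            }
            for (g, ch), tt in report.time_tests.items()
        },
        "age_si_correlation": (
            None if report.age_si_correlation is None else
            {"rho": report.age_si_correlation.statistic,
             "p_value": report.age_si_correlation.p_value}
        ),
    }
    f = out / "comparisons.json"
    f.write_text(json.dumps(payload, indent=2, sort_keys=True))
    manifest.append(f)
    return manifest
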