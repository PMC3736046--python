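"""Lifespan endpoint statistics and bootstrap uncertainty.

The endpoint of interest is the 50%-survival age t_half of each group's
fitted Gompertz law.  From it:

    residual lifespan  = t_half - start_age        (months lived after the
                                                    observation/treatment start)
    gain               = residual[treated] - residual[control]     (months)
    % increase (residual) = 100 * gain / residual[control]
    % increase (overall)  = 100 * gain / t_half[control]

The residual percentage is the treatment-relevant figure: it relates the
gain to the post-treatment lifespan only, excluding the untreated months.
All values are stored unrounded; display rounding (one decimal for months,
integer percent) happens only in :func:`format_summary`.

Uncertainty comes from a nonparametric case-resampling bootstrap, stratified
by group, that reruns the whole pipeline (Kaplan-Meier -> sequential fit ->
summary) on each replicate and reports percentile 95% intervals — the
smallest-assumption option for cohorts of fewer than ten animals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .fit import FitError, SequentialFitResult, sequential_fit
from .gompertz import GompertzParams, half_life
from .io import Cohort, LifespanRecord
from .km import km_estimate

__all__ = [
    "LifespanSummary",
    "DegenerateSummaryError",
    "UnstableBootstrapError",
    "BootstrapResult",
    "summarize",
    "summarize_half_lives",
    "bootstrap_summary",
    "format_summary",
]

#: fixed metric names used in reports and bootstrap intervals
METRIC_NAMES = (
    "t_half.control",
    "t_half.treated",
    "residual.control",
    "residual.treated",
    "gain_months",
    "percent_increase_residual",
    "percent_increase_overall",
)


class DegenerateSummaryError(ValueError):
    """Control residual lifespan is not positive; ratios are undefined."""


class UnstableBootstrapError(RuntimeError):
    """More than half of the bootstrap replicates failed to fit."""


@dataclass(frozen=True)
class LifespanSummary:
    """Per-group 50%-survival ages and the derived gain statistics."""

    start_age: float
    control: str
    treated: str
    t_half: dict[str, float]
    residual: dict[str, float]
    gain_months: float
    percent_increase_residual: float
    percent_increase_overall: float
    ci: dict[str, tuple[float, float]] | None = None
    params: dict[str, GompertzParams] | None = None


def summarize_half_lives(
    t_half: Mapping[str, float],
    start_age: float,
    control: str,
    treated: str,
) -> LifespanSummary:
    """Derive residual lifespans, gain and percent increases from 50%-survival
    ages directly (the arithmetic layer beneath :func:`summarize`)."""
    for label in (control, treated):
        if label not in t_half:
            raise KeyError(f"group {label!r} missing from t_half")
    residual = {g: th - start_age for g, th in t_half.items()}
    if residual[control] <= 0:
        raise DegenerateSummaryError(
            f"control residual lifespan {residual[control]:.3g} <= 0"
        )
    if t_half[control] <= 0:
        raise DegenerateSummaryError("control 50%-survival age must be positive")
    gain = residual[treated] - residual[control]
    return LifespanSummary(
        start_age=float(start_age),
        control=control,
        treated=treated,
        t_half={g: float(v) for g, v in t_half.items()},
        residual={g: float(v) for g, v in residual.items()},
        gain_months=float(gain),
        percent_increase_residual=float(100.0 * gain / residual[control]),
        percent_increase_overall=float(100.0 * gain / t_half[control]),
    )


def summarize(
    fit: SequentialFitResult,
    start_age: float,
    control: str,
    treated: str,
) -> LifespanSummary:
    """Summarize a sequential-fit result into the lifespan endpoints."""
    for label in (control, treated):
        if label not in fit.final_params:
            raise KeyError(f"group {label!r} missing from fit result")
    t_half = {g: half_life(p) for g, p in fit.final_params.items()}
    summary = summarize_half_lives(t_half, start_age, control, treated)
    return replace(summary, params=dict(fit.final_params))


def _resample(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    idx = rng.integers(0, len(cohort), size=len(cohort))
    records = tuple(
        LifespanRecord(
            subject_id=f"b{k}",
            group=cohort.group,
            entry_age=cohort.entry_age,
            event_age=cohort.records[i].event_age,
            event=cohort.records[i].event,
        )
        for k, i in enumerate(idx)
    )
    return Cohort(group=cohort.group, records=records, entry_age=cohort.entry_age)


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile intervals per metric, with the replicate failure count."""

    intervals: dict[str, tuple[float, float]]
    n_replicates: int
    n_failed: int

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / self.n_replicates


def bootstrap_summary(
    cohorts: Mapping[str, Cohort],
    control: str,
    treated: str,
    B: int = 500,
    seed: int = 0,
    order: str = "paper",
    level: float = 0.95,
) -> BootstrapResult:
    """Case-resampling bootstrap of the full pipeline.

    Each of the ``B`` replicates resamples animals with replacement within
    each group, reruns Kaplan-Meier estimation, the sequential fit and the
    summary, and records the metrics.  Replicates where fitting fails (e.g.
    a resample with fewer than three distinct death ages) are dropped and
    counted; more than 50% failures raises :class:`UnstableBootstrapError`.
    Identical seeds give identical intervals.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100 for stable percentiles, got {B}")
    rng = np.random.default_rng(seed)
    start_age = cohorts[control].entry_age
    draws: dict[str, list[float]] = {name: [] for name in METRIC_NAMES}
    n_failed = 0
    for _ in range(B):
        resampled = {g: _resample(c, rng) for g, c in cohorts.items()}
        try:
            curves = {g: km_estimate(c) for g, c in resampled.items()}
            fit = sequential_fit(curves, order=order)
            summary = summarize(fit, start_age, control, treated)
        except (FitError, DegenerateSummaryError, ValueError):
            n_failed += 1
            continue
        values = {
            "t_half.control": summary.t_half[control],
            "t_half.treated": summary.t_half[treated],
            "residual.control": summary.residual[control],
            "residual.treated": summary.residual[treated],
            "gain_months": summary.gain_months,
            "percent_increase_residual": summary.percent_increase_residual,
            "percent_increase_overall": summary.percent_increase_overall,
        }
        for name, v in values.items():
            draws[name].append(v)
    if n_failed > B / 2:
        raise UnstableBootstrapError(
            f"{n_failed}/{B} bootstrap replicates failed to fit"
        )
    alpha = (1.0 - level) / 2.0
    intervals = {
        name: (
            float(np.percentile(vals, 100 * alpha)),
            float(np.percentile(vals, 100 * (1 - alpha))),
        )
        for name, vals in draws.items()
    }
    return BootstrapResult(intervals=intervals, n_replicates=B, n_failed=n_failed)


def format_summary(summary: LifespanSummary) -> str:
    """Human-readable report with display rounding (months to one decimal,
    percentages to the nearest integer); stored values stay unrounded."""
    lines = [
        f"start age: {summary.start_age:g} months",
        f"t_half[{summary.control}]  = {summary.t_half[summary.control]:.1f} months",
        f"t_half[{summary.treated}]  = {summary.t_half[summary.treated]:.1f} months",
        f"residual[{summary.control}] = {summary.residual[summary.control]:.1f} months",
        f"residual[{summary.treated}] = {summary.residual[summary.treated]:.1f} months",
        f"gain = {summary.gain_months:.1f} months",
        f"residual lifespan increase = {summary.percent_increase_residual:.0f}%",
        f"overall lifespan increase  = {summary.percent_increase_overall:.0f}%",
    ]
    if summary.ci:
        lines.append("95% bootstrap intervals:")
        for name, (lo, hi) in summary.ci.items():
            lines.append(f"  {name}: [{lo:.2f}, {hi:.2f}]")
    return "\n".join(lines)
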