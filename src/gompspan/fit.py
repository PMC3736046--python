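"""Sequential sensitivity-guided constrained Gompertz fitting.

Small cohorts give noisy survival curves, and the three-parameter Gompertz
form F(t) = 100*exp(-P1*exp(P2*t - P3)) is over-parameterized for curve
fitting: survival depends on (P1, P3) only through ln(P1) - P3, so a free
three-parameter fit has a flat ridge.  The staged procedure implemented here
restores identifiability by sharing the least informative parameters across
groups:

  stage 1  independent three-parameter fit per group;
  stage 2  the least sensitive parameter is averaged across groups and
           fixed, the remaining two are refit per group;
  stage 3  the next parameter is averaged and fixed, and the final single
           parameter is refit per group.

With the canonical order (P1, P3, P2) the groups end up sharing scale and
offset and differing only in the rate of aging P2 — the parameter that
carries the treatment effect.  "Sensitivity" is measured, by default, as the
cross-group relative spread |max - min| / mean(|values|) of each stage-1
parameter; the canonical order bypasses the metric entirely.

Each stage is a box-constrained nonlinear least-squares fit of the model to
the survival percentages immediately after each distinct death age (the
post-drop step values), unweighted.  Positivity bounds P1 in (1e-12, 1e6),
P2 in (1e-6, 100); P3 unbounded.  P1 and P2 are optimized in log space
(their bounds span many decades); three seeded jittered restarts guard
against local minima, so refitting the same curve is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .gompertz import GompertzParams
from .km import KMCurve

__all__ = [
    "FitError",
    "UnderdeterminedFitError",
    "ConvergenceError",
    "UndefinedCorrelationError",
    "SequentialFitResult",
    "fit_three_param",
    "sensitivity_rank",
    "sequential_fit",
    "goodness_of_fit",
]

PARAM_NAMES = ("P1", "P2", "P3")
#: tie-break order for equal sensitivity scores
_TIE_ORDER = ("P1", "P3", "P2")
PAPER_ORDER = ("P1", "P3", "P2")

_BOUNDS = {"P1": (1e-12, 1e6), "P2": (1e-6, 100.0), "P3": (-np.inf, np.inf)}
#: parameters optimized on the log scale
_LOG_SCALE = {"P1", "P2"}

_N_RESTARTS = 3
_JITTER_SEED = 20130807


class FitError(RuntimeError):
    """Base class for fitting failures."""


class UnderdeterminedFitError(FitError):
    """Fewer distinct death times than free parameters."""


class ConvergenceError(FitError):
    """Optimizer failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (final residual {residual:.6g})")
        self.residual = residual


class UndefinedCorrelationError(FitError):
    """Pearson correlation undefined (fewer than 2 points or zero variance)."""


@dataclass(frozen=True)
class SequentialFitResult:
    """Output of the three-stage fit.

    ``shared`` maps the two averaged-and-fixed parameter names to their
    shared values; ``final_params`` holds the complete per-group parameter
    triples after stage 3.  ``stage_costs`` records the per-group sum of
    squared residuals after each stage (percent^2), for diagnostics.
    """

    sensitivity_order: tuple[str, str, str]
    stage1_params: dict[str, GompertzParams]
    shared: dict[str, float]
    final_params: dict[str, GompertzParams]
    correlation: dict[str, float]
    stage_costs: dict[str, tuple[float, float, float]]

    @property
    def shared_P1(self) -> float:
        return self.shared["P1"]

    @property
    def shared_P3(self) -> float:
        return self.shared["P3"]

    @property
    def per_group_P2(self) -> dict[str, float]:
        return {g: p.P2 for g, p in self.final_params.items()}


def _transform(name: str, value: float) -> float:
    return math.log(value) if name in _LOG_SCALE else value


def _untransform(name: str, value: float) -> float:
    return math.exp(value) if name in _LOG_SCALE else value


def _default_init(curve: KMCurve) -> GompertzParams:
    # Start with unit rate; place the offset so the inner exponent is ~0 at
    # the last death, and pick the scale so the initial 50%-crossing sits
    # near the median death age.
    p2 = 1.0
    p3 = p2 * float(curve.times[-1])
    t_med = float(np.median(curve.times))
    p1 = math.log(2.0) * math.exp(p3 - p2 * t_med)
    return GompertzParams(p1, p2, p3)


def _clip(name: str, value: float) -> float:
    lo, hi = _BOUNDS[name]
    return float(min(max(value, lo * (1 + 1e-12) if np.isfinite(lo) else value), hi))


def _adapt_init(
    prior: GompertzParams,
    fixed: Mapping[str, float],
    free: Sequence[str],
    curve: KMCurve,
) -> GompertzParams:
    """Re-anchor one free parameter so the initial curve crosses 50% at the
    median death age.

    Carrying a previous stage's parameters verbatim into a stage with newly
    fixed values can start the optimizer on a flat plateau (predicted
    survival 0 or 100 everywhere, zero gradient); anchoring the 50%-crossing
    inside the data range guarantees an informative start.
    """
    t_med = float(np.median(curve.times))
    vals = {n: fixed.get(n, getattr(prior, n)) for n in PARAM_NAMES}
    ln_ratio = math.log(math.log(2.0) / vals["P1"])
    if "P3" in free:
        vals["P3"] = vals["P2"] * t_med - ln_ratio
    elif "P1" in free:
        vals["P1"] = _clip("P1", math.log(2.0) * math.exp(vals["P3"] - vals["P2"] * t_med))
    elif "P2" in free:
        vals["P2"] = _clip("P2", (vals["P3"] + ln_ratio) / t_med)
    return GompertzParams(vals["P1"], vals["P2"], vals["P3"])


def _fit_constrained(
    curve: KMCurve,
    free: Sequence[str],
    fixed: Mapping[str, float],
    init: GompertzParams,
) -> tuple[GompertzParams, float]:
    """Box-constrained least squares over ``free`` parameters with the rest
    held at ``fixed``; returns the fitted triple and the cost (sum of squared
    residuals on the percent scale)."""
    x_data = curve.times
    y_data = curve.survival_pct
    if len(x_data) < len(free):
        raise UnderdeterminedFitError(
            f"{len(x_data)} distinct death times cannot determine "
            f"{len(free)} free parameters"
        )

    def assemble(vec: np.ndarray) -> GompertzParams:
        values = dict(fixed)
        for name, v in zip(free, vec):
            values[name] = _untransform(name, v)
        return GompertzParams(values["P1"], values["P2"], values["P3"])

    def residuals(vec: np.ndarray) -> np.ndarray:
        p = assemble(vec)
        z = p.P2 * x_data - p.P3
        with np.errstate(over="ignore"):
            pred = 100.0 * np.exp(-p.P1 * np.exp(z))
        return pred - y_data

    lower = np.array([_transform(n, _BOUNDS[n][0]) if np.isfinite(_BOUNDS[n][0]) else -np.inf for n in free])
    upper = np.array([_transform(n, _BOUNDS[n][1]) if np.isfinite(_BOUNDS[n][1]) else np.inf for n in free])

    rng = np.random.default_rng(_JITTER_SEED)
    starts = [init]
    for _ in range(_N_RESTARTS):
        p2 = _clip("P2", init.P2 * math.exp(rng.normal(0.0, 0.4)))
        p3 = init.P3 + rng.normal(0.0, 0.5) * max(abs(init.P3), 1.0) * 0.1
        p1 = _clip("P1", init.P1 * math.exp(rng.normal(0.0, 0.5)))
        starts.append(GompertzParams(p1, p2, p3))

    best: tuple[GompertzParams, float] | None = None
    last_residual = math.inf
    for start in starts:
        x0 = np.array([_transform(n, _clip(n, getattr(start, n))) for n in free])
        x0 = np.clip(x0, lower, upper)
        sol = least_squares(
            residuals,
            x0,
            bounds=(lower, upper),
            method="trf",
            ftol=1e-10,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=500 * (len(free) + 1),
        )
        cost = float(2.0 * sol.cost)  # scipy cost is 0.5 * sum r^2
        last_residual = min(last_residual, cost)
        if sol.status <= 0:
            continue
        if best is None or cost < best[1]:
            best = (assemble(sol.x), cost)
    if best is None:
        raise ConvergenceError("Gompertz least-squares fit did not converge", last_residual)
    return best


def fit_three_param(curve: KMCurve, init: GompertzParams | None = None) -> GompertzParams:
    """Stage-1 free fit of (P1, P2, P3) to one survival curve.

    Requires at least 3 distinct death times; raises
    :class:`UnderdeterminedFitError` otherwise.
    """
    if len(curve.times) < 3:
        raise UnderdeterminedFitError(
            f"need >= 3 distinct death times, got {len(curve.times)}"
        )
    params, _ = _fit_constrained(
        curve, free=PARAM_NAMES, fixed={}, init=init or _default_init(curve)
    )
    return params


def sensitivity_rank(stage1: Mapping[str, GompertzParams]) -> tuple[str, str, str]:
    """Order parameters by ascending cross-group relative spread.

    The score of a parameter is |max - min| / mean(|values|) over the
    stage-1 per-group fits; zero spread ties are broken by the fixed order
    (P1, P3, P2).  Requires at least two groups.
    """
    if len(stage1) < 2:
        raise ValueError("sensitivity ranking needs at least 2 groups")
    scores: dict[str, float] = {}
    for name in PARAM_NAMES:
        values = np.array([getattr(p, name) for p in stage1.values()])
        denom = float(np.mean(np.abs(values)))
        scores[name] = float(np.ptp(values)) / denom if denom > 0 else 0.0
    ranked = sorted(PARAM_NAMES, key=lambda n: (scores[n], _TIE_ORDER.index(n)))
    return tuple(ranked)  # type: ignore[return-value]


def sequential_fit(
    curves: Mapping[str, KMCurve],
    order: str | Sequence[str] = "paper",
    weighted: bool = False,
) -> SequentialFitResult:
    """Run the full three-stage constrained fit across groups.

    Parameters
    ----------
    curves
        One Kaplan-Meier curve per group (>= 2 groups, each with >= 3
        distinct death times).
    order
        ``"paper"`` for the canonical order (P1, P3, P2): scale first, then
        offset, leaving the rate of aging P2 group-specific.  ``"auto"``
        derives the order from :func:`sensitivity_rank` on the stage-1 fits.
        An explicit permutation of ("P1", "P2", "P3") is also accepted.
    weighted
        If True, cross-group averages are weighted by group size
        (``n_at_start``); default is the plain arithmetic mean.
    """
    if len(curves) < 2:
        raise ValueError("sequential fit needs at least 2 groups")

    def _attempt(stage: int, group: str, fn, *args):
        try:
            return fn(*args)
        except FitError as exc:
            raise type(exc)(f"stage {stage}, group {group!r}: {exc}") from exc

    stage1: dict[str, GompertzParams] = {}
    costs1: dict[str, float] = {}
    for group, curve in curves.items():
        if len(curve.times) < 3:
            raise UnderdeterminedFitError(
                f"stage 1, group {group!r}: need >= 3 distinct death times, "
                f"got {len(curve.times)}"
            )
        params, cost = _attempt(
            1, group, _fit_constrained, curve, PARAM_NAMES, {}, _default_init(curve)
        )
        stage1[group] = params
        costs1[group] = cost

    if isinstance(order, str) and order == "paper":
        names = PAPER_ORDER
    elif isinstance(order, str) and order == "auto":
        names = sensitivity_rank(stage1)
    else:
        names = tuple(order)
        if sorted(names) != sorted(PARAM_NAMES):
            raise ValueError(f"order must be a permutation of {PARAM_NAMES}, got {names}")
    first, second, last = names

    weights = (
        np.array([curves[g].n_at_start for g in curves], dtype=float)
        if weighted
        else None
    )

    def _average(params: Mapping[str, GompertzParams], name: str) -> float:
        values = [getattr(params[g], name) for g in curves]
        return float(np.average(values, weights=weights))

    shared: dict[str, float] = {}
    shared[first] = _average(stage1, first)

    stage2: dict[str, GompertzParams] = {}
    costs2: dict[str, float] = {}
    for group, curve in curves.items():
        fixed2 = {first: shared[first]}
        params, cost = _attempt(
            2, group, _fit_constrained, curve, (second, last), fixed2,
            _adapt_init(stage1[group], fixed2, (second, last), curve),
        )
        stage2[group] = params
        costs2[group] = cost

    shared[second] = _average(stage2, second)

    final: dict[str, GompertzParams] = {}
    costs3: dict[str, float] = {}
    for group, curve in curves.items():
        fixed3 = {first: shared[first], second: shared[second]}
        params, cost = _attempt(
            3, group, _fit_constrained, curve, (last,), fixed3,
            _adapt_init(stage2[group], fixed3, (last,), curve),
        )
        final[group] = params
        costs3[group] = cost

    correlation = {g: goodness_of_fit(curves[g], final[g]) for g in curves}
    return SequentialFitResult(
        sensitivity_order=names,
        stage1_params=stage1,
        shared=shared,
        final_params=final,
        correlation=correlation,
        stage_costs={g: (costs1[g], costs2[g], costs3[g]) for g in curves},
    )


def goodness_of_fit(curve: KMCurve, params: GompertzParams) -> float:
    """Pearson correlation between observed and model-predicted survival
    percentages at the fitted points."""
    y = np.asarray(curve.survival_pct, dtype=float)
    if y.size < 2:
        raise UndefinedCorrelationError("correlation needs at least 2 points")
    z = params.P2 * curve.times - params.P3
    with np.errstate(over="ignore"):
        pred = 100.0 * np.exp(-params.P1 * np.exp(z))
    if np.std(y) == 0 or np.std(pred) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant values")
    return float(np.corrcoef(y, pred)[0, 1])
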