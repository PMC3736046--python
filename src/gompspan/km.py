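"""Kaplan-Meier survival curves on the percent scale.

The empirical survival of each cohort is the product-limit step function,
anchored at 100% at the observation start age (the cohort entry age) and
expressed in percent.  With no censoring — the situation in a fully observed
cohort — the estimate reduces to direct counting: 100 x (number still alive
after t) / (number at start).  Censored animals leave the risk set at their
censoring age without producing a drop.

Steps are right-continuous: the value stored at a death age is the post-drop
survival.  Exact recorded ages define step locations; nothing is binned.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from lifelines import KaplanMeierFitter

from .io import Cohort

__all__ = ["KMCurve", "km_estimate", "km_evaluate", "plot_km"]


@dataclass(frozen=True, eq=False)
class KMCurve:
    """Empirical survival step function of one group.

    ``times`` are the distinct observed death ages (strictly increasing);
    ``survival_pct`` holds the post-drop survival percentage at each, so the
    implicit value on [start_age, times[0]) is 100.
    """

    group: str
    start_age: float
    times: np.ndarray
    survival_pct: np.ndarray
    n_at_start: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pct = np.asarray(self.survival_pct, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival_pct", pct)
        if times.shape != pct.shape:
            raise ValueError("times and survival_pct must have equal length")
        if times.size and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if times.size and times[0] <= self.start_age:
            raise ValueError("all event times must exceed start_age")
        if np.any(pct < 0) or np.any(pct > 100):
            raise ValueError("survival percentages must lie in [0, 100]")
        if pct.size and np.any(np.diff(pct) > 1e-12):
            raise ValueError("survival percentages must be non-increasing")
        if self.n_at_start < 1:
            raise ValueError("n_at_start must be positive")


def km_estimate(cohort: Cohort) -> KMCurve:
    """Product-limit estimate of a cohort's survival, in percent.

    Raises if the cohort is empty or any event age fails to exceed the
    entry age (both are data errors, not estimable situations).
    """
    start = cohort.entry_age
    ages = cohort.event_ages
    events = cohort.events
    if np.any(ages <= start):
        raise ValueError("every event_age must exceed the cohort entry_age")

    kmf = KaplanMeierFitter()
    kmf.fit(durations=ages, event_observed=events)
    death_times = np.unique(ages[events])
    # predict() evaluates the right-continuous step function: at a death
    # time this is already the post-drop value.
    pct = 100.0 * np.atleast_1d(np.asarray(kmf.predict(death_times), dtype=float))
    return KMCurve(
        group=cohort.group,
        start_age=start,
        times=death_times,
        survival_pct=pct,
        n_at_start=len(cohort),
    )


def km_evaluate(curve: KMCurve, t: float) -> float:
    """Right-continuous evaluation of the step function at age ``t`` (months)."""
    if t < curve.start_age:
        raise ValueError(f"t={t} is before the start age {curve.start_age}")
    idx = int(np.searchsorted(curve.times, t, side="right"))
    if idx == 0:
        return 100.0
    return float(curve.survival_pct[idx - 1])


def plot_km(
    curves: Mapping[str, KMCurve],
    path: str | os.PathLike,
    fits: Mapping[str, "object"] | None = None,
) -> None:
    """Export overlaid survival step curves (and optional fitted Gompertz
    curves, dashed) to an image file.

    The first two groups use the conventional black/gray pairing.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .gompertz import survival_pct

    colors = ["black", "gray", "tab:blue", "tab:orange"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for color, (group, curve) in zip(colors, curves.items()):
        xs = np.concatenate([[curve.start_age], curve.times])
        ys = np.concatenate([[100.0], curve.survival_pct])
        ax.step(xs, ys, where="post", color=color, label=group)
        if fits is not None and group in fits:
            grid = np.linspace(curve.start_age, curve.times[-1] + 0.5, 200)
            ax.plot(grid, survival_pct(fits[group], grid), "--", color=color,
                    label=f"{group} (Gompertz)")
    ax.set_xlabel("age (months)")
    ax.set_ylabel("survival (%)")
    ax.set_ylim(-2, 102)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
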