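"""Synthetic study-shaped cohorts with Gompertz mortality.

Generates the data-generating situation of a late-life intervention study:
small groups of animals, all alive at a common observation start age, whose
death ages follow Gompertz survival laws conditioned on survival to that
start.  The default design mirrors a two-arm mouse study — nine control and
eight treated animals entering at 21.5 months, with 50%-survival ages of
25.1 and 26.5 months respectively.

When a group is specified by a target 50%-survival age rather than a full
parameter triple, the rate of aging defaults to P2 = 1.5 per month (steep,
mouse-like late-life mortality at this age scale) and the offset to
P3 = P2 * t_half, which places the inner exponent at zero at t_half and
hence P1 = ln 2.

One global seed drives all groups through deterministic per-group
substreams (spawn-keyed by group index), so adding a group never perturbs
the draws of earlier groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gompertz import GompertzParams, half_life, sample_death_ages
from .io import Cohort, LifespanRecord

__all__ = [
    "StudyDesign",
    "params_from_half_life",
    "generate_study",
    "implied_gain",
    "DEFAULT_DESIGN",
]

_DEFAULT_P2 = 1.5  # per month


@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic multi-group lifespan study.

    ``groups`` is a sequence of ``(label, n, law)`` where ``law`` is either
    a :class:`GompertzParams` triple or a numeric target 50%-survival age in
    months (which must exceed ``start_age``).  ``round_to`` optionally snaps
    death ages to a grid (e.g. 0.25 month) to mimic coarse observation
    schedules; off by default.
    """

    start_age: float = 21.5
    groups: Sequence[tuple] = (("control", 9, 25.1), ("BMT", 8, 26.5))
    seed: int = 0
    round_to: float | None = None

    def __post_init__(self) -> None:
        if self.start_age < 0:
            raise ValueError("start_age must be >= 0")
        if not self.groups:
            raise ValueError("design needs at least one group")
        for label, n, law in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r}: n must be >= 1, got {n}")
            if not isinstance(law, GompertzParams):
                if float(law) <= self.start_age:
                    raise ValueError(
                        f"group {label!r}: target half-life {law} must exceed "
                        f"start_age {self.start_age}"
                    )
        if self.round_to is not None and self.round_to <= 0:
            raise ValueError("round_to must be positive")


#: the default two-arm design (9 control vs 8 treated, entry at 21.5 months)
DEFAULT_DESIGN = StudyDesign()


def params_from_half_life(
    t_half: float, P2: float = _DEFAULT_P2, P3: float | None = None
) -> GompertzParams:
    """Construct a Gompertz triple with an exact given 50%-survival age.

    Inverts the closed-form half-life: P1 = ln 2 / exp(P2*t_half - P3).
    With the default offset P3 = P2*t_half this reduces to P1 = ln 2.
    """
    if P2 <= 0:
        raise ValueError("P2 must be > 0")
    if P3 is None:
        P3 = P2 * t_half
    p1 = math.log(2.0) * math.exp(P3 - P2 * t_half)
    return GompertzParams(p1, P2, P3)


def _group_params(law) -> GompertzParams:
    return law if isinstance(law, GompertzParams) else params_from_half_life(float(law))


def generate_study(design: StudyDesign) -> dict[str, Cohort]:
    """Draw one synthetic study: per-group death ages conditioned on survival
    to ``design.start_age``, fully reproducible from ``design.seed``."""
    cohorts: dict[str, Cohort] = {}
    for idx, (label, n, law) in enumerate(design.groups):
        params = _group_params(law)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=design.seed, spawn_key=(idx,))
        )
        ages = sample_death_ages(params, design.start_age, n, rng)
        if design.round_to is not None:
            step = design.round_to
            ages = np.round(ages / step) * step
            # rounding must not push a death to or before the entry age
            floor = (math.floor(design.start_age / step) + 1) * step
            ages = np.maximum(ages, floor)
        records = tuple(
            LifespanRecord(
                subject_id=f"{label}-{i + 1:03d}",
                group=label,
                entry_age=design.start_age,
                event_age=float(age),
                event=True,
            )
            for i, age in enumerate(ages)
        )
        cohorts[label] = Cohort(group=label, records=records, entry_age=design.start_age)
    return cohorts


def implied_gain(design: StudyDesign, control: str, treated: str) -> float:
    """The design's true gain in months: difference of the generating laws'
    50%-survival ages."""
    laws = {label: _group_params(law) for label, _, law in design.groups}
    return half_life(laws[treated]) - half_life(laws[control])
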