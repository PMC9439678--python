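"""Task design and stimulus-condition enumeration.

The experiments interleave two tasks in a block design: an
eight-alternative tilt-discrimination task with planar surfaces defined
by tilt (0-315 deg, 45 deg steps), slant (0-60 deg, 15 deg steps) and
distance (37, 57, 97, 137 cm), and a visually guided saccade task with
eight target directions matching the choice-target locations.

A surface pose is (tilt, slant, distance).  At slant 0 (frontoparallel)
the tilt is undefined, so each distance contributes 8 tilts x 4 non-zero
slants + 1 frontoparallel = 33 orientation conditions; across the four
distances there are 132 unique poses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "TaskDesign",
    "StimulusCondition",
    "enumerate_conditions",
    "block_trial_conditions",
    "DEFAULT_TILTS",
    "DEFAULT_SLANTS",
    "DEFAULT_DISTANCES",
]

DEFAULT_TILTS = tuple(float(t) for t in range(0, 360, 45))
DEFAULT_SLANTS = (0.0, 15.0, 30.0, 45.0, 60.0)
DEFAULT_DISTANCES = (37.0, 57.0, 97.0, 137.0)


@dataclass(frozen=True)
class StimulusCondition:
    """One surface pose. ``tilt`` is ``None`` iff ``slant == 0``."""

    tilt: Optional[float]
    slant: float
    distance: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.slant < 90.0):
            raise ValueError(f"slant must be in [0, 90), got {self.slant}")
        if self.slant == 0.0:
            if self.tilt is not None:
                raise ValueError("tilt must be undefined (None) at slant 0")
        else:
            if self.tilt is None:
                raise ValueError("tilt required for non-zero slant")
            if not (0.0 <= self.tilt < 360.0):
                raise ValueError(f"tilt must be in [0, 360), got {self.tilt}")

    @property
    def frontoparallel(self) -> bool:
        return self.slant == 0.0


@dataclass(frozen=True)
class TaskDesign:
    """Parameters of the tilt-discrimination / saccade task pair.

    Durations are in ms, distances in cm, angles in degrees.
    ``saccade_repeats`` is the number of completed saccade trials per
    direction per block (4 in the standard block design).
    """

    tilts: Sequence[float] = DEFAULT_TILTS
    slants: Sequence[float] = DEFAULT_SLANTS
    distances: Sequence[float] = DEFAULT_DISTANCES
    fixation_distance: float = 57.0
    stimulus_duration: float = 1000.0
    fixation_duration: float = 300.0
    n_choice_targets: int = 8
    choice_eccentricity: float = 11.0
    frontoparallel_repeats: int = 8
    saccade_repeats: int = 4

    def __post_init__(self) -> None:
        if len(self.tilts) == 0 or len(self.distances) == 0:
            raise ValueError("tilts and distances must be non-empty")
        if not any(s > 0 for s in self.slants):
            raise ValueError("at least one non-zero slant is required")
        if self.stimulus_duration <= 0 or self.fixation_duration <= 0:
            raise ValueError("durations must be positive")

    @property
    def nonzero_slants(self) -> tuple:
        return tuple(s for s in self.slants if s > 0)

    @property
    def choice_directions(self) -> tuple:
        step = 360.0 / self.n_choice_targets
        return tuple(i * step for i in range(self.n_choice_targets))


def enumerate_conditions(design: TaskDesign) -> list:
    """Every unique pose of the design grid, in deterministic order.

    Ordering is distance-major, then slant ascending (frontoparallel
    first), then tilt ascending.  With the default design this yields 33
    conditions per distance and 132 overall.
    """
    conditions = []
    for d in design.distances:
        for s in sorted(design.slants):
            if s == 0.0:
                conditions.append(StimulusCondition(None, 0.0, d))
            else:
                for t in sorted(design.tilts):
                    conditions.append(StimulusCondition(t, s, d))
    return conditions


def block_trial_conditions(design: TaskDesign) -> list:
    """Tilt-task trial list for one block (with repeats, unshuffled).

    One completed trial per tilt x non-zero-slant x distance condition
    plus ``frontoparallel_repeats`` frontoparallel trials per distance:
    (8 tilts x 4 slants + 8) x 4 distances = 160 trials by default.
    """
    trials = []
    for d in design.distances:
        for _ in range(design.frontoparallel_repeats):
            trials.append(StimulusCondition(None, 0.0, d))
        for s in sorted(design.nonzero_slants):
            for t in sorted(design.tilts):
                trials.append(StimulusCondition(t, s, d))
    return trials
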