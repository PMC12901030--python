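"""Enumeration of the three-alternative decision task and the retinotopic localizer.

The decision task presents three Gabor patches at fixed angular positions
(0°, 120°, 240° around fixation, 0° pointing upward, counter-clockwise
positive).  Each trial draws three of five linearly spaced contrast levels
without replacement and assigns them to the three locations; patch
orientations are either all identical or all different; a framing cue
("high" / "low") defines which contrast is the correct choice.  Full
randomization of framing x contrast assignment x orientation condition
yields 1080 unique trials.

The localizer presents a single full-contrast patch per trial; each
position x orientation combination is repeated ten times per block, once
paired with a central fixation flicker (flicker trials are excluded from
model training).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np

#: Angular positions of the three alternatives, degrees (0° up, CCW positive).
POSITIONS: tuple[float, float, float] = (0.0, 120.0, 240.0)

#: Grating orientations used for the three-level orientation factor, degrees.
ORIENTATIONS: tuple[float, float, float] = (0.0, 60.0, 120.0)


class ConfigurationError(ValueError):
    """Raised when a task/simulation configuration is invalid."""


@dataclass(frozen=True)
class TrialCondition:
    """One unique decision-trial condition."""

    framing: str                      # "high" or "low"
    contrasts: tuple[float, ...]      # contrast at (top, left, right)
    orientations: tuple[float, ...]   # orientation at (top, left, right)


@dataclass(frozen=True)
class TaskDesign:
    """Fully enumerated decision-task design."""

    framings: tuple[str, ...]
    contrast_levels: tuple[float, ...]
    positions: tuple[float, ...]
    orientation_set: tuple[float, ...]
    trial_list: tuple[TrialCondition, ...]

    @property
    def n_trials(self) -> int:
        return len(self.trial_list)


def contrast_triplets(levels) -> list[tuple[float, float, float]]:
    """Unordered triplets of contrast levels drawn without replacement."""
    return list(combinations(levels, 3))


def default_contrast_levels(n_levels: int = 5) -> tuple[float, ...]:
    """``n_levels`` linearly spaced contrasts in (0, 1]."""
    return tuple(np.linspace(1.0 / n_levels, 1.0, n_levels))


def enumerate_design(
    framings: tuple[str, ...] = ("high", "low"),
    n_levels: int = 5,
    n_positions: int = 3,
    orientation_rule: str = "identical_or_all_different",
) -> TaskDesign:
    """Enumerate every unique decision-trial condition exactly once.

    Parameters
    ----------
    framings : labels of the framing factor (default the two-level
        high/low contrast framing).
    n_levels : number of linearly spaced contrast levels (default 5).
    n_positions : number of stimulus locations (default 3).
    orientation_rule : ``"identical_or_all_different"`` (all three patches
        share one of 3 orientations, or carry all 3 in one of 6 ordered
        assignments: 9 conditions) or ``"fixed"`` (orientation not varied).

    Returns
    -------
    TaskDesign with ``trial_list`` holding every unique combination of
    framing x ordered contrast assignment x orientation condition.  With
    the defaults this is 2 x 60 x 9 = 1080 trials.
    """
    if orientation_rule not in ("identical_or_all_different", "fixed"):
        raise ConfigurationError(
            f"unknown orientation_rule {orientation_rule!r}; expected "
            "'identical_or_all_different' or 'fixed'"
        )
    if n_levels < n_positions:
        raise ConfigurationError(
            f"need at least as many contrast levels ({n_levels}) as "
            f"positions ({n_positions})"
        )
    levels = default_contrast_levels(n_levels)
    positions = tuple(POSITIONS[:n_positions])

    # Ordered assignments of a contrast triplet to the locations:
    # permutations of the levels taken n_positions at a time.
    contrast_assignments = list(permutations(levels, n_positions))

    if orientation_rule == "identical_or_all_different":
        orientation_conditions = [
            (o,) * n_positions for o in ORIENTATIONS
        ] + [tuple(p) for p in permutations(ORIENTATIONS, n_positions)]
    else:
        orientation_conditions = [(ORIENTATIONS[0],) * n_positions]

    trials = tuple(
        TrialCondition(framing=f, contrasts=c, orientations=o)
        for f in framings
        for c in contrast_assignments
        for o in orientation_conditions
    )
    return TaskDesign(
        framings=tuple(framings),
        contrast_levels=levels,
        positions=positions,
        orientation_set=ORIENTATIONS,
        trial_list=trials,
    )


def value_ranks(contrasts: tuple[float, ...], framing: str) -> dict[float, str]:
    """Map each position angle to its decision-value rank (H/M/L).

    Under "high" framing the highest contrast has the highest value;
    under "low" framing the ordering flips.
    """
    order = np.argsort(contrasts)  # ascending contrast
    labels = ["L", "M", "H"] if framing == "high" else ["H", "M", "L"]
    return {POSITIONS[pos]: labels[rank] for rank, pos in enumerate(order)}


@dataclass(frozen=True)
class LocalizerTrial:
    position: float
    orientation: float
    flicker: bool


def enumerate_localizer_block(
    n_positions: int = 3,
    n_orientations: int = 3,
    reps: int = 10,
) -> list[LocalizerTrial]:
    """One localizer block: each position x orientation combination
    repeated ``reps`` times, exactly one repetition per combination
    carrying the central fixation-flicker flag.

    With the defaults this yields 90 presentations and 9 flicker trials.
    The returned list is in enumeration order; shuffle it with the
    session seed when simulating.
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    trials = []
    for p in POSITIONS[:n_positions]:
        for o in ORIENTATIONS[:n_orientations]:
            for r in range(reps):
                trials.append(LocalizerTrial(p, o, flicker=(r == 0)))
    return trials
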