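"""Limit-of-stability task geometry and scoring.

The task: after calibration, eight targets are laid out around the home
position — four on the cardinal body axes at 75 % of the subject's maximal
CoP excursion in that direction, four on the 45-degree rays.  Targets light
up one at a time in random order; the subject has 10 s to move the CoP onto
each target and must then hold the home position for 5 s before the next one.
The trial score is the number of targets hit (0-8).

Because only the four cardinal directions are calibrated, the reachable
movement area is modelled as the rectangle with those four half-extents; the
diagonal targets are placed where the 45-degree rays meet that rectangle's
boundary (at the corner when adjacent extents are equal, on the nearer edge
otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError, FormatError
from .preprocess import HomePosition, PreprocessedTrial

__all__ = [
    "CARDINAL_DIRECTIONS",
    "DIRECTIONS_8",
    "CalibrationProfile",
    "TargetLayout",
    "TargetOutcome",
    "LoSScore",
    "compute_calibration",
    "place_targets",
    "detect_hits",
    "TARGET_TIMEOUT_S",
    "HOME_HOLD_S",
    "TARGET_DISTANCE_FRACTION",
]

CARDINAL_DIRECTIONS = ("forward", "backward", "left", "right")

#: the eight target directions, clockwise from anterior
DIRECTIONS_8 = (
    "forward",
    "forward_right",
    "right",
    "backward_right",
    "backward",
    "backward_left",
    "left",
    "forward_left",
)

#: targets sit at this fraction of the maximal calibrated excursion
TARGET_DISTANCE_FRACTION = 0.75
TARGET_TIMEOUT_S = 10.0
HOME_HOLD_S = 5.0

# unit vectors: x mediolateral (+right), y anteroposterior (+anterior)
_UNIT = {
    "forward": np.array([0.0, 1.0]),
    "backward": np.array([0.0, -1.0]),
    "left": np.array([-1.0, 0.0]),
    "right": np.array([1.0, 0.0]),
}


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-direction maximal CoP excursions and derived target distances.

    ``max_excursion`` maps each cardinal direction to the largest excursion
    (mm, measured from home) over the calibration attempts; targets are placed
    at 75 % of it.
    """

    max_excursion: Mapping[str, float]
    n_attempts: int = 3

    def __post_init__(self) -> None:
        missing = [d for d in CARDINAL_DIRECTIONS if d not in self.max_excursion]
        if missing:
            raise FormatError(f"calibration missing direction(s): {missing}")
        for d in CARDINAL_DIRECTIONS:
            if not self.max_excursion[d] > 0:
                raise DataError(
                    f"max excursion must be positive, got {self.max_excursion[d]} "
                    f"for {d!r}"
                )
        object.__setattr__(
            self,
            "max_excursion",
            {d: float(self.max_excursion[d]) for d in CARDINAL_DIRECTIONS},
        )

    @property
    def target_distance(self) -> dict[str, float]:
        """75 % of the maximal excursion, per direction (mm)."""
        return {d: TARGET_DISTANCE_FRACTION * v for d, v in self.max_excursion.items()}


@dataclass(frozen=True)
class TargetLayout:
    """Eight target positions around home, plus the hit radius (mm)."""

    home: HomePosition
    targets: Mapping[str, np.ndarray]
    target_radius: float

    def __post_init__(self) -> None:
        if not self.target_radius > 0:
            raise ConfigError(f"target radius must be positive, got {self.target_radius}")
        missing = [d for d in DIRECTIONS_8 if d not in self.targets]
        if missing:
            raise FormatError(f"layout missing target(s): {missing}")


@dataclass(frozen=True)
class TargetOutcome:
    direction: str
    hit: bool
    time_to_hit: Optional[float]  # seconds from target onset; None when missed
    attempted: bool = True


@dataclass(frozen=True)
class LoSScore:
    """Replayed trial outcome: hits per target and the 0-8 total."""

    total_score: int
    per_target: tuple
    truncated: bool
    timeout: float = TARGET_TIMEOUT_S
    hold: float = HOME_HOLD_S


def compute_calibration(
    attempts: Mapping[str, Sequence[float]],
    home: Optional[HomePosition] = None,
) -> CalibrationProfile:
    """Reduce per-direction calibration attempts to a profile.

    ``attempts`` maps each cardinal direction to the excursion magnitudes
    (mm, relative to home) of the recorded attempts — normally three.  The
    profile keeps the maximum per direction; targets go at 75 % of it.
    """
    missing = [d for d in CARDINAL_DIRECTIONS if d not in attempts or len(attempts[d]) == 0]
    if missing:
        raise FormatError(f"calibration attempts missing for direction(s): {missing}")
    max_exc = {}
    n = 0
    for d in CARDINAL_DIRECTIONS:
        vals = [float(v) for v in attempts[d]]
        nonpos = [v for v in vals if not v > 0]
        if nonpos:
            raise DataError(f"non-positive excursion(s) {nonpos} for direction {d!r}")
        max_exc[d] = max(vals)
        n = max(n, len(vals))
    return CalibrationProfile(max_excursion=max_exc, n_attempts=n)


def default_target_radius(calib: CalibrationProfile) -> float:
    """Hit radius when none is configured: 10 % of the mean target distance."""
    return 0.10 * float(np.mean(list(calib.target_distance.values())))


def place_targets(
    calib: CalibrationProfile,
    home: HomePosition,
    target_radius: Optional[float] = None,
) -> TargetLayout:
    """Lay out the 8 targets around home from a calibration profile.

    Cardinal targets sit at the per-direction target distance on their axis.
    Each diagonal target is the intersection of its 45-degree ray with the
    boundary of the rectangle whose half-extents are the four target
    distances: along a 45-degree ray both coordinates grow together, so the
    ray exits at ``(±m, ±m)`` with ``m`` the smaller of the two adjacent
    extents.
    """
    if target_radius is None:
        target_radius = default_target_radius(calib)
    dist = calib.target_distance
    h = home.as_array()
    targets: dict[str, np.ndarray] = {}
    for d in CARDINAL_DIRECTIONS:
        targets[d] = h + dist[d] * _UNIT[d]
    for ydir in ("forward", "backward"):
        for xdir in ("left", "right"):
            m = min(dist[xdir], dist[ydir])
            targets[f"{ydir}_{xdir}"] = h + m * (_UNIT[xdir] + _UNIT[ydir])
    return TargetLayout(home=home, targets=targets, target_radius=float(target_radius))


def detect_hits(
    trial: PreprocessedTrial,
    layout: TargetLayout,
    order: Sequence[str],
    timeout: float = TARGET_TIMEOUT_S,
    hold: float = HOME_HOLD_S,
) -> LoSScore:
    """Replay the task timeline against a trajectory and score it.

    For each target in ``order``: the target is hit at the first sample
    within ``target_radius`` of it no later than ``timeout`` seconds after
    target onset (inclusive).  After a hit or timeout the home phase begins:
    the CoP must stay within ``target_radius`` of home continuously for
    ``hold`` seconds.  If the trajectory ends mid-phase, the score covers the
    completed phases and the result is flagged truncated.
    """
    unknown = [d for d in order if d not in layout.targets]
    if unknown:
        raise ConfigError(f"unknown target direction(s) in order: {unknown}")
    if len(order) != len(set(order)):
        raise ConfigError("target order contains duplicates")
    t = trial.traj.t
    pos = np.column_stack([trial.traj.x, trial.traj.y])
    home = layout.home.as_array()
    r = layout.target_radius
    n = t.size

    outcomes: list[TargetOutcome] = []
    truncated = False
    i = 0  # index of the first sample of the current phase
    for direction in order:
        if i >= n:
            outcomes.append(TargetOutcome(direction, False, None, attempted=False))
            truncated = True
            continue
        onset = t[i]
        # --- target phase ---
        in_window = np.flatnonzero(t[i:] - onset <= timeout) + i
        d2 = np.sum((pos[in_window] - layout.targets[direction]) ** 2, axis=1)
        hit_local = np.flatnonzero(d2 <= r * r)
        window_covers_timeout = t[-1] - onset >= timeout
        if hit_local.size:
            j = in_window[hit_local[0]]
            outcomes.append(TargetOutcome(direction, True, float(t[j] - onset)))
            i = j + 1
        elif window_covers_timeout:
            outcomes.append(TargetOutcome(direction, False, None))
            after = np.flatnonzero(t - onset > timeout)
            i = int(after[0]) if after.size else n
        else:
            # record ends inside the 10-s window without a hit
            outcomes.append(TargetOutcome(direction, False, None, attempted=False))
            truncated = True
            i = n
            continue
        # --- home phase: continuous hold s within radius of home ---
        i = _home_hold_end(t, pos, home, r, hold, i)
        if i < 0:
            truncated = True
            i = n

    total = sum(o.hit for o in outcomes)
    return LoSScore(
        total_score=int(total),
        per_target=tuple(outcomes),
        truncated=truncated,
        timeout=timeout,
        hold=hold,
    )


def _home_hold_end(t, pos, home, radius, hold, start) -> int:
    """First index after a continuous ``hold``-second stay near home.

    Returns -1 when the record ends before the hold completes.
    """
    n = t.size
    inside = np.sum((pos[start:] - home) ** 2, axis=1) <= radius * radius
    run_start_time = None
    for k in range(inside.size):
        if inside[k]:
            if run_start_time is None:
                run_start_time = t[start + k]
            if t[start + k] - run_start_time >= hold:
                return start + k + 1
        else:
            run_start_time = None
    return -1
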