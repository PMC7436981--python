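"""Signal conditioning for LoS trials.

The recorded trial starts with 5 s of quiet stance used only to locate the
home position; analysis removes that prefix and low-pass filters the rest
with a zero-phase 4th-order Butterworth at 10 Hz.  Zero-phase (forward plus
backward) filtering is the posturography norm — a causal filter's group delay
would shift dwell-time boundaries — so the effective magnitude response is
the squared single-pass response: gain 1/2, not 1/sqrt(2), at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ConfigError, DataError
from .io import CoPTrajectory

__all__ = [
    "HomePosition",
    "PreprocessedTrial",
    "lowpass_filter",
    "estimate_home",
    "trim_quiet_stance",
    "preprocess_trial",
    "QUIET_STANCE_S",
]

#: default duration of the quiet-stance prefix (seconds)
QUIET_STANCE_S = 5.0


@dataclass(frozen=True)
class HomePosition:
    """Home (reference) CoP position in mm, the quiet-stance average."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise DataError(f"home position must be finite, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class PreprocessedTrial:
    """A filtered trial with the quiet-stance prefix removed.

    ``traj.t`` is re-zeroed to start at 0; ``home`` is estimated from the
    removed prefix.
    """

    traj: CoPTrajectory
    home: HomePosition
    removed_duration: float = QUIET_STANCE_S


def lowpass_filter(traj: CoPTrajectory, order: int = 4, cutoff: float = 10.0) -> CoPTrajectory:
    """Zero-phase Butterworth low-pass of both CoP coordinates.

    Applies :func:`scipy.signal.filtfilt` (reflective edge padding) with a
    Butterworth design of the given order per pass, so the two-pass magnitude
    at ``cutoff`` is 0.5.  Timestamps and length are unchanged; DC gain is 1.
    """
    if not 0 < cutoff < traj.fs / 2:
        raise ConfigError(
            f"cutoff must lie in (0, fs/2) = (0, {traj.fs / 2} Hz), got {cutoff} Hz"
        )
    min_len = 3 * (order + 1)
    if len(traj) <= min_len:
        raise DataError(
            f"signal too short to filter: {len(traj)} samples, need > {min_len}"
        )
    b, a = butter(order, cutoff, btype="low", fs=traj.fs)
    x = filtfilt(b, a, traj.x, padtype="even")
    y = filtfilt(b, a, traj.y, padtype="even")
    return replace(traj, x=x, y=y)


def estimate_home(traj: CoPTrajectory, window: float = QUIET_STANCE_S) -> HomePosition:
    """Average the CoP over the initial quiet-stance window.

    Uses all samples with ``t - t[0] < window``; the trial must last at least
    ``window`` seconds.
    """
    if traj.duration < window:
        raise DataError(
            f"trial lasts {traj.duration:.3f} s but home estimation needs "
            f"{window:.3f} s of quiet stance"
        )
    mask = (traj.t - traj.t[0]) < window
    return HomePosition(x=float(np.mean(traj.x[mask])), y=float(np.mean(traj.y[mask])))


def trim_quiet_stance(traj: CoPTrajectory, window: float = QUIET_STANCE_S) -> CoPTrajectory:
    """Drop the first ``window`` seconds and re-zero the time axis.

    Retained sample values are untouched.
    """
    mask = (traj.t - traj.t[0]) >= window
    if mask.sum() < 2:
        raise DataError(
            f"trial lasts {traj.duration:.3f} s; nothing left after removing "
            f"{window:.3f} s of quiet stance"
        )
    t = traj.t[mask]
    return CoPTrajectory(t=t - t[0], x=traj.x[mask], y=traj.y[mask], fs=traj.fs)


def preprocess_trial(
    traj: CoPTrajectory,
    order: int = 4,
    cutoff: float = 10.0,
    quiet_stance_s: float = QUIET_STANCE_S,
    filter_before_trim: bool = False,
) -> PreprocessedTrial:
    """Home estimation, quiet-stance removal and low-pass filtering.

    The home position is always computed from the raw (unfiltered) prefix.
    By default the prefix is removed first and the remainder filtered;
    ``filter_before_trim=True`` filters the whole record before trimming,
    which changes only edge samples near the trim boundary.
    """
    home = estimate_home(traj, window=quiet_stance_s)
    if filter_before_trim:
        filtered = lowpass_filter(traj, order=order, cutoff=cutoff)
        out = trim_quiet_stance(filtered, window=quiet_stance_s)
    else:
        trimmed = trim_quiet_stance(traj, window=quiet_stance_s)
        out = lowpass_filter(trimmed, order=order, cutoff=cutoff)
    return PreprocessedTrial(traj=out, home=home, removed_duration=quiet_stance_s)
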