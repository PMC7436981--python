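"""Seeded synthetic CoP data: calibration, LoS trials, dwell patterns, cohorts.

Everything downstream of acquisition is testable without recordings:

* :func:`simulate_calibration` draws per-direction maximal-excursion attempts;
* :func:`simulate_dwell_trajectory` is the exactness harness for the FTR
  statistic — it places exact sample counts uniformly inside each RFA band
  (no dynamics, no filtering), so the expected FTRs are known to rounding;
* :func:`simulate_los_trial` generates a full task timeline — 5 s quiet
  stance, then eight goal-directed reaches with 10-s timeouts and 5-s home
  holds — as critically damped point-mass motion plus band-limited (4-7 Hz)
  tremor, with a ground-truth event log;
* :func:`make_cohort` builds whole low-/high-FoF cohorts whose trials encode
  group-dependent dwell patterns: low-FoF subjects park the CoP near the
  centre (region 1), high-FoF subjects drift through the middle band
  (region 2), mirroring the reduced peripheral mobility and poorer CoP
  guidance described clinically for fearful parkinsonian patients.

Cohort trials use a segment-based dwell generator (contiguous 0.5-5 s holds
at anchor points inside the target region) rather than i.i.d. shuffled
samples: independent per-sample placement is spectrally white, and the 10 Hz
analysis low-pass would collapse it toward its mean, erasing the dwell
structure.  Dwell segments are quasi-static, so they survive filtering.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ConfigError, DataError
from .ftr import RFASet, classify_samples
from .io import HEIGHT_LEVELS, CoPTrajectory, Session, SubjectRecord, TrialCondition
from .preprocess import QUIET_STANCE_S, HomePosition
from .protocol import (
    DIRECTIONS_8,
    HOME_HOLD_S,
    TARGET_TIMEOUT_S,
    CalibrationProfile,
    TargetLayout,
    compute_calibration,
    place_targets,
)

__all__ = [
    "SimProfile",
    "SimTrial",
    "low_fof_profile",
    "high_fof_profile",
    "simulate_calibration",
    "simulate_dwell_trajectory",
    "simulate_los_trial",
    "make_cohort",
    "cohort_feature_table",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class SimProfile:
    """Behavioural parameters of a simulated participant group.

    Units: speeds mm/s, amplitudes/accuracies mm, bands Hz.  The dwell
    fractions (region 1, 2, 3, outside) drive the dwell-mode generators and
    must sum to 1; ``hit_probability`` is the per-target chance that a reach
    is aimed at the target rather than falling short.
    """

    label: str
    reach_speed: float = 50.0
    reach_accuracy: float = 1.5
    tremor_amplitude: float = 0.6
    tremor_band: tuple[float, float] = (4.0, 7.0)
    dwell_fractions: tuple[float, float, float, float] = (0.57, 0.28, 0.15, 0.0)
    hit_probability: float = 0.9
    max_excursion_means: Mapping[str, float] = field(
        default_factory=lambda: {"forward": 40.0, "backward": 35.0, "left": 32.0, "right": 32.0}
    )
    calibration_noise_frac: float = 0.05
    fes_i_range: tuple[int, int] = (16, 64)
    subject_dwell_sd: float = 0.08  # between-subject log-ratio jitter
    trial_dwell_sd: float = 0.05  # between-trial log-ratio jitter

    def __post_init__(self) -> None:
        p = np.asarray(self.dwell_fractions, dtype=float)
        if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ConfigError(
                f"dwell fractions must be 4 nonnegative values summing to 1, got {tuple(p)}"
            )
        if not (self.reach_speed > 0 and self.reach_accuracy >= 0 and self.tremor_amplitude >= 0):
            raise ConfigError("speeds must be positive and amplitudes nonnegative")
        if not 0.0 <= self.hit_probability <= 1.0:
            raise ConfigError(f"hit_probability must be in [0,1], got {self.hit_probability}")


def low_fof_profile() -> SimProfile:
    """Confident mover: fast accurate reaches, CoP parked near the centre."""
    return SimProfile(
        label="low_fof_like",
        reach_speed=60.0,
        reach_accuracy=1.2,
        tremor_amplitude=0.5,
        dwell_fractions=(0.68, 0.15, 0.13, 0.04),
        hit_probability=0.95,
        max_excursion_means={"forward": 42.0, "backward": 36.0, "left": 33.0, "right": 33.0},
        fes_i_range=(16, 22),
    )


def high_fof_profile() -> SimProfile:
    """Fearful mover: slower, less accurate, lingers in the middle band."""
    return SimProfile(
        label="high_fof_like",
        reach_speed=35.0,
        reach_accuracy=2.5,
        tremor_amplitude=1.0,
        dwell_fractions=(0.45, 0.36, 0.15, 0.04),
        hit_probability=0.70,
        max_excursion_means={"forward": 35.0, "backward": 30.0, "left": 28.0, "right": 28.0},
        fes_i_range=(23, 64),
    )


@dataclass(frozen=True)
class SimTrial:
    """A simulated LoS trial with its ground truth."""

    traj: CoPTrajectory
    event_log: dict
    true_score: int
    true_region_dwell: tuple[float, float, float, float]


def simulate_calibration(profile: SimProfile, rng_seed) -> dict[str, list[float]]:
    """Three positive excursion attempts per direction around the profile means."""
    rng = _rng(rng_seed)
    attempts: dict[str, list[float]] = {}
    for d, mean in profile.max_excursion_means.items():
        sd = profile.calibration_noise_frac * mean
        vals = mean + sd * rng.standard_normal(3)
        attempts[d] = [float(max(v, 0.1 * mean)) for v in vals]
    return attempts


def _apportion(fractions: Sequence[float], n: int) -> np.ndarray:
    """Integer counts per fraction summing exactly to n (largest remainder)."""
    p = np.asarray(fractions, dtype=float)
    exact = p * n
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def _uniform_in_band(rfas: RFASet, region: int, count: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside one disjoint RFA band (region 0 = outside ring).

    Rejection sampling from the enclosing rectangle (1.5x the outer rectangle
    for the outside ring, which is truncated there by construction).
    """
    if count == 0:
        return np.empty((0, 2))
    cx, cy = rfas.center
    if region == 1:
        outer_level, inner_level = rfas.levels[0], None
    elif region == 2:
        outer_level, inner_level = rfas.levels[1], rfas.levels[0]
    elif region == 3:
        outer_level, inner_level = rfas.levels[2], rfas.levels[1]
    elif region == 0:
        outer_level, inner_level = 1.5 * rfas.levels[2], rfas.levels[2]
    else:
        raise ConfigError(f"unknown region {region}")
    le, ri, ba, fo = rfas.half_extents(outer_level)
    if inner_level is not None and outer_level <= inner_level:
        raise ConfigError(f"region {region} has zero area")
    out = np.empty((0, 2))
    while out.shape[0] < count:
        m = max(4 * (count - out.shape[0]), 64)
        x = rng.uniform(cx - le, cx + ri, m)
        y = rng.uniform(cy - ba, cy + fo, m)
        keep = np.ones(m, dtype=bool)
        if inner_level is not None:
            keep = ~rfas.contains(x, y, inner_level)
        out = np.vstack([out, np.column_stack([x, y])[keep]])
    return out[:count]


def simulate_dwell_trajectory(
    fractions: Sequence[float],
    rfas: RFASet,
    n_samples: int,
    rng_seed,
    fs: float = 100.0,
) -> CoPTrajectory:
    """Exact-placement dwell trajectory: the FTR oracle harness.

    Emits exactly the apportioned number of samples uniformly inside each RFA
    band (region 1, 2, 3, outside), shuffled in time, so the FTRs computed
    against the *same* ``rfas`` (fixed centre, no re-centring, no filtering)
    equal the requested fractions up to integer rounding.
    """
    p = np.asarray(fractions, dtype=float)
    if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ConfigError(f"fractions must be 4 nonnegative values summing to 1, got {p}")
    if n_samples < 4:
        raise DataError(f"need at least 4 samples, got {n_samples}")
    rng = _rng(rng_seed)
    counts = _apportion(p, n_samples)
    pts = np.vstack(
        [
            _uniform_in_band(rfas, region, counts[i], rng)
            for i, region in enumerate((1, 2, 3, 0))
        ]
    )
    pts = pts[rng.permutation(n_samples)]
    t = np.arange(n_samples) / fs
    return CoPTrajectory(t=t, x=pts[:, 0], y=pts[:, 1], fs=fs)


def _band_limited_tremor(
    n: int, fs: float, band: tuple[float, float], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, 2) band-limited noise with the requested RMS amplitude per axis."""
    if amplitude == 0 or n < 40:
        return np.zeros((n, 2))
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    b, a = butter(2, [lo, hi], btype="bandpass", fs=fs)
    noise = filtfilt(b, a, rng.standard_normal((2, n)), axis=1).T
    rms = np.sqrt(np.mean(noise**2, axis=0))
    rms[rms == 0] = 1.0
    return noise / rms * amplitude


def _critically_damped(start: np.ndarray, aim: np.ndarray, omega: float, n: int, fs: float) -> np.ndarray:
    """Positions of a critically damped unit step from start to aim, n samples."""
    t = (np.arange(n) + 1) / fs
    decay = (1.0 + omega * t) * np.exp(-omega * t)
    return aim + np.outer(decay, start - aim)


def simulate_los_trial(
    profile: SimProfile,
    layout: TargetLayout,
    rng_seed,
    fs: float = 100.0,
    order: Optional[Sequence[str]] = None,
    timeout: float = TARGET_TIMEOUT_S,
    hold: float = HOME_HOLD_S,
) -> SimTrial:
    """Generate one full LoS trial and its ground-truth score.

    Timeline: 5 s quiet stance at home, then for each of the eight targets (in
    ``order``, shuffled by the seed when not given) a goal-directed reach —
    critically damped motion toward the target (successful reaches, chosen
    with ``hit_probability``) or toward a point well short of it (failures,
    which run out the 10-s timeout) — followed by a return to home and a hold
    comfortably exceeding the required 5 s.  Band-limited tremor rides on the
    whole record; during quiet stance and home holds the excursion from home
    is clamped well inside the hit radius so holds are never broken by noise.

    The ground truth (score, per-phase event log) is obtained by replaying
    the task rules over the generated samples themselves, independently of
    :func:`copstab.protocol.detect_hits`.
    """
    rng = _rng(rng_seed)
    if order is None:
        order = list(DIRECTIONS_8)
        rng.shuffle(order)
    order = list(order)
    home = layout.home.as_array()
    r = layout.target_radius
    dt = 1.0 / fs

    chunks: list[np.ndarray] = []
    protected: list[np.ndarray] = []  # masks: clamp these samples near home

    def add(segment: np.ndarray, protect: bool) -> None:
        chunks.append(segment)
        protected.append(np.full(segment.shape[0], protect))

    nq = int(round(QUIET_STANCE_S * fs))
    add(np.tile(home, (nq, 1)), True)

    pos = home.copy()
    for direction in order:
        target = np.asarray(layout.targets[direction], dtype=float)
        d = float(np.linalg.norm(target - pos))
        success = rng.random() < profile.hit_probability
        if success:
            noise = rng.standard_normal(2) * profile.reach_accuracy
            norm = np.linalg.norm(noise)
            if norm > 0.3 * r:
                noise *= 0.3 * r / norm
            aim = target + noise
        else:
            back = max(2.5 * r, 0.35 * d)
            aim = target + (pos - target) / max(d, 1e-9) * back
        omega = math.e * profile.reach_speed / max(d, 1e-9)
        if success:
            # run until well inside the hit radius (margin for tremor), + short dwell
            n_reach = int(math.ceil(_time_to_converge(d, omega, 0.3 * r) * fs)) + int(0.3 * fs)
            n_reach = min(n_reach, int((timeout - 0.5) * fs))
        else:
            n_reach = int(timeout * fs)  # run out the clock short of the target
        seg = _critically_damped(pos, aim, omega, n_reach, fs)
        add(seg, False)
        pos = seg[-1]
        # return home and hold (1 s beyond the required 5 s, for margin)
        d_home = float(np.linalg.norm(pos - home))
        omega_h = math.e * profile.reach_speed / max(d_home, 1e-9)
        n_ret = int(math.ceil(_time_to_converge(d_home, omega_h, 0.2 * r) * fs))
        seg = _critically_damped(pos, home, omega_h, n_ret, fs)
        add(seg, False)
        add(np.tile(home, (int((hold + 1.0) * fs), 1)), True)
        pos = home.copy()

    backbone = np.vstack(chunks)
    protect = np.concatenate(protected)
    n = backbone.shape[0]
    tremor = _band_limited_tremor(n, fs, profile.tremor_band, profile.tremor_amplitude, rng)
    xy = backbone + tremor
    # clamp protected (home-hold / quiet-stance) samples well inside the radius
    disp = xy[protect] - home
    norms = np.linalg.norm(disp, axis=1)
    cap = 0.6 * r
    over = norms > cap
    disp[over] *= (cap / norms[over])[:, None]
    xy[protect] = home + disp

    t = np.arange(n) * dt
    traj = CoPTrajectory(t=t, x=xy[:, 0], y=xy[:, 1], fs=fs)

    task_mask = t - t[0] >= QUIET_STANCE_S
    outcomes, phases = _replay(
        t[task_mask] - t[task_mask][0], xy[task_mask], layout, order, timeout, hold
    )
    true_score = sum(1 for o in outcomes if o["hit"])
    dwell = _region_dwell(xy[task_mask], layout)
    return SimTrial(
        traj=traj,
        event_log={"order": order, "phases": phases, "timeout_s": timeout, "hold_s": hold},
        true_score=int(true_score),
        true_region_dwell=dwell,
    )


def _time_to_converge(d: float, omega: float, tol: float) -> float:
    """Time for a critically damped step of size d to come within tol."""
    if d <= tol:
        return 0.05
    # solve (1 + w t) exp(-w t) = tol/d by bisection on w t
    ratio = tol / d
    lo, hi = 0.0, 60.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if (1 + mid) * math.exp(-mid) > ratio:
            lo = mid
        else:
            hi = mid
    return hi / omega


def _replay(t, xy, layout: TargetLayout, order, timeout, hold):
    """Per-sample replay of the task rules; the simulator's own bookkeeping."""
    home = layout.home.as_array()
    r2 = layout.target_radius**2
    n = t.size
    outcomes = []
    phases = []
    i = 0
    for direction in order:
        target = np.asarray(layout.targets[direction], dtype=float)
        if i >= n:
            outcomes.append({"direction": direction, "hit": False, "time_to_hit": None})
            continue
        onset = t[i]
        hit_time = None
        j = i
        while j < n and t[j] - onset <= timeout:
            if (xy[j, 0] - target[0]) ** 2 + (xy[j, 1] - target[1]) ** 2 <= r2:
                hit_time = t[j]
                break
            j += 1
        if hit_time is not None:
            outcomes.append(
                {"direction": direction, "hit": True, "time_to_hit": float(hit_time - onset)}
            )
            phases.append(
                {"type": "target", "direction": direction, "onset": float(onset),
                 "end": float(hit_time), "hit": True}
            )
            i = j + 1
        else:
            outcomes.append({"direction": direction, "hit": False, "time_to_hit": None})
            phases.append(
                {"type": "target", "direction": direction, "onset": float(onset),
                 "end": float(min(onset + timeout, t[-1])), "hit": False}
            )
            while i < n and t[i] - onset <= timeout:
                i += 1
        # home phase
        run_start = None
        home_done = None
        k = i
        while k < n:
            if (xy[k, 0] - home[0]) ** 2 + (xy[k, 1] - home[1]) ** 2 <= r2:
                if run_start is None:
                    run_start = t[k]
                if t[k] - run_start >= hold:
                    home_done = k
                    break
            else:
                run_start = None
            k += 1
        if home_done is None:
            i = n
        else:
            phases.append({"type": "home", "onset": float(t[i]) if i < n else None,
                           "end": float(t[home_done])})
            i = home_done + 1
    return outcomes, phases


def _layout_reference(layout: TargetLayout) -> dict[str, float]:
    """Per-direction target distances recovered from the cardinal targets."""
    h = layout.home.as_array()
    return {
        "forward": float(layout.targets["forward"][1] - h[1]),
        "backward": float(h[1] - layout.targets["backward"][1]),
        "left": float(h[0] - layout.targets["left"][0]),
        "right": float(layout.targets["right"][0] - h[0]),
    }


def _region_dwell(xy, layout: TargetLayout) -> tuple[float, float, float, float]:
    rfas = RFASet(center=(layout.home.x, layout.home.y), reference=_layout_reference(layout))
    region = classify_samples(xy[:, 0], xy[:, 1], rfas)
    counts = np.bincount(region, minlength=4)
    n = region.size
    return (counts[1] / n, counts[2] / n, counts[3] / n, counts[0] / n)


# ---------------------------------------------------------------------------
# cohort generation (segment-based dwell trials)
# ---------------------------------------------------------------------------


def _jitter_fractions(p, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Logistic-normal perturbation of a composition (keeps sum 1, >= 0)."""
    p = np.asarray(p, dtype=float)
    z = np.log(np.maximum(p, 1e-6)) + sd * rng.standard_normal(p.size)
    q = np.exp(z)
    return q / q.sum()


def _segment_dwell_trial(
    fractions,
    rfas: RFASet,
    rng: np.random.Generator,
    duration_s: float = 110.0,
    fs: float = 100.0,
    quiet_stance_s: float = QUIET_STANCE_S,
    jitter_mm: float = 0.3,
    ramp_s: float = 0.15,
) -> CoPTrajectory:
    """Quasi-static dwell trial: quiet stance, then anchored dwell segments.

    Region occupancy follows ``fractions`` up to transition contamination
    (linear ramps between anchors) — realistic enough to survive the 10 Hz
    low-pass and the downstream median re-centring.
    """
    n_task = int(round(duration_s * fs))
    nq = int(round(quiet_stance_s * fs))
    home = np.asarray(rfas.center, dtype=float)
    pts = [np.tile(home, (nq, 1)) + jitter_mm * rng.standard_normal((nq, 2))]
    pos = home.copy()
    placed = 0
    while placed < n_task:
        region_idx = rng.choice(4, p=np.asarray(fractions, dtype=float))
        region = (1, 2, 3, 0)[region_idx]
        anchor = _uniform_in_band(rfas, region, 1, rng)[0]
        n_seg = int(np.clip(rng.exponential(1.0), 0.3, 3.0) * fs)
        n_seg = min(n_seg, n_task - placed)
        n_ramp = min(int(ramp_s * fs), n_seg)
        ramp = pos + (anchor - pos) * np.linspace(0, 1, n_ramp + 1)[1:, None]
        n_hold = n_seg - n_ramp
        hold = np.tile(anchor, (n_hold, 1)) + jitter_mm * rng.standard_normal((n_hold, 2))
        pts.append(np.vstack([ramp, hold]) if n_ramp else hold)
        pos = anchor
        placed += n_seg
    xy = np.vstack(pts)
    t = np.arange(xy.shape[0]) / fs
    return CoPTrajectory(t=t, x=xy[:, 0], y=xy[:, 1], fs=fs)


#: extra dwell mass shifted from region 1 to region 2 under postural threat
HEIGHT_THREAT_SHIFT = {"ground": 0.0, "h20cm": 0.015, "h40cm": 0.035}


def _shift_threat(p: np.ndarray, shift: float) -> np.ndarray:
    q = p.copy()
    moved = min(shift, q[0])
    q[0] -= moved
    q[1] += moved
    return q


def make_cohort(
    n_low: int,
    n_high: int,
    rng_seed,
    fs: float = 100.0,
    trial_duration_s: float = 110.0,
    low_profile: Optional[SimProfile] = None,
    high_profile: Optional[SimProfile] = None,
) -> list[Session]:
    """Simulate a cohort of sessions: 3 repetitions at each of 3 height levels.

    Each subject gets group-consistent FES-I and clinical scores, a calibrated
    target geometry, and per-trial dwell fractions — the group profile's
    fractions with between-subject and between-trial logistic-normal jitter,
    plus a small region-1-to-region-2 shift at raised height (postural
    threat).  Deterministic under the seed.
    """
    if n_low < 0 or n_high < 0:
        raise ConfigError("cohort sizes must be nonnegative")
    rng = _rng(rng_seed)
    low = low_profile or low_fof_profile()
    high = high_profile or high_fof_profile()
    sessions: list[Session] = []
    groups = [("low", low)] * n_low + [("high", high)] * n_high
    for idx, (group, profile) in enumerate(groups):
        sid = f"SIM{idx + 1:03d}"
        fes_lo, fes_hi = profile.fes_i_range
        fes_i = int(rng.integers(fes_lo, fes_hi + 1))
        if group == "low":
            subject = SubjectRecord(
                subject_id=sid, fes_i=fes_i,
                pt=int(rng.choice([0, 0, 0, 1])),
                bbs=int(np.clip(round(rng.normal(53.3, 2.4)), 0, 56)),
                tug=float(max(rng.normal(6.6, 0.7), 3.0)),
                hy_stage=float(rng.choice([1, 1.5, 2])),
            )
        else:
            subject = SubjectRecord(
                subject_id=sid, fes_i=fes_i,
                pt=int(rng.choice([1, 1, 2, 2, 3])),
                bbs=int(np.clip(round(rng.normal(44.5, 4.9)), 0, 56)),
                tug=float(max(rng.normal(8.5, 1.6), 3.0)),
                hy_stage=float(rng.choice([2, 2.5, 3])),
            )
        attempts = simulate_calibration(profile, rng)
        calib = compute_calibration(attempts)
        home = HomePosition(0.0, 0.0)
        rfas = RFASet(center=(home.x, home.y), reference=calib.target_distance)
        subj_fracs = _jitter_fractions(profile.dwell_fractions, profile.subject_dwell_sd, rng)
        trials = []
        for level in HEIGHT_LEVELS:
            base = _shift_threat(subj_fracs, HEIGHT_THREAT_SHIFT[level])
            for rep in (1, 2, 3):
                fracs = _jitter_fractions(base, profile.trial_dwell_sd, rng)
                traj = _segment_dwell_trial(
                    fracs, rfas, rng, duration_s=trial_duration_s, fs=fs
                )
                trials.append((TrialCondition(level, rep), traj, None))
        sessions.append(Session(subject=subject, calibration=calib, trials=trials))
    return sessions


def cohort_feature_table(sessions: Sequence[Session]):
    """Per-subject FTR features from the full analysis pipeline, as a DataFrame.

    Runs preprocess -> RFA construction (median centre) -> FTR computation for
    every trial and averages the three repetitions per height level; columns
    are ``ftr1_<level>``, ``ftr2_<level>``, ``ftr3_<level>``, ``ftr12_<level>``
    plus subject metadata.
    """
    import pandas as pd

    from .ftr import aggregate_trials, build_rfas, compute_ftrs
    from .preprocess import preprocess_trial

    rows = []
    for session in sessions:
        row: dict = {
            "subject_id": session.subject.subject_id,
            "fes_i": session.subject.fes_i,
            "fof_group": session.subject.fof_group,
            "pt": session.subject.pt,
            "bbs": session.subject.bbs,
            "tug": session.subject.tug,
        }
        by_level: dict[str, list] = {}
        for cond, traj, _ in session.trials:
            pre = preprocess_trial(traj)
            rfas = build_rfas(session.calibration, pre.traj)
            by_level.setdefault(cond.height_level, []).append(compute_ftrs(pre.traj, rfas))
        for level, results in by_level.items():
            agg = aggregate_trials(results)
            row[f"ftr1_{level}"] = agg.ftr1
            row[f"ftr2_{level}"] = agg.ftr2
            row[f"ftr3_{level}"] = agg.ftr3
            row[f"ftr12_{level}"] = agg.ftr12
        rows.append(row)
    return pd.DataFrame(rows)
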