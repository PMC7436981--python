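"""Reading, writing and validating CoP trajectories, subjects and sessions.

On-disk formats
---------------
CoP trajectory CSV: comma-separated, UTF-8, header ``time_s,cop_x_mm,cop_y_mm``,
optionally preceded by ``#``-prefixed metadata lines of the form
``# key: value`` (recognised keys: ``fs_hz``, ``units``, ``subject_id``,
``height_level``, ``repetition_index``).  Coordinates are mediolateral (x,
positive toward the subject's right) and anteroposterior (y, positive
anterior), in millimetres internally; a ``units`` key of ``mm``, ``cm`` or
``m`` declares the on-disk unit and is converted on read.

Session manifest: a JSON file listing the subject record, calibration
attempts, and per-trial CSV paths with condition labels.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

__all__ = [
    "CoPTrajectory",
    "TrialCondition",
    "SubjectRecord",
    "Session",
    "read_cop_csv",
    "write_cop_csv",
    "read_session_manifest",
    "write_session_manifest",
    "validate_session",
    "HEIGHT_LEVELS",
]

HEIGHT_LEVELS = ("ground", "h20cm", "h40cm")

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}

#: tolerance on per-step deviation from 1/fs, in seconds
_UNIFORMITY_TOL_S = 1e-6


@dataclass(frozen=True)
class CoPTrajectory:
    """A uniformly sampled 2-D centre-of-pressure time series.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing and uniform.
    x, y : ndarray
        Mediolateral / anteroposterior CoP position in millimetres.
    fs : float
        Sampling rate in Hz, consistent with ``t`` to within 1e-6 s per step.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or t.size < 2:
            raise DataError("trajectory needs at least 2 samples in 1-D arrays")
        if x.shape != t.shape or y.shape != t.shape:
            raise DataError(
                f"length mismatch: t has {t.size}, x has {x.size}, y has {y.size}"
            )
        for name, arr in (("t", t), ("x", x), ("y", y)):
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise DataError(
                    f"non-finite values in {name}: {bad.size} samples, "
                    f"first at index {bad[0]}"
                )
        dt = np.diff(t)
        nonmono = np.flatnonzero(dt <= 0)
        if nonmono.size:
            raise DataError(
                f"time not strictly increasing, first offending index {nonmono[0] + 1}"
            )
        if not (self.fs > 0):
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        dev = np.max(np.abs(dt - 1.0 / self.fs))
        if dev >= _UNIFORMITY_TOL_S:
            raise DataError(
                f"non-uniform sampling: max |dt - 1/fs| = {dev:.3g} s "
                f"exceeds {_UNIFORMITY_TOL_S:g} s"
            )

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Trial duration in seconds (last minus first timestamp)."""
        return float(self.t[-1] - self.t[0])

    def translated(self, dx: float, dy: float) -> "CoPTrajectory":
        return replace(self, x=self.x + dx, y=self.y + dy)


@dataclass(frozen=True)
class TrialCondition:
    """Height level and repetition index of a recorded LoS trial."""

    height_level: str
    repetition_index: int

    def __post_init__(self) -> None:
        if self.height_level not in HEIGHT_LEVELS:
            raise DataError(
                f"height_level must be one of {HEIGHT_LEVELS}, got {self.height_level!r}"
            )
        if self.repetition_index not in (1, 2, 3):
            raise DataError(
                f"repetition_index must be 1..3, got {self.repetition_index}"
            )


def fesi_group(fes_i: int) -> str:
    """Dichotomise a FES-I total score into ``'low'`` / ``'high'`` fear of falling.

    The FES-I totals 16 (no concern) to 64 (severe concern); scores of 16-22
    are graded low FoF and 23-64 high FoF.
    """
    if not 16 <= fes_i <= 64:
        raise DataError(f"FES-I total must be within [16, 64], got {fes_i}")
    return "low" if fes_i <= 22 else "high"


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical metadata for one participant.

    ``fof_group`` is derived from the FES-I total when omitted; if supplied it
    must agree with the FES-I grouping.
    """

    subject_id: str
    fes_i: int
    pt: Optional[int] = None
    bbs: Optional[int] = None
    tug: Optional[float] = None
    hy_stage: Optional[float] = None
    moca: Optional[int] = None
    hads_anxiety: Optional[int] = None
    hads_depression: Optional[int] = None
    fof_group: Optional[str] = None

    def __post_init__(self) -> None:
        derived = fesi_group(self.fes_i)
        if self.fof_group is None:
            object.__setattr__(self, "fof_group", derived)
        if self.pt is not None and not 0 <= self.pt <= 4:
            raise DataError(f"Pull test score must be 0..4, got {self.pt}")
        if self.bbs is not None and not 0 <= self.bbs <= 56:
            raise DataError(f"BBS score must be 0..56, got {self.bbs}")
        if self.tug is not None and not self.tug > 0:
            raise DataError(f"TUG time must be positive, got {self.tug}")
        if self.hy_stage is not None and self.hy_stage not in (1, 1.5, 2, 2.5, 3):
            raise DataError(f"HY stage must be in {{1,1.5,2,2.5,3}}, got {self.hy_stage}")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectRecord":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class Session:
    """One subject's full recording session.

    ``calibration`` is the per-direction calibration (``CalibrationProfile``
    from :mod:`copstab.protocol`); trials pair a :class:`TrialCondition` with
    a :class:`CoPTrajectory` and an optional event log.
    """

    subject: SubjectRecord
    calibration: object  # CalibrationProfile; kept loose to avoid an import cycle
    trials: list = field(default_factory=list)  # (TrialCondition, CoPTrajectory, event_log|None)


def _parse_metadata(lines: list[str]) -> dict:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    return meta


def read_cop_csv(path) -> CoPTrajectory:
    """Read a CoP trajectory CSV, validating columns, monotonicity and NaNs.

    The sampling rate is taken from an ``# fs_hz:`` metadata line when
    present, otherwise inferred as ``1/median(dt)``; an explicit rate must
    agree with the timestamps to within 0.1 %.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    text = path.read_text(encoding="utf-8")
    comment_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    meta = _parse_metadata(comment_lines)
    df = pd.read_csv(_io.StringIO(text), comment="#")
    for col in ("time_s", "cop_x_mm", "cop_y_mm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in ("time_s", "cop_x_mm", "cop_y_mm"):
        nan_idx = np.flatnonzero(df[col].isna().to_numpy())
        if nan_idx.size:
            raise DataError(
                f"{path}: {nan_idx.size} NaN value(s) in {col!r}, "
                f"indices {nan_idx[:10].tolist()}"
            )
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise DataError(
            f"{path}: time_s not strictly increasing, first offending index {bad[0] + 1}"
        )
    scale = _UNIT_TO_MM.get(meta.get("units", "mm"))
    if scale is None:
        raise FormatError(f"{path}: unknown units {meta['units']!r} (use mm/cm/m)")
    inferred_fs = 1.0 / float(np.median(dt))
    if "fs_hz" in meta:
        fs = float(meta["fs_hz"])
        if abs(fs - inferred_fs) > 1e-3 * fs:
            raise DataError(
                f"{path}: declared fs {fs} Hz disagrees with timestamps "
                f"(inferred {inferred_fs:.6g} Hz)"
            )
    else:
        fs = inferred_fs
    x = df["cop_x_mm"].to_numpy(dtype=float) * scale
    y = df["cop_y_mm"].to_numpy(dtype=float) * scale
    return CoPTrajectory(t=t, x=x, y=y, fs=fs)


def write_cop_csv(traj: CoPTrajectory, path, metadata: Optional[dict] = None) -> None:
    """Write a trajectory in the documented CSV dialect.

    Numbers are serialised with 17 significant digits so a read/write round
    trip is lossless to well below 1e-9 mm.
    """
    path = Path(path)
    lines = [f"# fs_hz: {traj.fs!r}", "# units: mm"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    lines.append("time_s,cop_x_mm,cop_y_mm")
    for ti, xi, yi in zip(traj.t, traj.x, traj.y):
        lines.append(f"{ti:.17g},{xi:.17g},{yi:.17g}")
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:  # pragma: no cover - depends on filesystem state
        raise FormatError(f"cannot write {path}: {exc}") from exc


def validate_session(session: Session) -> list[str]:
    """Collect invariant violations for a session without raising.

    Returns an empty list iff the session is valid.  Checks: calibration
    present, at most 3 repetitions per height level, consistent sampling rate
    across trials, and fof_group consistency with the FES-I score.
    """
    violations: list[str] = []
    if session.calibration is None:
        violations.append("missing calibration")
    per_level: dict[str, int] = {}
    fs_seen: set[float] = set()
    for cond, traj, _ in session.trials:
        per_level[cond.height_level] = per_level.get(cond.height_level, 0) + 1
        fs_seen.add(traj.fs)
    for level, count in per_level.items():
        if count > 3:
            violations.append(f"repetitions > 3 at height level {level!r} ({count})")
    if len(fs_seen) > 1:
        violations.append(f"sampling rate differs across trials: {sorted(fs_seen)}")
    expected = fesi_group(session.subject.fes_i)
    if session.subject.fof_group != expected:
        violations.append(
            f"fof_group {session.subject.fof_group!r} inconsistent with "
            f"FES-I {session.subject.fes_i} (expected {expected!r})"
        )
    return violations


def write_session_manifest(session: Session, directory) -> Path:
    """Write a session as a manifest JSON plus one CSV per trial.

    Returns the manifest path.  Calibration is stored as the raw per-direction
    attempt lists plus the derived profile.
    """
    from .protocol import CalibrationProfile  # local import: avoid cycle at module load

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = session.subject.subject_id
    trial_entries = []
    for cond, traj, event_log in session.trials:
        fname = f"{sid}_{cond.height_level}_rep{cond.repetition_index}.csv"
        write_cop_csv(
            traj,
            directory / fname,
            metadata={
                "subject_id": sid,
                "height_level": cond.height_level,
                "repetition_index": cond.repetition_index,
            },
        )
        trial_entries.append(
            {
                "csv": fname,
                "height_level": cond.height_level,
                "repetition_index": cond.repetition_index,
                "event_log": event_log,
            }
        )
    calib = session.calibration
    manifest = {
        "schema_version": 1,
        "subject": session.subject.to_dict(),
        "calibration": None
        if calib is None
        else {
            "max_excursion_mm": dict(calib.max_excursion),
            "n_attempts": calib.n_attempts,
        },
        "trials": trial_entries,
    }
    manifest_path = directory / f"{sid}_session.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest_path


def read_session_manifest(path) -> Session:
    """Load a session manifest written by :func:`write_session_manifest`."""
    from .protocol import CalibrationProfile

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such manifest: {path}")
    try:
        manifest = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("subject", "trials"):
        if key not in manifest:
            raise FormatError(f"{path}: manifest missing key {key!r}")
    subject = SubjectRecord.from_dict(manifest["subject"])
    calibration = None
    if manifest.get("calibration"):
        calibration = CalibrationProfile(
            max_excursion=manifest["calibration"]["max_excursion_mm"],
            n_attempts=manifest["calibration"].get("n_attempts", 1),
        )
    trials = []
    for entry in manifest["trials"]:
        cond = TrialCondition(
            height_level=entry["height_level"],
            repetition_index=int(entry["repetition_index"]),
        )
        traj = read_cop_csv(path.parent / entry["csv"])
        trials.append((cond, traj, entry.get("event_log")))
    return Session(subject=subject, calibration=calibration, trials=trials)
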