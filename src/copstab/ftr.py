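"""Rectangular functional areas (RFAs) and functional time ratios (FTRs).

The analyzed movement area of a LoS trial is modelled as a rectangle whose
per-direction half-extents are the calibrated target distances (75 % of the
maximal excursion in each of forward / backward / left / right).  Three
co-centric rectangles at 33 %, 67 % and 100 % of those extents, centred on
the per-axis *median* of the analyzed CoP samples, carve the plane into
disjoint regions:

* region 1 — inside (or on) the 33 % rectangle;
* region 2 — the band between the 33 % and 67 % rectangles;
* region 3 — the band between the 67 % and 100 % rectangles;
* outside  — beyond the 100 % rectangle (possible because the centre is the
  sample median, not the calibration home).

``FTR_i`` is the percentage of analyzed trial time spent in region ``i``
(sample-count fraction at uniform sampling); ``FTR_1/2 = FTR_1 / FTR_2`` is
the derived stability index.  The regions are disjoint bands, not nested
cumulative areas, so FTR_1 + FTR_2 + FTR_3 + FTR_out = 100 for every trial.
Boundaries are closed toward the smaller region (a point exactly on the 33 %
edge counts as region 1) — a measure-zero choice on continuous data, made
deterministic for grid data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .io import CoPTrajectory
from .protocol import CARDINAL_DIRECTIONS, CalibrationProfile

__all__ = [
    "RFA_LEVELS",
    "RFASet",
    "FTRResult",
    "build_rfas",
    "classify_sample",
    "classify_samples",
    "compute_ftrs",
    "aggregate_trials",
]

#: band levels as printed fractions of the per-direction reference distance
RFA_LEVELS = (0.33, 0.67, 1.0)


@dataclass(frozen=True)
class RFASet:
    """Three co-centric rectangles centred on the CoP median.

    ``reference`` maps each cardinal direction to the 100 % half-extent (mm);
    the 33 % and 67 % rectangles scale all four extents by those factors.
    """

    center: tuple[float, float]
    reference: dict[str, float]
    levels: tuple[float, ...] = RFA_LEVELS

    def __post_init__(self) -> None:
        missing = [d for d in CARDINAL_DIRECTIONS if d not in self.reference]
        if missing:
            raise DataError(f"RFA reference missing direction(s): {missing}")
        for d, v in self.reference.items():
            if not v > 0:
                raise DataError(f"RFA extent must be positive, got {v} for {d!r}")
        if not all(0 < a < b for a, b in zip(self.levels, self.levels[1:])):
            raise ConfigError(f"levels must be increasing and positive: {self.levels}")

    def half_extents(self, level: float) -> tuple[float, float, float, float]:
        """(left, right, backward, forward) half-extents at a band level."""
        r = self.reference
        return (
            level * r["left"],
            level * r["right"],
            level * r["backward"],
            level * r["forward"],
        )

    def contains(self, x, y, level: float):
        """Vectorised closed-rectangle membership at one band level."""
        cx, cy = self.center
        le, ri, ba, fo = self.half_extents(level)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= cx - le) & (x <= cx + ri) & (y >= cy - ba) & (y <= cy + fo)


@dataclass(frozen=True)
class FTRResult:
    """Functional time ratios of one trial (or a trial average), in percent.

    ``ftr12`` is ``+inf`` with ``ftr12_degenerate=True`` when no time was
    spent in region 2.
    """

    ftr1: float
    ftr2: float
    ftr3: float
    ftr_out: float
    ftr12: float
    n_samples: int
    ftr12_degenerate: bool = False

    def __post_init__(self) -> None:
        total = self.ftr1 + self.ftr2 + self.ftr3 + self.ftr_out
        if abs(total - 100.0) > 1e-9:
            raise DataError(f"FTR components must sum to 100, got {total!r}")

    def as_dict(self) -> dict:
        return {
            "ftr1": self.ftr1,
            "ftr2": self.ftr2,
            "ftr3": self.ftr3,
            "ftr_out": self.ftr_out,
            "ftr12": self.ftr12,
            "n_samples": self.n_samples,
            "ftr12_degenerate": self.ftr12_degenerate,
        }


def build_rfas(
    calib: CalibrationProfile,
    traj: CoPTrajectory,
    center: Optional[tuple[float, float]] = None,
    use_max_excursion: bool = False,
) -> RFASet:
    """Construct the RFAs for an analyzed (preprocessed) trial.

    The centre defaults to the per-axis median of the trial's CoP samples;
    pass ``center`` explicitly to pin it (e.g. the simulator's fixed-centre
    mode).  The 100 % reference distance per direction is the calibrated
    target distance; ``use_max_excursion=True`` switches the reference to the
    raw maximal excursion instead.
    """
    if len(traj) == 0:  # pragma: no cover - CoPTrajectory already enforces >= 2
        raise DataError("cannot build RFAs from an empty trajectory")
    if center is None:
        center = (float(np.median(traj.x)), float(np.median(traj.y)))
    ref = dict(calib.max_excursion) if use_max_excursion else calib.target_distance
    return RFASet(center=(float(center[0]), float(center[1])), reference=ref)


def classify_samples(x, y, rfas: RFASet) -> np.ndarray:
    """Region index (1, 2, 3; 0 = outside) for each sample, vectorised.

    Inner regions win ties: a point on a shared boundary belongs to the
    smaller rectangle.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    region = np.zeros(x.shape, dtype=np.int64)
    for idx in (3, 2, 1):  # paint outermost first so inner bands overwrite
        region[rfas.contains(x, y, rfas.levels[idx - 1])] = idx
    return region


def classify_sample(point: Sequence[float], rfas: RFASet) -> int:
    """Region of a single (x, y) point: 1, 2, 3, or 0 for outside."""
    return int(classify_samples([point[0]], [point[1]], rfas)[0])


def compute_ftrs(traj: CoPTrajectory, rfas: RFASet) -> FTRResult:
    """Time-share of each RFA band: ``FTR_i = n_i / n_total × 100``.

    At uniform sampling the dwell time in a region is its sample count times
    the sample period, so the ratio reduces to a sample fraction; no boundary
    interpolation is attempted.
    """
    region = classify_samples(traj.x, traj.y, rfas)
    n = region.size
    counts = np.bincount(region, minlength=4)
    ftr1, ftr2, ftr3 = (100.0 * counts[i] / n for i in (1, 2, 3))
    ftr_out = 100.0 * counts[0] / n
    degenerate = counts[2] == 0
    ftr12 = math.inf if degenerate else ftr1 / ftr2
    return FTRResult(
        ftr1=ftr1,
        ftr2=ftr2,
        ftr3=ftr3,
        ftr_out=ftr_out,
        ftr12=ftr12,
        n_samples=int(n),
        ftr12_degenerate=bool(degenerate),
    )


def aggregate_trials(results: Sequence[FTRResult], ratio_of_means: bool = True) -> FTRResult:
    """Average FTRs over repetitions of one condition.

    Components are averaged arithmetically.  ``FTR_1/2`` of the aggregate is
    ``mean(FTR_1) / mean(FTR_2)`` by default; ``ratio_of_means=False``
    averages the per-trial ratios instead.
    """
    if len(results) == 0:
        raise DataError("cannot aggregate an empty list of FTR results")
    ftr1 = float(np.mean([r.ftr1 for r in results]))
    ftr2 = float(np.mean([r.ftr2 for r in results]))
    ftr3 = float(np.mean([r.ftr3 for r in results]))
    ftr_out = float(np.mean([r.ftr_out for r in results]))
    if ratio_of_means:
        degenerate = ftr2 == 0
        ftr12 = math.inf if degenerate else ftr1 / ftr2
    else:
        degenerate = any(r.ftr12_degenerate for r in results)
        ftr12 = math.inf if degenerate else float(np.mean([r.ftr12 for r in results]))
    return FTRResult(
        ftr1=ftr1,
        ftr2=ftr2,
        ftr3=ftr3,
        ftr_out=ftr_out,
        ftr12=ftr12,
        n_samples=int(sum(r.n_samples for r in results)),
        ftr12_degenerate=bool(degenerate),
    )
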