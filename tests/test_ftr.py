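import math

import numpy as np
import pytest

from copstab import (
    DataError,
    RFASet,
    aggregate_trials,
    build_rfas,
    classify_sample,
    compute_ftrs,
)
from copstab.ftr import classify_samples

from .conftest import make_traj


def region_oracle(px, py, rfas):
    """Direct four-inequality membership check, smallest region wins."""
    cx, cy = rfas.center
    for region, level in ((1, 0.33), (2, 0.67), (3, 1.0)):
        le, ri, ba, fo = rfas.half_extents(level)
        if (cx - le <= px <= cx + ri) and (cy - ba <= py <= cy + fo):
            return region
    return 0


class TestBuildRfas:
    def test_band_boundaries_33_67_100(self, square_calib, random_traj):
        rfas = build_rfas(square_calib, random_traj)
        le, ri, ba, fo = rfas.half_extents(rfas.levels[0])
        assert (le, ri, ba, fo) == pytest.approx((9.9,) * 4)
        assert rfas.half_extents(rfas.levels[1]) == pytest.approx((20.1,) * 4)
        assert rfas.half_extents(rfas.levels[2]) == pytest.approx((30.0,) * 4)

    def test_center_is_median_sort_and_pick_oracle(self, square_calib, rng):
        n = 501  # odd: the median is an order statistic
        traj = make_traj(rng.normal(2, 8, n), rng.normal(-1, 8, n))
        rfas = build_rfas(square_calib, traj)
        assert rfas.center[0] == sorted(traj.x)[n // 2]
        assert rfas.center[1] == sorted(traj.y)[n // 2]

    def test_offset_shifts_center_not_extents(self, square_calib, random_traj):
        r0 = build_rfas(square_calib, random_traj)
        r1 = build_rfas(square_calib, random_traj.translated(5.0, -3.0))
        assert r1.center[0] == pytest.approx(r0.center[0] + 5.0)
        assert r1.center[1] == pytest.approx(r0.center[1] - 3.0)
        assert r1.reference == r0.reference

    def test_max_excursion_reference_option(self, square_calib, random_traj):
        rfas = build_rfas(square_calib, random_traj, use_max_excursion=True)
        assert rfas.reference["forward"] == pytest.approx(40.0)


class TestClassifySample:
    def test_center_is_region_1(self, square_rfas):
        assert classify_sample((0.0, 0.0), square_rfas) == 1

    def test_boundaries_closed_toward_smaller_region(self, square_rfas):
        assert classify_sample((9.9, 0.0), square_rfas) == 1  # on the 33 % edge
        assert classify_sample((9.9 + 1e-9, 0.0), square_rfas) == 2
        assert classify_sample((20.1, 0.0), square_rfas) == 2
        assert classify_sample((30.0, 0.0), square_rfas) == 3
        assert classify_sample((30.0 + 1e-9, 0.0), square_rfas) == 0

    def test_asymmetric_extents_respected(self):
        rfas = RFASet(center=(0, 0), reference={"forward": 30, "backward": 10, "left": 20, "right": 40})
        assert classify_sample((0.0, -9.0), rfas) == 3  # 0.67*10 < 9 <= 10
        assert classify_sample((0.0, 9.0), rfas) == 1  # 9 <= 0.33*30

    def test_agrees_with_membership_oracle_on_10k_points(self, square_rfas, rng):
        x = rng.uniform(-45, 45, 10_000)
        y = rng.uniform(-45, 45, 10_000)
        vec = classify_samples(x, y, square_rfas)
        for i in range(10_000):
            assert vec[i] == region_oracle(x[i], y[i], square_rfas)


class TestComputeFtrs:
    def test_all_samples_at_center(self, square_rfas):
        traj = make_traj(np.zeros(100), np.zeros(100))
        res = compute_ftrs(traj, square_rfas)
        assert (res.ftr1, res.ftr2, res.ftr3, res.ftr_out) == (100.0, 0.0, 0.0, 0.0)
        assert math.isinf(res.ftr12) and res.ftr12_degenerate

    def test_six_three_three_split(self, square_rfas):
        # 6 samples in region 1, 3 in region 2, 3 in region 3 (verified vs oracle)
        xs = [0, 1, -2, 3, 0, 5, 15, -15, 16, 25, -25, 28]
        ys = [0.0] * 12
        assert [region_oracle(x, y, square_rfas) for x, y in zip(xs, ys)] == [1] * 6 + [2] * 3 + [3] * 3
        res = compute_ftrs(make_traj(xs, ys), square_rfas)
        assert (res.ftr1, res.ftr2, res.ftr3) == (50.0, 25.0, 25.0)
        assert res.ftr12 == pytest.approx(2.0)

    def test_everything_outside(self, square_rfas):
        traj = make_traj(np.full(50, 40.0), np.zeros(50))
        res = compute_ftrs(traj, square_rfas)
        assert res.ftr_out == 100.0
        assert (res.ftr1, res.ftr2, res.ftr3) == (0.0, 0.0, 0.0)

    def test_conservation_and_loop_oracle_on_random_trials(self, square_rfas, rng):
        for _ in range(100):
            n = int(rng.integers(20, 400))
            traj = make_traj(rng.uniform(-40, 40, n), rng.uniform(-40, 40, n))
            res = compute_ftrs(traj, square_rfas)
            assert abs(res.ftr1 + res.ftr2 + res.ftr3 + res.ftr_out - 100.0) <= 1e-9
            counts = [0, 0, 0, 0]
            for x, y in zip(traj.x, traj.y):
                counts[region_oracle(x, y, square_rfas)] += 1
            assert res.ftr1 == 100.0 * counts[1] / n
            assert res.ftr2 == 100.0 * counts[2] / n
            assert res.ftr3 == 100.0 * counts[3] / n
            assert res.ftr_out == 100.0 * counts[0] / n

    def test_nesting_monotonicity(self, square_rfas, rng):
        traj = make_traj(rng.uniform(-40, 40, 500), rng.uniform(-40, 40, 500))
        res = compute_ftrs(traj, square_rfas)
        within_33 = res.ftr1
        within_67 = res.ftr1 + res.ftr2
        within_100 = within_67 + res.ftr3
        assert within_33 <= within_67 <= within_100

    def test_scale_coherence(self, square_calib, rng):
        from copstab.protocol import CalibrationProfile

        traj = make_traj(rng.uniform(-40, 40, 300), rng.uniform(-40, 40, 300))
        rfas = RFASet(center=(0, 0), reference=square_calib.target_distance)
        base = compute_ftrs(traj, rfas)
        k = 3.7
        scaled_calib = CalibrationProfile(
            {d: k * v for d, v in square_calib.max_excursion.items()}
        )
        scaled_rfas = RFASet(center=(0, 0), reference=scaled_calib.target_distance)
        scaled_traj = make_traj(k * traj.x, k * traj.y)
        scaled = compute_ftrs(scaled_traj, scaled_rfas)
        assert (scaled.ftr1, scaled.ftr2, scaled.ftr3) == (base.ftr1, base.ftr2, base.ftr3)


class TestAggregateTrials:
    def _res(self, ftr1, ftr2, ftr3):
        from copstab.ftr import FTRResult

        out = 100.0 - ftr1 - ftr2 - ftr3
        return FTRResult(ftr1=ftr1, ftr2=ftr2, ftr3=ftr3, ftr_out=out,
                         ftr12=ftr1 / ftr2, n_samples=100)

    def test_identical_triplicates(self):
        r = self._res(60, 25, 10)
        agg = aggregate_trials([r, r, r])
        assert (agg.ftr1, agg.ftr2, agg.ftr3) == (60, 25, 10)
        assert agg.ftr12 == pytest.approx(60 / 25)

    def test_ratio_of_means_default(self):
        results = [self._res(60, 20, 10), self._res(50, 25, 15), self._res(40, 30, 20)]
        agg = aggregate_trials(results)
        assert agg.ftr1 == pytest.approx(50.0)
        assert agg.ftr2 == pytest.approx(25.0)
        assert agg.ftr12 == pytest.approx(2.0)

    def test_mean_of_ratios_option(self):
        results = [self._res(60, 20, 10), self._res(50, 25, 15), self._res(40, 30, 20)]
        agg = aggregate_trials(results, ratio_of_means=False)
        assert agg.ftr12 == pytest.approx((3.0 + 2.0 + 4.0 / 3.0) / 3.0)

    def test_empty_list_rejected(self):
        with pytest.raises(DataError):
            aggregate_trials([])
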