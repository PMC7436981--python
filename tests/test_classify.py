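import itertools
import math

import numpy as np
import pytest

from copstab import DataError, apply_threshold, caic, fesi_group, fit_logistic, roc_analysis
from copstab.classify import crossvalidate, youden_cutoff


def auc_pair_oracle(scores, y):
    """Proportion of correctly ordered (pos, neg) pairs, ties count 1/2."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        if p > q:
            total += 1.0
        elif p == q:
            total += 0.5
    return total / (len(pos) * len(neg))


def youden_oracle(scores, y, orientation):
    """Exhaustive enumeration of J over all observed thresholds."""
    best = (-np.inf, None, None, None)
    pos = np.asarray([s for s, t in zip(scores, y) if t == 1])
    neg = np.asarray([s for s, t in zip(scores, y) if t == 0])
    for c in np.unique(scores):
        if orientation == "higher_is_positive":
            sens = float(np.mean(pos >= c))
            spec = float(np.mean(neg < c))
            extreme = c
        else:
            sens = float(np.mean(pos <= c))
            spec = float(np.mean(neg > c))
            extreme = -c
        key = (sens + spec - 1.0, sens, extreme)
        if key > best[:3]:
            best = (*key, (c, sens, spec))
    return best[3]


def logistic_loglik(x, y, b0, b1):
    z = b0 + b1 * x
    return float(np.sum(y * z - np.log1p(np.exp(z))))


class TestFesiGroup:
    @pytest.mark.parametrize("score,group", [(16, "low"), (22, "low"), (23, "high"), (64, "high")])
    def test_questionnaire_cutoffs(self, score, group):
        assert fesi_group(score) == group

    @pytest.mark.parametrize("score", [15, 65])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(DataError):
            fesi_group(score)


class TestFitLogistic:
    def test_loglik_matches_grid_search_mle(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 16))
            x = rng.normal(0, 1.5, n)
            # labels from a known model, resampled until both classes present
            # and not separated (separation handled in its own test)
            while True:
                y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(int)
                if 0 < y.sum() < n and not (
                    x[y == 0].max() < x[y == 1].min() or x[y == 1].max() < x[y == 0].min()
                ):
                    break
            fit = fit_logistic(x, y)
            assert fit.converged
            # dense 2-D grid around the fitted optimum
            b0s = np.linspace(fit.beta0 - 1.0, fit.beta0 + 1.0, 81)
            b1s = np.linspace(fit.beta1 - 1.0, fit.beta1 + 1.0, 81)
            grid_best = max(
                logistic_loglik(x, y, b0, b1) for b0 in b0s for b1 in b1s
            )
            # the grid contains the fitted point, so equality up to float noise
            # means no surrounding grid point improves on the reported MLE
            assert abs(fit.log_likelihood - grid_best) <= 1e-4
            assert fit.log_likelihood == pytest.approx(
                logistic_loglik(x, y, fit.beta0, fit.beta1), abs=1e-8
            )

    def test_or_ci_brackets_point_estimate(self, rng):
        x = rng.normal(0, 1, 60)
        y = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(int)
        fit = fit_logistic(x, y)
        assert fit.or_ci95[0] <= fit.odds_ratio <= fit.or_ci95[1]

    def test_independent_predictor_or_near_one(self, rng):
        x = rng.normal(0, 1, 500)
        y = rng.integers(0, 2, 500)
        fit = fit_logistic(x, y)
        assert fit.or_ci95[0] <= 1.0 <= fit.or_ci95[1]

    def test_complete_separation_flagged(self):
        x = np.array([0.0, 1, 2, 3, 10, 11, 12, 13])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = fit_logistic(x, y)
        assert fit.separated and not fit.converged
        assert fit.or_ci95 == (0.0, math.inf)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            fit_logistic(np.arange(10.0), np.ones(10, int))


class TestRocAnalysis:
    def test_perfect_separation_auc_one(self):
        roc = roc_analysis([1.0, 2, 3, 4], [0, 0, 1, 1], n_boot=50)
        assert roc.auc == 1.0
        cutoff, sens, spec = youden_cutoff(roc)
        assert sens == 1.0 and spec == 1.0
        assert cutoff == 3.0  # observed value, inclusive >=

    def test_tie_handling_matches_pair_counting(self):
        scores = [1.0, 2.0, 2.0, 4.0]
        labels = [0, 0, 1, 1]
        roc = roc_analysis(scores, labels, n_boot=50)
        assert roc.auc == pytest.approx(auc_pair_oracle(scores, labels))

    def test_auc_and_youden_match_oracles_on_random_datasets(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 51))
            # mix of continuous and heavily tied integer scores
            if rng.random() < 0.5:
                scores = rng.normal(0, 1, n)
            else:
                scores = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            roc = roc_analysis(scores, y, n_boot=2)
            oriented = auc_pair_oracle(scores, y)
            expected_auc = max(oriented, 1.0 - oriented)
            assert roc.auc == pytest.approx(expected_auc, abs=1e-12)
            c, sens, spec = youden_oracle(scores, y, roc.orientation)
            assert roc.youden_sens + roc.youden_spec == pytest.approx(sens + spec, abs=1e-12)
            assert roc.youden_cutoff == pytest.approx(c)

    def test_orientation_flips_for_low_positive_scores(self, rng):
        x_pos = rng.normal(-2, 1, 30)
        x_neg = rng.normal(2, 1, 30)
        scores = np.concatenate([x_pos, x_neg])
        y = np.array([1] * 30 + [0] * 30)
        roc = roc_analysis(scores, y, n_boot=50)
        assert roc.orientation == "lower_is_positive"
        assert roc.auc >= 0.5

    def test_constant_scores_degenerate(self):
        roc = roc_analysis(np.ones(10), [0, 1] * 5, n_boot=10)
        assert roc.degenerate and roc.auc == 0.5
        assert roc.youden_sens + roc.youden_spec - 1.0 == pytest.approx(0.0)

    def test_curve_contains_trivial_endpoints(self, rng):
        scores = rng.normal(0, 1, 40)
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        roc = roc_analysis(scores, y, n_boot=2)
        pts = set(zip(np.round(1 - roc.specificities, 12), np.round(roc.sensitivities, 12)))
        assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_training_reclassification_matches_reported_sens_spec(self, rng):
        scores = rng.normal(0, 1, 50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        roc = roc_analysis(scores, y, n_boot=2)
        preds = np.array(
            [apply_threshold(s, roc.youden_cutoff, roc.orientation) == "high" for s in scores]
        )
        sens = preds[y == 1].mean()
        spec = (~preds[y == 0]).mean()
        assert sens == pytest.approx(roc.youden_sens)
        assert spec == pytest.approx(roc.youden_spec)

    def test_independent_scores_auc_near_half(self, rng):
        scores = rng.normal(0, 1, 2000)
        y = rng.integers(0, 2, 2000)
        roc = roc_analysis(scores, y, n_boot=2)
        assert roc.auc == pytest.approx(0.5, abs=0.05)


class TestCaic:
    def test_aicc_formula(self):
        assert caic(-10.0, 2, 38, "aicc") == pytest.approx(24 + 12 / 35)

    def test_consistent_formula(self):
        assert caic(-10.0, 2, 38, "consistent") == pytest.approx(20 + 2 * (math.log(38) + 1))

    def test_ranking_monotone_in_loglik(self):
        for variant in ("aicc", "consistent"):
            assert caic(-5.0, 2, 38, variant) < caic(-10.0, 2, 38, variant)

    def test_small_n_rejected_for_aicc(self):
        with pytest.raises(DataError):
            caic(-10.0, 5, 6, "aicc")


class TestApplyThreshold:
    def test_published_ground_rule_inclusive(self):
        assert apply_threshold(2.83) == "high"
        assert apply_threshold(2.84) == "low"

    def test_published_40cm_rule_inclusive(self):
        assert apply_threshold(2.71, cutoff=2.71) == "high"
        assert apply_threshold(2.72, cutoff=2.71) == "low"

    def test_infinite_ratio_maps_to_low(self):
        assert apply_threshold(math.inf) == "low"

    def test_higher_is_positive_orientation(self):
        assert apply_threshold(5.0, cutoff=5.0, orientation="higher_is_positive") == "high"
        assert apply_threshold(4.9, cutoff=5.0, orientation="higher_is_positive") == "low"


class TestCrossvalidate:
    def test_separable_scores_perfect(self, rng):
        scores = np.concatenate([rng.uniform(0, 1, 25), rng.uniform(5, 6, 25)])
        y = np.array([0] * 25 + [1] * 25)
        cv = crossvalidate(scores, y, seed=3)
        assert cv.error_pct == 0.0
        assert cv.sensitivity_pct == 100.0
        assert cv.specificity_pct == 100.0

    def test_bit_reproducible_under_seed(self, rng):
        scores = rng.normal(0, 1, 60)
        y = rng.integers(0, 2, 60)
        y[:5], y[5:10] = 0, 1
        a = crossvalidate(scores, y, seed=11)
        b = crossvalidate(scores, y, seed=11)
        assert a == b

    def test_permuted_labels_error_near_half(self, rng):
        scores = rng.normal(0, 1, 200)
        y = np.array([0] * 100 + [1] * 100)
        cv = crossvalidate(scores, y, seed=5)
        assert cv.error_pct == pytest.approx(50.0, abs=10.0)

    def test_class_smaller_than_folds_rejected(self):
        with pytest.raises(DataError):
            crossvalidate(np.arange(10.0), np.array([1] + [0] * 9), folds=5)

    def test_reuse_global_cutoff_option_runs(self, rng):
        scores = np.concatenate([rng.uniform(0, 1, 10), rng.uniform(5, 6, 10)])
        y = np.array([0] * 10 + [1] * 10)
        cv = crossvalidate(scores, y, seed=1, reuse_global_cutoff=True)
        assert cv.error_pct == 0.0
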