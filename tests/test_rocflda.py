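"""ROC curves, Youden thresholds, DeLong test and Fisher's discriminant."""

import numpy as np
import pytest

from dwiresponse import (
    delong_test,
    fit_flda,
    mann_whitney_u,
    optimal_threshold,
    project_flda,
    roc_curve,
)
from dwiresponse.errors import DegenerateInputError, ValidationError
from dwiresponse.rocflda import GREATER, LESS, delong_auc_variance


def _labels(n_pos, n_neg):
    return np.asarray(["therapy"] * n_pos + ["control"] * n_neg)


def concordance_auc(pos_scores, neg_scores):
    """Brute-force AUC: pairwise concordance count with ties worth 1/2."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos_scores for n in neg_scores)
    return wins / (len(pos_scores) * len(neg_scores))


def exhaustive_threshold_scan(scores, labels, direction):
    """Oracle for the Youden-optimal operating point: scan every candidate
    threshold (score midpoints plus sentinels) directly on confusion counts."""
    scores = np.asarray(scores, float)
    pos = labels == "therapy"
    distinct = np.unique(scores)
    cands = np.concatenate([[-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]])
    best = None
    for thr in cands:
        called = scores > thr if direction == GREATER else scores < thr
        sens = called[pos].mean()
        spec = (~called[~pos]).mean()
        key = (sens + spec - 1, spec, -thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    return best[1], best[2], best[3]


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve([3, 4, 1, 2], _labels(2, 2), GREATER)
        assert roc.auc == 1.0

    def test_tied_score_example(self):
        roc = roc_curve([0.9, 0.7, 0.7, 0.1], _labels(2, 2), GREATER)
        assert roc.auc == pytest.approx(0.875)  # (3 wins + 0.5 tie) / 4

    def test_negation_symmetry_tie_free(self, rng):
        scores = rng.normal(size=12)
        labels = _labels(6, 6)
        a = roc_curve(scores, labels, GREATER).auc
        b = roc_curve(-scores, labels, GREATER).auc
        assert a + b == pytest.approx(1.0)

    def test_direction_flip(self, rng):
        scores = rng.normal(size=15)
        labels = _labels(7, 8)
        assert roc_curve(scores, labels, GREATER).auc == pytest.approx(
            roc_curve(-scores, labels, LESS).auc)

    def test_auc_equals_mann_whitney_identity(self, rng):
        """AUC == (U_pos + t/2) / (n1 n2): checked on 100 random datasets with
        ties, against both the rank-test module and brute-force concordance."""
        for i in range(100):
            n1, n2 = rng.integers(3, 10, size=2)
            scores = np.round(rng.normal(size=n1 + n2), 1)  # rounding makes ties
            labels = _labels(n1, n2)
            auc = roc_curve(scores, labels, GREATER).auc
            assert auc == pytest.approx(concordance_auc(scores[:n1], scores[n1:]),
                                        abs=1e-12)
            u_min = mann_whitney_u(scores[:n1], scores[n1:]).statistic
            assert min(auc, 1 - auc) == pytest.approx(u_min / (n1 * n2), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([1, 2], np.asarray(["therapy", "therapy"]), GREATER)


class TestOptimalThreshold:
    def test_separable_example(self):
        roc = roc_curve([0.5, 0.9, 0.1, 0.3], _labels(2, 2), GREATER)
        best = optimal_threshold(roc)
        assert best.threshold == pytest.approx(0.4)
        assert best.sens == best.spec == best.accuracy == 1.0

    def test_identical_multisets_pick_sentinel(self):
        roc = roc_curve([1, 2, 3, 1, 2, 3], _labels(3, 3), GREATER)
        best = optimal_threshold(roc)
        assert best.youden_j == pytest.approx(0.0)
        assert best.spec == 1.0 and np.isinf(best.threshold)

    def test_study_style_confusion_counts(self):
        # therapy: 11 below the cut and 1 above; control: all 11 above
        scores = np.r_[np.linspace(-1.0, -0.1, 11), [0.5],
                       np.linspace(0.2, 1.2, 11)]
        labels = _labels(12, 11)
        best = optimal_threshold(roc_curve(scores, labels, LESS))
        assert best.sens == pytest.approx(11 / 12)
        assert best.spec == 1.0
        assert best.accuracy == pytest.approx(22 / 23)

    def test_matches_exhaustive_scan(self, rng):
        for i in range(50):
            n1, n2 = rng.integers(3, 12, size=2)
            scores = np.round(rng.normal(size=n1 + n2), 1)
            labels = _labels(n1, n2)
            direction = GREATER if i % 2 else LESS
            best = optimal_threshold(roc_curve(scores, labels, direction))
            thr, sens, spec = exhaustive_threshold_scan(scores, labels, direction)
            assert best.threshold == pytest.approx(thr)
            assert best.sens == pytest.approx(sens)
            assert best.spec == pytest.approx(spec)


class TestDeLong:
    def test_self_comparison(self, rng):
        scores = rng.normal(size=23)
        res = delong_test(scores, scores, _labels(12, 11))
        assert res.p_value == 1.0

    def test_variance_matches_hand_computed_placements(self):
        # 3 positives {3, 5, 1}, 3 negatives {2, 4, 0}
        scores = np.asarray([3.0, 5.0, 1.0, 2.0, 4.0, 0.0])
        labels = _labels(3, 3)
        auc, var = delong_auc_variance(scores, labels, GREATER)
        # placements by hand: positives beat {2/3, 3/3, 1/3}; negatives are
        # beaten by {2/3, 1/3, 3/3}
        v10 = np.asarray([2, 3, 1]) / 3
        v01 = np.asarray([2, 1, 3]) / 3
        assert auc == pytest.approx(v10.mean())
        assert var == pytest.approx(np.var(v10, ddof=1) / 3 + np.var(v01, ddof=1) / 3)

    def test_zero_variance_unequal_auc_degenerate(self):
        # both classifiers separate perfectly -> zero variance, AUCs 1 vs 1
        a = np.r_[np.ones(3) + np.arange(3), np.zeros(3) - np.arange(3)]
        res = delong_test(a, a + 100, _labels(3, 3))
        assert res.p_value == 1.0  # equal AUCs
        with pytest.raises(DegenerateInputError):
            # one perfect, one perfectly reversed: unequal AUCs, zero variance
            delong_test(a, -a, _labels(3, 3))

    def test_direction_handling(self, rng):
        scores = rng.normal(size=23)
        other = rng.normal(size=23)
        labels = _labels(12, 11)
        res1 = delong_test(scores, other, labels, directions=(GREATER, GREATER))
        res2 = delong_test(-scores, other, labels, directions=(LESS, GREATER))
        assert res1.p_value == pytest.approx(res2.p_value)


class TestFLDA:
    THERAPY = np.asarray([(2, 0), (0, 0), (1, 1), (1, -1)], float)
    CONTROL = np.asarray([(1, 2), (-1, 2), (0, 3), (0, 1)], float)

    def _features_labels(self):
        features = np.vstack([self.THERAPY, self.CONTROL])
        return features, _labels(4, 4)

    def test_worked_example_direction(self):
        """Pooled scatter is isotropic, so the weight direction must parallel
        the mean difference (-1, 2); the canonical model is unit-norm and
        oriented so the control group scores higher."""
        features, labels = self._features_labels()
        model = fit_flda(features, labels)
        w = model.weights
        assert np.linalg.norm(w) == pytest.approx(1.0)
        cross = w[0] * 2 - w[1] * (-1)  # w x (-1, 2) = 0 iff parallel
        assert cross == pytest.approx(0.0, abs=1e-12)
        scores = project_flda(model, features)
        assert scores[4:].mean() > scores[:4].mean()  # control higher
        assert abs(w[0]) == pytest.approx(1 / np.sqrt(5))
        assert abs(w[1]) == pytest.approx(2 / np.sqrt(5))

    def test_direction_matches_sklearn(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        features = rng.normal(size=(20, 2)) * [30.0, 0.1]
        features[:10] += [40.0, 0.1]
        labels = _labels(10, 10)
        model = fit_flda(features, labels)
        lda = LinearDiscriminantAnalysis(solver="lsqr").fit(features, labels)
        coef = lda.coef_.ravel()
        cross = model.w_dvol * coef[1] - model.w_dadc * coef[0]
        assert cross == pytest.approx(0.0, abs=1e-8 * np.linalg.norm(coef))

    def test_identical_means_degenerate(self):
        features = np.asarray([(0, 0), (1, 1), (0, 0), (1, 1)], float)
        with pytest.raises(DegenerateInputError):
            fit_flda(features, _labels(2, 2))

    def test_affine_rescaling_equivariance(self, rng):
        features, labels = self._features_labels()
        features = features + rng.normal(0, 0.01, features.shape)
        model = fit_flda(features, labels)
        scores = project_flda(model, features)
        scale = np.asarray([100.0, 0.01])
        model2 = fit_flda(features * scale, labels)
        scores2 = project_flda(model2, features * scale)
        ratio = np.ptp(scores2) / np.ptp(scores)
        np.testing.assert_allclose(
            (scores2 - scores2.mean()) / ratio, scores - scores.mean(), atol=1e-9
        )
        # the induced ROC is identical
        a = roc_curve(scores, labels, LESS).auc
        b = roc_curve(scores2, labels, LESS).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_projection_arithmetic_with_study_weights(self):
        from dwiresponse.rocflda import FLDAModel

        model = FLDAModel(w_dvol=0.0033, w_dadc=-1.0366, scaling="pinned",
                          threshold=0.139)
        score = project_flda(model, [(33.30, 0.10)])[0]
        assert score == pytest.approx(0.0033 * 33.30 - 1.0366 * 0.10)
        assert score == pytest.approx(0.00623, abs=1e-5)
        assert project_flda(model, [(0.0, 0.0)])[0] == 0.0
        # with a negative ADC weight the score strictly decreases in d_adc
        lo = project_flda(model, [(10.0, 0.2)])[0]
        hi = project_flda(model, [(10.0, 0.1)])[0]
        assert lo < hi

    def test_pinned_rescaling(self):
        features, labels = self._features_labels()
        model = fit_flda(features, labels)
        pinned = model.with_pinned_dadc(model.w_dadc * 2.5)
        assert pinned.scaling == "pinned"
        assert pinned.w_dvol == pytest.approx(model.w_dvol * 2.5)
        ratio_before = model.w_dvol / model.w_dadc
        assert pinned.w_dvol / pinned.w_dadc == pytest.approx(ratio_before)
        with pytest.raises(ValidationError):
            model.with_pinned_dadc(-model.w_dadc)
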