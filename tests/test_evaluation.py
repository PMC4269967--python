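"""Mask similarity, classification scores, significance and matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from papnuclei import evaluation as ev
from papnuclei.clustering import OverlapCall
from papnuclei.synthetic_data import GroundTruth

from conftest import region_from_mask


def _calls(spec):
    """spec: list of (label, predicted)."""
    return [OverlapCall(lab, pred, 1.0) for lab, pred in spec]


class TestTanimoto:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        assert ev.tanimoto(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, 0] = b[5, 5] = True
        assert ev.tanimoto(a, b) == 0.0

    def test_hand_counted_shifted_square(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[0:10, 0:10] = True
        b[0:10, 4:14] = True        # overlap 10 x 6 = 60, 40 exclusive each
        assert ev.tanimoto(a, b) == pytest.approx(60 / 140, abs=1e-12)

    def test_both_empty_is_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert ev.tanimoto(np.zeros((3, 3), bool),
                               np.zeros((3, 3), bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.tanimoto(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    def test_symmetric_and_bounded(self, seed_a, seed_b):
        a = np.random.default_rng(seed_a).random((6, 6)) > 0.5
        b = np.random.default_rng(seed_b).random((6, 6)) > 0.5
        if not (a.any() or b.any()):
            return
        t = ev.tanimoto(a, b)
        assert t == ev.tanimoto(b, a)
        assert 0.0 <= t <= 1.0
        assert (t == 1.0) == np.array_equal(a, b)


class TestClassificationMetrics:
    def test_perfect_calls(self):
        truth = {1: "single", 2: "overlapped", 3: "overlapped"}
        p, r, f1, counts = ev.classification_metrics(
            _calls([(1, "single"), (2, "overlapped"), (3, "overlapped")]),
            truth)
        assert (p, r, f1) == (1.0, 1.0, 1.0)
        assert counts == {"Tp": 2, "Tn": 1, "Fp": 0, "Fn": 0}

    def test_hand_arithmetic_confusion(self):
        # Tp=2, Fp=1, Fn=2, Tn=3
        truth = {1: "overlapped", 2: "overlapped", 3: "overlapped",
                 4: "overlapped", 5: "single", 6: "single", 7: "single",
                 8: "single"}
        calls = _calls([(1, "overlapped"), (2, "overlapped"),
                        (3, "single"), (4, "single"), (5, "overlapped"),
                        (6, "single"), (7, "single"), (8, "single")])
        p, r, f1, counts = ev.classification_metrics(calls, truth)
        assert p == pytest.approx(2 / 3)
        assert r == pytest.approx(0.5)
        assert f1 == pytest.approx(0.5714285714, abs=1e-9)
        assert counts == {"Tp": 2, "Tn": 3, "Fp": 1, "Fn": 2}

    def test_no_positive_predictions_scores_zero_with_warning(self):
        truth = {1: "overlapped", 2: "single"}
        with pytest.warns(UserWarning):
            p, r, f1, _ = ev.classification_metrics(
                _calls([(1, "single"), (2, "single")]), truth)
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            ev.classification_metrics([], {1: "single"})

    def test_order_invariant(self):
        truth = {i: ("overlapped" if i % 3 == 0 else "single")
                 for i in range(1, 10)}
        spec = [(i, "overlapped" if i % 2 == 0 else "single")
                for i in range(1, 10)]
        fwd = ev.classification_metrics(_calls(spec), truth)
        rev = ev.classification_metrics(_calls(spec[::-1]), truth)
        assert fwd == rev


class TestFeatureSignificance:
    def test_identical_classes_score_zero(self):
        x = np.random.default_rng(0).normal(size=(10, 5))
        both = np.vstack([x, x])
        labels = np.repeat([0, 1], 10)
        assert ev.feature_significance(both, labels) == pytest.approx(
            np.zeros(5))

    def test_zero_variance_gives_inf_sentinel(self):
        x = np.vstack([np.zeros((5, 2)), np.full((5, 2), 10.0)])
        labels = np.repeat([0, 1], 5)
        with pytest.warns(UserWarning):
            scores = ev.feature_significance(x, labels)
        assert np.isinf(scores).all()

    def test_hand_computed_two_sample_score(self):
        a = np.array([[0.0], [1.0], [2.0], [3.0]])
        b = a + 2.0
        x = np.vstack([a, b])
        labels = np.repeat([0, 1], 4)
        # |1.5 - 3.5| / sqrt((5/3)/4 + (5/3)/4) = 2 / sqrt(5/6)
        expected = 2.0 / np.sqrt(5 / 6)
        assert ev.feature_significance(x, labels)[0] == pytest.approx(
            expected, abs=1e-9)

    def test_invariant_under_additive_shift(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 5))
        labels = (rng.random(20) > 0.5).astype(int)
        if labels.sum() < 2 or (1 - labels).sum() < 2:
            labels[:2] = 0
            labels[-2:] = 1
        shifted = x + np.array([10.0, -3.0, 0.5, 100.0, 0.0])
        assert ev.feature_significance(x, labels) == pytest.approx(
            ev.feature_significance(shifted, labels))

    def test_requires_two_samples_per_class(self):
        with pytest.raises(ValueError):
            ev.feature_significance(np.zeros((3, 2)), np.array([0, 1, 1]))


def _truth_from_masks(masks):
    inst = np.zeros(masks[0].shape, np.uint16)
    for i, m in enumerate(masks, 1):
        inst[m] = i
    labels = {i: "single" for i in range(1, len(masks) + 1)}
    return GroundTruth(instance_mask=inst, region_labels=labels,
                       cluster_mask=inst > 0)


class TestMatchRegions:
    def _masks(self):
        shape = (40, 40)
        m1 = np.zeros(shape, bool)
        m2 = np.zeros(shape, bool)
        m3 = np.zeros(shape, bool)
        m1[2:10, 2:10] = True
        m2[15:25, 15:25] = True
        m3[30:38, 2:12] = True
        return [m1, m2, m3]

    def test_identical_predictions_locate_everything(self):
        masks = self._masks()
        truth = _truth_from_masks(masks)
        regions = [region_from_mask(m, label=i)
                   for i, m in enumerate(masks, 1)]
        res = ev.match_regions(regions, truth)
        assert res.located_fraction == 1.0
        assert all(t == 1.0 for _, _, t in res.matches)

    def test_no_predictions(self):
        truth = _truth_from_masks(self._masks())
        res = ev.match_regions([], truth)
        assert res.located_fraction == 0.0
        assert res.unmatched_truth == [1, 2, 3]

    def test_two_perfect_one_spurious(self):
        masks = self._masks()
        truth = _truth_from_masks(masks)
        spurious = np.zeros((40, 40), bool)
        spurious[30:35, 25:35] = True
        regions = [region_from_mask(masks[0], label=1),
                   region_from_mask(masks[1], label=2),
                   region_from_mask(spurious, label=3)]
        res = ev.match_regions(regions, truth)
        assert res.located_fraction == pytest.approx(2 / 3)
        assert res.unmatched_predictions == [3]
        assert len(res.unmatched_truth) == 1
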