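"""Dice, confusion metrics, Pearson, Bland–Altman, and k-fold summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import eatquant as eq
from eatquant.evaluate import EvaluateError


class TestDice:
    def test_identical_nonempty_masks(self):
        g = np.zeros((8, 8), dtype=np.uint8)
        g[2:5, 2:5] = 1
        assert eq.dice(g, g) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[:2] = 1
        b[6:] = 1
        assert eq.dice(a, b) == 0.0

    def test_hand_value(self):
        # |A|=100, |B|=100, |A∩B|=84 -> 0.84
        a = np.zeros(200, dtype=np.uint8)
        b = np.zeros(200, dtype=np.uint8)
        a[:100] = 1
        b[16:116] = 1
        assert eq.dice(a, b) == pytest.approx(0.84)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert eq.dice(z, z) == 1.0
        assert np.isnan(eq.dice(z, z, both_empty=None))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(EvaluateError):
            eq.dice(np.zeros((4, 4)), np.zeros((5, 5)))

    @given(
        hnp.arrays(np.int8, (6, 6), elements=st.integers(0, 1)),
        hnp.arrays(np.int8, (6, 6), elements=st.integers(0, 1)),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_bounds(self, a, b):
        d = eq.dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == eq.dice(b, a)


class TestConfusionMetrics:
    def test_study_confusion_matrix_f1(self):
        cm = eq.ConfusionMatrix.from_counts(tn=1388, fp=24, fn=34, tp=1702)
        m = eq.confusion_metrics(cm, positive_class=1)
        assert m.f1 == pytest.approx(0.983, abs=5e-4)

    def test_perfect_diagonal(self):
        m = eq.confusion_metrics(eq.ConfusionMatrix.from_counts(10, 0, 0, 10))
        assert (m.precision, m.recall, m.f1, m.accuracy) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_case(self):
        m = eq.confusion_metrics(eq.ConfusionMatrix.from_counts(tn=0, fp=10, fn=0, tp=10), 1)
        assert m.precision == pytest.approx(0.5)
        assert m.recall == pytest.approx(1.0)
        assert m.f1 == pytest.approx(2 / 3)

    def test_swapped_positive_class_exchanges_precision_recall(self):
        cm = eq.ConfusionMatrix.from_counts(tn=1388, fp=24, fn=34, tp=1702)
        m1 = eq.confusion_metrics(cm, positive_class=1)
        # for a 2x2 matrix: precision of class 1 uses column 1, recall uses row 1;
        # transposing the matrix swaps the two roles
        cm_t = eq.ConfusionMatrix(cm.counts.T)
        m1t = eq.confusion_metrics(cm_t, positive_class=1)
        assert m1t.precision == pytest.approx(m1.recall)
        assert m1t.recall == pytest.approx(m1.precision)

    def test_undefined_ratio_is_nan(self):
        m = eq.confusion_metrics(eq.ConfusionMatrix.from_counts(tn=5, fp=0, fn=5, tp=0), 1)
        assert np.isnan(m.precision)

    def test_from_predictions(self):
        cm = eq.ConfusionMatrix.from_predictions([0, 0, 1, 1], [0, 1, 1, 1])
        assert cm.counts.tolist() == [[1, 1], [0, 2]]


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert eq.pearson_r(x, x).r == pytest.approx(1.0)
        assert eq.pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.5, 3.1, 4.8, 5.0])
        y = np.array([0.9, 2.1, 3.9, 4.2, 6.1])
        # direct product-moment evaluation
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        pr = eq.pearson_r(x, y)
        assert pr.r == pytest.approx(r, abs=1e-12)
        assert pr.r_squared == pytest.approx(r ** 2, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r0 = eq.pearson_r(x, y).r
        assert eq.pearson_r(3.0 * x + 7.0, y).r == pytest.approx(r0, abs=1e-10)
        assert eq.pearson_r(x, 0.5 * y - 2.0).r == pytest.approx(r0, abs=1e-10)

    def test_constant_input_flagged(self):
        res = eq.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined

    def test_too_few_pairs_rejected(self):
        with pytest.raises(EvaluateError):
            eq.pearson_r([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_inputs(self):
        ba = eq.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (ba.mean_diff, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)

    def test_hand_value_with_sample_sd(self):
        ba = eq.bland_altman([0.0, 0.0], [1.0, 3.0])
        assert ba.mean_diff == pytest.approx(2.0)
        assert ba.loa_low == pytest.approx(2.0 - 1.96 * np.sqrt(2.0))
        assert ba.loa_high == pytest.approx(2.0 + 1.96 * np.sqrt(2.0))

    def test_constant_offset_identity(self):
        x = np.array([3.0, 9.0, 27.0, 81.0])
        ba = eq.bland_altman(x, x + 5.5)
        assert ba.mean_diff == pytest.approx(5.5)
        assert ba.loa_low == pytest.approx(5.5)
        assert ba.loa_high == pytest.approx(5.5)

    def test_loa_symmetric_about_mean(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=15), rng.normal(size=15)
        ba = eq.bland_altman(a, b)
        assert ba.loa_high - ba.mean_diff == pytest.approx(ba.mean_diff - ba.loa_low)

    def test_single_pair_rejected(self):
        with pytest.raises(EvaluateError):
            eq.bland_altman([1.0], [2.0])


class TestKFold:
    @staticmethod
    def _dataset(n=50):
        rng = np.random.default_rng(0)
        items = []
        for _ in range(n):
            m = (rng.random((8, 8)) > 0.6).astype(np.uint8)
            items.append((m.astype(float), m))
        return items

    def test_folds_partition_data(self):
        ds = self._dataset(50)
        seen = []
        truth_trainer = lambda train: (lambda img: (img > 0.5).astype(np.uint8))
        summaries = eq.kfold_dsc_summary(ds, trainer=truth_trainer, k=5, seed=1)
        assert len(summaries) == 5
        assert sum(s.n_val for s in summaries) == 50
        assert all(s.n_val == 10 for s in summaries)

    def test_truth_returning_trainer_gives_dice_one(self):
        ds = self._dataset(20)
        trainer = lambda train: (lambda img: (img > 0.5).astype(np.uint8))
        for s in eq.kfold_dsc_summary(ds, trainer=trainer, k=4, seed=2):
            assert s.mean == 1.0 and s.median == 1.0 and s.max == 1.0

    def test_constant_score_summary(self):
        # predictor with a fixed partial overlap: every item scores the same c
        img = np.zeros((8, 8))
        truth = np.zeros((8, 8), dtype=np.uint8)
        truth[:4] = 1
        pred = np.zeros((8, 8), dtype=np.uint8)
        pred[:2] = 1
        c = eq.dice(pred, truth)
        ds = [(img, truth)] * 10
        trainer = lambda train: (lambda image: pred)
        for s in eq.kfold_dsc_summary(ds, trainer=trainer, k=5, seed=3):
            assert s.mean == pytest.approx(c)
            assert s.sd == pytest.approx(0.0)
            assert s.max == pytest.approx(c)
            assert s.median == pytest.approx(c)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(EvaluateError):
            eq.kfold_dsc_summary(self._dataset(3), trainer=lambda t: (lambda i: i), k=5)
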