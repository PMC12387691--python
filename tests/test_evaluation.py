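import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sliceinform import (ConfusionCounts, ModelConfig, TrainHyper,
                         accuracy_grid, attention_report, compute_metrics,
                         confusion, mean_attention, split_dataset,
                         stratified_cv, trapezoidal_auc)
from tests.conftest import separable_images


def auc_oracle(y_true, scores):
    """Mann–Whitney pairwise comparison; ties count one half."""
    pos = [s for s, t in zip(scores, y_true) if t == 1]
    neg = [s for s, t in zip(scores, y_true) if t == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestSplitDataset:
    def test_cohort_of_1125_trains_on_900(self):
        split = split_dataset(1125, seed=0)
        assert split.counts.train == 900
        assert (split.counts.val, split.counts.test) == (112, 113)

    def test_ten_items(self):
        c = split_dataset(10, seed=0).counts
        assert (c.train, c.val, c.test) == (8, 1, 1)

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            split_dataset(2)

    @given(n=st.integers(3, 500), seed=st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_parts_partition_the_indices(self, n, seed):
        s = split_dataset(n, seed=seed)
        allidx = np.concatenate([s.train_idx, s.val_idx, s.test_idx])
        assert len(allidx) == n
        np.testing.assert_array_equal(np.sort(allidx), np.arange(n))

    def test_stratified_when_labels_supplied(self):
        labels = np.array([0] * 50 + [1] * 50)
        s = split_dataset(100, seed=3, labels=labels)
        assert labels[s.test_idx].sum() == 5
        assert labels[s.val_idx].sum() == 5


class TestStratifiedCV:
    def test_balanced_test_holdouts(self):
        labels = np.array([0] * 50 + [1] * 50)
        folds = stratified_cv(labels, k=5, seed=0)
        assert len(folds) == 5
        for _tr, _val, te in folds:
            assert len(te) == 10
            assert labels[te].sum() == 5

    def test_each_fold_partitions_all_indices(self):
        labels = np.array([0] * 23 + [1] * 17)
        for tr, val, te in stratified_cv(labels, k=5, seed=1):
            allidx = np.sort(np.concatenate([tr, val, te]))
            np.testing.assert_array_equal(allidx, np.arange(40))
            assert len(set(tr) & set(val)) == 0
            assert len(set(tr) & set(te)) == 0

    def test_class_proportions_within_one_item(self):
        labels = np.array([0] * 30 + [1] * 20)
        frac = 0.4
        for part_idx in stratified_cv(labels, k=5, seed=2):
            for part in part_idx:
                expected = frac * len(part)
                assert abs(labels[part].sum() - expected) <= 1.0

    def test_seed_determinism(self):
        labels = np.array([0, 1] * 20)
        a = stratified_cv(labels, k=5, seed=9)
        b = stratified_cv(labels, k=5, seed=9)
        for (t1, v1, e1), (t2, v2, e2) in zip(a, b):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(e1, e2)

    def test_plain_mode_is_exact_kfold(self):
        labels = np.array([0, 1] * 15)
        folds = stratified_cv(labels, k=5, seed=0, mode="plain")
        test_union = np.sort(np.concatenate([te for _t, _v, te in folds]))
        np.testing.assert_array_equal(test_union, np.arange(30))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match=">= k"):
            stratified_cv(np.array([0] * 20 + [1] * 3), k=5)


class TestConfusion:
    def test_perfect_predictions(self):
        y = np.array([1] * 10 + [0] * 10)
        c = confusion(y, y, positive_class=1)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_all_predicted_positive(self):
        y = np.array([1] * 10 + [0] * 10)
        c = confusion(np.ones(20), y, positive_class=1)
        assert (c.tp, c.fp, c.tn, c.fn) == (10, 10, 0, 0)

    def test_string_labels_with_explicit_positive_class(self):
        y_true = np.array(["AD", "CN", "AD", "CN"])
        y_pred = np.array(["AD", "AD", "CN", "CN"])
        c = confusion(y_pred, y_true, positive_class="AD")
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_matches_exhaustive_counting(self, rng):
        y_true = rng.integers(0, 2, 50)
        y_pred = rng.integers(0, 2, 50)
        c = confusion(y_pred, y_true)
        tp = sum(1 for p, t in zip(y_pred, y_true) if p == 1 and t == 1)
        tn = sum(1 for p, t in zip(y_pred, y_true) if p == 0 and t == 0)
        fp = sum(1 for p, t in zip(y_pred, y_true) if p == 1 and t == 0)
        fn = sum(1 for p, t in zip(y_pred, y_true) if p == 0 and t == 1)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        assert c.total == 50

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.zeros(3), np.zeros(4))


class TestMetrics:
    def test_hand_computed_example(self):
        m = compute_metrics(ConfusionCounts(tp=50, tn=40, fp=10, fn=0))
        assert m.accuracy == pytest.approx(0.9)
        assert m.precision == pytest.approx(50 / 60)
        assert m.sensitivity == 1.0
        assert m.specificity == pytest.approx(0.8)
        assert m.f1 == pytest.approx(2 * (50 / 60) / (50 / 60 + 1), abs=1e-9)
        assert m.f1 == pytest.approx(0.9091, abs=5e-5)

    def test_undefined_ratios_flagged_not_zero(self):
        with pytest.warns(RuntimeWarning, match="precision undefined"):
            m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert np.isnan(m.precision)
        assert np.isnan(m.f1)

    @given(tp=st.integers(0, 30), tn=st.integers(0, 30),
           fp=st.integers(0, 30), fn=st.integers(0, 30))
    @settings(max_examples=100, deadline=None)
    def test_f1_harmonic_identity_and_ranges(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        for v in (m.accuracy, m.precision, m.sensitivity, m.specificity, m.f1):
            assert np.isnan(v) or 0.0 <= v <= 1.0
        if not (np.isnan(m.precision) or np.isnan(m.sensitivity)
                or m.precision + m.sensitivity == 0):
            expect = (2 * m.precision * m.sensitivity
                      / (m.precision + m.sensitivity))
            assert m.f1 == pytest.approx(expect, abs=1e-9)

    def test_perfectly_separating_scores_auc_one(self):
        y = np.array([0, 0, 1, 1])
        assert trapezoidal_auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_constant_scores_auc_half(self):
        y = np.array([0, 0, 1, 1])
        assert trapezoidal_auc(y, np.full(4, 0.5)) == pytest.approx(0.5)

    def test_auc_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # induce some ties
            assert trapezoidal_auc(y, scores) == pytest.approx(
                auc_oracle(y, scores), abs=1e-12)


class TestAttentionReport:
    def test_single_item_is_identity(self):
        w = mean_attention(np.array([0.5, 0.3, 0.2]))
        assert w.as_array() == pytest.approx([0.5, 0.3, 0.2])

    def test_averaging_preserves_simplex(self):
        w = mean_attention(np.array([[0.98, 0.01, 0.01],
                                     [0.01, 0.98, 0.01]]))
        assert w.as_array() == pytest.approx([0.495, 0.495, 0.01])
        assert w.as_array().sum() == pytest.approx(1.0, abs=1e-6)

    def test_report_equals_brute_force_mean(self, rng):
        raw = rng.dirichlet(np.ones(3), size=11)
        df = attention_report({("task", "axial", 9): raw})
        np.testing.assert_allclose(
            df[["w_low", "w_mid", "w_high"]].to_numpy()[0],
            raw.mean(axis=0), atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            attention_report({})
        with pytest.raises(ValueError):
            mean_attention(np.empty((0, 3)))


def _two_cell_inputs(rng, n=12, side=16):
    """One separable cell, one pure-noise cell."""
    x_sig, y = separable_images(n, side, rng)
    x_noise = rng.normal(0.0, 0.05, size=(n, side, side, 3))
    return {("axial", 9): x_sig, ("coronal", 5): x_noise}, y


class TestAccuracyGrid:
    @pytest.fixture()
    def grid_and_labels(self, rng, tiny_model_cfg):
        cells, y = _two_cell_inputs(rng)
        hyper = TrainHyper(epochs=6, cv_folds=2, dtype="float32")
        grid = accuracy_grid(cells, y, tiny_model_cfg, hyper=hyper, seed=5,
                             task="toy")
        return grid, y

    def test_all_cells_populated_with_fold_metrics(self, grid_and_labels):
        grid, _ = grid_and_labels
        assert set(grid.cells) == {("axial", 9), ("coronal", 5)}
        for cell in grid.cells.values():
            assert len(cell.fold_metrics) == 2
            assert cell.attention.as_array().sum() == pytest.approx(
                1.0, abs=1e-6)

    def test_signal_cell_beats_noise_cell(self, grid_and_labels):
        grid, _ = grid_and_labels
        assert grid.argmax_accuracy() == ("axial", 9)

    def test_orientation_average_is_mean_of_cells(self, grid_and_labels):
        grid, _ = grid_and_labels
        avg = grid.orientation_averages()
        ax = avg[avg.orientation == "axial"]["accuracy"].iloc[0]
        assert ax == pytest.approx(grid.cells[("axial", 9)].metrics.accuracy)

    def test_evaluation_order_invariance(self, rng, tiny_model_cfg):
        cells, y = _two_cell_inputs(rng)
        reordered = dict(reversed(list(cells.items())))
        hyper = TrainHyper(epochs=3, cv_folds=2, dtype="float32")
        g1 = accuracy_grid(cells, y, tiny_model_cfg, hyper=hyper, seed=5)
        g2 = accuracy_grid(reordered, y, tiny_model_cfg, hyper=hyper, seed=5)
        for key in g1.cells:
            a = g1.cells[key].metrics.as_dict()
            b = g2.cells[key].metrics.as_dict()
            for name in a:
                np.testing.assert_equal(a[name], b[name])
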