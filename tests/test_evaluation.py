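"""Metrics identities, LOOCV contracts, grid-search structure, triage, pairing."""

import dataclasses

import numpy as np
import pytest

from mctl3d.classifier import ClassifierConfig
from mctl3d.evaluation import (
    CVResult,
    confusion_metrics,
    default_grid,
    prepare_fold,
    run_grid_search,
    run_loocv,
    triage_curve,
)
from mctl3d.preprocessing import fit_normalizer
from mctl3d.types import Prediction

FAST_CFG = ClassifierConfig(
    n_conv_layers=1, filters_per_layer=16, fc_nodes=16, epochs=2, batch_size=4, learning_rate=1e-3, seed=0
)


def _preds(labels):
    return [Prediction.from_probability(0.9 if l else 0.1) for l in labels]


class TestConfusionMetrics:
    def test_hand_computed_table(self):
        labels = [1, 1, 0, 0]
        preds = _preds([1, 0, 0, 0])
        m = confusion_metrics(labels, preds)
        assert (m.tp, m.fn, m.tn, m.fp) == (1, 1, 2, 0)
        assert m.accuracy == 0.75
        assert m.sensitivity == 0.5
        assert m.specificity == 1.0

    def test_all_correct(self):
        labels = [0, 1, 0, 1]
        m = confusion_metrics(labels, _preds(labels))
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    def test_undefined_denominator_is_nan(self):
        labels = [0, 0, 0]
        m = confusion_metrics(labels, _preds([0, 1, 0]))
        assert np.isnan(m.sensitivity)
        assert m.specificity == pytest.approx(2 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_metrics([0, 1], _preds([0]))

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            labels = rng.integers(0, 2, size=n).tolist()
            predicted = rng.integers(0, 2, size=n).tolist()
            m = confusion_metrics(labels, _preds(predicted))
            # brute-force recount
            pairs = list(zip(labels, predicted))
            tp = sum(1 for y, p in pairs if y == 1 and p == 1)
            tn = sum(1 for y, p in pairs if y == 0 and p == 0)
            fp = sum(1 for y, p in pairs if y == 0 and p == 1)
            fn = sum(1 for y, p in pairs if y == 1 and p == 0)
            assert (m.tp, m.tn, m.fp, m.fn) == (tp, tn, fp, fn)
            assert m.accuracy == pytest.approx((tp + tn) / n)
            if tp + fn:
                assert m.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m.specificity == pytest.approx(tn / (tn + fp))


class TestRunLoocv:
    def test_fold_and_prediction_counts(self, tiny_dataset):
        cv = run_loocv(tiny_dataset, FAST_CFG, seed=1)
        assert cv.n_folds == len(tiny_dataset)
        assert cv.labels == [s.label for s in tiny_dataset]

    def test_single_class_dataset_rejected(self, tiny_dataset):
        healthy_only = [s for s in tiny_dataset if s.label == 0] * 2
        with pytest.raises(ValueError, match="both classes"):
            run_loocv(healthy_only, FAST_CFG, seed=0)

    def test_too_small_dataset_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="at least 4"):
            run_loocv(tiny_dataset[:3], FAST_CFG, seed=0)

    def test_deterministic_under_seed(self, tiny_dataset):
        a = run_loocv(tiny_dataset, FAST_CFG, seed=5)
        b = run_loocv(tiny_dataset, FAST_CFG, seed=5)
        assert [p.probability for p in a.predictions] == [p.probability for p in b.predictions]

    def test_fold_normalizer_excludes_heldout(self, tiny_dataset):
        # leakage guard: the fold-0 normalizer differs from the all-data one
        # whenever sample 0 shifts the pooled statistics
        windowed_all, norm_all = prepare_fold(tiny_dataset, list(range(len(tiny_dataset))))
        _, norm_fold0 = prepare_fold(tiny_dataset, list(range(1, len(tiny_dataset))))
        assert norm_fold0 != norm_all
        # and recomputation with the same training indices is bit-identical
        _, norm_fold0_again = prepare_fold(tiny_dataset, list(range(1, len(tiny_dataset))))
        assert norm_fold0 == norm_fold0_again


class TestDefaultGrid:
    def test_paired_grid_has_nine_rows(self):
        grid = default_grid()
        assert len(grid) == 9
        assert {(c.n_conv_layers, c.filters_per_layer) for c in grid} == {(1, 16), (2, 32), (3, 64)}
        assert sorted({c.fc_nodes for c in grid}) == [16, 32, 64]

    def test_full_grid_has_27(self):
        grid = default_grid(full=True)
        assert len(grid) == 27
        assert len({(c.n_conv_layers, c.filters_per_layer, c.fc_nodes) for c in grid}) == 27


@pytest.fixture(scope="module")
def small_grid_result(tiny_dataset):
    grid = [
        dataclasses.replace(FAST_CFG, fc_nodes=16),
        dataclasses.replace(FAST_CFG, fc_nodes=32),
    ]
    return run_grid_search(tiny_dataset, grid=grid, repeats=2, seed=3)


class TestGridSearch:

    def test_repeat_bookkeeping(self, small_grid_result):
        assert set(small_grid_result.results) == {0, 1}
        assert all(len(runs) == 2 for runs in small_grid_result.results.values())

    def test_summary_ranges_are_ordered(self, small_grid_result):
        s = small_grid_result.summary
        for metric in ("accuracy", "sensitivity", "specificity"):
            sub = s[[f"{metric}_min", f"{metric}_mean", f"{metric}_max"]].dropna()
            assert (sub[f"{metric}_min"] <= sub[f"{metric}_mean"] + 1e-12).all()
            assert (sub[f"{metric}_mean"] <= sub[f"{metric}_max"] + 1e-12).all()

    def test_best_config_tiebreak_prefers_fewer_params(self, small_grid_result):
        s = small_grid_result.summary
        best = small_grid_result.best_index
        top = s["accuracy_mean"].max()
        tied = s[s["accuracy_mean"] == top]
        assert s.loc[best, "n_params"] == tied["n_params"].min()

    def test_deterministic_under_master_seed(self, tiny_dataset):
        grid = [FAST_CFG]
        a = run_grid_search(tiny_dataset, grid=grid, repeats=2, seed=9)
        b = run_grid_search(tiny_dataset, grid=grid, repeats=2, seed=9)
        assert a.summary.equals(b.summary)

    def test_empty_grid_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="nonempty"):
            run_grid_search(tiny_dataset, grid=[], repeats=1)


class TestTriageCurve:
    def _cv(self, confidences, correct):
        preds, labels = [], []
        for conf, ok in zip(confidences, correct):
            p = 0.5 + conf / 2  # label 1 prediction with given confidence
            preds.append(Prediction.from_probability(p))
            labels.append(1 if ok else 0)
        from mctl3d.evaluation import confusion_metrics as cm

        return CVResult(
            predictions=preds, labels=labels, metrics=cm(labels, preds),
            config=FAST_CFG, init_mode="random", seed=0,
        )

    def test_full_coverage_reproduces_overall_accuracy(self):
        cv = self._cv([0.9, 0.5, 0.3, 0.1], [True, False, True, False])
        curve = triage_curve(cv, coverages=(1.0,))
        assert curve.accuracies[0] == cv.metrics.accuracy

    def test_top_one_selection(self):
        cv = self._cv([0.9, 0.1], [True, False])
        curve = triage_curve(cv, coverages=(0.5,))
        assert curve.accuracies[0] == 1.0
        assert curve.n_included[0] == 1

    def test_invalid_coverage_rejected(self):
        cv = self._cv([0.9], [True])
        with pytest.raises(ValueError, match="coverage"):
            triage_curve(cv, coverages=(0.0,))

    def test_included_counts_are_ceil(self):
        cv = self._cv([0.9, 0.8, 0.7], [True, True, False])
        curve = triage_curve(cv, coverages=(0.4, 0.7, 1.0))
        assert curve.n_included == [2, 3, 3]
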