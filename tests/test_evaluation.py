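"""Dataset assembly, grouped CV, the five metrics, AUROC, importances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegemo as E
from eegemo.bands import CONDITIONS, FEATURE_NAMES
from eegemo.evaluation import (
    ClassifierSpec,
    assemble_dataset,
    benchmark_contrasts,
    binary_counts,
    compute_auroc,
    compute_metrics,
    confusion_matrix_counts,
    default_specs,
    feature_importance,
    macro_ovr_auroc,
    participant_folds,
    run_cv,
    run_full_benchmark,
)
from eegemo.exceptions import InsufficientDataError, InvalidParameterError

from oracles import auroc_pairwise, metrics_direct


def _feature_table(rng, n_participants=10, effect=3.0, n_features=8):
    """Synthetic feature table with a per-condition mean shift on every column."""
    rows = []
    shift = {c: i * effect for i, c in enumerate(CONDITIONS)}
    for p in range(n_participants):
        subj = rng.normal(scale=0.5)
        for c in CONDITIONS:
            vals = {f"F{i}": shift[c] + subj + rng.normal() for i in range(n_features)}
            rows.append({"participant_id": f"P{p:02d}", "condition": c, **vals})
    return pd.DataFrame(rows)


FEATS = [f"F{i}" for i in range(8)]


class TestAssembleDataset:
    def test_full_cohort_shape(self, rng):
        table = _feature_table(rng, n_participants=15)
        ds = assemble_dataset(table, FEATS, CONDITIONS)
        assert ds.n_rows == 60
        assert ds.X.shape == (60, 8)
        ds14 = assemble_dataset(table, FEATS[:4], ("baseline", "low_arousal"))
        assert ds14.n_rows == 30

    def test_row_order_deterministic(self, rng):
        table = _feature_table(rng)
        shuffled = table.sample(frac=1, random_state=1).reset_index(drop=True)
        a = assemble_dataset(table, FEATS, CONDITIONS)
        b = assemble_dataset(shuffled, FEATS, CONDITIONS)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.groups, b.groups)
        pd.testing.assert_frame_equal(a.X, b.X)

    def test_empty_or_thin_contrasts_rejected(self, rng):
        table = _feature_table(rng)
        with pytest.raises(InsufficientDataError):
            assemble_dataset(table, FEATS, ())
        with pytest.raises(InsufficientDataError):
            assemble_dataset(table[table.participant_id == "P00"], FEATS,
                             ("baseline", "low_arousal"))


class TestComputeMetrics:
    def test_textbook_counts(self):
        # TP=9 FP=1 FN=3 TN=7 in the canonical matrix layout
        cm = np.array([[7, 1], [3, 9]])
        m = compute_metrics(cm)
        assert m["precision"] == pytest.approx(0.900, abs=1e-3)
        assert m["recall"] == pytest.approx(0.750, abs=1e-3)
        assert m["f1"] == pytest.approx(0.818, abs=1e-3)
        assert m["accuracy"] == pytest.approx(0.800, abs=1e-3)

    def test_perfect_classifier(self):
        m = compute_metrics(np.array([[5, 0], [0, 5]]))
        assert all(m[k] == 1.0 for k in ("precision", "recall", "f1", "accuracy"))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_formula_oracle(self, seed):
        r = np.random.default_rng(seed)
        tp, fp, tn, fn = r.integers(1, 50, size=4)
        cm = np.array([[tn, fp], [fn, tp]])
        m = compute_metrics(cm)
        p, rec, f1, acc = metrics_direct(tp, fp, tn, fn)
        assert m["precision"] == pytest.approx(p, abs=1e-12)
        assert m["recall"] == pytest.approx(rec, abs=1e-12)
        assert m["f1"] == pytest.approx(f1, abs=1e-12)
        assert m["accuracy"] == pytest.approx(acc, abs=1e-12)
        assert all(0 <= v <= 1 for v in m.values())

    def test_multiclass_macro_average(self, rng):
        cm = rng.integers(0, 20, size=(3, 3))
        m = compute_metrics(cm)
        per_class = [metrics_direct(*_ovr(cm, k)) for k in range(3)]
        assert m["precision"] == pytest.approx(np.mean([x[0] for x in per_class]))
        assert m["accuracy"] == pytest.approx(np.trace(cm) / cm.sum())

    def test_undefined_class_excluded_with_warning(self):
        cm = np.array([[5, 0, 0], [2, 3, 0], [1, 0, 0]])  # class 2 never predicted
        with pytest.warns(UserWarning, match="undefined"):
            m = compute_metrics(cm)
        assert np.isfinite(m["precision"])


def _ovr(cm, k):
    tp = cm[k, k]
    fp = cm[:, k].sum() - tp
    fn = cm[k, :].sum() - tp
    tn = cm.sum() - tp - fp - fn
    return tp, fp, tn, fn


class TestAuroc:
    def test_perfect_and_constant_scores(self):
        labels = np.array([0, 0, 1, 1], dtype=bool)
        assert compute_auroc([0.1, 0.2, 0.8, 0.9], labels)[0] == 1.0
        auroc, points = compute_auroc([0.5] * 4, labels)
        assert auroc == 0.5
        assert points.shape == (2, 2)  # one diagonal segment

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_pairwise_mann_whitney(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 40))
        scores = np.round(r.normal(size=n), 1)  # rounding forces ties
        labels = r.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        mine, points = compute_auroc(scores, labels)
        assert mine == pytest.approx(auroc_pairwise(scores, labels), abs=1e-12)
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)

    def test_antisymmetry_under_score_negation(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30).astype(bool)
        a = compute_auroc(scores, labels)[0]
        b = compute_auroc(-scores, labels)[0]
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_auroc([0.1, 0.2], [True, True])

    def test_macro_ovr(self, rng):
        proba = rng.dirichlet(np.ones(3), size=30)
        y = rng.integers(0, 3, 30)
        ref = np.mean([auroc_pairwise(proba[:, k], y == k)
                       for k in range(3) if 0 < (y == k).sum() < 30])
        assert macro_ovr_auroc(proba, y, [0, 1, 2]) == pytest.approx(ref, abs=1e-12)


class TestGroupedCV:
    def test_folds_partition_participants(self, rng):
        groups = np.repeat([f"P{i}" for i in range(11)], 4)
        folds = participant_folds(groups, 5, seed=3)
        flat = np.concatenate(folds)
        assert sorted(flat) == sorted(set(groups))

    def test_no_participant_in_train_and_test(self, rng):
        table = _feature_table(rng, n_participants=8)
        ds = assemble_dataset(table, FEATS, CONDITIONS)
        for fold in participant_folds(ds.groups, 4, seed=0):
            test = np.isin(ds.groups, fold)
            assert not set(ds.groups[test]) & set(ds.groups[~test])

    def test_leave_one_participant_out_tests_every_row_once(self, rng):
        table = _feature_table(rng, n_participants=6)
        ds = assemble_dataset(table, FEATS, CONDITIONS)
        folds = participant_folds(ds.groups, 6, seed=0)
        tested = np.zeros(ds.n_rows, dtype=int)
        for fold in folds:
            tested += np.isin(ds.groups, fold).astype(int)
        assert np.all(tested == 1)

    def test_too_few_participants(self, rng):
        table = _feature_table(rng, n_participants=3)
        ds = assemble_dataset(table, FEATS, CONDITIONS)
        with pytest.raises(InsufficientDataError):
            participant_folds(ds.groups, 5, seed=0)

    def test_separable_dataset_high_accuracy(self, rng):
        """Strong planted effects: every classifier reaches >= 0.95 accuracy."""
        table = _feature_table(rng, n_participants=10, effect=8.0)
        ds = assemble_dataset(table, FEATS, ("baseline", "social_anxiety"))
        for spec in default_specs():
            cell = run_cv(ds, spec, n_folds=5, seed=0)
            assert cell.metrics["accuracy"] >= 0.95, spec.kind

    def test_determinism(self, rng):
        table = _feature_table(rng, n_participants=8)
        ds = assemble_dataset(table, FEATS, ("baseline", "high_arousal"))
        a = run_cv(ds, ClassifierSpec("xgboost"), seed=7)
        b = run_cv(ds, ClassifierSpec("xgboost"), seed=7)
        assert a.metrics == b.metrics
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_metric_bounds_and_confusion_total(self, rng):
        table = _feature_table(rng, n_participants=8, effect=1.0)
        ds = assemble_dataset(table, FEATS, CONDITIONS)
        cell = run_cv(ds, ClassifierSpec("logreg"), seed=0)
        assert all(0 <= v <= 1 for v in cell.metrics.values())
        assert cell.confusion.sum() == ds.n_rows


class TestFeatureImportance:
    def test_planted_feature_dominates(self, rng):
        """A single informative column takes rank 1 with >= 0.5 of the gain."""
        for s in range(10):
            local = np.random.default_rng(s)
            rows = []
            for p in range(10):
                for c in ("baseline", "social_anxiety"):
                    sig = (2.0 if c == "social_anxiety" else -2.0) + 0.2 * local.normal()
                    vals = {"KEY": sig, **{f"N{i}": local.normal() for i in range(5)}}
                    rows.append({"participant_id": f"P{p}", "condition": c, **vals})
            table = pd.DataFrame(rows)
            ds = assemble_dataset(table, ["KEY"] + [f"N{i}" for i in range(5)],
                                  ("baseline", "social_anxiety"))
            cell = run_cv(ds, ClassifierSpec("xgboost"), seed=s)
            assert cell.importance[0][0] == "KEY"
            assert cell.importance[0][1] >= 0.5

    def test_importance_normalized_top5(self, rng):
        table = _feature_table(rng, n_participants=10)
        ds = assemble_dataset(table, FEATS, CONDITIONS)
        cell = run_cv(ds, ClassifierSpec("xgboost"), seed=0)
        assert len(cell.importance) == 5
        assert all(s > 0 for _, s in cell.importance)

    def test_zero_gain_warns_empty(self):
        with pytest.warns(UserWarning, match="no splits"):
            out = feature_importance([{"A": 0.0, "B": 0.0}])
        assert out == []


class TestFullBenchmark:
    def test_contrast_list(self):
        contrasts = benchmark_contrasts()
        assert len(contrasts) == 10
        assert sum(len(c) == 2 for c in contrasts) == 6
        assert sum(len(c) > 2 for c in contrasts) == 4
        assert CONDITIONS in contrasts

    def test_thirty_cells_and_report_frames(self, rng):
        table = _feature_table(rng, n_participants=6)
        report = run_full_benchmark(table, FEATS, seed=0, n_folds=3)
        assert len(report.cells) == 30
        mf = report.metrics_frame()
        assert set(mf.columns) == {"condition", "classifier", "precision",
                                   "recall", "f1", "accuracy", "auroc"}
        assert len(mf) == 30
        imp = report.importance_frame()
        assert set(imp["condition"]) == set(mf["condition"])
        assert imp["rank"].max() <= 5


def test_label_permutation_reaches_chance(rng):
    """With labels shuffled, grouped-CV accuracy averages to ~1/K."""
    table = _feature_table(rng, n_participants=10, effect=4.0)
    accs = []
    for s in range(20):
        local = np.random.default_rng(s)
        shuffled = table.copy()
        shuffled["condition"] = table["condition"].to_numpy()[
            local.permutation(len(table))
        ]
        try:
            ds = assemble_dataset(shuffled, FEATS, ("baseline", "high_arousal"))
            cell = run_cv(ds, ClassifierSpec("logreg"), seed=s)
        except InsufficientDataError:
            continue
        accs.append(cell.metrics["accuracy"])
    assert abs(np.mean(accs) - 0.5) < 0.15
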