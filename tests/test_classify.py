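"""Metric formulas, fold plans and the cross-validation harness."""
import numpy as np
import pandas as pd
import pytest

from cookietalk.classify import (
    ConfusionCounts,
    ModelSpec,
    compute_metrics,
    evaluate_models,
    stratified_repeated_kfold,
)
from cookietalk.errors import StratificationError


def oracle_metrics(tp, tn, fp, fn):
    total = tp + tn + fp + fn
    acc = (tp + tn) / total * 100
    prec = tp / (tp + fp) * 100 if tp + fp else 0.0
    rec = tp / (tp + fn) * 100 if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1


class TestMetrics:
    def test_symmetric_case_all_fifty(self):
        m = compute_metrics(ConfusionCounts(25, 25, 25, 25))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (50.0, 50.0, 50.0, 50.0)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=30, tn=20, fp=0, fn=0))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (100.0, 100.0, 100.0, 100.0)

    def test_hand_computed(self):
        m = compute_metrics(ConfusionCounts(tp=40, fn=10, fp=10, tn=40))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (80.0, 80.0, 80.0, 80.0)

    def test_matches_integer_oracle_with_harmonic_bound(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, size=4))
            if tp + tn + fp + fn == 0:
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            acc, prec, rec, f1 = oracle_metrics(tp, tn, fp, fn)
            assert (m.accuracy, m.precision, m.recall, m.f1) == pytest.approx(
                (acc, prec, rec, f1)
            )
            assert min(m.precision, m.recall) - 1e-9 <= m.f1
            assert m.f1 <= (m.precision + m.recall) / 2 + 1e-9
            assert all(0 <= v <= 100 for v in (m.accuracy, m.precision, m.recall, m.f1))

    def test_degenerate_denominators_warn(self):
        with pytest.warns(UserWarning, match="precision"):
            m = compute_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=5))
        assert m.precision == 0.0 and m.f1 == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestFoldPlan:
    def test_partition_and_stratification(self):
        labels = np.array(["AD"] * 55 + ["HC"] * 45)
        plan = stratified_repeated_kfold(labels, k=10, repeats=10, seed=3)
        assert len(plan) == 10
        for folds in plan:
            test_indices = np.concatenate([test for _, test in folds])
            assert sorted(test_indices) == list(range(100))
            for train, test in folds:
                assert set(train).isdisjoint(test)
                ad_share = np.mean(labels[test] == "AD")
                assert abs(ad_share * len(test) - 0.55 * len(test)) <= 1.0

    def test_even_split(self):
        labels = np.array(["AD", "HC"] * 50)
        plan = stratified_repeated_kfold(labels, k=10, repeats=1, seed=0)
        assert all(len(test) == 10 for _, test in plan[0])

    def test_seed_determinism(self):
        labels = np.array(["AD"] * 30 + ["HC"] * 30)
        p1 = stratified_repeated_kfold(labels, seed=11)
        p2 = stratified_repeated_kfold(labels, seed=11)
        for f1, f2 in zip(sum(p1, []), sum(p2, [])):
            assert np.array_equal(f1[1], f2[1])

    def test_small_class_rejected(self):
        labels = np.array(["AD"] * 5 + ["HC"] * 95)
        with pytest.raises(StratificationError):
            stratified_repeated_kfold(labels, k=10)


def blobs(n=100, distance=8.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack(
        [
            rng.standard_normal((n // 2, 5)) - distance / 2,
            rng.standard_normal((n // 2, 5)) + distance / 2,
        ]
    )
    labels = np.array(["HC"] * (n // 2) + ["AD"] * (n // 2))
    return pd.DataFrame(x, columns=[f"f{i}" for i in range(5)]), labels


class TestEvaluateModels:
    def test_separable_blobs_are_learned(self):
        x, y = blobs()
        summary = evaluate_models(x, y, [ModelSpec("svm_linear")], repeats=2, seed=0)
        assert summary.mean("svm_linear", "accuracy") >= 99.0

    def test_single_spec_reported_alone(self):
        x, y = blobs()
        summary = evaluate_models(x, y, [ModelSpec("knn")], repeats=1, seed=0)
        assert list(summary.table.index) == ["knn"]
        assert len(summary.trace) == 10

    def test_chance_level_on_shuffled_labels(self, rng):
        x, y = blobs(n=200)
        shuffled = rng.permutation(y)
        summary = evaluate_models(
            x, shuffled, [ModelSpec("knn"), ModelSpec("svm_rbf")], repeats=2, seed=1
        )
        for model in ("knn", "svm_rbf"):
            assert 40.0 <= summary.mean(model, "accuracy") <= 60.0

    def test_per_fold_internal_consistency(self):
        x, y = blobs()
        summary = evaluate_models(x, y, [ModelSpec("random_forest")], repeats=1, seed=2)
        for _, row in summary.trace.iterrows():
            total = row.tp + row.tn + row.fp + row.fn
            assert total == 10
            assert row.accuracy == pytest.approx((row.tp + row.tn) / total * 100)

    def test_precomputed_matches_linear(self):
        x, y = blobs(seed=4)
        summary = evaluate_models(
            x, y, [ModelSpec("svm_linear"), ModelSpec("svm_precomputed")], repeats=1, seed=0
        )
        lin = summary.trace.query("model == 'svm_linear'")[["tp", "tn", "fp", "fn"]]
        pre = summary.trace.query("model == 'svm_precomputed'")[["tp", "tn", "fp", "fn"]]
        assert np.array_equal(lin.to_numpy(), pre.to_numpy())

    def test_standardization_uses_train_folds_only(self):
        # a wild outlier in one test fold must not move the training-side
        # statistics: predictions equal a hand-rolled loop that scales with
        # train-only mean/sd
        from sklearn.neighbors import KNeighborsClassifier

        x, y = blobs(n=40, distance=4.0, seed=5)
        x.iloc[0] = 1e6  # outlier that would wreck a leaky scaler
        summary = evaluate_models(x, y, [ModelSpec("knn")], k=5, repeats=1, seed=6)
        plan = stratified_repeated_kfold(y, k=5, repeats=1, seed=6)
        xv = x.to_numpy()
        for f, (train, test) in enumerate(plan[0]):
            mean = xv[train].mean(axis=0)
            sd = xv[train].std(axis=0)
            model = KNeighborsClassifier(n_neighbors=30)
            model.fit((xv[train] - mean) / sd, y[train])
            pred = model.predict((xv[test] - mean) / sd)
            row = summary.trace.query(f"fold == {f}").iloc[0]
            assert row.tp == np.sum((y[test] == "AD") & (pred == "AD"))
            assert row.tn == np.sum((y[test] == "HC") & (pred == "HC"))

    def test_nonfinite_feature_named(self):
        x, y = blobs()
        x.loc[3, "f2"] = np.nan
        with pytest.raises(ValueError, match="f2"):
            evaluate_models(x, y, [ModelSpec("knn")], repeats=1)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("gradient_boosting")
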