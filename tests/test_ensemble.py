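"""Base classifiers, stacking, metric arithmetic, CV partitioning."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from preictal import (
    EnsembleConfig,
    PipelineConfig,
    StackedEnsemble,
    SynthConfig,
    audit_leakage,
    compute_metrics,
    fit_base,
    generate_labeled_segments,
    kfold_cv,
    stack_fit,
    stack_predict,
)


def separable_xy(rng, n=120):
    x0 = rng.normal(-2.0, 0.7, (n // 2, 2))
    x1 = rng.normal(+2.0, 0.7, (n // 2, 2))
    x = np.vstack([x0, x1])
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    perm = rng.permutation(n)
    return x[perm], y[perm]


class _OracleBase:
    """Stand-in base-model set whose three scores equal the true label."""

    def __init__(self, lookup):
        self.lookup = lookup  # maps row tuple -> label

    def predict_proba(self, x):
        y = np.array([self.lookup[tuple(row)] for row in np.atleast_2d(x)], float)
        return np.column_stack([y, y, y])


class TestFitBase:
    def test_linearly_separable_toy_all_models_above_095(self, rng):
        x, y = separable_xy(rng)
        base = fit_base(x, y, EnsembleConfig(lstm_epochs=120, seed=0))
        scores = base.predict_proba(x)
        for col in range(3):
            acc = ((scores[:, col] >= 0.5) == (y == 1)).mean()
            assert acc >= 0.95, f"model {col}"

    def test_scores_within_unit_interval(self, rng):
        x, y = separable_xy(rng, n=60)
        base = fit_base(x, y, EnsembleConfig(lstm_epochs=10, seed=0))
        s = base.predict_proba(rng.normal(size=(20, 2)))
        assert np.all((s >= 0) & (s <= 1))

    def test_seeded_determinism(self, rng):
        x, y = separable_xy(rng, n=60)
        cfg = EnsembleConfig(lstm_epochs=20, seed=5)
        s1 = fit_base(x, y, cfg).predict_proba(x)
        s2 = fit_base(x, y, cfg).predict_proba(x)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            fit_base(rng.normal(size=(10, 2)), np.zeros(10))


class TestStacking:
    def test_oracle_bases_give_perfect_meta(self, rng):
        from sklearn.linear_model import LogisticRegression

        x, y = separable_xy(rng, n=40)
        oracle = _OracleBase({tuple(row): int(lab) for row, lab in zip(x, y)})
        z = oracle.predict_proba(x)
        meta = LogisticRegression().fit(z, y)
        ens = StackedEnsemble(
            base=oracle, meta=meta, split_fraction=0.25,
            train_indices=np.arange(0), meta_indices=np.arange(len(y)),
        )
        scores, labels = stack_predict(ens, x)
        assert (labels == y).all()
        assert labels[y == 1].min() == 1  # all-ones base scores -> positive call

    def test_split_is_stratified_and_disjoint(self, rng):
        x, y = separable_xy(rng, n=80)
        ens = stack_fit(x, y, EnsembleConfig(lstm_epochs=5, seed=0))
        assert set(ens.train_indices) & set(ens.meta_indices) == set()
        assert len(ens.meta_indices) == 20  # 0.25 of 80
        assert 0 < y[ens.meta_indices].sum() < len(ens.meta_indices)

    def test_batch_prediction_equals_elementwise(self, rng):
        x, y = separable_xy(rng, n=60)
        ens = stack_fit(x, y, EnsembleConfig(lstm_epochs=10, seed=1))
        batch, _ = stack_predict(ens, x[:5])
        singles = np.concatenate([stack_predict(ens, x[i : i + 1])[0] for i in range(5)])
        np.testing.assert_allclose(batch, singles)

    def test_stacked_auc_not_below_best_base(self, rng):
        """On held-out data, stacking should track the best base classifier
        (within a small stochastic margin), averaged over seeds."""
        diffs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 400
            x = r.normal(size=(n, 6))
            logit = 1.5 * x[:, 0] + 1.2 * np.sign(x[:, 1] * x[:, 2]) + x[:, 3] ** 2 - 1
            y = (logit + r.logistic(0, 1.0, n) > 0).astype(int)
            x_tr, x_te, y_tr, y_te = x[: n // 2], x[n // 2 :], y[: n // 2], y[n // 2 :]
            ens = stack_fit(x_tr, y_tr, EnsembleConfig(lstm_epochs=40, seed=seed))
            s_stack, _ = stack_predict(ens, x_te)
            base_scores = ens.base.predict_proba(x_te)
            auc_stack = roc_auc_score(y_te, s_stack)
            auc_best = max(roc_auc_score(y_te, base_scores[:, j]) for j in range(3))
            diffs.append(auc_stack - auc_best)
        assert np.mean(diffs) >= -0.02


class TestComputeMetrics:
    @staticmethod
    def _from_confusion(tp, fp, tn, fn):
        y = np.r_[np.ones(tp + fn, int), np.zeros(tn + fp, int)]
        s = np.r_[np.full(tp, 0.9), np.full(fn, 0.1), np.full(tn, 0.1), np.full(fp, 0.9)]
        return y, s

    def test_handworked_confusion_fixture(self):
        y, s = self._from_confusion(tp=50, fp=10, tn=40, fn=0)
        m = compute_metrics(y, s, interictal_hours=2.0)
        assert m.sensitivity == 100.0
        assert m.specificity == 80.0
        assert m.accuracy == 90.0
        assert m.fp_rate == pytest.approx(0.2)
        assert m.fp_per_hour == pytest.approx(5.0)
        assert m.confusion == {"tp": 50, "fp": 10, "tn": 40, "fn": 0}

    def test_perfect_scores(self):
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        s = np.r_[np.full(5, 0.99), np.full(5, 0.01)]
        m = compute_metrics(y, s)
        assert m.mcc == pytest.approx(1.0)
        assert m.auc_roc == pytest.approx(1.0)

    def test_exhaustive_small_confusions_match_sklearn(self):
        for tp in range(0, 6):
            for fp in range(0, 6):
                for tn in range(0, 6):
                    for fn in range(0, 6):
                        if (tp + fn) == 0 or (tn + fp) == 0:
                            continue
                        y, s = self._from_confusion(tp, fp, tn, fn)
                        m = compute_metrics(y, s)
                        pred = (s >= 0.5).astype(int)
                        assert m.accuracy == pytest.approx(100 * (pred == y).mean())
                        assert m.mcc == pytest.approx(
                            matthews_corrcoef(y, pred), abs=1e-12
                        )
                        assert m.auc_roc == pytest.approx(
                            roc_auc_score(y, s), abs=1e-12
                        )

    def test_auc_against_sklearn_on_random_scores(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            if y.min() == y.max():
                continue
            s = rng.uniform(size=50)
            m = compute_metrics(y, s)
            assert m.auc_roc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = rng.uniform(size=200)
        a1 = compute_metrics(y, s).auc_roc
        a2 = compute_metrics(y, 1 / (1 + np.exp(-7 * (s - 0.3)))).auc_roc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_random_scores_on_balanced_labels_near_half(self, rng):
        y = np.r_[np.ones(1000, int), np.zeros(1000, int)]
        s = rng.uniform(size=2000)
        m = compute_metrics(y, s)
        assert 0.45 <= m.auc_roc <= 0.55

    def test_single_class_auc_missing_with_warning(self):
        with pytest.warns(UserWarning, match="AUC undefined"):
            m = compute_metrics(np.ones(5, int), np.full(5, 0.7))
        assert m.auc_roc is None


class TestKfoldCv:
    @pytest.fixture(scope="class")
    def small_cv(self):
        config = SynthConfig(n_channels=3, seed=21, class_separation=3.0)
        segs = generate_labeled_segments(config, 30)
        pipeline = PipelineConfig(
            seed=21,
            cnn_epochs=3,
            ensemble=EnsembleConfig(lstm_epochs=10, rf_trees=50),
        )
        return segs, kfold_cv(segs, pipeline, k=3)

    def test_folds_partition_the_data(self, small_cv):
        segs, report = small_cv
        seen = np.concatenate([rec.test_indices for rec in report.folds])
        assert sorted(seen.tolist()) == list(range(len(segs)))

    def test_leakage_audit_passes_in_default_mode(self, small_cv):
        _, report = small_cv
        audit_leakage(report)

    def test_summary_reports_mean_and_std(self, small_cv):
        _, report = small_cv
        summary = report.summary()
        assert set(summary) >= {"accuracy", "sensitivity", "specificity", "mcc"}
        for mean, std in summary.values():
            assert np.isfinite(mean) and np.isfinite(std)

    def test_high_separation_classifies_well(self, small_cv):
        _, report = small_cv
        mean_acc = report.summary()["accuracy"][0]
        assert mean_acc >= 90.0

    def test_balance_before_split_flagged_by_audit(self):
        config = SynthConfig(n_channels=2, seed=22, class_separation=2.0)
        segs = generate_labeled_segments(config, 12)
        pipeline = PipelineConfig(
            seed=22, cnn_epochs=2, balance_before_split=True,
            ensemble=EnsembleConfig(lstm_epochs=5, rf_trees=20),
        )
        with pytest.warns(UserWarning, match="balance_before_split"):
            report = kfold_cv(segs, pipeline, k=2)
        with pytest.raises(AssertionError, match="trained on"):
            audit_leakage(report)

    def test_unlabeled_segments_rejected(self):
        config = SynthConfig(n_channels=2, seed=23)
        segs = generate_labeled_segments(config, 4)
        segs[0].label = "unlabeled"
        with pytest.raises(ValueError, match="unlabeled"):
            kfold_cv(segs, PipelineConfig(seed=0), k=2)

    def test_tiny_class_reduces_k_with_warning(self):
        config = SynthConfig(n_channels=2, seed=24, class_separation=2.0)
        segs = generate_labeled_segments(config, 4)
        pipeline = PipelineConfig(
            seed=24, cnn_epochs=2,
            ensemble=EnsembleConfig(lstm_epochs=5, rf_trees=20),
        )
        with pytest.warns(UserWarning, match="reducing k"):
            kfold_cv(segs, pipeline, k=5)
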