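"""Cross-validated decoding: folds, standardization, residualization, estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import balanced_accuracy_score

import touchdecode as td
from touchdecode import simulate as sim
from touchdecode.decoding import (
    AnalysisConfig, balanced_accuracy, decode_time_categorical,
    decode_time_continuous, fit_lda, loso_folds, residualize_confounds,
    standardize,
)


class TestLosoFolds:
    def test_one_fold_per_sequence_partition(self):
        seq = np.array([0, 0, 1, 1, 2, 2, 2])
        folds = loso_folds(seq)
        assert len(folds) == 3
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(7))
        for tr, te in folds:
            assert set(tr) | set(te) == set(range(7))
            assert not set(tr) & set(te)

    def test_fold_sets_invariant_to_trial_order(self):
        seq = np.array([0, 1, 0, 1, 0, 1])
        shuffled = seq[::-1]
        f1 = loso_folds(seq)
        f2 = loso_folds(shuffled)
        sets1 = [frozenset(seq[i] for i in te) for _, te in f1]
        sets2 = [frozenset(shuffled[i] for i in te) for _, te in f2]
        assert sets1 == sets2

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            loso_folds([5, 5, 5])


class TestStandardize:
    def test_two_point_column(self):
        tr, te = standardize(np.array([[1.0], [3.0]]), np.array([[2.0]]))
        np.testing.assert_allclose(tr.ravel(), [-1.0, 1.0])
        np.testing.assert_allclose(te.ravel(), [0.0])

    def test_constant_column_maps_to_zeros(self):
        tr, te = standardize(np.full((3, 1), 4.0), np.array([[9.0]]))
        assert not tr.any() and not te.any()

    def test_test_uses_train_statistics(self):
        rng = np.random.default_rng(0)
        train = rng.standard_normal((20, 3)) * 5 + 2
        test = rng.standard_normal((10, 3))
        _, te = standardize(train, test)
        expected = (test - train.mean(0)) / train.std(0)
        np.testing.assert_allclose(te, expected, atol=1e-10)
        tr, _ = standardize(train, test)
        np.testing.assert_allclose(tr.mean(0), 0, atol=1e-8)
        np.testing.assert_allclose(tr.std(0), 1, atol=1e-8)


class TestResidualize:
    def test_confound_equal_to_feature_leaves_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 4))
        conf = x[:, [0]]
        tr, _ = residualize_confounds(x, x[:5], conf, conf[:5])
        np.testing.assert_allclose(tr[:, 0], 0, atol=1e-8)

    def test_orthogonal_confound_changes_nothing(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((50, 3))
        conf = rng.standard_normal((50, 1))
        # orthogonalize the confound to the data and the intercept
        design = np.column_stack([np.ones(50), x])
        beta, *_ = np.linalg.lstsq(design, conf, rcond=None)
        conf = conf - design @ beta
        tr, _ = residualize_confounds(x, x[:5], conf, conf[:5])
        np.testing.assert_allclose(tr, x - x.mean(0), atol=1e-8)

    def test_planted_dependence_removed(self):
        rng = np.random.default_rng(3)
        c = rng.standard_normal(40)
        y = 2 * c + 0.1 * rng.standard_normal(40)
        tr, _ = residualize_confounds(
            y[:, None], y[:5, None], c[:, None], c[:5, None]
        )
        assert abs(np.corrcoef(tr.ravel(), c)[0, 1]) < 1e-8

    def test_collinear_columns_dropped(self, caplog):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((20, 2))
        c = rng.standard_normal((20, 1))
        conf = np.column_stack([c, 2 * c])  # rank deficient
        with caplog.at_level("WARNING"):
            tr, te = residualize_confounds(x, x[:4], conf, conf[:4])
        assert "collinear" in caplog.text
        assert np.isfinite(tr).all()

    def test_constant_confound_is_noop_after_intercept(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((25, 3))
        conf = np.full((25, 1), 3.3)
        tr, _ = residualize_confounds(x, x[:5], conf, conf[:5])
        np.testing.assert_allclose(tr, x - x.mean(0), atol=1e-8)


class TestLda:
    def test_separable_clusters_classified_perfectly(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = np.repeat([0, 1], 20)
        clf = fit_lda(X, y)
        assert balanced_accuracy(y, clf.predict(X)) == 1.0

    def test_null_classes_score_at_chance(self):
        rng = np.random.default_rng(7)
        scores = []
        y = np.tile([0, 1], 20)  # balanced in both splits
        for _ in range(30):
            X = rng.standard_normal((40, 5))
            clf = fit_lda(X[:30], y[:30])
            scores.append(balanced_accuracy(y[30:], clf.predict(X[30:])))
        assert np.mean(scores) == pytest.approx(0.5, abs=0.06)

    def test_zero_shrinkage_matches_closed_form_oracle(self):
        # 6-point, well-conditioned toy set: w = Sigma^-1 (mu1 - mu0)
        X = np.array(
            [[0.0, 0.0], [1.0, 0.2], [0.2, 1.0],
             [3.0, 3.0], [4.0, 3.2], [3.2, 4.0]]
        )
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = fit_lda(X, y, shrinkage=0.0)
        mu0, mu1 = X[:3].mean(0), X[3:].mean(0)
        pooled = ((X[:3] - mu0).T @ (X[:3] - mu0) + (X[3:] - mu1).T @ (X[3:] - mu1)) / 6
        w = np.linalg.solve(pooled, mu1 - mu0)
        b = -0.5 * (mu1 + mu0) @ w + np.log(0.5 / 0.5)
        oracle = X @ w + b
        ours = clf.decision_function(X)
        np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_singleton_class_still_fits(self):
        X = np.array([[0.0, 0.0], [0.1, 0.1], [5.0, 5.0]])
        y = np.array([0, 0, 1])
        clf = fit_lda(X, y)  # shrinkage keeps covariance invertible
        assert set(clf.predict(X)) <= {0, 1}


class TestBalancedAccuracy:
    def test_perfect_prediction(self):
        assert balanced_accuracy([1, 2, 3], [1, 2, 3]) == 1.0

    def test_confusion_count_example(self):
        assert balanced_accuracy([0, 0, 1, 1], [0, 1, 1, 1]) == 0.75

    def test_constant_prediction_on_balanced_classes(self):
        y = np.repeat(np.arange(4), 5)
        assert balanced_accuracy(y, np.zeros_like(y)) == 0.25

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_matches_sklearn_on_random_confusions(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 4, 30)
        y_pred = rng.integers(0, 5, 30)  # may predict an unseen class
        if len(np.unique(y_true)) < 1:
            return
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(
            balanced_accuracy_score(y_true, y_pred)
        )

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_equals_plain_accuracy_for_balanced_classes(self, seed):
        rng = np.random.default_rng(seed)
        y_true = np.repeat(np.arange(3), 8)
        y_pred = rng.integers(0, 3, 24)
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(
            np.mean(y_true == y_pred)
        )


@pytest.fixture(scope="module")
def effect_epochs(small_design, small_plan):
    """One subject with a strong four-class orientation effect at 100 ms."""
    eff = sim.EffectSpec(
        "orientation", onset=0.10, duration=0.15, amplitude=8.0, seed=2
    )
    return sim.simulate_subject(
        small_design, small_plan, effects=[eff],
        noise=sim.NoiseSpec(1.0, 1.0), seed=13,
        sampling_rate=256.0, n_channels=16,
    )


class TestTimeResolvedDecoding:
    def test_injected_effect_decodes_after_onset_only(
        self, effect_epochs, small_design
    ):
        labels = td.trial_labels(effect_epochs, small_design, "orientation")
        res = decode_time_categorical(effect_epochs, labels)
        assert res.chance == 0.25
        pre = res.axis < 0.05
        during = (res.axis >= 0.14) & (res.axis <= 0.22)
        assert abs(res.fold_mean[pre].mean() - 0.25) < 0.1
        assert res.fold_mean[during].mean() > 0.6

    def test_permuted_labels_score_at_chance(self, effect_epochs, small_design):
        labels = td.trial_labels(effect_epochs, small_design, "orientation")
        nt = ~effect_epochs.trials["is_target"].to_numpy()
        rng = np.random.default_rng(0)
        perm = labels.copy()
        perm[nt] = rng.permutation(perm[nt])
        res = decode_time_categorical(effect_epochs, perm)
        assert abs(res.fold_mean.mean() - 0.25) < 0.08

    def test_continuous_effect_recovered_at_latency(
        self, small_design, small_plan
    ):
        eff = sim.EffectSpec(
            "arousal", kind="continuous-amplitude", onset=0.10,
            duration=0.15, amplitude=5.0, seed=2,
        )
        ep = sim.simulate_subject(
            small_design, small_plan, effects=[eff],
            noise=sim.NoiseSpec(1.0, 1.0), seed=6,
            sampling_rate=256.0, n_channels=16,
        )
        ratings = td.trial_labels(ep, small_design, "arousal")
        res = decode_time_continuous(ep, ratings)
        assert res.chance == 0.0
        peak_window = (res.axis >= 0.14) & (res.axis <= 0.22)
        assert res.fold_mean[peak_window].max() > 0.5

    def test_targets_are_excluded_from_folds(self, effect_epochs, small_design):
        labels = td.trial_labels(effect_epochs, small_design, "orientation")
        res = decode_time_categorical(effect_epochs, labels)
        n_nt = int((~effect_epochs.trials["is_target"]).sum())
        total_test = sum(
            1
            for _ in range(res.per_fold.shape[0])
        )
        assert total_test == effect_epochs.trials["sequence_index"].nunique()
        assert res.meta["n_classes"] == 4
        assert n_nt == 32

    def test_residualizing_the_coding_confound_abolishes_decoding(
        self, small_design, small_plan
    ):
        # Confound == the rating that drives the amplitude coding: once it
        # is regressed out per fold, the ridge decoder finds nothing.
        eff = sim.EffectSpec(
            "arousal", kind="continuous-amplitude", onset=0.10,
            duration=0.15, amplitude=5.0, seed=2,
        )
        ep = sim.simulate_subject(
            small_design, small_plan, effects=[eff],
            noise=sim.NoiseSpec(1.0, 1.0), seed=6,
            sampling_rate=256.0, n_channels=16,
        )
        ratings = td.trial_labels(ep, small_design, "arousal")
        nt = ~ep.trials["is_target"].to_numpy()
        conf = ratings.astype(float)[nt, None]
        raw = decode_time_continuous(ep, ratings)
        res = decode_time_continuous(ep, ratings, confounds=conf)
        peak_window = (res.axis >= 0.14) & (res.axis <= 0.22)
        assert raw.fold_mean[peak_window].max() > 0.5
        assert res.fold_mean[peak_window].mean() < 0.2
        assert (
            res.fold_mean[peak_window].max()
            < 0.5 * raw.fold_mean[peak_window].max()
        )
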