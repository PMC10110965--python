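"""Decoding: standardization, logistic fit, AUC, CV timecourse, pooling, ROI."""

import numpy as np
import pytest

from conftest import make_synthetic_epochs
from vseeg.decoding import (ROILabeling, auc, decode_timecourse, fit_logistic,
                            make_folds, pool, standardize_apply,
                            standardize_fit, subset_roi)


def pairwise_auc_oracle(values, labels):
    """Exhaustive pairwise counting, ties counted 1/2."""
    v = np.asarray(values, float)
    pos = v[np.asarray(labels) == 1]
    neg = v[np.asarray(labels) == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestStandardize:
    def test_train_columns_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5.0, 3.0, size=(40, 6))
        params = standardize_fit(X)
        Z = standardize_apply(params, X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(Z.var(axis=0), 1.0, atol=1e-9)

    def test_train_params_leave_test_means_nonzero(self):
        rng = np.random.default_rng(1)
        params = standardize_fit(rng.normal(size=(30, 4)))
        Z = standardize_apply(params, rng.normal(2.0, 1.0, size=(30, 4)))
        assert np.abs(Z.mean(axis=0)).min() > 0.1

    def test_constant_column_flagged_and_dropped(self):
        X = np.random.default_rng(2).normal(size=(20, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning):
            params = standardize_fit(X)
        assert not params.keep[1]
        assert standardize_apply(params, X).shape == (20, 2)


class TestLogistic:
    def test_separable_1d_weight_sign(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        dec = fit_logistic(X, y, l2=0.5)
        assert dec.weights[0] > 0

    def test_all_zero_features_give_base_rate_intercept(self):
        y = np.array([1, 1, 1, 0])
        dec = fit_logistic(np.zeros((4, 3)), y, l2=1.0)
        np.testing.assert_allclose(dec.weights, 0.0, atol=1e-6)
        assert abs(dec.intercept - np.log(3.0)) < 1e-6

    def test_matches_slow_gradient_descent_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 5))
        y = (rng.random(20) > 0.5).astype(int)
        l2 = 1.0
        dec = fit_logistic(X, y, l2=l2, tol=1e-12, max_iter=5000)

        def loss(w, b):
            z = (2.0 * y - 1.0) * (X @ w + b)
            return np.sum(np.logaddexp(0, -z)) + 0.5 * l2 * (w @ w)

        # independent plain gradient descent
        w, b = np.zeros(5), 0.0
        lr = 0.01
        for _ in range(200_000):
            s = 2.0 * y - 1.0
            g = -s / (1.0 + np.exp(s * (X @ w + b)))
            gw = X.T @ g + l2 * w
            gb = g.sum()
            w -= lr * gw
            b -= lr * gb
        assert abs(loss(dec.weights, dec.intercept) - loss(w, b)) < 1e-6

    def test_matches_sklearn_reference(self):
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 4))
        y = (X[:, 0] + 0.5 * rng.standard_normal(60) > 0).astype(int)
        dec = fit_logistic(X, y, l2=1.0, tol=1e-12, max_iter=5000)
        ref = LogisticRegression(C=1.0, tol=1e-12, max_iter=5000).fit(X, y)
        np.testing.assert_allclose(dec.weights, ref.coef_[0], atol=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((4, 2)), np.ones(4))


class TestAUC:
    def test_hand_computed_example(self):
        v = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        y = [1, 1, 1, 0, 0, 0]
        assert abs(auc(np.array(v), np.array(y)) - 8.0 / 9.0) < 1e-12

    def test_perfect_separation_and_ties(self):
        assert auc(np.array([3.0, 2.0, 1.0, 0.0]), np.array([1, 1, 0, 0])) == 1.0
        assert auc(np.ones(6), np.array([1, 1, 1, 0, 0, 0])) == 0.5

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(4, 30)
            v = rng.integers(0, 6, size=n).astype(float)   # heavy ties
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if y.min() == y.max():
                continue
            assert abs(auc(v, y) - pairwise_auc_oracle(v, y)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.arange(4.0), np.ones(4))


class TestFolds:
    def test_partition_and_class_coverage(self):
        labels = np.array(["OLD"] * 50 + ["NEW"] * 50, dtype=object)
        folds = make_folds(labels, n_folds=20, seed=0)
        assert np.bincount(folds.fold_of_trial).sum() == 100
        for train, test in folds.split():
            assert len(np.intersect1d(train, test)) == 0
            assert {"OLD", "NEW"} == set(labels[test])

    def test_reproducible_with_seed(self):
        labels = np.array(["OLD", "NEW"] * 30, dtype=object)
        a = make_folds(labels, 10, seed=3)
        b = make_folds(labels, 10, seed=3)
        assert np.array_equal(a.fold_of_trial, b.fold_of_trial)

    def test_too_few_trials_suggests_fewer_folds(self):
        labels = np.array(["OLD"] * 5 + ["NEW"] * 5, dtype=object)
        with pytest.raises(ValueError, match="n_folds"):
            make_folds(labels, 20, seed=0)


class TestTimecourse:
    def test_output_shape_and_determinism(self):
        ep = make_synthetic_epochs(n_trials=60, n_channels=4, n_samples=12,
                                   seed=0)
        a = decode_timecourse(ep, n_folds=5, seed=1)
        b = decode_timecourse(ep, n_folds=5, seed=1)
        assert a.scores.shape == (5, 12)
        assert np.array_equal(a.scores, b.scores)

    def test_null_data_scores_near_chance(self):
        """Zero class effect, 200 trials: time-mean fold-mean AUC in
        [0.45, 0.55] and every timepoint within the same band."""
        ep = make_synthetic_epochs(n_trials=200, n_channels=8, n_samples=10,
                                   effect_size=0.0, seed=1)
        sc = decode_timecourse(ep, n_folds=10, seed=2)
        assert 0.45 <= sc.fold_mean().mean() <= 0.55
        # individual timepoints fluctuate with ~0.05 SD under the null;
        # only gross departures would indicate leakage
        assert np.all((sc.fold_mean() > 0.3) & (sc.fold_mean() < 0.7))

    def test_confined_effect_recovered(self):
        ep = make_synthetic_epochs(n_trials=400, n_channels=8, n_samples=30,
                                   effect_window=(10, 20), effect_size=3.0,
                                   seed=2)
        sc = decode_timecourse(ep, n_folds=20, seed=3)
        mean = sc.fold_mean()
        assert np.all(mean[10:20] > 0.9)
        outside = np.r_[mean[:10], mean[20:]]
        assert np.all((outside > 0.4) & (outside < 0.6))

    def test_too_few_trials_rejected(self):
        ep = make_synthetic_epochs(n_trials=20, n_channels=3, n_samples=5)
        with pytest.raises(ValueError):
            decode_timecourse(ep, n_folds=20)


class TestPool:
    def test_channel_counts_add(self):
        a = make_synthetic_epochs(n_trials=40, n_channels=5, seed=0)
        b = make_synthetic_epochs(n_trials=40, n_channels=3, seed=0)
        b.data = b.data * 50.0         # different physical scale
        b.space = "seeg-bipolar"
        out = pool([a, b])
        assert out.n_channels == 8 and out.space == "pooled"

    def test_pooled_tracks_best_modality(self):
        """Adding a pure-noise modality to an informative one costs at most
        0.03 of effect-window AUC."""
        good = make_synthetic_epochs(n_trials=400, n_channels=6, n_samples=8,
                                     effect_window=(2, 6), effect_size=2.5,
                                     seed=4)
        noise = make_synthetic_epochs(n_trials=400, n_channels=6, n_samples=8,
                                      effect_size=0.0, seed=5)
        noise.labels = good.labels.copy()     # same trials, no signal
        noise.space = "seeg-bipolar"
        sc_good = decode_timecourse(good, n_folds=10, seed=6)
        sc_pool = decode_timecourse(pool([good, noise]), n_folds=10, seed=6)
        win = slice(2, 6)
        assert sc_pool.fold_mean()[win].mean() >= \
            sc_good.fold_mean()[win].mean() - 0.03

    def test_mismatched_trials_rejected(self):
        a = make_synthetic_epochs(n_trials=40)
        b = make_synthetic_epochs(n_trials=42)
        with pytest.raises(ValueError):
            pool([a, b])


class TestROI:
    def test_subset_channels_and_partition(self):
        ep = make_synthetic_epochs(n_trials=30, n_channels=6)
        roi = ROILabeling({"ch00": "Hc", "ch01": "Hc", "ch02": "ACC",
                           "ch03": "ACC", "ch04": "F"})
        sub = subset_roi(ep, roi, "Hc")
        assert sub.channel_ids == ["ch00", "ch01"]
        assert sub.space == "roi:Hc"
        covered = set()
        for label in ("Hc", "ACC", "F"):
            covered |= set(subset_roi(ep, roi, label).channel_ids)
        unlabeled = set(ep.channel_ids) - set(roi.labels)
        assert covered | unlabeled == set(ep.channel_ids)

    def test_source_roi_beats_source_free_roi(self):
        ep = make_synthetic_epochs(n_trials=300, n_channels=8, n_samples=8,
                                   effect_channels=[0, 1, 2],
                                   effect_window=(2, 6), effect_size=2.0,
                                   seed=7)
        roi = ROILabeling({"ch00": "Hc", "ch01": "Hc", "ch02": "Hc",
                           "ch05": "F", "ch06": "F", "ch07": "F"})
        win = slice(2, 6)
        sc_hc = decode_timecourse(subset_roi(ep, roi, "Hc"), 10, seed=8)
        sc_f = decode_timecourse(subset_roi(ep, roi, "F"), 10, seed=8)
        assert sc_hc.fold_mean()[win].mean() - sc_f.fold_mean()[win].mean() > 0.1

    def test_empty_selection_and_unknown_label(self):
        ep = make_synthetic_epochs(n_trials=30, n_channels=4)
        roi = ROILabeling({"ch00": "Hc"})
        with pytest.raises(ValueError):
            subset_roi(ep, roi, "ACC")
        with pytest.raises(ValueError):
            subset_roi(ep, roi, "NotARegion")


class TestAffineInvariance:
    def test_unregularized_auc_invariant_to_invertible_mixing(self):
        """Per-timepoint fold AUCs agree to 1e-3 between X and X A' for a
        random invertible A when the decoder is unregularized."""
        ep = make_synthetic_epochs(n_trials=160, n_channels=6, n_samples=4,
                                   effect_window=(0, 4), effect_size=1.2,
                                   seed=9)
        rng = np.random.default_rng(10)
        A = rng.standard_normal((6, 6)) + 0.5 * np.eye(6)
        assert np.linalg.cond(A) < 1e3
        ep_mix = make_synthetic_epochs(n_trials=160, n_channels=6, n_samples=4,
                                       effect_window=(0, 4), effect_size=1.2,
                                       seed=9)
        ep_mix.data = np.einsum("dc,tcs->tds", A, ep.data)
        kw = dict(n_folds=8, l2=0.0, seed=11, tol=1e-12, max_iter=20000)
        sc = decode_timecourse(ep, **kw)
        sc_mix = decode_timecourse(ep_mix, **kw)
        assert np.abs(sc.scores - sc_mix.scores).max() < 1e-3
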