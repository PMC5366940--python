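import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import methylsex as mx
from methylsex import plr
from methylsex.errors import ConfigurationError, DataError

from _oracles import enumerate_best_cluster, greedy_reachable, plr_instance


class TestStandardize:
    def test_location_invariance(self, signal_matrix):
        shifted = signal_matrix.values * 1.0
        col = shifted.columns[0]
        a, _, _ = plr.standardize(signal_matrix.values)
        shifted[col] = shifted[col] + 0.1  # may leave [0,1]; fine for the test
        b, _, _ = plr.standardize(shifted)
        np.testing.assert_allclose(a[col], b[col], atol=1e-12)

    def test_training_columns_centered_scaled(self, signal_matrix):
        std, means, sds = plr.standardize(signal_matrix.values)
        assert np.allclose(std.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(std.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_test_samples_use_training_parameters(self, signal_matrix):
        values = signal_matrix.values
        train = values.index[:10]
        std, means, sds = plr.standardize(values, training_ids=train)
        # held-out rows standardized by the training mean, not their own
        held = values.index[10:]
        expect = (values.loc[held] - means) / sds
        pd.testing.assert_frame_equal(std.loc[held], expect)

    def test_zero_variance_feature_dropped(self, signal_matrix):
        values = signal_matrix.values.copy()
        values[values.columns[3]] = 0.5
        with pytest.warns(UserWarning, match="zero-variance"):
            std, _, _ = plr.standardize(values)
        assert values.columns[3] not in std.columns


class TestRidgeLogistic:
    def test_gradient_at_optimum_small(self):
        X, y = plr_instance(n=30, p=4, seed=1)
        design = np.column_stack([np.ones(30), X[:, :2]])
        _, _, gmax, converged = plr.ridge_logistic_fit(design, y, 1 / 32)
        assert converged and gmax < 1e-6

    def test_large_lambda_limit(self):
        X, y = plr_instance(n=30, p=3, seed=2)
        design = np.column_stack([np.ones(30), X])
        beta, _, _, _ = plr.ridge_logistic_fit(design, y, 1e6)
        assert np.all(np.abs(beta[1:]) < 1e-3)
        assert beta[0] == pytest.approx(logit(y.mean()), abs=1e-3)

    def test_separable_data_stays_finite_and_beats_null(self):
        y = np.repeat([0.0, 1.0], 10)
        z = np.repeat([-1.0, 1.0], 10)
        design = np.column_stack([np.ones(20), z])
        beta, crit, _, conv = plr.ridge_logistic_fit(design, y, 1 / 32)
        assert conv and np.isfinite(beta).all()
        _, crit_null, _, _ = plr.ridge_logistic_fit(np.ones((20, 1)), y, 1 / 32)
        assert crit < crit_null

    def test_beats_random_search(self):
        rng = np.random.default_rng(3)
        X, y = plr_instance(n=30, p=2, seed=3)
        design = np.column_stack([np.ones(30), X])
        beta, crit, _, _ = plr.ridge_logistic_fit(design, y, 1 / 32)
        pen = np.array([0.0, 1.0, 1.0])
        for _ in range(1000):
            b = rng.normal(0, 2, size=3)
            eta = design @ b
            c = float(
                np.sum(np.logaddexp(0, eta) - y * eta) + (1 / 32) * np.sum(pen * b**2)
            )
            assert crit <= c + 1e-12


class TestGrowCluster:
    def test_perfect_feature_selected_first(self):
        rng = np.random.default_rng(4)
        n = 24
        y = np.repeat([0.0, 1.0], n // 2)
        X = rng.normal(size=(n, 10))
        X[:, 7] = np.where(y == 1, 1.0, -1.0) + rng.normal(0, 0.05, n)
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        _, crit0, _, _ = plr.ridge_logistic_fit(np.ones((n, 1)), y, 1 / 32)
        members, _, _ = plr.grow_cluster(
            X, y, np.empty((n, 0)), crit0, plr.PLRConfig()
        )
        assert members[0][0] == 7

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        """On greedy-reachable instances the first cluster attains the
        enumerated optimum (p=6, n=20); unreachable instances (where no
        forward path leads to the optimum) are excluded by the oracle."""
        X, y = plr_instance(n=20, p=6, seed=seed)
        lam = 1 / 32
        if not greedy_reachable(X, y, lam, max_size=3):
            pytest.skip("enumerated optimum not forward-reachable")
        config = plr.PLRConfig(lam=lam, max_cluster_size=3)
        _, crit0, _, _ = plr.ridge_logistic_fit(np.ones((20, 1)), y, lam)
        members, crit, _ = plr.grow_cluster(
            X, y, np.empty((20, 0)), crit0, config
        )
        best_crit, best_members = enumerate_best_cluster(X, y, lam, max_size=3)
        assert crit - best_crit <= 1e-9

    def test_duplicate_of_singleton_member_is_a_tie_and_rejected(self):
        X, y = plr_instance(n=20, p=1, delta=2.0, seed=9)
        X = np.column_stack([X, X[:, 0]])  # feature 1 duplicates feature 0
        _, crit0, _, _ = plr.ridge_logistic_fit(np.ones((20, 1)), y, 1 / 32)
        members, _, _ = plr.grow_cluster(
            X, y, np.empty((20, 0)), crit0, plr.PLRConfig()
        )
        # adding the duplicate leaves the centroid unchanged: a tie, not
        # a strict improvement, so the cluster stays a singleton
        assert members == [(0, 1)]


class TestFit:
    def test_q1_yields_single_cluster(self, signal_matrix):
        model = plr.fit(signal_matrix, config=plr.PLRConfig(n_clusters=1))
        assert model.n_clusters == 1

    def test_criterion_not_above_null_model(self, signal_matrix):
        rng = np.random.default_rng(0)
        noise = signal_matrix.values.copy()
        noise[:] = rng.uniform(size=noise.shape)
        m = mx.FeatureMatrix(noise, signal_matrix.sex, signal_matrix.tiles)
        model = plr.fit(m, config=plr.PLRConfig(n_clusters=3))
        y = (signal_matrix.sex == model.classes[1]).to_numpy(float)
        _, crit_null, _, _ = plr.ridge_logistic_fit(np.ones((len(y), 1)), y, 1 / 32)
        assert model.criterion <= crit_null + 1e-12

    def test_planted_feature_in_first_cluster(self, signal_matrix):
        model = plr.fit(signal_matrix)
        planted = signal_matrix.values.columns[0]
        assert planted in [fid for fid, _ in model.clusters[0]]

    def test_single_class_is_configuration_error(self, signal_matrix):
        m = mx.FeatureMatrix(
            signal_matrix.values,
            pd.Series("F", index=signal_matrix.values.index),
            signal_matrix.tiles,
        )
        with pytest.raises(ConfigurationError):
            plr.fit(m)

    def test_deterministic(self, signal_matrix):
        a = plr.fit(signal_matrix)
        b = plr.fit(signal_matrix)
        assert a.clusters == b.clusters
        np.testing.assert_array_equal(a.coef, b.coef)

    def test_sign_flip_of_input_leaves_probabilities_unchanged(self, signal_matrix):
        model_a = plr.fit(signal_matrix)
        flipped = signal_matrix.values.copy()
        col = flipped.columns[0]
        flipped[col] = 1.0 - flipped[col]  # reflect within [0,1]
        m = mx.FeatureMatrix(flipped, signal_matrix.sex, signal_matrix.tiles)
        model_b = plr.fit(m)
        pa = plr.predict(model_a, signal_matrix)["probability"]
        pb = plr.predict(model_b, m)["probability"]
        np.testing.assert_allclose(pa, pb, atol=1e-6)


class TestPredictProject:
    def test_training_predictions_consistent(self, signal_matrix):
        model = plr.fit(signal_matrix)
        pred = plr.predict(model, signal_matrix)
        assert (pred["predicted"] == signal_matrix.sex).all()

    def test_missing_model_feature_raises(self, signal_matrix):
        model = plr.fit(signal_matrix)
        used = model.selected_features()[0]
        reduced = signal_matrix.values.drop(columns=[used])
        with pytest.raises(DataError, match=used.split(":")[0]):
            plr.predict(model, reduced)

    def test_probability_monotone_in_centroid(self, signal_matrix):
        model = plr.fit(signal_matrix, config=plr.PLRConfig(n_clusters=1))
        cents = plr.project_centroids(model, signal_matrix)["predictor_1"]
        prob = plr.predict(model, signal_matrix)["probability"]
        order = np.argsort(cents.to_numpy())
        diffs = np.diff(prob.to_numpy()[order]) * np.sign(model.coef[1])
        assert (diffs >= -1e-12).all()

    def test_single_cluster_second_coordinate_zero(self, signal_matrix):
        model = plr.fit(signal_matrix, config=plr.PLRConfig(n_clusters=1))
        proj = plr.project_centroids(model, signal_matrix)
        assert (proj["predictor_2"] == 0).all()

    def test_projection_invariant_to_unused_features(self, signal_matrix):
        model = plr.fit(signal_matrix)
        proj_a = plr.project_centroids(model, signal_matrix)
        extended = signal_matrix.values.copy()
        extended["chr9:0-500"] = 0.25
        proj_b = plr.project_centroids(model, extended)
        pd.testing.assert_frame_equal(proj_a, proj_b)

    def test_classes_separate_along_predictor_one(self, signal_matrix):
        model = plr.fit(signal_matrix)
        proj = plr.project_centroids(model, signal_matrix)
        c1 = proj["predictor_1"]
        f, m = c1[signal_matrix.sex == "F"], c1[signal_matrix.sex == "M"]
        pooled_sd = np.sqrt((f.var(ddof=1) + m.var(ddof=1)) / 2)
        assert abs(m.mean() - f.mean()) > 2 * pooled_sd

    def test_json_round_trip(self, signal_matrix):
        model = plr.fit(signal_matrix)
        back = plr.FittedPLR.from_json(model.to_json())
        assert back.clusters == model.clusters
        np.testing.assert_allclose(back.coef, model.coef)
        pred_a = plr.predict(model, signal_matrix)["probability"]
        pred_b = plr.predict(back, signal_matrix)["probability"]
        np.testing.assert_allclose(pred_a, pred_b, atol=1e-12)
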