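import json

import numpy as np
import pytest

from grainray import trait_models as tm
from grainray.phantom import HRR_CLASS_VALUES


def identity_model(theta=17.0):
    return tm.ChaffyClusterModel(
        mean_pc=np.zeros(3), covariance_pc=np.eye(3), theta_chaffy=theta
    )


class TestMahalanobis:
    def test_euclidean_under_identity(self):
        assert tm.mahalanobis_distance(np.array([3.0, 4.0, 0.0]),
                                       identity_model()) == pytest.approx(5.0)

    def test_diagonal_scaling(self):
        model = tm.ChaffyClusterModel(np.zeros(3), np.diag([4.0, 1.0, 1.0]))
        assert tm.mahalanobis_distance(np.array([2.0, 0.0, 0.0]),
                                       model) == pytest.approx(1.0)

    def test_random_spd_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            cov = A @ A.T + 0.5 * np.eye(3)
            mean = rng.normal(size=3)
            model = tm.ChaffyClusterModel(mean, cov)
            inv = np.linalg.inv(cov)
            for _ in range(5):
                x = rng.normal(size=3)
                expected = np.sqrt((x - mean) @ inv @ (x - mean))
                assert tm.mahalanobis_distance(x, model) == pytest.approx(
                    expected, abs=1e-9
                )

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            tm.ChaffyClusterModel(np.zeros(3), np.zeros((3, 3)))


class TestClassifyChaffy:
    def test_below_threshold_non_chaffy(self):
        flags, dists = tm.classify_chaffy(np.array([[16.99, 0, 0]]), identity_model())
        assert dists[0] == pytest.approx(16.99)
        assert not flags[0]

    def test_exactly_threshold_non_chaffy(self):
        flags, _ = tm.classify_chaffy(np.array([[17.0, 0.0, 0.0]]), identity_model())
        assert not flags[0]

    def test_above_threshold_chaffy(self):
        flags, _ = tm.classify_chaffy(np.array([[17.001, 0.0, 0.0]]), identity_model())
        assert flags[0]

    def test_monotone_threshold_response(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=10, size=(200, 3))
        counts = []
        for theta in (5.0, 10.0, 17.0, 25.0):
            flags, _ = tm.classify_chaffy(coords, identity_model(theta))
            counts.append(int(flags.sum()))
        assert counts == sorted(counts, reverse=True)

    def test_well_separated_clusters(self, chaffy_training):
        from grainray.embedding import project, subset_columns
        analysis, (scaler, pca, model) = chaffy_training
        coords = project(scaler, pca, subset_columns(analysis.features, "chaffiness"))
        flags, _ = tm.classify_chaffy(coords, model)
        truth = np.array([g.chaffy for g in analysis.truth])
        assert np.mean(flags == truth) >= 0.99


class TestFitChaffyCluster:
    def test_recovers_sample_moments(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3)) @ np.diag([2.0, 1.0, 0.5]) + [1.0, -1.0, 0.0]
        model = tm.fit_chaffy_cluster(X)
        assert np.allclose(model.mean_pc, X.mean(axis=0))
        assert np.allclose(model.covariance_pc, np.cov(X, rowvar=False))
        assert model.theta_chaffy == 17.0

    def test_degenerate_gets_ridge(self):
        X = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.warns(UserWarning, match="ridge"):
            model = tm.fit_chaffy_cluster(X)
        assert np.isfinite(model.condition_number)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        a = tm.fit_chaffy_cluster(X)
        b = tm.fit_chaffy_cluster(X[rng.permutation(30)])
        assert np.allclose(a.mean_pc, b.mean_pc)
        assert np.allclose(a.covariance_pc, b.covariance_pc)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            tm.fit_chaffy_cluster(np.ones((3, 3)))


class TestVirtualDehusk:
    def test_equal_means_identity(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        out = tm.virtual_dehusk(x, np.ones(4), np.ones(4))
        assert np.array_equal(out, x)

    def test_direct_substitution(self):
        out = tm.virtual_dehusk(np.array([10.0]), np.array([4.0]), np.array([7.0]))
        assert out[0] == pytest.approx(13.0)

    def test_shifted_population_mean_matches_target(self):
        rng = np.random.default_rng(8)
        grains = rng.normal(5.0, 2.0, size=(200, 4))
        kernels = rng.normal(3.0, 1.0, size=(150, 4))
        shifted = tm.virtual_dehusk(grains, grains.mean(axis=0), kernels.mean(axis=0))
        assert np.max(np.abs(shifted.mean(axis=0) - kernels.mean(axis=0))) < 1e-12


class TestChalkyHyperplane:
    def test_symmetric_1d_boundary_at_zero(self):
        X = np.array([[-1.0, 0, 0]] * 10 + [[1.0, 0, 0]] * 10)
        y = [False] * 10 + [True] * 10
        model = tm.fit_chalky_hyperplane(X, y)
        # decision boundary: normal . x + offset = 0 at x = 0
        boundary = -model.offset / model.normal_pc[0]
        assert boundary == pytest.approx(0.0, abs=1e-6)

    def test_separable_training_is_perfect(self):
        rng = np.random.default_rng(11)
        neg = rng.normal([-3, 0, 0], 0.3, size=(40, 3))
        pos = rng.normal([3, 0, 0], 0.3, size=(40, 3))
        X = np.vstack([neg, pos])
        y = [False] * 40 + [True] * 40
        model = tm.fit_chalky_hyperplane(X, y)
        pred = model.decision_values(X) > 0
        assert np.array_equal(pred, np.array(y))

    def test_duplicated_set_same_plane(self):
        # invariance holds for separable data, where the max-margin plane is
        # unique and unaffected by the per-point penalty rescaling
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 3))
        X[:, 0] = np.where(X[:, 0] > 0, X[:, 0] + 1.5, X[:, 0] - 1.5)
        y = X[:, 0] > 0
        a = tm.fit_chalky_hyperplane(X, y)
        b = tm.fit_chalky_hyperplane(np.vstack([X, X]), np.concatenate([y, y]))
        assert np.allclose(a.normal_pc, b.normal_pc, atol=1e-6)
        assert a.offset == pytest.approx(b.offset, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tm.fit_chalky_hyperplane(np.ones((5, 3)), [True] * 5)


class TestClassifyChalky:
    @pytest.fixture()
    def trivial_embedding(self):
        from grainray.embedding import PCAModel, Scaler
        names = ("f2", "f3", "f4", "f6")
        scaler = Scaler(names, np.zeros(4), np.ones(4))
        pca = PCAModel(names, np.eye(3, 4), np.zeros(4), np.array([0.5, 0.3, 0.2]))
        return scaler, pca

    def test_ratio_definition(self, trivial_embedding):
        scaler, pca = trivial_embedding
        model = tm.HyperplaneModel(np.array([1.0, 0, 0]), 0.0, np.zeros(4))
        X = np.zeros((12, 4))
        X[:3, 0] = 5.0            # 3 of 12 on the positive side
        X[3:, 0] = -5.0
        flags, crk = tm.classify_chalky(X, model, scaler, pca, dehusk=False)
        assert flags.sum() == 3
        assert crk == pytest.approx(25.0)

    def test_boundary_value_non_chalky(self, trivial_embedding):
        scaler, pca = trivial_embedding
        model = tm.HyperplaneModel(np.array([1.0, 0, 0]), 0.0, np.zeros(4))
        flags, _ = tm.classify_chalky(np.zeros((1, 4)), model, scaler, pca,
                                      dehusk=False)
        assert not flags[0]

    def test_permutation_invariant_crk(self, trivial_embedding):
        scaler, pca = trivial_embedding
        model = tm.HyperplaneModel(np.array([1.0, 0, 0]), 0.0, np.zeros(4))
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        _, crk1 = tm.classify_chalky(X, model, scaler, pca, dehusk=False)
        _, crk2 = tm.classify_chalky(X[rng.permutation(40)], model, scaler, pca,
                                     dehusk=False)
        assert crk1 == crk2


class TestHRR:
    def test_paper_worked_example(self):
        probs = [0.21, 0.18, 0.66, 0.75, 0.35]
        cls, reliability = tm.predict_grain_hrr(probs)
        assert cls == 40
        assert reliability == pytest.approx(75.0)

    def test_certain_first_class(self):
        cls, reliability = tm.predict_grain_hrr([1.0, 0, 0, 0, 0])
        assert cls == 100 and reliability == 100.0

    def test_tie_takes_lowest_class(self):
        cls, reliability = tm.predict_grain_hrr([0.4] * 5)
        assert cls == 20
        assert reliability == pytest.approx(40.0)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            tm.predict_grain_hrr([1.5, 0, 0, 0, 0])

    def test_two_class_separation(self):
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal([-4, 0, 0], 0.5, size=(60, 3)),
                       rng.normal([4, 0, 0], 0.5, size=(60, 3))])
        y = [100] * 60 + [20] * 60
        model = tm.fit_hrr_model(X[::2], np.asarray(y)[::2])
        probs = tm.predict_hrr_probabilities(X[1::2], model)
        pred = [tm.predict_grain_hrr(p)[0] for p in probs]
        assert np.mean(np.array(pred) == np.asarray(y)[1::2]) >= 0.95

    def test_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(40, 3))
        y = [100 if x > 0 else 20 for x in X[:, 0]]
        model = tm.fit_hrr_model(X, y)
        probs = tm.predict_hrr_probabilities(rng.normal(size=(10, 3)) * 100, model)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_label_order_invariance(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 0] > 0, 80, 40)
        perm = rng.permutation(60)
        a = tm.fit_hrr_model(X, y)
        b = tm.fit_hrr_model(X[perm], y[perm])
        pa = tm.predict_hrr_probabilities(X, a)
        pb = tm.predict_hrr_probabilities(X, b)
        assert np.allclose(pa, pb, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tm.fit_hrr_model(np.ones((5, 3)), [100] * 5)


class TestAggregateHRR:
    def test_mean_of_classes(self):
        assert tm.aggregate_sample_hrr([40, 60, 60, 80]) == pytest.approx(60.0)

    def test_all_lowest(self):
        assert tm.aggregate_sample_hrr([20, 20, 20]) == 20.0

    def test_uniform_mix(self):
        assert tm.aggregate_sample_hrr(list(HRR_CLASS_VALUES)) == pytest.approx(60.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tm.aggregate_sample_hrr([])


class TestHRRGroundTruth:
    def test_direct_substitution(self):
        assert tm.hrr_ground_truth(15.0, 20.0) == pytest.approx(75.0)

    def test_zero_polished(self):
        assert tm.hrr_ground_truth(0.0, 20.0) == 0.0

    def test_full_recovery(self):
        assert tm.hrr_ground_truth(20.0, 20.0) == 100.0

    @pytest.mark.parametrize("w_pg,w_op", [(1.0, 0.0), (-1.0, 5.0), (6.0, 5.0)])
    def test_invalid_weights(self, w_pg, w_op):
        with pytest.raises(ValueError):
            tm.hrr_ground_truth(w_pg, w_op)


class TestEvaluate:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        r2, rmse, slope, intercept = tm.evaluate(obs, obs)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_alternating_unit_residuals(self):
        obs = np.array([10.0, 20.0, 30.0, 40.0])
        pred = obs + np.array([1.0, -1.0, 1.0, -1.0])
        _, rmse, _, _ = tm.evaluate(pred, obs)
        assert rmse == pytest.approx(1.0)

    def test_closed_form_ols_oracle(self):
        obs = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        pred = np.array([2.1, 2.9, 6.2, 6.8, 10.1])
        n = len(obs)
        sx, sy = obs.sum(), pred.sum()
        sxx, sxy = (obs * obs).sum(), (obs * pred).sum()
        slope_o = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept_o = (sy - slope_o * sx) / n
        resid = pred - (slope_o * obs + intercept_o)
        r2_o = 1 - resid @ resid / ((pred - pred.mean()) @ (pred - pred.mean()))
        r2, rmse, slope, intercept = tm.evaluate(pred, obs)
        assert slope == pytest.approx(slope_o, abs=1e-9)
        assert intercept == pytest.approx(intercept_o, abs=1e-9)
        assert r2 == pytest.approx(r2_o, abs=1e-9)
        assert rmse == pytest.approx(np.sqrt(np.mean((pred - obs) ** 2)), abs=1e-12)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            tm.evaluate(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestSerialization:
    def test_round_trip_all_models(self, tmp_path):
        rng = np.random.default_rng(31)
        chaffy = tm.fit_chaffy_cluster(rng.normal(size=(30, 3)))
        X = rng.normal(size=(40, 3))
        chalky = tm.fit_chalky_hyperplane(X, X[:, 0] > 0,
                                          dehusk_shift=np.arange(4.0))
        hrr = tm.fit_hrr_model(X, np.where(X[:, 1] > 0, 100, 20))
        path = tmp_path / "models.json"
        tm.save_models(path, chaffy=chaffy, chalky=chalky, hrr=hrr)
        loaded = tm.load_models(path)
        assert np.allclose(loaded["chaffy"].mean_pc, chaffy.mean_pc)
        assert np.allclose(loaded["chalky"].normal_pc, chalky.normal_pc)
        assert np.allclose(loaded["chalky"].dehusk_shift, chalky.dehusk_shift)
        assert loaded["hrr"].class_values == hrr.class_values
        x = rng.normal(size=(5, 3))
        assert np.allclose(
            tm.predict_hrr_probabilities(x, loaded["hrr"]),
            tm.predict_hrr_probabilities(x, hrr),
        )
        # valid JSON on disk
        json.loads(path.read_text())


class TestSampleTraitReport:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            tm.SampleTraitReport(10, 11, 50.0, 60.0, [])
        with pytest.raises(ValueError):
            tm.SampleTraitReport(10, 2, 150.0, 60.0, [])
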