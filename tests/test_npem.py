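"""npEM core: bandwidths, weighted KDEs, E/M steps, fitting, serialization."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import npemix
from npemix.npem import (NpemConfig, NpemError, WeightedKde,
                         bandwidth_default, e_step, estimate_kdes, fit,
                         init_kmeans, m_step)

from conftest import fit_quiet


class TestBandwidth:
    def test_matches_silverman_formula(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=100)
        sd = col.std(ddof=1)
        iqr = np.subtract(*np.percentile(col, [75, 25]))
        expected = 0.9 * min(sd, iqr / 1.34) * 100 ** (-0.2)
        assert bandwidth_default(col) == pytest.approx(expected, rel=1e-12)

    def test_balanced_binary_column_picks_sd(self):
        col = np.array([-0.5, 0.5] * 50)
        sd = col.std(ddof=1)  # IQR/1.34 = 0.746 > sd, so sd wins
        assert bandwidth_default(col) == pytest.approx(
            0.9 * sd * 100 ** (-0.2), rel=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=64)
        assert bandwidth_default(2 * col) == pytest.approx(
            2 * bandwidth_default(col), rel=1e-12)

    def test_degenerate_iqr_falls_back_to_sd(self):
        col = np.array([0.0] * 95 + [1.0] * 5)  # IQR = 0
        sd = col.std(ddof=1)
        assert bandwidth_default(col) == pytest.approx(
            0.9 * sd * 100 ** (-0.2), rel=1e-12)

    def test_constant_column_is_error(self):
        with pytest.raises(NpemError):
            bandwidth_default(np.ones(10))


class TestWeightedKde:
    def test_single_point_density_is_phi0_over_h(self):
        kde = WeightedKde([0.3], [1.0], bandwidth=0.5)
        assert kde.evaluate(0.3) == pytest.approx(norm.pdf(0) / 0.5, rel=1e-12)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=20)
        w = rng.random(20)
        kde = WeightedKde(pts, w / w.sum(), bandwidth=0.4)
        total, _ = quad(kde.evaluate, -15, 15, limit=200)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_nonnegative_and_weight_validation(self):
        kde = WeightedKde([0.0, 1.0], [0.5, 0.5], 0.3)
        assert (kde.evaluate(np.linspace(-5, 5, 101)) >= 0).all()
        with pytest.raises(ValueError):
            WeightedKde([0.0, 1.0], [0.6, 0.6], 0.3)
        with pytest.raises(ValueError):
            WeightedKde([0.0], [1.0], -1.0)

    def test_hard_posterior_kdes_use_only_members(self):
        data = np.array([[0.0], [0.0], [10.0]])
        post = np.array([[1.0, 0], [1.0, 0], [0, 1.0]])
        dens = estimate_kdes(data, post, np.array([0.5]))
        # cluster 1 density at 10 is the single-point kernel peak
        assert dens[0][1].evaluate(10.0) == pytest.approx(norm.pdf(0) / 0.5)
        # cluster 0 sees essentially nothing at 10
        assert dens[0][0].evaluate(10.0) < 1e-10

    def test_zero_mass_cluster_is_error(self):
        data = np.zeros((3, 1)) + [[0.0], [1.0], [2.0]]
        post = np.column_stack([np.ones(3), np.zeros(3)])
        with pytest.raises(NpemError):
            estimate_kdes(data, post, np.array([0.5]))


class TestSteps:
    def test_equal_densities_give_lambda(self):
        kde = WeightedKde([0.0], [1.0], 1.0)
        model = npemix.NpemModel(
            n_clusters=2, lambdas=np.array([0.3, 0.7]),
            densities=[[kde, kde]], feature_names=["f0"],
            reference_stats=None, final_loglik=0.0, n_iter=0,
            converged=True, seed=1)
        post = e_step(np.array([[0.5]]), model)
        np.testing.assert_allclose(post[0], [0.3, 0.7], atol=1e-12)

    def test_doubled_density_three_features_gives_8_to_1(self):
        # f_1 = 2 f_2 for each of 3 features at the query point:
        # posterior odds (1/2)*2^3 : (1/2) -> (8/9, 1/9)
        h = 1.0
        x = 0.0
        # choose point offsets so phi(d1)/phi(d2) = 2 at x=0
        d2 = 1.5
        d1 = np.sqrt(d2 ** 2 - 2 * np.log(2.0))
        k1 = WeightedKde([d1], [1.0], h)
        k2 = WeightedKde([d2], [1.0], h)
        assert k1.evaluate(x) / k2.evaluate(x) == pytest.approx(2.0, rel=1e-12)
        model = npemix.NpemModel(
            n_clusters=2, lambdas=np.array([0.5, 0.5]),
            densities=[[k1, k2]] * 3, feature_names=["a", "b", "c"],
            reference_stats=None, final_loglik=0.0, n_iter=0,
            converged=True, seed=1)
        post = e_step(np.array([[x, x, x]]), model)
        np.testing.assert_allclose(post[0], [8 / 9, 1 / 9], atol=1e-12)

    def test_onehot_lambda_dominates(self):
        k1 = WeightedKde([0.0], [1.0], 1.0)
        k2 = WeightedKde([3.0], [1.0], 1.0)
        model = npemix.NpemModel(
            n_clusters=2, lambdas=np.array([1.0, 0.0]),
            densities=[[k1, k2]], feature_names=["f0"],
            reference_stats=None, final_loglik=0.0, n_iter=0,
            converged=True, seed=1)
        post = e_step(np.array([[2.9]]), model)
        np.testing.assert_allclose(post[0], [1.0, 0.0], atol=1e-12)

    def test_m_step_is_column_mean(self):
        post = np.array([[1, 0], [0, 1], [0.5, 0.5], [0.5, 0.5]], dtype=float)
        np.testing.assert_allclose(m_step(post), [0.5, 0.5])
        np.testing.assert_allclose(m_step(np.ones((4, 3)) / 3),
                                   [1 / 3] * 3)

    def test_m_step_rejects_bad_posterior(self):
        with pytest.raises(ValueError):
            m_step(np.array([[0.5, 0.4]]))


class TestInitKmeans:
    def test_l1_and_separable_clouds(self):
        rng = np.random.default_rng(0)
        assert (init_kmeans(rng.normal(size=(10, 2)), 1, 1) == 0).all()
        a = rng.normal([-1, -1], 0.05, size=(20, 2))
        b = rng.normal([1, 1], 0.05, size=(20, 2))
        labels = init_kmeans(np.vstack([a, b]), 2, 1)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 4))
        np.testing.assert_array_equal(init_kmeans(X, 3, 7),
                                      init_kmeans(X, 3, 7))


class TestFit:
    def test_recovers_well_separated_1d_mixture(self):
        rng = np.random.default_rng(3)
        n = 200
        z = rng.random(n) < 0.5
        x = np.where(z, rng.normal(-2, 0.3, n), rng.normal(2, 0.3, n))
        model = fit_quiet(x.reshape(-1, 1), NpemConfig(n_clusters=2, seed=1))
        lam = np.sort(model.lambdas)
        assert abs(lam[0] - 0.5) <= 0.05 and abs(lam[1] - 0.5) <= 0.05
        hard = model.posterior(x.reshape(-1, 1)).argmax(axis=1)
        acc = max((hard == z).mean(), (hard == ~z).mean())
        assert acc >= 0.99

    def test_l1_fit_is_degenerate_single_component(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2))
        model = fit(X, NpemConfig(n_clusters=1, seed=1))
        np.testing.assert_allclose(model.lambdas, [1.0])
        np.testing.assert_allclose(model.posterior(X), 1.0)

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 3)) + np.repeat([[0], [4]], 30, axis=0)
        m1 = fit_quiet(X, NpemConfig(n_clusters=2, seed=9))
        m2 = fit_quiet(X, NpemConfig(n_clusters=2, seed=9))
        np.testing.assert_array_equal(m1.lambdas, m2.lambdas)
        np.testing.assert_array_equal(m1.posterior(X), m2.posterior(X))

    def test_posterior_rows_and_lambda_sum_to_one(self, cas_model,
                                                  cas_preprocessed):
        train, _t, _s = cas_preprocessed
        post = cas_model.posterior(train.to_numpy())
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert (post >= 0).all()
        assert cas_model.lambdas.sum() == pytest.approx(1.0, abs=1e-9)
        assert (cas_model.lambdas >= 0).all()

    def test_fit_rejects_missing_entries(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            fit(X, NpemConfig(n_clusters=1, seed=1))


class TestLoglik:
    def test_matches_bruteforce_products_on_toy(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 3))
        model = fit_quiet(X, NpemConfig(n_clusters=2, seed=1, max_iter=5,
                                        tol=1e-12))
        # brute force: direct products, no log tricks
        total = 0.0
        for i in range(5):
            mix = 0.0
            for k in range(model.n_clusters):
                prod = model.lambdas[k]
                for j in range(3):
                    prod *= model.densities[j][k].evaluate(X[i, j])
                mix += prod
            total += np.log(mix)
        assert model.loglik(X) == pytest.approx(total, abs=1e-10)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 2))
        model = fit_quiet(X, NpemConfig(n_clusters=2, seed=1, max_iter=10))
        perm = rng.permutation(20)
        assert model.loglik(X[perm]) == pytest.approx(model.loglik(X),
                                                      rel=1e-12)

    def test_single_row_single_feature(self):
        kde = WeightedKde([0.0], [1.0], 1.0)
        # pick x so the kernel density evaluates to exactly 0.2
        model = npemix.NpemModel(
            n_clusters=1, lambdas=np.array([1.0]), densities=[[kde]],
            feature_names=["f0"], reference_stats=None, final_loglik=0.0,
            n_iter=0, converged=True, seed=1)
        x = np.sqrt(-2 * np.log(0.2 * np.sqrt(2 * np.pi)))
        assert kde.evaluate(x) == pytest.approx(0.2, rel=1e-12)
        assert model.loglik([[x]]) == pytest.approx(np.log(0.2), abs=1e-12)


class TestBayesAgreement:
    def test_posteriors_match_analytic_bayes_in_identifiable_design(self):
        """Three conditionally iid coordinates of a 2-component Gaussian
        mixture (4 sd separation): npEM posteriors should agree with the
        analytic Bayes posterior of the generating model."""
        rng = np.random.default_rng(1)
        n, m = 2000, 3
        z = rng.random(n) < 0.5
        X = np.where(z[:, None], rng.normal(-2, 1, (n, m)),
                     rng.normal(2, 1, (n, m)))
        model = fit_quiet(X, NpemConfig(n_clusters=2, seed=1))
        post = model.posterior(X)
        l1 = norm.logpdf(X, -2, 1).sum(axis=1)
        l2 = norm.logpdf(X, 2, 1).sum(axis=1)
        b1 = 1.0 / (1.0 + np.exp(l2 - l1))
        bayes = np.column_stack([b1, 1 - b1])
        mad = min(np.abs(post - bayes).mean(),
                  np.abs(post[:, ::-1] - bayes).mean())
        assert mad <= 0.05
        lam = np.sort(model.lambdas)
        assert abs(lam[0] - 0.5) <= 0.05


class TestSerialization:
    def test_model_json_roundtrip(self, cas_model, cas_preprocessed,
                                  tmp_path):
        train, _t, _s = cas_preprocessed
        path = tmp_path / "model.json"
        cas_model.save(path)
        back = npemix.NpemModel.load(path)
        np.testing.assert_array_equal(back.lambdas, cas_model.lambdas)
        assert back.feature_names == cas_model.feature_names
        X = train.to_numpy()[:10]
        np.testing.assert_allclose(back.posterior(X),
                                   cas_model.posterior(X), atol=1e-15)
        assert back.reference_stats.median.equals(
            cas_model.reference_stats.median)

    def test_label_permutation_symmetry(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 2)) + np.repeat([[0], [5]], 15, axis=0)
        model = fit_quiet(X, NpemConfig(n_clusters=2, seed=1))
        d = model.to_dict()
        d["lambdas"] = d["lambdas"][::-1]
        d["densities"] = [row[::-1] for row in d["densities"]]
        flipped = npemix.NpemModel.from_dict(d)
        np.testing.assert_allclose(flipped.posterior(X),
                                   model.posterior(X)[:, ::-1], atol=1e-12)
        assert flipped.loglik(X) == pytest.approx(model.loglik(X), rel=1e-12)
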