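import numpy as np
import pytest

import svmix
from svmix.mixture import MixtureModel


def make_model(tau, means, covs):
    return MixtureModel(tau=np.asarray(tau, float),
                        means=np.asarray(means, float),
                        covs=np.asarray(covs, float))


def brute_force_loglik(X, model):
    total = 0.0
    for x in X:
        dens = 0.0
        for k in range(model.G):
            diff = x - model.means[k]
            cov = model.covs[k]
            inv = np.linalg.inv(cov)
            norm = 1.0 / (2 * np.pi * np.sqrt(np.linalg.det(cov)))
            dens += model.tau[k] * norm * np.exp(-0.5 * diff @ inv @ diff)
        total += np.log(dens)
    return total


def sample_three_clusters(n=600, seed=0):
    """Well-separated bivariate clusters laid out like the deletion feature
    space: homozygous (high discordant, ~zero depth), heterozygous
    (mid/mid), normal (low discordant, high depth)."""
    rng = np.random.default_rng(seed)
    means = np.array([[30.0, 1.0], [15.0, 15.0], [4.0, 31.0]])
    sds = np.array([[3.0, 0.5], [2.5, 2.0], [1.5, 3.0]])
    per = n // 3
    X = np.vstack([
        rng.normal(means[k], sds[k], size=(per, 2)) for k in range(3)
    ])
    labels = np.repeat([0, 1, 2], per)
    return X, labels, means, sds


class TestLogLikelihood:
    def test_standard_normal_at_mean(self):
        m = make_model([1.0], [[0.0, 0.0]], [np.eye(2)])
        assert svmix.log_likelihood([[0.0, 0.0]], m) == \
            pytest.approx(-np.log(2 * np.pi))

    def test_matches_brute_force_density_sum(self):
        m = make_model([0.3, 0.7], [[0, 0], [3, 1]],
                       [[[2, 0.5], [0.5, 1]], [[1, -0.2], [-0.2, 0.7]]])
        X = np.array([[0.5, 0.2], [2.5, 1.5]])
        assert svmix.log_likelihood(X, m) == \
            pytest.approx(brute_force_loglik(X, m), rel=1e-12)

    def test_duplicating_points_doubles_value(self):
        m = make_model([1.0], [[1.0, 2.0]], [np.eye(2)])
        X = np.array([[0.0, 0.0], [1.5, 2.5]])
        single = svmix.log_likelihood(X, m)
        assert svmix.log_likelihood(np.vstack([X, X]), m) == \
            pytest.approx(2 * single)


class TestEStep:
    def test_single_component_gives_unit_responsibility(self):
        m = make_model([1.0], [[0, 0]], [np.eye(2)])
        z = svmix.e_step(np.array([[5.0, 5.0], [0.0, 0.0]]), m)
        assert np.allclose(z, 1.0)

    def test_equidistant_point_splits_evenly(self):
        m = make_model([0.5, 0.5], [[-1, 0], [1, 0]],
                       [np.eye(2), np.eye(2)])
        z = svmix.e_step(np.array([[0.0, 0.0]]), m)
        assert z[0] == pytest.approx([0.5, 0.5])

    def test_matches_brute_force_bayes_rule(self):
        m = make_model([0.2, 0.8], [[0, 0], [4, 4]],
                       [[[1, 0.3], [0.3, 2]], [[0.5, 0], [0, 0.5]]])
        X = np.array([[0.0, 1.0], [3.0, 3.0], [-2.0, 0.5]])
        z = svmix.e_step(X, m)
        for i, x in enumerate(X):
            dens = []
            for k in range(2):
                diff = x - m.means[k]
                inv = np.linalg.inv(m.covs[k])
                norm = 1 / (2 * np.pi * np.sqrt(np.linalg.det(m.covs[k])))
                dens.append(m.tau[k] * norm * np.exp(-0.5 * diff @ inv @ diff))
            expected = np.array(dens) / sum(dens)
            assert z[i] == pytest.approx(expected, rel=1e-10)

    def test_rows_sum_to_one_tightly(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        m = make_model([0.25, 0.5, 0.25],
                       rng.normal(size=(3, 2)),
                       [np.eye(2) * s for s in (0.5, 1.0, 2.0)])
        z = svmix.e_step(X, m)
        assert np.abs(z.sum(axis=1) - 1.0).max() < 1e-12


class TestMStep:
    def test_hard_responsibilities_give_group_moments(self):
        X = np.array([[0, 0], [2, 0], [10, 10], [12, 14]], dtype=float)
        z = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        m = svmix.m_step(X, z, ridge=1e-9)
        assert m.tau == pytest.approx([0.5, 0.5])
        assert m.means[0] == pytest.approx([1, 0])
        assert m.means[1] == pytest.approx([11, 12])
        assert m.covs[0] == pytest.approx(np.array([[1.0, 0], [0, 0]]),
                                          abs=1e-6)

    def test_uniform_responsibilities_give_global_moments(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 2))
        z = np.full((50, 2), 0.5)
        m = svmix.m_step(X, z, ridge=1e-12)
        global_mean = X.mean(axis=0)
        global_cov = np.cov(X, rowvar=False, ddof=0)
        for k in range(2):
            assert m.means[k] == pytest.approx(global_mean)
            assert m.covs[k] == pytest.approx(global_cov, abs=1e-9)

    def test_random_responsibilities_match_weighted_moment_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 2)) * [3, 1] + [1, 5]
        raw = rng.random((20, 2))
        z = raw / raw.sum(axis=1, keepdims=True)
        m = svmix.m_step(X, z, ridge=1e-12)
        for k in range(2):
            nk = z[:, k].sum()
            mean = (z[:, k, None] * X).sum(axis=0) / nk
            diff = X - mean
            cov = (z[:, k, None] * diff).T @ diff / nk
            assert m.tau[k] == pytest.approx(nk / 20)
            assert m.means[k] == pytest.approx(mean)
            assert m.covs[k] == pytest.approx(cov, abs=1e-9)


class TestFitEM:
    def test_recovers_separated_components(self):
        X, _, true_means, true_sds = sample_three_clusters()
        model = svmix.fit_em(X, G=3, seed=0)
        order = np.argsort(model.means[:, 0])
        true_order = np.argsort(true_means[:, 0])
        for k, tk in zip(order, true_order):
            # recovered means within 0.5 sd of the generating truth
            assert np.all(np.abs(model.means[k] - true_means[tk])
                          <= 0.5 * true_sds[tk])

    def test_infinite_tolerance_runs_exactly_one_iteration(self):
        X, _, _, _ = sample_three_clusters(n=60)
        model = svmix.fit_em(X, G=3, tol=np.inf)
        assert model.n_iter == 1
        assert len(model.history) == 2

    def test_log_likelihood_never_decreases(self):
        X, _, _, _ = sample_three_clusters(n=300, seed=4)
        model = svmix.fit_em(X, G=3, tol=1e-12, max_iter=300)
        h = model.history
        assert all(b >= a - 1e-9 * max(1.0, abs(a))
                   for a, b in zip(h, h[1:]))

    def test_too_few_points_is_fatal(self):
        with pytest.raises(ValueError, match="too few"):
            svmix.fit_em(np.zeros((2, 2)), G=3)

    def test_non_finite_features_are_fatal_with_index(self):
        X = np.array([[0.0, 0.0], [np.nan, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="index 1"):
            svmix.fit_em(X, G=2)

    def test_agrees_with_reference_em_implementation(self):
        """Independent cross-check: scikit-learn's full-covariance EM
        converges to the same solution (means within 1e-4) on separated
        seeded data."""
        from sklearn.mixture import GaussianMixture

        X, _, _, _ = sample_three_clusters(n=450, seed=2)
        ours = svmix.fit_em(X, G=3, tol=1e-13, max_iter=5000, ridge=1e-6)
        ref = GaussianMixture(
            n_components=3, covariance_type="full", reg_covar=1e-6,
            tol=1e-10, max_iter=5000, n_init=5, random_state=0,
        ).fit(X)
        ours_sorted = ours.means[np.argsort(ours.means[:, 0])]
        ref_sorted = ref.means_[np.argsort(ref.means_[:, 0])]
        assert np.abs(ours_sorted - ref_sorted).max() < 1e-4
        tau_sorted = ours.tau[np.argsort(ours.means[:, 0])]
        ref_tau = ref.weights_[np.argsort(ref.means_[:, 0])]
        assert np.abs(tau_sorted - ref_tau).max() < 1e-4


class TestLabelComponents:
    def test_deletion_layout(self):
        m = make_model([1 / 3] * 3, [[20, 0.3], [10, 6], [4, 12]],
                       [np.eye(2)] * 3)
        labels = svmix.label_components(m, "DEL")
        assert labels == {0: "HOM_DEL", 1: "HET_DEL", 2: "NORMAL"}

    def test_inversion_layout(self):
        m = make_model([0.5, 0.5], [[8, 5], [1, 0]], [np.eye(2)] * 2)
        assert svmix.label_components(m, "INV") == {0: "INV", 1: "NORMAL"}

    def test_identical_components_tie_break_by_index(self):
        m = make_model([0.5, 0.5], [[1, 1], [1, 1]], [np.eye(2)] * 2)
        labels = svmix.label_components(m, "INV")
        assert set(labels.values()) == {"INV", "NORMAL"}
        assert labels[0] == "INV"  # deterministic index-order tie break


class TestClassify:
    def test_uncertainty_is_one_minus_max_membership(self):
        m = make_model([0.5, 0.5], [[-1, 0], [1, 0]],
                       [np.eye(2), np.eye(2)])
        labels = {0: "A", 1: "B"}
        got = svmix.classify(np.array([[0.0, 0.0], [-5.0, 0.0]]), m, labels)
        assert got[0].uncertainty == pytest.approx(0.5)
        assert got[1].label == "A"
        assert got[1].uncertainty == pytest.approx(0.0, abs=1e-4)

    def test_uncertainty_bounded_by_one_minus_inverse_g(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 2)) * 5
        m = make_model([0.25, 0.5, 0.25], rng.normal(size=(3, 2)) * 3,
                       [np.eye(2)] * 3)
        for a in svmix.classify(X, m, {0: "a", 1: "b", 2: "c"}):
            assert 0.0 <= a.uncertainty <= 1 - 1 / 3 + 1e-12
            assert a.responsibilities.sum() == pytest.approx(1.0, abs=1e-12)


def test_bic_penalizes_parameters():
    X, _, _, _ = sample_three_clusters(n=300, seed=6)
    m3 = svmix.fit_em(X, G=3)
    ll = svmix.log_likelihood(X, m3)
    assert svmix.bic(X, m3) < 2 * ll
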