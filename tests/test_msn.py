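"""Multi-site neutral model: primitives, Gibbs sampler, neutrality tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import digamma
from scipy.stats import chisquare

from nicheneutral import (MultiSiteNeutralModel, dirichlet_multinomial_loglik,
                          gen_neutral, gibbs_fit, immigration_rate,
                          log_antoniak_pmf, migration_probability,
                          neutrality_test, sample_crt, stick_breaking_sample)
from nicheneutral.msn import NeutralityTestResult, expected_richness


class TestAntoniak:
    @pytest.mark.parametrize("S, theta, N, expected", [
        (1, 1.0, 2, 0.5),      # two seatings: both at one table / two tables
        (2, 1.0, 2, 0.5),
        (3, 1.0, 3, 1 / 6),    # s(3,3)=1, Gamma(1)/Gamma(4)=1/6
    ])
    def test_small_enumerations(self, S, theta, N, expected):
        assert np.exp(log_antoniak_pmf(S, theta, N)) == pytest.approx(
            expected, abs=1e-12)

    @pytest.mark.parametrize("theta, N", [(3.7, 10), (0.5, 60), (5.0, 120)])
    def test_normalizes(self, theta, N):
        total = sum(np.exp(log_antoniak_pmf(S, theta, N))
                    for S in range(1, N + 1))
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("S, theta, N", [(0, 1.0, 5), (6, 1.0, 5),
                                             (2, 0.0, 5), (2, -1.0, 5)])
    def test_domain_errors(self, S, theta, N):
        with pytest.raises(ValueError):
            log_antoniak_pmf(S, theta, N)


class TestCRT:
    def test_single_customer_always_one_table(self, rng):
        assert all(sample_crt(1, a, rng) == 1 for a in (0.01, 1.0, 50.0))

    def test_matches_exact_stirling_pmf(self, rng):
        # pmf of t for x=3, alpha=1 is proportional to s(3,t): (2, 3, 1)/6
        draws = np.bincount([sample_crt(3, 1.0, rng)
                             for _ in range(30_000)], minlength=4)[1:]
        p = chisquare(draws, 30_000 * np.array([2, 3, 1]) / 6).pvalue
        assert p > 0.01

    def test_large_alpha_limit(self, rng):
        assert all(sample_crt(5, 1e9, rng) == 5 for _ in range(50))

    def test_domain_error(self, rng):
        with pytest.raises(ValueError):
            sample_crt(0, 1.0, rng)


class TestStickBreaking:
    def test_mass_sums_to_one(self, rng):
        for theta in (0.3, 5.0, 40.0):
            assert stick_breaking_sample(theta, rng=rng).sum() == \
                pytest.approx(1.0, abs=1e-12)

    def test_deterministic_under_seed(self):
        a = stick_breaking_sample(5.0, rng=np.random.default_rng(3))
        b = stick_breaking_sample(5.0, rng=np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_occupancy_matches_digamma_identity(self, rng):
        # E[#distinct among N draws] = theta * (psi(theta+N) - psi(theta))
        theta, N, reps = 5.0, 100, 2000
        expect = expected_richness(theta, N)
        assert expect == pytest.approx(
            theta * (digamma(theta + N) - digamma(theta)))
        distinct = np.empty(reps)
        for r in range(reps):
            beta = stick_breaking_sample(theta, rng=rng)
            draws = rng.choice(beta.size, size=N, p=beta)
            distinct[r] = np.unique(draws).size
        se = distinct.std(ddof=1) / np.sqrt(reps)
        assert abs(distinct.mean() - expect) < 3 * se

    def test_domain_error(self):
        with pytest.raises(ValueError):
            stick_breaking_sample(0.0)


class TestDirichletMultinomial:
    def test_degenerate_single_species_is_certain(self):
        assert dirichlet_multinomial_loglik([2], 2, [0.37]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_uniform_pair(self):
        assert dirichlet_multinomial_loglik([1, 1], 2, [1.0, 1.0]) == \
            pytest.approx(np.log(1 / 3), abs=1e-12)

    @pytest.mark.parametrize("N, alpha", [
        (4, (0.7, 1.3)), (6, (0.5, 1.0, 2.5)), (3, (2.0, 0.1, 0.9)),
    ])
    def test_total_probability_by_enumeration(self, N, alpha):
        S = len(alpha)
        total = 0.0
        for combo in itertools.product(range(N + 1), repeat=S):
            if sum(combo) == N:
                total += np.exp(dirichlet_multinomial_loglik(combo, N, alpha))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_concentration_limit_is_multinomial(self):
        # I -> infinity: DP concentrates on beta, counts become multinomial
        x, beta = np.array([3, 1, 2]), np.array([0.5, 0.2, 0.3])
        big_I = 1e8
        dm = dirichlet_multinomial_loglik(x, 6, big_I * beta)
        from scipy.stats import multinomial
        assert dm == pytest.approx(multinomial.logpmf(x, 6, beta), abs=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            dirichlet_multinomial_loglik([1, 1], 3, [1.0, 1.0])
        with pytest.raises(ValueError):
            dirichlet_multinomial_loglik([1, 1], 2, [1.0, 0.0])


@settings(derandomize=True, max_examples=50)
@given(m=st.floats(1e-6, 1 - 1e-6), N=st.integers(2, 10_000))
def test_migration_immigration_round_trip(m, N):
    I = immigration_rate(m, N)
    assert migration_probability(I, N) == pytest.approx(m, abs=1e-12)


class TestGibbs:
    def test_identical_seed_identical_chains(self, neutral_small):
        mat, _ = neutral_small
        cfg = dict(n_iter=200, n_burn=100, thin=10)
        a = gibbs_fit(mat, cfg, rng=11)
        b = gibbs_fit(mat, cfg, rng=11)
        assert np.array_equal(a.theta_chain, b.theta_chain)
        assert np.array_equal(a.beta_thin, b.beta_thin)

    def test_posterior_shapes_and_thinning(self, neutral_small):
        mat, _ = neutral_small
        post = gibbs_fit(mat, dict(n_iter=300, n_burn=100, thin=10), rng=1)
        assert post.theta_chain.shape == (200,)
        assert post.n_sets == 20
        assert post.beta_thin.shape == (20, mat.n_species + 1)
        assert np.allclose(post.beta_thin.sum(axis=1), 1.0)

    def test_single_column_still_fits(self):
        from nicheneutral import AbundanceMatrix
        mat = AbundanceMatrix(np.array([[30], [20], [10]]),
                              ["a", "b", "c"], ["t0"], "one")
        post = gibbs_fit(mat, dict(n_iter=200, n_burn=100, thin=10), rng=2)
        assert post.I_chain.shape == (100, 1)
        assert post.theta_median > 0

    def test_single_species_theta_below_prior_median(self):
        # no diversity signal: the chain should sit well below the
        # Gamma(1, 0.1) prior median (~6.93)
        from nicheneutral import AbundanceMatrix
        mat = AbundanceMatrix(np.full((1, 6), 400), ["a"],
                              [f"t{i}" for i in range(6)], "mono")
        post = gibbs_fit(mat, dict(n_iter=1000, n_burn=500, thin=10), rng=3)
        assert post.theta_median < np.log(2) * 10

    def test_estimator_api(self, neutral_small):
        mat, _ = neutral_small
        model = MultiSiteNeutralModel(n_iter=200, n_burn=100, thin=10,
                                      random_state=5)
        assert model.get_params()["n_iter"] == 200
        model.fit(mat)
        assert model.theta_median_ > 0
        assert 0 < model.M_value_ < 1
        assert model.m_median_.shape == (mat.n_samples,)


class TestNeutralityTest:
    @pytest.fixture(scope="class")
    def fitted(self, neutral_small):
        mat, _ = neutral_small
        post = gibbs_fit(mat, dict(n_iter=600, n_burn=300, thin=10), rng=9)
        return mat, post

    @pytest.mark.parametrize("level", ["metacommunity", "local"])
    def test_pseudo_p_is_pass_fraction(self, fitted, level):
        mat, post = fitted
        res = neutrality_test(mat, post, level, np.random.default_rng(1))
        assert res.N == post.n_sets
        assert res.P == res.N_pass_sims / res.N
        assert 0.0 <= res.P <= 1.0

    def test_from_counts_matches_reported_ratio(self):
        res = NeutralityTestResult.from_counts("metacommunity", -1.0, -2.0,
                                               2437, 2500)
        assert res.P == pytest.approx(0.9748)
        assert res.passes(0.05) and not res.passes(0.99)

    def test_unknown_level_and_empty_posterior_error(self, fitted):
        mat, post = fitted
        with pytest.raises(ValueError):
            neutrality_test(mat, post, "galactic")
        import dataclasses
        empty = dataclasses.replace(post, theta_thin=np.empty(0),
                                    I_thin=np.empty((0, mat.n_samples)),
                                    beta_thin=np.empty((0, mat.n_species + 1)))
        with pytest.raises(ValueError):
            neutrality_test(mat, empty, "local")


def test_generated_data_recovers_theta_direction(rng):
    # single smoke-level recovery; the full oracle lives in the
    # acceptance suite
    mat, truth = gen_neutral(15.0, 10.0, [1000] * 15, rng=rng)
    post = gibbs_fit(mat, dict(n_iter=1500, n_burn=750, thin=15), rng=rng)
    assert 5.0 < post.theta_median < 40.0
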