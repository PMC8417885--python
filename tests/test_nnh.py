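"""Niche-neutral hybrid model: SAD pmf, per-niche fits, chi-square tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nicheneutral import (NicheNeutralHybridModel, VolkovParams,
                          expected_sad, fit_niche, gen_hybrid,
                          local_neutrality_tests, nnh_metacommunity_test,
                          nnh_summary, volkov_pmf)
from nicheneutral.nnh import (BinnedSAD, _chi2_test, _theta_from_richness,
                              preston_octaves)
from nicheneutral.synthetic import _zt_volkov_sample


class TestVolkovPmf:
    def test_gamma_one_is_geometric(self):
        n = np.arange(51)
        assert np.allclose(volkov_pmf(n, 0.5, 1.0), 0.5 * 0.5 ** n,
                           atol=1e-12)

    def test_normalizes(self):
        n = np.arange(5000)
        assert volkov_pmf(n, 0.8, 2.3).sum() == pytest.approx(1.0,
                                                              abs=1e-12)

    @pytest.mark.parametrize("x, gamma", [(1.0, 1.0), (0.0, 1.0),
                                          (-0.2, 1.0), (0.5, 0.0)])
    def test_domain_errors(self, x, gamma):
        with pytest.raises(ValueError):
            volkov_pmf(1, x, gamma)


class TestExpectedSAD:
    def test_direct_values(self):
        p = VolkovParams(theta=10.0, x=0.5, gamma=1.0)
        assert expected_sad(1, p) == pytest.approx(5.0)
        assert expected_sad(2, p) == pytest.approx(2.5)

    def test_linear_in_theta(self):
        a = expected_sad(np.arange(1, 20), theta=3.0, x=0.6, gamma=0.8)
        b = expected_sad(np.arange(1, 20), theta=6.0, x=0.6, gamma=0.8)
        assert np.allclose(b, 2 * a, rtol=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(n=st.integers(1, 200), x=st.floats(0.05, 0.95),
           gamma=st.floats(0.1, 10.0))
    def test_ratio_identity(self, n, x, gamma):
        r = expected_sad(n + 1, theta=2.0, x=x, gamma=gamma) / \
            expected_sad(n, theta=2.0, x=x, gamma=gamma)
        assert r == pytest.approx(x * (n + gamma) / (n + 1), rel=1e-10)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            expected_sad(0, theta=1.0, x=0.5, gamma=1.0)


class TestFitNiche:
    def test_recovers_simulated_parameters(self):
        rng = np.random.default_rng(42)
        xs, gs = [], []
        for _ in range(5):
            ab = _zt_volkov_sample(0.7, 1.5, 200, rng)
            p = fit_niche(ab)
            xs.append(p.x)
            gs.append(p.gamma)
        assert abs(np.median(xs) - 0.7) < 0.05
        assert abs(np.median(gs) - 1.5) < 0.5

    def test_all_singletons_flagged_at_boundary(self):
        p = fit_niche(np.ones(30, dtype=int))
        assert not p.converged
        assert p.x < 0.05

    def test_theta_scales_with_richness(self):
        assert _theta_from_richness(40, 0.6, 1.2) == pytest.approx(
            2 * _theta_from_richness(20, 0.6, 1.2))

    def test_records_niche_size(self):
        p = fit_niche([4, 2, 9, 1, 1, 3])
        assert p.J == 20 and p.S == 6

    def test_rejects_empty_or_zero(self):
        with pytest.raises(ValueError):
            fit_niche([])
        with pytest.raises(ValueError):
            fit_niche([0, 1, 2])


class TestChiSquare:
    def test_perfect_fit(self):
        b = BinnedSAD(np.array([1, 2, 4, 8]), np.array([5.0, 3.0, 2.0]),
                      np.array([5.0, 3.0, 2.0]))
        chi2, df, P, R2 = _chi2_test(b)
        assert chi2 == 0.0 and P == pytest.approx(1.0)
        assert R2 == pytest.approx(1.0)

    def test_two_bin_arithmetic(self):
        b = BinnedSAD(np.array([1, 2, 4]), np.array([8.0, 12.0]),
                      np.array([10.0, 10.0]))
        chi2 = _chi2_test(b)[0]
        assert chi2 == pytest.approx(0.8)

    def test_bin_order_invariance(self):
        O, E = np.array([4.0, 9.0, 2.0]), np.array([5.0, 8.0, 2.0])
        a = _chi2_test(BinnedSAD(np.arange(4), O, E))[0]
        b = _chi2_test(BinnedSAD(np.arange(4), O[::-1], E[::-1]))[0]
        assert a == pytest.approx(b)

    def test_octave_edges_cover_max(self):
        edges = preston_octaves(100)
        assert edges[0] == 1 and edges[-1] > 100
        assert np.all(np.diff(np.log2(edges[1:])) == 1)


class TestHybridModel:
    @pytest.fixture(scope="class")
    def hybrid(self):
        params = [VolkovParams(1.0, x=0.5, gamma=1.0) if i % 2 == 0
                  else VolkovParams(1.0, x=0.9, gamma=0.2)
                  for i in range(10)]
        mat, _ = gen_hybrid(10, params, 25, rng=np.random.default_rng(5),
                            species_pool=60)
        return mat

    def test_fit_reports_all_summaries(self, hybrid):
        m = NicheNeutralHybridModel().fit(hybrid)
        assert m.K_ == 10
        assert m.df_ >= 1 and np.isfinite(m.chi2_)
        assert 0.0 <= m.p_value_ <= 1.0
        assert m.summary_.N_pass == m.n_pass_
        assert 0 < m.summary_.x < 1
        # expected bins never fall below the pooling floor
        assert (m.result_.binned.E >= m.e_floor).all()
        # expected and observed totals agree (theta matches richness)
        assert m.result_.binned.E.sum() == pytest.approx(
            m.result_.binned.O.sum(), rel=1e-6)

    def test_local_pass_monotone_in_threshold(self, hybrid):
        m = NicheNeutralHybridModel().fit(hybrid)
        n_low, _ = m.local_pass(0.05)
        n_high, _ = m.local_pass(0.95)
        assert n_high <= n_low <= len(m.valid_niches_)

    def test_wrappers_match_estimator(self, hybrid):
        m = NicheNeutralHybridModel().fit(hybrid)
        fits = [None] * hybrid.n_samples
        for i, p in zip(m.valid_niches_, m.result_.per_niche):
            fits[i] = p
        res = nnh_metacommunity_test(hybrid, fits)
        assert res.chi2 == pytest.approx(m.chi2_)
        n_pass, pct = local_neutrality_tests(hybrid, fits, 0.05)
        assert (n_pass, pct) == (m.n_pass_, m.pct_pass_)

    def test_k1_reduces_to_single_community_test(self, hybrid):
        col = hybrid.counts[:, [0]]
        from nicheneutral import AbundanceMatrix
        single = AbundanceMatrix(col[col.sum(axis=1) > 0],
                                 [s for s, c in zip(hybrid.species_ids,
                                                    col.sum(axis=1)) if c],
                                 ["t0"], "k1")
        m = NicheNeutralHybridModel().fit(single)
        # with one niche the metacommunity chi-square equals the niche's own
        assert m.local_p_values_[0] == pytest.approx(m.p_value_)

    def test_too_few_species_excluded(self):
        from nicheneutral import AbundanceMatrix
        counts = np.array([[5, 20], [3, 9], [0, 4], [0, 2], [0, 1], [0, 1]])
        mat = AbundanceMatrix(counts, list("abcdef"), ["t0", "t1"], "sm")
        m = NicheNeutralHybridModel(min_species=3).fit(mat)
        assert m.valid_niches_ == [1]


class TestSummary:
    def test_migration_coefficient_convention(self):
        p = VolkovParams(theta=4.0, x=0.8, gamma=1.236, J=164, S=8)
        assert p.m == pytest.approx(0.0075, abs=5e-4)
        row = nnh_summary([p], subject_id="s")
        assert row.J == 164 and row.m == pytest.approx(p.m)

    def test_identical_fits_average_to_common_values(self):
        ps = [VolkovParams(theta=3.0, x=0.6, gamma=0.9, J=200, S=12)] * 4
        row = nnh_summary(ps)
        assert row.theta == pytest.approx(3.0)
        assert row.x == pytest.approx(0.6)

    def test_gamma_to_zero_limit(self):
        m = VolkovParams(theta=1.0, x=0.5, gamma=1e-6, J=100, S=3).m
        assert m == pytest.approx(0.0, abs=1e-7)

    def test_no_valid_fits_raises(self):
        with pytest.raises(ValueError):
            nnh_summary([None, None])
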