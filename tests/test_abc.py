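"""ABC engine: rejection oracle, regression adjustment, posterior summaries."""
import numpy as np
import pandas as pd
import pytest

from abcmk import PriorSpec, build_parameter_grid, generate_dataset
from abcmk.abc import (
    abc_reject,
    bootstrap_datasets,
    default_x_grid,
    loclinear_adjust,
    posterior_summary,
    simulate_summaries,
    summarize_for_abc,
)
from abcmk.mk import cumulative_alpha
from abcmk.sampling import ObservedCounts


class TestXGrids:
    def test_sample_size_classes(self):
        assert default_x_grid(661) == (2, 5, 20, 50, 200, 661, 925)
        assert default_x_grid(500) == (2, 5, 20, 50, 200, 500, 700)
        assert default_x_grid(50) == (2, 4, 5, 10, 20, 30, 50, 70)

    def test_singletons_rejected(self, solved_04_01):
        ds = generate_dataset(solved_04_01, 1000, seed=1)
        curve = cumulative_alpha(ds.pooled)
        with pytest.raises(ValueError, match="singletons"):
            summarize_for_abc(curve, (1, 5, 20))

    def test_vector_follows_x_points(self, solved_04_01):
        ds = generate_dataset(solved_04_01, 5000, seed=2)
        curve = cumulative_alpha(ds.pooled)
        v1 = summarize_for_abc(curve, (2, 5, 20))
        v2 = summarize_for_abc(curve, (20, 2, 5))
        assert v1.size == 3
        np.testing.assert_allclose(np.sort(v1), np.sort(v2))


class TestReject:
    def test_tolerance_one_accepts_everything(self, rng):
        sims = rng.normal(size=(200, 4))
        acc = abc_reject(np.zeros(4), sims, tolerance=1.0)
        assert acc.indices.size == 200

    def test_accept_count_is_ceil(self, rng):
        sims = rng.normal(size=(100_000, 3))
        acc = abc_reject(np.zeros(3), sims, tolerance=0.025)
        assert acc.indices.size == 2500

    def test_matches_exhaustive_sort_oracle(self, rng):
        sims = rng.normal(size=(500, 4))
        obs = rng.normal(size=4)
        acc = abc_reject(obs, sims, tolerance=0.1)
        from scipy.stats import median_abs_deviation

        mad = median_abs_deviation(sims, axis=0)
        d = np.sqrt((((sims - obs) / mad) ** 2).sum(axis=1))
        oracle = np.argsort(d, kind="stable")[:50]
        np.testing.assert_array_equal(np.sort(acc.indices), np.sort(oracle))

    def test_degenerate_dimension_dropped_with_warning(self, rng):
        sims = rng.normal(size=(100, 3))
        sims[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-spread"):
            acc = abc_reject(np.array([0.0, 7.0, 0.0]), sims, tolerance=0.5)
        assert acc.indices.size == 50

    def test_nan_rows_never_accepted(self, rng):
        sims = rng.normal(size=(100, 2))
        sims[:60] = np.nan
        acc = abc_reject(np.zeros(2), sims, tolerance=0.4)
        assert np.all(acc.indices >= 60)


class TestLoclinear:
    def test_exactly_linear_relation_collapses(self, rng):
        # params are an exact linear map of summaries: after adjustment all
        # draws agree at the observed point
        S = rng.normal(size=(80, 3))
        beta = np.array([[1.0, -2.0, 0.5]]).T
        theta = pd.DataFrame(S @ beta + 0.3, columns=["p"])
        obs = np.array([0.2, -0.1, 0.4])
        adj = loclinear_adjust(theta, S, obs)
        want = float((obs @ beta)[0] + 0.3)
        np.testing.assert_allclose(adj["p"], want, atol=1e-8)

    def test_independent_params_unchanged(self, rng):
        S = rng.normal(size=(300, 2))
        theta = pd.DataFrame({"p": rng.normal(5.0, 1.0, 300)})
        adj = loclinear_adjust(theta, S, np.zeros(2))
        assert adj["p"].mean() == pytest.approx(theta["p"].mean(), abs=0.05)
        assert adj["p"].std() == pytest.approx(theta["p"].std(), rel=0.1)

    def test_conjugate_gaussian_oracle(self, rng):
        # theta ~ N(0,1), summary = theta + noise(0, sigma^2):
        # E[theta | s_obs] = s_obs / (1 + sigma^2)
        n, sigma, s_obs = 4000, 0.5, 0.8
        theta = rng.normal(0, 1, n)
        s = theta + rng.normal(0, sigma, n)
        keep = np.abs(s - s_obs) < 0.4  # crude acceptance window
        adj = loclinear_adjust(
            pd.DataFrame({"t": theta[keep]}), s[keep, None], np.array([s_obs])
        )
        want = s_obs / (1 + sigma**2)
        assert adj["t"].mean() == pytest.approx(want, abs=0.05)

    def test_adjustment_never_widens_exact_linear_posterior(self, rng):
        S = rng.normal(size=(100, 2))
        theta = pd.DataFrame(S @ np.array([[2.0, 1.0]]).T, columns=["p"])
        adj = loclinear_adjust(theta, S, np.zeros(2))
        assert adj["p"].std() <= theta["p"].std() + 1e-12

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError, match="accepted draws"):
            loclinear_adjust(
                pd.DataFrame({"p": [1.0, 2.0]}), np.zeros((2, 3)), np.zeros(3)
            )


class TestPosteriorSummary:
    def test_gaussian_mode_near_mean(self, rng):
        draws = pd.DataFrame({"p": rng.normal(3.0, 0.5, 5000)})
        s = posterior_summary(draws)
        assert s.loc["p", "mode"] == pytest.approx(3.0, abs=0.1)
        assert s.loc["p", "ci_low"] == pytest.approx(3.0 - 1.96 * 0.5, abs=0.1)
        assert s.loc["p", "ci_high"] == pytest.approx(3.0 + 1.96 * 0.5, abs=0.1)

    def test_point_mass(self):
        draws = pd.DataFrame({"p": np.full(200, 1.23)})
        s = posterior_summary(draws)
        assert s.loc["p", "mode"] == 1.23
        assert s.loc["p", "ci_low"] == s.loc["p", "ci_high"] == 1.23


class TestBootstrap:
    def _genes(self, rng, k=40):
        return [
            ObservedCounts(rng.poisson(3, 9), rng.poisson(3, 9),
                           int(rng.poisson(4)), int(rng.poisson(4)), 5)
            for _ in range(k)
        ]

    def test_seeded_and_distinct(self, rng):
        genes = self._genes(rng)
        a = bootstrap_datasets(genes, 3, seed=9)
        b = bootstrap_datasets(genes, 3, seed=9)
        for x, y in zip(a, b):
            assert x.DN == y.DN and np.array_equal(x.sfs_nonsyn, y.sfs_nonsyn)
        c = bootstrap_datasets(genes, 3, seed=10)
        assert any(x.DN != y.DN for x, y in zip(a, c))

    def test_moments(self, rng):
        genes = self._genes(rng, k=100)
        reps = bootstrap_datasets(genes, 400, seed=1)
        dns = np.array([r.DN for r in reps])
        mean_dn = sum(g.DN for g in genes)
        assert dns.mean() == pytest.approx(mean_dn, rel=0.05)
        var_gene = np.var([g.DN for g in genes])
        assert dns.var() == pytest.approx(var_gene * len(genes), rel=0.3)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            bootstrap_datasets([], 1, seed=0)


class TestSimulatedSummaries:
    def test_deterministic_and_shaped(self, solved_04_01):
        ds = generate_dataset(solved_04_01, 5000, seed=5)
        grid = build_parameter_grid(PriorSpec(), 50, seed=4)
        s1 = simulate_summaries(grid, ds.pooled, seed=6)
        s2 = simulate_summaries(grid, ds.pooled, seed=6)
        np.testing.assert_array_equal(s1, s2)
        assert s1.shape == (50, 7)

    def test_basis_reconstruction_matches_model_spectra(self, solved_04_01):
        # the accelerated basis path must agree with the direct per-model
        # spectra computation on the nonsynonymous/synonymous share
        from abcmk.abc import _spectra_basis, _interp_pos_rows
        from abcmk.model import downsample_binomial, expected_sfs_gamma, expected_sfs_point
        from scipy import stats as sps

        m = solved_04_01.model.with_B(0.73)
        S_basis, S_edges, basis_neg, basis_pos, psi_syn = _spectra_basis(m.N, m.n)
        cdf = sps.gamma.cdf(
            S_edges / (2 * m.B), a=m.gam_shape, scale=m.gam_mean / m.gam_shape
        )
        fast_neg = np.diff(cdf) @ basis_neg + cdf[0] * psi_syn
        direct = expected_sfs_gamma(m)
        direct_neg = downsample_binomial(
            direct.psi_neg / (m.theta_coding * m.B) / m.frac_neg, m.n
        )
        np.testing.assert_allclose(fast_neg, direct_neg, rtol=2e-3)
        fast_w = _interp_pos_rows(np.array([2 * m.B * m.s_weak]), S_basis, basis_pos)[0]
        direct_w = downsample_binomial(
            expected_sfs_point(m.B * m.s_weak, 1.0, m.N), m.n
        )
        np.testing.assert_allclose(fast_w, direct_w, rtol=2e-3)
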