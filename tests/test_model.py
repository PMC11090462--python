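"""Analytic spectra and fixation rates against independent oracles."""
import mpmath as mp
import numpy as np
import pytest
from scipy import integrate, stats

from abcmk import (
    SelectionModel,
    downsample_binomial,
    expected_alpha,
    expected_sfs_gamma,
    expected_sfs_point,
    fixation_rates,
)
from abcmk.model import ExpectedRates, dfe_fixation, pfix_beneficial
from abcmk.special import hurwitz_zeta


def _sfs_oracle(s2N, theta, N):
    """Literal high-precision evaluation of the diffusion SFS formula."""
    out = []
    for i in range(1, 2 * N):
        x = mp.mpf(i) / (2 * N)
        S = mp.mpf(4) * s2N / 2  # 4Ns
        if s2N == 0:
            out.append(theta / x)
        else:
            val = theta / (x * (1 - x)) * mp.e**S * (1 - mp.e**(-S * (1 - x))) / (mp.e**S - 1)
            out.append(float(val))
    return np.array(out, dtype=float)


class TestExpectedSfsPoint:
    def test_neutral_limit_is_theta_over_x(self):
        N, theta = 200, 0.01
        x = np.arange(1, 2 * N) / (2 * N)
        got = expected_sfs_point(0.0, theta, N)
        np.testing.assert_allclose(got, theta / x, rtol=1e-10)

    def test_matches_high_precision_oracle(self):
        got = expected_sfs_point(5.0, 0.001, 500)
        np.testing.assert_allclose(got, _sfs_oracle(5.0, 0.001, 500), rtol=1e-8)

    def test_strong_negative_selection_vanishes_above_lowest_bins(self):
        spec = expected_sfs_point(-1e6, 0.01, 100)
        assert np.all(np.isfinite(spec))
        assert spec[5:].max() < 1e-200
        assert spec[0] >= 0

    def test_extreme_positive_selection_finite(self):
        spec = expected_sfs_point(1e6, 0.01, 100)
        assert np.all(np.isfinite(spec)) and np.all(spec >= 0)

    def test_continuity_at_zero(self):
        a = expected_sfs_point(1e-9, 1.0, 100)
        b = expected_sfs_point(0.0, 1.0, 100)
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_frequency_reflection_identity(self):
        # the diffusion solution satisfies psi(x; S) + psi(1-x; -S) =
        # theta / (x (1-x)): beneficial and reflected-deleterious spectra
        # share the neutral envelope
        N, S2, theta = 40, 3.0, 0.7
        fwd = expected_sfs_point(S2, theta, N)
        rev = expected_sfs_point(-S2, theta, N)[::-1]
        x = np.arange(1, 2 * N) / (2 * N)
        np.testing.assert_allclose(fwd + rev, theta / (x * (1 - x)), rtol=1e-9)


class TestExpectedSfsGamma:
    def test_dfe_collapsing_to_neutrality(self):
        m = SelectionModel(N=100, n=100, gam_mean=1e-6, B=1.0)
        sp = expected_sfs_gamma(m)
        neutral = expected_sfs_point(0.0, m.theta_coding, m.N)
        np.testing.assert_allclose(sp.psi_neg, neutral, rtol=1e-4)

    def test_matches_monte_carlo_mixture(self, rng):
        m = SelectionModel(N=100, n=100, B=1.0)
        sp = expected_sfs_gamma(m)
        draws = rng.gamma(m.gam_shape, m.gam_mean / m.gam_shape, size=20000)
        mc = np.zeros(2 * m.N - 1)
        for g in draws:
            mc += expected_sfs_point(-g, m.theta_coding, m.N)
        mc /= draws.size
        # MC error: compare pooled mass in coarse frequency windows
        for sl in (slice(0, 5), slice(5, 50), slice(50, 199)):
            assert sp.psi_neg[sl].sum() == pytest.approx(mc[sl].sum(), rel=0.05)

    def test_degenerate_strong_mixture(self):
        m = SelectionModel(N=100, n=100, p_strong=1.0, p_weak=0.0, B=1.0)
        sp = expected_sfs_gamma(m)
        point = expected_sfs_point(m.s_strong, m.theta_coding, m.N)
        np.testing.assert_allclose(sp.psi_pos, m.frac_strong * point, rtol=1e-12)


class TestDownsample:
    def test_point_mass_at_half(self):
        pop = np.zeros(19)  # N = 10
        pop[9] = 1.0  # frequency 0.5
        got = downsample_binomial(pop, 1)
        assert got.shape == (1,)
        assert got[0] == pytest.approx(0.5)

    def test_matches_direct_summation(self, rng):
        pop = rng.uniform(size=99)  # N = 50
        got = downsample_binomial(pop, 10)
        N, n = 50, 10
        direct = np.zeros(2 * n - 1)
        for j in range(1, 2 * n):
            for i in range(1, 2 * N):
                direct[j - 1] += pop[i - 1] * stats.binom.pmf(j, 2 * n, i / (2 * N))
        np.testing.assert_allclose(got, direct, atol=1e-12)

    def test_total_mass_never_increases(self, rng):
        pop = rng.uniform(size=199)
        for n in (5, 20, 50, 100):
            assert downsample_binomial(pop, n).sum() <= pop.sum() + 1e-9

    def test_rejects_oversampling(self):
        with pytest.raises(ValueError, match="n=51 > N=50"):
            downsample_binomial(np.ones(99), 51)


class TestHurwitzZeta:
    @pytest.mark.parametrize("s", [0.046, 0.184, 0.5, 0.736, 1.5, 3.0])
    @pytest.mark.parametrize("q", [0.6, 0.999, 1.0002, 1.7])
    def test_matches_mpmath(self, s, q):
        assert hurwitz_zeta(s, q) == pytest.approx(float(mp.zeta(s, q)), rel=1e-11)


def _dfe_fixation_quad(shape, mean2Ns, N, B=1.0):
    """Kimura fixation probability integrated over the Gamma DFE."""
    Ne = N * B

    def pfix_del(g):  # g = |2 Ne s|
        num = np.expm1(g / Ne)
        return num * np.exp(-2 * g) if g > 300 else num / np.expm1(2 * g)

    f = lambda g: stats.gamma.pdf(g, a=shape, scale=mean2Ns * B / shape) * pfix_del(g)
    val, _ = integrate.quad(f, 0, np.inf, limit=500)
    return val


class TestFixationRates:
    def test_zeta_form_equals_dfe_quadrature(self):
        assert dfe_fixation(0.184, 457.0, 500) == pytest.approx(
            _dfe_fixation_quad(0.184, 457.0, 500), rel=1e-6
        )

    def test_zeta_form_random_draws(self, rng):
        for _ in range(20):
            shape = 0.184 * 2 ** rng.uniform(-2, 2)
            mean = rng.uniform(200, 1000)
            N = int(rng.integers(100, 2000))
            B = rng.uniform(0.1, 1.0)
            assert dfe_fixation(shape, mean, N, B) == pytest.approx(
                _dfe_fixation_quad(shape, mean, N, B), rel=1e-6
            )

    def test_neutral_model_rate(self):
        # no beneficial input and a vanishing deleterious load: the only
        # nonsynonymous fixations are effectively neutral, at ~1/2N each
        m = SelectionModel(N=500, n=500, gam_mean=1e-8, B=1.0)
        r = fixation_rates(m)
        assert r.d_weak == 0 and r.d_strong == 0
        assert r.d_neg == pytest.approx(1.0 / 1000.0, rel=1e-3)

    def test_weak_class_uses_kimura_form(self):
        m = SelectionModel(N=500, n=500, p_weak=0.01, B=1.0)
        r = fixation_rates(m)
        s = 10.0 / 1000.0
        kimura = -np.expm1(-2 * s) / -np.expm1(-2 * 10.0)
        assert r.d_weak == pytest.approx(0.5 * 0.01 * kimura, rel=1e-12)

    def test_strong_class_uses_branching_process(self):
        # 2Ns = 500 at N = 500 means s = 0.5; the branching-process fixed
        # point is ~0.5835, well below the diffusion value 1 - e^-1 = 0.632
        p = pfix_beneficial(500.0, 500)
        assert p == pytest.approx(1 - np.exp(-(1.5) * p), abs=1e-12)
        assert 0.57 < p < 0.59

    def test_expected_alpha_limits(self):
        assert expected_alpha(ExpectedRates(0.0, 1.0, 0.0, 0.0)) == (0.0, 0.0, 0.0)
        a, aw, as_ = expected_alpha(ExpectedRates(0.0, 0.0, 0.25, 0.75))
        assert a == 1.0 and aw == 0.25 and as_ == 0.75
        with pytest.raises(ValueError):
            expected_alpha(ExpectedRates(0.0, 0.0, 0.0, 0.0))


class TestSelectionModelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"B": 0.0},
            {"B": 1.2},
            {"gam_shape": -0.1},
            {"s_weak": -1.0},
            {"n": 600, "N": 500},
            {"p_weak": 1.5, "p_strong": 0.8},
            {"nonsyn_fraction": 1.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SelectionModel(**kwargs)
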