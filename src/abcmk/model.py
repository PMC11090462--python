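"""Analytic expectations under directional selection.

Site frequency spectra and fixation rates for a coding locus whose new
nonsynonymous mutations are a mixture of

* deleterious alleles with population-scaled coefficients ``-2Ns`` drawn from
  a Gamma distribution (shape ``gam_shape``, mean magnitude ``gam_mean``),
* two beneficial point masses (weak ``s_weak`` and strong ``s_strong``,
  both positive ``2Ns``), and
* an implicitly neutral remainder.

Background selection enters as an effective population size ``Ne = B * N``:
all frequency spectra and the deleterious/neutral fixation probabilities are
evaluated at ``Ne``, while strongly beneficial fixations are unaffected and
weakly beneficial fixations are handled by the interference factor computed in
:mod:`abcmk.linkage`.

Conventions
-----------
All selection coefficients are stored as positive population-scaled
magnitudes ``2Ns``; the deleterious sign is applied at class level.  The
beneficial mutation probabilities ``p_weak``/``p_strong`` follow the reference
bookkeeping in which the *effective* probability that a new nonsynonymous
mutation belongs to a beneficial class is ``p/2`` (a new mutant is a single
heterozygous copy; the tabulated rates carry the factor two).  The per-class
fixation probability uses Kimura's diffusion form for unscaled ``s < 0.1``
and the branching-process solution ``p = 1 - exp(-(1+s) p)`` for larger
coefficients, where the diffusion form noticeably overshoots.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import stats

from .special import hurwitz_zeta

__all__ = [
    "SelectionModel",
    "ExpectedRates",
    "ExpectedSpectra",
    "expected_sfs_point",
    "expected_sfs_gamma",
    "downsample_binomial",
    "fixation_rates",
    "expected_alpha",
    "pfix_beneficial",
    "dfe_fixation",
    "neutral_fixation",
]

# threshold (unscaled s) above which the branching-process fixation
# probability replaces Kimura's diffusion form
_BRANCHING_S = 0.1
_DFE_QUAD_NODES = 128


@dataclass(frozen=True)
class SelectionModel:
    """One fully parameterised evolutionary scenario.

    Parameters
    ----------
    N : int
        Analytic (diploid) population size; population spectra live on a
        ``2N - 1`` frequency grid.
    n : int
        Diploid sample size; sample spectra have ``2n - 1`` entries.
    gam_shape, gam_mean : float
        Shape and mean magnitude ``|2Ns|`` of the Gamma DFE over deleterious
        coefficients.
    s_weak, s_strong : float
        Positive ``2Ns`` of the weakly / strongly beneficial point masses.
    p_weak, p_strong : float
        Beneficial mutation probabilities in the tabulated (doubled)
        convention; the effective class fractions are ``p/2`` each.
    B : float
        Background-selection strength, expected pi/pi0 in (0, 1].
    theta_coding, theta_flanking : float
        Population-scaled mutation rates (4*N*mu) per site.
    rho : float
        Population-scaled per-base recombination rate (4*N*r).
    L_flank : int
        Length in bp of each of the two flanking deleterious loci.
    t_flank : float
        Magnitude ``|2Nt|`` of the flanking deleterious coefficient.
    nonsyn_fraction : float
        Fraction of new coding mutations that are nonsynonymous.
    """

    N: int = 500
    n: int = 500
    gam_shape: float = 0.184
    gam_mean: float = 457.0
    s_weak: float = 10.0
    s_strong: float = 500.0
    p_weak: float = 0.0
    p_strong: float = 0.0
    B: float = 0.999
    theta_coding: float = 1e-3
    theta_flanking: float = 1e-3
    rho: float = 1e-3
    L_flank: int = 100_000
    t_flank: float = 700.0
    nonsyn_fraction: float = 0.75

    def __post_init__(self):
        if not (0.0 < self.B <= 1.0):
            raise ValueError(f"B must lie in (0, 1], got {self.B}")
        if self.gam_shape <= 0 or self.gam_mean <= 0:
            raise ValueError("Gamma DFE shape and mean must be positive")
        if self.s_weak <= 0 or self.s_strong <= 0:
            raise ValueError("beneficial coefficients must be positive 2Ns")
        if self.p_weak < 0 or self.p_strong < 0:
            raise ValueError("beneficial probabilities must be non-negative")
        if self.frac_weak + self.frac_strong > 1.0:
            raise ValueError("effective beneficial fractions exceed 1")
        if self.n > self.N:
            raise ValueError(f"sample size n={self.n} exceeds N={self.N}")
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if min(self.theta_coding, self.theta_flanking, self.rho) < 0:
            raise ValueError("theta and rho must be non-negative")
        if self.L_flank < 0:
            raise ValueError("L_flank must be non-negative")
        if not (0.0 <= self.nonsyn_fraction <= 1.0):
            raise ValueError("nonsyn_fraction must lie in [0, 1]")

    # effective mutation-class fractions (see module docstring)
    @property
    def frac_weak(self) -> float:
        return 0.5 * self.p_weak

    @property
    def frac_strong(self) -> float:
        return 0.5 * self.p_strong

    @property
    def frac_neg(self) -> float:
        return 1.0 - self.frac_weak - self.frac_strong

    @property
    def frac_neutral(self) -> float:
        """Neutral nonsynonymous fraction (zero: the Gamma DFE carries the
        nearly-neutral mass)."""
        return 0.0

    def with_positive_mass(self, p_weak: float, p_strong: float) -> "SelectionModel":
        return replace(self, p_weak=p_weak, p_strong=p_strong)

    def with_B(self, B: float) -> "SelectionModel":
        return replace(self, B=B)


@dataclass(frozen=True)
class ExpectedRates:
    """Per-nonsynonymous-mutation expected fixation rates by fitness class.

    ``d0`` is the neutral rate, ``d_neg`` the Gamma-deleterious mixture,
    ``d_weak``/``d_strong`` the beneficial point masses (interference
    already applied to the weak class).
    """

    d0: float
    d_neg: float
    d_weak: float
    d_strong: float

    @property
    def total(self) -> float:
        return self.d0 + self.d_neg + self.d_weak + self.d_strong

    @property
    def alpha(self) -> float:
        return (self.d_weak + self.d_strong) / self.total

    @property
    def alpha_weak(self) -> float:
        return self.d_weak / self.total

    @property
    def alpha_strong(self) -> float:
        return self.d_strong / self.total


@dataclass(frozen=True)
class ExpectedSpectra:
    """Class-specific expected frequency spectra (per nonsynonymous site,
    weighted by mutation-class fractions)."""

    psi0: np.ndarray
    psi_neg: np.ndarray
    psi_pos: np.ndarray

    @property
    def nonsyn_total(self) -> np.ndarray:
        return self.psi0 + self.psi_neg + self.psi_pos

    def downsampled(self, n: int) -> "ExpectedSpectra":
        return ExpectedSpectra(
            psi0=downsample_binomial(self.psi0, n),
            psi_neg=downsample_binomial(self.psi_neg, n),
            psi_pos=downsample_binomial(self.psi_pos, n),
        )


def expected_sfs_point(s2N: float, theta: float, N: int) -> np.ndarray:
    """Equilibrium diffusion SFS for a point selection coefficient.

    Evaluates ``theta / (x (1-x)) * (e^S - e^{S x}) / (e^S - 1)`` with
    ``S = 4Ns = 2 * s2N`` at ``x = i/(2N)``, ``i = 1..2N-1``.  The three
    algebraic branches below are each overflow-free (all exponents
    non-positive), so the formula is stable for arbitrarily strong selection;
    the ``S -> 0`` limit is taken analytically.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    x = np.arange(1, 2 * N) / (2.0 * N)
    S = 2.0 * float(s2N)
    if abs(S) < 1e-8:
        g = 1.0 - x
    elif S > 0:
        g = np.expm1(S * (x - 1.0)) / np.expm1(-S)
    else:
        g = (np.expm1(S) - np.expm1(S * x)) / np.expm1(S)
    out = theta * g / (x * (1.0 - x))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite SFS for s2N={s2N}")
    return out


def _gamma_dfe_nodes(shape: float, mean: float, n_nodes: int = _DFE_QUAD_NODES):
    """Gauss-Legendre nodes in the Gamma quantile domain.

    Integrating ``f`` against the DFE becomes a plain average of
    ``f(Q(u))`` over uniform ``u``; the quantile substitution absorbs the
    integrable density singularity at zero that small shapes produce.
    """
    u, w = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (u + 1.0)
    w = 0.5 * w
    gam = stats.gamma.ppf(u, a=shape, scale=mean / shape)
    return gam, w


def expected_sfs_gamma(model: SelectionModel) -> ExpectedSpectra:
    """Expected class spectra on the population grid under the model's DFE.

    The deleterious spectrum integrates the point SFS over the Gamma DFE by
    fixed-order quadrature in the quantile domain; the beneficial spectrum is
    the weighted sum of the two point masses.  All classes are evaluated at
    the effective size ``Ne = B N`` (scaled theta and scaled coefficients).
    """
    B = model.B
    theta = model.theta_coding * B  # 4*Ne*mu
    gam, w = _gamma_dfe_nodes(model.gam_shape, model.gam_mean)
    psi_neg = np.zeros(2 * model.N - 1)
    for g_i, w_i in zip(gam, w):
        psi_neg += w_i * expected_sfs_point(-B * g_i, theta, model.N)
    if not np.all(np.isfinite(psi_neg)):
        raise FloatingPointError(
            "DFE spectrum integration failed for "
            f"shape={model.gam_shape}, mean={model.gam_mean}"
        )
    psi_neg *= model.frac_neg
    psi_pos = model.frac_weak * expected_sfs_point(B * model.s_weak, theta, model.N)
    psi_pos += model.frac_strong * expected_sfs_point(B * model.s_strong, theta, model.N)
    psi0 = model.frac_neutral * expected_sfs_point(0.0, theta, model.N)
    return ExpectedSpectra(psi0=psi0, psi_neg=psi_neg, psi_pos=psi_pos)


@lru_cache(maxsize=8)
def _projection_matrix(N: int, n: int) -> np.ndarray:
    """Binomial downsampling matrix from the 2N-1 population grid to the
    2n-1 sample grid (monomorphic sample classes dropped)."""
    p = np.arange(1, 2 * N) / (2.0 * N)
    j = np.arange(1, 2 * n)
    return stats.binom.pmf(j[:, None], 2 * n, p[None, :])


def downsample_binomial(pop_spectrum: np.ndarray, n: int) -> np.ndarray:
    """Project a population spectrum onto a sample of ``2n`` chromosomes.

    Entry ``j`` is ``sum_i pop[i] * Binom(j; 2n, i/(2N))`` — the expected
    sample SFS after binomial sampling of chromosomes.
    """
    pop_spectrum = np.asarray(pop_spectrum, dtype=float)
    if pop_spectrum.ndim != 1 or pop_spectrum.size % 2 != 1:
        raise ValueError("population spectrum must have odd length 2N-1")
    N = (pop_spectrum.size + 1) // 2
    if n > N:
        raise ValueError(f"cannot downsample to n={n} > N={N}")
    if n < 1:
        raise ValueError("n must be at least 1")
    return _projection_matrix(N, n) @ pop_spectrum


def pfix_beneficial(s2N, N):
    """Fixation probability of a new beneficial mutant (vectorised).

    Kimura's diffusion result ``(1 - e^{-2s}) / (1 - e^{-4Ns})`` for unscaled
    ``s = s2N / 2N`` below 0.1; for stronger selection the diffusion form
    overshoots and the branching-process fixed point ``p = 1 - e^{-(1+s)p}``
    is used instead.
    """
    s2N = np.asarray(s2N, dtype=float)
    if np.any(s2N < 0):
        raise ValueError("pfix_beneficial expects positive scaled coefficients")
    s = s2N / (2.0 * N)
    tiny = s2N < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        kimura = np.where(
            tiny, 1.0 / (2.0 * N), -np.expm1(-2.0 * s) / -np.expm1(-2.0 * s2N)
        )
    p = -np.expm1(-(1.0 + s))
    for _ in range(200):
        p = -np.expm1(-(1.0 + s) * p)
    out = np.where(s < _BRANCHING_S, kimura, p)
    return out if out.ndim else float(out)


def dfe_fixation(shape, mean2Ns, N, B=1.0):
    """Mean fixation probability of a Gamma-deleterious mutation, closed form.

    With ``beta = shape / mean`` the Gamma rate over ``|2Ns|``, the average of
    Kimura's fixation probability over the DFE (at effective size ``B*N``)
    telescopes into a difference of Hurwitz zeta values:

        2^-shape B^-shape beta^shape *
            [ zeta(shape, 1 - 1/(2NB) + beta/(2B)) - zeta(shape, 1 + beta/(2B)) ]

    Agreement with direct quadrature over the DFE is part of the test suite.
    Vectorised over all arguments.
    """
    shape = np.asarray(shape, dtype=float)
    beta = shape / np.asarray(mean2Ns, dtype=float)
    B = np.asarray(B, dtype=float)
    q_hi = 1.0 + beta / (2.0 * B)
    q_lo = q_hi - 1.0 / (2.0 * np.asarray(N, dtype=float) * B)
    out = (
        2.0**-shape
        * B**-shape
        * beta**shape
        * (hurwitz_zeta(shape, q_lo) - hurwitz_zeta(shape, q_hi))
    )
    return out if out.ndim else float(out)


def neutral_fixation(N, B=1.0) -> float:
    """Neutral fixation probability at the effective size, 1/(2 Ne)."""
    return 1.0 / (2.0 * N * B)


def fixation_rates(model: SelectionModel, phi_weak: float | None = None) -> ExpectedRates:
    """Expected per-nonsynonymous-mutation fixation rates for each class.

    ``phi_weak`` is the interference reduction applied to the weakly
    beneficial class; when omitted it is derived from the model's flanking
    parameters so that the neutral reduction matches ``model.B`` (see
    :func:`abcmk.linkage.interference_reduction`).
    """
    if phi_weak is None:
        from . import linkage  # deferred: linkage imports nothing from here

        if model.B < 1.0:
            mu_f = linkage.solve_flanking_mu(
                model.B, model.t_flank, model.rho, model.L_flank, model.N
            )
            phi_weak = linkage.interference_reduction(
                model.t_flank, model.s_weak, mu_f, model.rho, model.L_flank, model.N
            )
        else:
            phi_weak = 1.0
    d0 = model.frac_neutral * neutral_fixation(model.N, model.B)
    d_neg = model.frac_neg * dfe_fixation(
        model.gam_shape, model.gam_mean, model.N, model.B
    )
    d_weak = model.frac_weak * phi_weak * pfix_beneficial(model.s_weak, model.N)
    d_strong = model.frac_strong * pfix_beneficial(model.s_strong, model.N)
    return ExpectedRates(d0=d0, d_neg=d_neg, d_weak=d_weak, d_strong=d_strong)


def expected_alpha(rates: ExpectedRates) -> tuple[float, float, float]:
    """Decompose the expected adaptive substitution proportion.

    Returns ``(alpha, alpha_weak, alpha_strong)`` where alpha is the share of
    nonsynonymous fixations driven by positive selection.
    """
    if rates.total <= 0:
        raise ValueError("all fixation-rate components are zero")
    return rates.alpha, rates.alpha_weak, rates.alpha_strong
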