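"""Scenario solving: from target adaptation rates to mutation probabilities.

The proportion of adaptive nonsynonymous substitutions is a model *output*:
given a DFE, beneficial coefficients and a target ``(alpha, alpha_weak)`` in
the absence of background selection, the beneficial mutation probabilities
``(p_weak, p_strong)`` must be solved for.  Because the expected fixation
rates are linear in the two probabilities, the solve is exact linear algebra;
the achieved alpha round-trips to machine precision and is checked against
the 1e-6 contract.

This module also hosts the uniform prior ranges used to precompute the
parameter grid that serves as the ABC reference table.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import linkage
from .model import (
    ExpectedRates,
    SelectionModel,
    dfe_fixation,
    expected_sfs_gamma,
    fixation_rates,
    pfix_beneficial,
)

__all__ = [
    "PriorSpec",
    "SolvedScenario",
    "solve_positive_mass",
    "solve_scenario",
    "realized_alpha_under_B",
    "build_parameter_grid",
    "GRID_COLUMNS",
]

SOLVER_TOL = 1e-6


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior ranges for the ABC reference grid.

    Defaults are the demographic-equilibrium analysis settings: alpha in
    [0, 0.9]; weak/strong coefficients 2Ns in [1, 10] and [200, 2000]; mean
    deleterious magnitude |2Ns| in [200, 1000]; DFE shape 0.184 * 2^u with
    u in [-2, 2]; flanking coefficient magnitude |2Nt| in [500, 1000]; B in
    [0.1, 0.999].  ``alpha_weak`` is drawn uniformly on [0, alpha] for each
    draw (least-informative partition of alpha).
    """

    alpha: tuple[float, float] = (0.0, 0.9)
    s_weak: tuple[float, float] = (1.0, 10.0)
    s_strong: tuple[float, float] = (200.0, 2000.0)
    gam_mean: tuple[float, float] = (200.0, 1000.0)
    shape_log2: tuple[float, float] = (-2.0, 2.0)
    shape_base: float = 0.184
    t_mag: tuple[float, float] = (500.0, 1000.0)
    B: tuple[float, float] = (0.1, 0.999)
    N: int = 500
    n: int = 500
    rho: float = 1e-3
    L_flank: int = 100_000

    def __post_init__(self):
        for name in ("alpha", "s_weak", "s_strong", "gam_mean", "shape_log2", "t_mag", "B"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValueError(f"empty prior range for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class SolvedScenario:
    """A SelectionModel with solved beneficial probabilities plus its
    no-BGS rates and (lazily computed) expected spectra."""

    model: SelectionModel
    rates_b1: ExpectedRates

    @property
    def alpha(self) -> float:
        return self.rates_b1.alpha

    @property
    def alpha_weak(self) -> float:
        return self.rates_b1.alpha_weak

    def rates(self) -> ExpectedRates:
        """Rates realized at the model's own B."""
        return fixation_rates(self.model)

    def spectra(self, downsample: bool = True):
        sp = expected_sfs_gamma(self.model)
        return sp.downsampled(self.model.n) if downsample else sp


def _solve_vec(alpha, alpha_weak, A, C, E):
    """Vectorised exact solve of the rate decomposition.

    ``A``/``C`` are the per-class weak/strong fixation probabilities, ``E``
    the DFE-averaged deleterious fixation probability; returns probabilities
    in the tabulated (doubled) convention.
    """
    alpha = np.asarray(alpha, dtype=float)
    alpha_weak = np.asarray(alpha_weak, dtype=float)
    alpha_strong = alpha - alpha_weak
    with np.errstate(divide="ignore", invalid="ignore"):
        Rw = np.where(alpha < 1, alpha_weak * E / ((1.0 - alpha) * 0.5 * A), np.inf)
        Rs = np.where(alpha < 1, alpha_strong * E / ((1.0 - alpha) * 0.5 * C), np.inf)
    frac_neg = 1.0 / (1.0 + 0.5 * (Rw + Rs))
    return Rw * frac_neg, Rs * frac_neg


def solve_positive_mass(
    target_alpha: float, target_alpha_weak: float, model: SelectionModel
) -> tuple[float, float]:
    """Beneficial mutation probabilities achieving target (alpha, alpha_W).

    Solved in the no-BGS reference (B = 1).  Raises if the target is outside
    [0, 1) or the implied beneficial fractions are infeasible.
    """
    if not (0.0 <= target_alpha_weak <= target_alpha):
        raise ValueError("need 0 <= alpha_weak <= alpha")
    if target_alpha >= 1.0:
        raise ValueError(
            "alpha >= 1 is unattainable: the maximum attainable alpha "
            "approaches 1 only as the deleterious fraction vanishes"
        )
    A = pfix_beneficial(model.s_weak, model.N)
    C = pfix_beneficial(model.s_strong, model.N)
    E = dfe_fixation(model.gam_shape, model.gam_mean, model.N, B=1.0)
    p_weak, p_strong = _solve_vec(target_alpha, target_alpha_weak, A, C, E)
    p_weak, p_strong = float(p_weak), float(p_strong)
    check = fixation_rates(model.with_positive_mass(p_weak, p_strong).with_B(1.0))
    if abs(check.alpha - target_alpha) > SOLVER_TOL or abs(
        check.alpha_weak - target_alpha_weak
    ) > SOLVER_TOL:
        raise RuntimeError(
            f"solver residual exceeds {SOLVER_TOL}: achieved "
            f"({check.alpha}, {check.alpha_weak})"
        )
    return p_weak, p_strong


def solve_scenario(
    target_alpha: float, target_alpha_weak: float, model: SelectionModel
) -> SolvedScenario:
    """Solve the beneficial masses and package the resulting scenario."""
    p_weak, p_strong = solve_positive_mass(target_alpha, target_alpha_weak, model)
    solved = model.with_positive_mass(p_weak, p_strong)
    rates_b1 = fixation_rates(solved.with_B(1.0))
    return SolvedScenario(model=solved, rates_b1=rates_b1)


def realized_alpha_under_B(
    scenario: SolvedScenario, B: float, context: linkage.LinkageContext | None = None
) -> tuple[float, float, float]:
    """Adaptation rates realized under background selection of strength B.

    The deleterious (and neutral) classes are recomputed at ``Ne = B N``; the
    weak class is scaled by the interference factor Phi at the flanking
    mutation rate that produces this B; the strong class is unchanged.
    """
    model = scenario.model.with_B(B)
    if context is not None:
        phi = linkage.interference_reduction(
            context.t_mag, model.s_weak, context.mu_flank, context.rho,
            context.L_flank, model.N,
        )
        rates = fixation_rates(model, phi_weak=phi)
    else:
        rates = fixation_rates(model)
    return rates.alpha, rates.alpha_weak, rates.alpha_strong


GRID_COLUMNS = [
    "alpha_target", "alpha_weak_target", "s_weak", "s_strong", "gam_mean",
    "gam_shape", "t_mag", "B", "p_weak", "p_strong",
    "alpha", "alpha_weak", "alpha_strong",
    "d_weak", "d_strong", "d_neg", "d_syn",
]


def build_parameter_grid(
    priors: PriorSpec, n_draws: int, seed: int
) -> pd.DataFrame:
    """Draw and solve ``n_draws`` scenarios from the prior (vectorised).

    Each row carries the drawn parameters, the solved beneficial mutation
    probabilities (solved at B = 1), and the fixation rates and adaptation
    proportions realized at the drawn B — the quantities the ABC posterior is
    formed over.  Deterministic given the seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    N = priors.N
    alpha = rng.uniform(*priors.alpha, n_draws)
    alpha_weak = rng.uniform(0.0, 1.0, n_draws) * alpha
    s_weak = rng.uniform(*priors.s_weak, n_draws)
    s_strong = rng.uniform(*priors.s_strong, n_draws)
    gam_mean = rng.uniform(*priors.gam_mean, n_draws)
    gam_shape = priors.shape_base * 2.0 ** rng.uniform(*priors.shape_log2, n_draws)
    t_mag = rng.uniform(*priors.t_mag, n_draws)
    B = rng.uniform(*priors.B, n_draws)

    A = pfix_beneficial(s_weak, N)
    C = pfix_beneficial(s_strong, N)
    E1 = dfe_fixation(gam_shape, gam_mean, N, B=1.0)
    p_weak, p_strong = _solve_vec(alpha, alpha_weak, A, C, E1)

    # realized rates at the drawn B
    mu_f = linkage.solve_flanking_mu(B, t_mag, priors.rho, priors.L_flank, N)
    phi_w = linkage.interference_reduction(t_mag, s_weak, mu_f, priors.rho, priors.L_flank, N)
    EB = dfe_fixation(gam_shape, gam_mean, N, B=B)
    d_weak = 0.5 * p_weak * phi_w * A
    d_strong = 0.5 * p_strong * C
    d_neg = (1.0 - 0.5 * (p_weak + p_strong)) * EB
    d_syn = 1.0 / (2.0 * N * B)
    total = d_weak + d_strong + d_neg
    grid = pd.DataFrame(
        {
            "alpha_target": alpha, "alpha_weak_target": alpha_weak,
            "s_weak": s_weak, "s_strong": s_strong,
            "gam_mean": gam_mean, "gam_shape": gam_shape,
            "t_mag": t_mag, "B": B,
            "p_weak": p_weak, "p_strong": p_strong,
            "alpha": (d_weak + d_strong) / total,
            "alpha_weak": d_weak / total,
            "alpha_strong": d_strong / total,
            "d_weak": d_weak, "d_strong": d_strong,
            "d_neg": d_neg, "d_syn": d_syn,
        }
    )
    grid.attrs["priors"] = priors
    grid.attrs["seed"] = seed
    return grid
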