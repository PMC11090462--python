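"""Approximate Bayesian Computation over the precomputed scenario grid.

For every prior draw the analytic class spectra are rebuilt, the observed
dataset's per-bin polymorphism totals and total fixation count are
re-partitioned between synonymous and nonsynonymous classes according to the
draw's expectations (Poisson process variance on top of the binomial sampling
variance already in the expected spectra), and the cumulative alpha(x) values
at a small set of derived-allele-count thresholds form the summary vector.
Rejection keeps the nearest ``tolerance`` fraction in MAD-standardised
Euclidean distance, followed by the standard weighted local-linear regression
adjustment and kernel-density posterior summaries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .mk import cumulative_alpha
from .model import _projection_matrix
from .sampling import ObservedCounts
from .solver import PriorSpec

__all__ = [
    "default_x_grid",
    "summarize_for_abc",
    "simulate_summaries",
    "abc_reject",
    "loclinear_adjust",
    "posterior_summary",
    "bootstrap_datasets",
    "infer",
    "PosteriorSample",
    "POSTERIOR_PARAMS",
]

POSTERIOR_PARAMS = ["alpha", "alpha_weak", "alpha_strong", "gam_mean", "gam_shape", "B"]

_X_GRIDS = {
    "large": (2, 5, 20, 50, 200, 661, 925),
    "medium": (2, 5, 20, 50, 200, 500, 700),
    "small": (2, 4, 5, 10, 20, 30, 50, 70),
}


def default_x_grid(n: int) -> tuple[int, ...]:
    """Summary thresholds by sample-size class (derived allele counts in a
    sample of 2n chromosomes; singletons are never used)."""
    if 2 * n > 1000:
        return _X_GRIDS["large"]
    if 2 * n > 100:
        return _X_GRIDS["medium"]
    return _X_GRIDS["small"]


def summarize_for_abc(curve, x_points) -> np.ndarray:
    """Ordered alpha(x) values at the configured thresholds."""
    if 1 in x_points:
        raise ValueError("singletons are excluded from ABC summaries")
    return np.array([curve.at(x) for x in x_points])


def _sfs_shape(S, x):
    """Unit-theta SFS factor g(x; S)/(x(1-x)) broadcast over rows of S."""
    S = np.atleast_1d(np.asarray(S, dtype=float))[:, None]
    small = np.abs(S) < 1e-8
    Ssafe = np.where(small, 1.0, S)
    with np.errstate(over="ignore", invalid="ignore"):
        pos = np.expm1(Ssafe * (x - 1.0)) / np.expm1(-Ssafe)
        neg = (np.expm1(Ssafe) - np.expm1(Ssafe * x)) / np.expm1(Ssafe)
    g = np.where(small, 1.0 - x, np.where(S > 0, pos, neg))
    return g / (x * (1.0 - x))


# scaled-coefficient basis for fast per-draw spectra: |4Ns| from well below
# nearly-neutral to far beyond the strongest plausible prior draw
_BASIS_MIN, _BASIS_MAX, _BASIS_K = 1e-3, 5e4, 384


@lru_cache(maxsize=4)
def _spectra_basis(N: int, n: int):
    """Projected sample-grid spectra on a log grid of |S| = |4Ns|.

    Per-draw spectra then become weighted combinations of these rows
    (Gamma bin masses for the deleterious mixture, log-linear interpolation
    for the beneficial point masses), replacing millions of transcendental
    evaluations by one BLAS product per chunk.
    """
    x_pop = np.arange(1, 2 * N) / (2.0 * N)
    proj = _projection_matrix(N, n)
    S = np.geomspace(_BASIS_MIN, _BASIS_MAX, _BASIS_K)
    edges = np.concatenate([[0.0], np.sqrt(S[1:] * S[:-1]), [np.inf]])
    neg = _sfs_shape(-S, x_pop) @ proj.T
    pos = _sfs_shape(S, x_pop) @ proj.T
    neutral = proj @ _sfs_shape(0.0, x_pop)[0]
    return S, edges, neg, pos, neutral


def _interp_pos_rows(S_query, S, pos):
    """Log-linear interpolation of beneficial basis rows at |4Ns| values."""
    logS = np.log(S)
    q = np.clip(np.log(S_query), logS[0], logS[-1])
    idx = np.clip(np.searchsorted(logS, q) - 1, 0, S.size - 2)
    t = (q - logS[idx]) / (logS[idx + 1] - logS[idx])
    return (1.0 - t)[:, None] * pos[idx] + t[:, None] * pos[idx + 1]


def simulate_summaries(
    grid: pd.DataFrame,
    observed: ObservedCounts,
    seed: int,
    x_points=None,
    chunk: int = 2048,
) -> np.ndarray:
    """Sampled cumulative alpha(x) summaries for every grid row.

    Conditions on the observed per-bin total SFS (nonsynonymous plus
    synonymous) and total divergence, splitting both according to each row's
    expectations; rows whose sampled summaries are undefined (zero counts at
    a threshold) come back NaN and are treated as infinitely distant by
    rejection.
    """
    priors: PriorSpec = grid.attrs.get("priors") or PriorSpec()
    N, n = priors.N, priors.n
    if n != observed.n:
        raise ValueError(f"grid sample size n={n} != data n={observed.n}")
    if x_points is None:
        x_points = default_x_grid(n)
    x_idx = np.asarray(x_points, dtype=int) - 1
    rng = np.random.default_rng(seed)

    S_basis, S_edges, basis_neg, basis_pos, psi_syn = _spectra_basis(N, n)

    T_sfs = (observed.sfs_nonsyn + observed.sfs_syn).astype(float)
    D_tot = observed.DN + observed.DS
    fr_n = 0.75

    m = len(grid)
    out = np.full((m, x_idx.size), np.nan)
    cols = grid[["gam_shape", "gam_mean", "B", "s_weak", "s_strong",
                 "p_weak", "p_strong", "d_weak", "d_strong", "d_neg", "d_syn"]].to_numpy()
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        sh, mn, B, sw, ss, pw, ps_, dW, dS_, dNeg, dSyn = cols[lo:hi].T
        # Gamma mass per basis bin: the draw's DFE over |4Ne s| = 2 B |2Ns|
        gam_edges = S_edges[None, :] / (2.0 * B[:, None])
        cdf = stats.gamma.cdf(gam_edges, a=sh[:, None], scale=(mn / sh)[:, None])
        w_bins = np.diff(cdf, axis=1)
        psi_neg = w_bins @ basis_neg + cdf[:, :1] * psi_syn[None, :]
        psi_n = (1.0 - 0.5 * (pw + ps_))[:, None] * psi_neg
        psi_n += 0.5 * pw[:, None] * _interp_pos_rows(2.0 * B * sw, S_basis, basis_pos)
        psi_n += 0.5 * ps_[:, None] * _interp_pos_rows(2.0 * B * ss, S_basis, basis_pos)

        wN = fr_n * psi_n
        wS = (1.0 - fr_n) * psi_syn[None, :]
        share = wN / (wN + wS)
        pn = rng.poisson(T_sfs[None, :] * share)
        psn = rng.poisson(T_sfs[None, :] * (1.0 - share))

        rate_n = fr_n * (dW + dS_ + dNeg)
        rate_s = (1.0 - fr_n) * dSyn
        dn = rng.poisson(D_tot * rate_n / (rate_n + rate_s))
        ds = rng.poisson(D_tot * rate_s / (rate_n + rate_s))

        PN = np.cumsum(pn[:, ::-1], axis=1)[:, ::-1][:, x_idx].astype(float)
        PS = np.cumsum(psn[:, ::-1], axis=1)[:, ::-1][:, x_idx].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = 1.0 - (ds / dn)[:, None] * (PN / PS)
        vals[(PS <= 0) | (dn[:, None] <= 0)] = np.nan
        out[lo:hi] = vals
    return out


@dataclass(frozen=True)
class AcceptResult:
    indices: np.ndarray
    distances: np.ndarray    # distances of the accepted rows (ascending)
    scale: np.ndarray        # per-dimension MAD used for standardisation


def abc_reject(
    observed: np.ndarray,
    simulated: np.ndarray,
    tolerance: float,
) -> AcceptResult:
    """Keep the ceil(tolerance * rows) draws nearest to the observed summary.

    Distances are Euclidean after standardising each summary dimension by its
    median absolute deviation across the simulations; zero-spread dimensions
    are dropped with a warning, and rows with non-finite summaries are never
    accepted.
    """
    if not (0.0 < tolerance <= 1.0):
        raise ValueError("tolerance must lie in (0, 1]")
    observed = np.asarray(observed, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if simulated.shape[1] != observed.size:
        raise ValueError("summary dimensions disagree")
    finite = np.isfinite(simulated).all(axis=1)
    mad = stats.median_abs_deviation(simulated[finite], axis=0)
    keep_dim = mad > 0
    if not keep_dim.all():
        warnings.warn(
            f"dropping {int((~keep_dim).sum())} zero-spread summary dimension(s)",
            stacklevel=2,
        )
    if not keep_dim.any():
        raise ValueError("all summary dimensions are degenerate")
    dev = (simulated[:, keep_dim] - observed[keep_dim]) / mad[keep_dim]
    dist = np.sqrt(np.sum(dev * dev, axis=1))
    dist[~finite] = np.inf
    n_accept = int(np.ceil(tolerance * simulated.shape[0]))
    order = np.argsort(dist, kind="stable")[:n_accept]
    return AcceptResult(indices=order, distances=dist[order], scale=mad)


def loclinear_adjust(
    accepted_params: pd.DataFrame,
    accepted_summaries: np.ndarray,
    observed: np.ndarray,
    distances: np.ndarray | None = None,
    ridge: float = 1e-8,
) -> pd.DataFrame:
    """Weighted local-linear regression adjustment of accepted draws.

    Each parameter is regressed on the (centred) summaries with Epanechnikov
    weights in distance; draws are translated along the fitted plane to the
    observed summary point.  Deterministic.  A small ridge penalty guards
    singular designs.
    """
    S = np.asarray(accepted_summaries, dtype=float) - np.asarray(observed, dtype=float)
    theta = accepted_params.to_numpy(dtype=float)
    if theta.shape[0] < S.shape[1] + 2:
        raise ValueError("need at least dim(summaries)+2 accepted draws")
    if distances is None:
        w = np.ones(S.shape[0])
    else:
        dmax = distances.max()
        if dmax <= 0:
            w = np.ones(S.shape[0])
        else:
            w = 1.0 - (distances / dmax) ** 2
            w = np.maximum(w, 1e-12)
    X = np.column_stack([np.ones(S.shape[0]), S])
    XtW = X.T * w
    gram = XtW @ X
    gram[np.diag_indices_from(gram)] += ridge
    coef = np.linalg.solve(gram, XtW @ theta)  # (1+dim) x n_params
    adjusted = theta - S @ coef[1:]
    return pd.DataFrame(adjusted, columns=accepted_params.columns)


def posterior_summary(draws: pd.DataFrame) -> pd.DataFrame:
    """Mode (Gaussian KDE maximum, Silverman bandwidth) and central 95%
    interval for each parameter column."""
    if len(draws) < 100:
        raise ValueError("need at least 100 posterior draws to summarise")
    rows = {}
    for col in draws.columns:
        v = draws[col].to_numpy(dtype=float)
        lo, hi = np.quantile(v, [0.025, 0.975])
        if np.ptp(v) == 0:
            mode = v[0]
        else:
            kde = stats.gaussian_kde(v, bw_method="silverman")
            grid = np.linspace(v.min(), v.max(), 512)
            mode = grid[np.argmax(kde(grid))]
        rows[col] = {"mode": float(mode), "ci_low": float(lo), "ci_high": float(hi)}
    return pd.DataFrame(rows).T


def bootstrap_datasets(
    genes: list[ObservedCounts], n_boot: int, seed: int
) -> list[ObservedCounts]:
    """Gene-level bootstrap: resample genes with replacement and pool."""
    if not genes:
        raise ValueError("empty gene list")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(genes), size=len(genes))
        out.append(ObservedCounts.pooled([genes[i] for i in idx]))
    return out


@dataclass
class PosteriorSample:
    """Accepted and regression-adjusted draws with posterior summaries."""

    accepted: pd.DataFrame
    adjusted: pd.DataFrame
    summary: pd.DataFrame
    tolerance: float
    n_clamped: int = 0


def infer(
    observed: ObservedCounts,
    grid: pd.DataFrame,
    seed: int,
    tolerance: float = 0.025,
    x_points=None,
    max_daf: float = 1.0,
    params: list[str] | None = None,
) -> PosteriorSample:
    """End-to-end ABC: simulate summaries, reject, adjust, summarise.

    Adjusted alpha components are clamped to [0, 1]; the number of clamped
    values is reported on the result.
    """
    if x_points is None:
        x_points = default_x_grid(observed.n)
    obs_vec = summarize_for_abc(cumulative_alpha(observed, max_daf=max_daf), x_points)
    sims = simulate_summaries(grid, observed, seed=seed, x_points=x_points)
    acc = abc_reject(obs_vec, sims, tolerance)
    cols = params or POSTERIOR_PARAMS
    accepted = grid.iloc[acc.indices][cols].reset_index(drop=True)
    adjusted = loclinear_adjust(
        accepted, sims[acc.indices], obs_vec, distances=acc.distances
    )
    n_clamped = 0
    for col in ("alpha", "alpha_weak", "alpha_strong"):
        if col in adjusted:
            bad = (adjusted[col] < 0) | (adjusted[col] > 1)
            n_clamped += int(bad.sum())
            adjusted[col] = adjusted[col].clip(0.0, 1.0)
    return PosteriorSample(
        accepted=accepted,
        adjusted=adjusted,
        summary=posterior_summary(adjusted),
        tolerance=tolerance,
        n_clamped=n_clamped,
    )
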