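"""MK-family estimators of the adaptive substitution proportion.

``alpha(x)`` curves come in two flavours:

* *cumulative* — ``PN(x)``/``PS(x)`` count polymorphisms at derived allele
  count >= x (the summary-statistic form used for ABC; it scales well with
  sample size because both cumulative counts share an asymptote), and
* *binned* — per-frequency-class counts, the form used by the classic
  asymptotic-MK point estimate.

The asymptotic estimate fits ``alpha(x) = a + b * exp(-c x)`` over the curve
(frequency axis normalised to (0, 1], singletons excluded by default) and
reads off the fitted value at ``x = 1``, which removes the footprint of
weakly deleterious polymorphism.  Weakly *beneficial* polymorphism bends the
curve down at high frequency and biases the estimate low — quantifying (and
then modelling) that bias is the point of the surrounding package.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .sampling import ObservedCounts

__all__ = [
    "AlphaCurve",
    "AmkFit",
    "cumulative_alpha",
    "binned_alpha",
    "amk_fit",
    "classic_mk",
    "fww_mk",
]


@dataclass(frozen=True)
class AlphaCurve:
    """alpha(x) evaluated on the derived-allele-count grid 1..2n-1.

    ``valid`` flags thresholds where the synonymous count is positive (and
    within the polarization guard); values elsewhere are NaN, never silently
    dropped.
    """

    x: np.ndarray          # derived-allele-count thresholds
    values: np.ndarray
    valid: np.ndarray
    n: int
    cumulative: bool

    def at(self, x_point: int) -> float:
        idx = int(x_point) - 1
        if idx < 0 or idx >= self.values.size:
            raise ValueError(f"threshold {x_point} outside 1..{self.values.size}")
        if not self.valid[idx]:
            raise ValueError(f"alpha(x) undefined at x={x_point} (PS(x)=0 or masked)")
        return float(self.values[idx])


def _counts_with_guard(data: ObservedCounts, max_daf: float):
    if data.DN <= 0 or data.DS <= 0:
        raise ValueError("alpha(x) requires positive DN and DS")
    nn = 2 * data.n
    freq = np.arange(1, nn) / nn
    keep = freq <= max_daf
    return data.sfs_nonsyn * keep, data.sfs_syn * keep


def cumulative_alpha(data: ObservedCounts, max_daf: float = 1.0) -> AlphaCurve:
    """Cumulative alpha(x): 1 - (DS/DN) * PN(>=x)/PS(>=x).

    Variants above ``max_daf`` (polarization guard; 0.7 is the conventional
    cutoff for empirical unfolded data) are excluded from the counts.
    """
    pn, ps = _counts_with_guard(data, max_daf)
    PN = np.cumsum(pn[::-1])[::-1].astype(float)
    PS = np.cumsum(ps[::-1])[::-1].astype(float)
    valid = PS > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 1.0 - (data.DS / data.DN) * (PN / PS)
    vals[~valid] = np.nan
    return AlphaCurve(
        x=np.arange(1, 2 * data.n), values=vals, valid=valid, n=data.n, cumulative=True
    )


def binned_alpha(data: ObservedCounts, max_daf: float = 1.0) -> AlphaCurve:
    """Per-frequency-bin alpha(x) (classic asymptotic-MK form)."""
    pn, ps = _counts_with_guard(data, max_daf)
    valid = ps > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 1.0 - (data.DS / data.DN) * (pn / ps.astype(float))
    vals = np.where(valid, vals, np.nan)
    return AlphaCurve(
        x=np.arange(1, 2 * data.n), values=vals, valid=valid, n=data.n, cumulative=False
    )


@dataclass(frozen=True)
class AmkFit:
    a: float
    b: float
    c: float
    alpha_hat: float      # fitted curve at x = 1


_C_STARTS = (1.0, 2.0, 5.0, 10.0, 50.0)


def amk_fit(curve: AlphaCurve, exclude_singletons: bool = True) -> AmkFit:
    """Asymptotic-MK exponential fit ``a + b e^{-c x}`` evaluated at x = 1.

    ``x`` is the derived allele count normalised by 2n.  Nonlinear least
    squares with multi-start over the decay rate; ties broken by residual
    norm.
    """
    mask = curve.valid.copy()
    if exclude_singletons:
        mask[0] = False
    x = curve.x[mask] / (2.0 * curve.n)
    y = curve.values[mask]
    if x.size < 4:
        raise ValueError(f"need >= 4 usable alpha(x) points, have {x.size}")
    best = None
    last_err = None
    for c0 in _C_STARTS:
        p0 = [y[-1], y[0] - y[-1], c0]
        try:
            popt, _ = optimize.curve_fit(
                lambda t, a, b, c: a + b * np.exp(-c * t), x, y, p0=p0, maxfev=20000
            )
        except RuntimeError as err:  # non-convergence for this start
            last_err = err
            continue
        resid = float(np.sum((y - (popt[0] + popt[1] * np.exp(-popt[2] * x))) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError(
            f"exponential fit failed from all starts {_C_STARTS}: {last_err}"
        )
    a, b, c = (float(v) for v in best[0])
    return AmkFit(a=a, b=b, c=c, alpha_hat=a + b * np.exp(-c))


def classic_mk(data: ObservedCounts) -> float:
    """Point estimate 1 - (PN/PS)(DS/DN) using all polymorphism."""
    if data.DN <= 0 or data.DS <= 0 or data.PS <= 0:
        raise ValueError("classic MK requires positive DN, DS and PS")
    return 1.0 - (data.PN / data.PS) * (data.DS / data.DN)


def fww_mk(data: ObservedCounts, daf_threshold: float = 0.15) -> float:
    """Frequency-thresholded MK: drop variants below a derived allele
    frequency before applying the classic estimator."""
    if not (0.0 <= daf_threshold < 1.0):
        raise ValueError("daf_threshold must lie in [0, 1)")
    nn = 2 * data.n
    keep = np.arange(1, nn) / nn >= daf_threshold
    PN = float(data.sfs_nonsyn[keep].sum())
    PS = float(data.sfs_syn[keep].sum())
    if PS <= 0:
        raise ValueError("threshold removed all synonymous polymorphism")
    return 1.0 - (PN / PS) * (data.DS / data.DN)
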