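"""Special functions not covered by scipy.

scipy.special.zeta only supports the Hurwitz zeta for exponent > 1, while the
closed form for the mean fixation probability of Gamma-distributed deleterious
mutations needs the analytic continuation at exponents in (0, 1) (the Gamma DFE
shape).  The Euler-Maclaurin expansion below provides that continuation and is
fully vectorised, which matters when evaluating ~1e5 prior draws.
"""
from __future__ import annotations

import numpy as np

__all__ = ["hurwitz_zeta"]

# Bernoulli numbers B_2, B_4, B_6 for the Euler-Maclaurin tail correction
_BERNOULLI = (1.0 / 6.0, -1.0 / 30.0, 1.0 / 42.0)
_K = 30  # terms summed explicitly before switching to the tail expansion


def hurwitz_zeta(s, q):
    """Hurwitz zeta ``sum_{k>=0} (k+q)^-s`` by analytic continuation.

    Parameters
    ----------
    s : float or array
        Exponent; any real value except 1.  Values in (0, 1) are the relevant
        regime here (Gamma DFE shapes).
    q : float or array
        Offset, must be positive (broadcast against ``s``).

    Accurate to ~1e-12 relative for q in (0.5, 2), which covers every use in
    this package; validated against mpmath in the test suite.
    """
    s = np.asarray(s, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("hurwitz_zeta requires q > 0")
    if np.any(s == 1.0):
        raise ValueError("hurwitz_zeta has a pole at s = 1")

    k = np.arange(_K, dtype=float)
    head = np.sum((k + q[..., None]) ** (-s[..., None]), axis=-1)

    m = _K + q
    tail = m ** (1.0 - s) / (s - 1.0) + 0.5 * m ** (-s)
    # Euler-Maclaurin correction terms: B_2j/(2j)! * rising factorial of s
    fac = s * m ** (-s - 1.0)
    tail = tail + _BERNOULLI[0] / 2.0 * fac
    fac = fac * (s + 1.0) * (s + 2.0) / m**2
    tail = tail + _BERNOULLI[1] / 24.0 * fac
    fac = fac * (s + 3.0) * (s + 4.0) / m**2
    tail = tail + _BERNOULLI[2] / 720.0 * fac
    return head + tail
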