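"""Independent brute-force references used across the test suite.

These are deliberately naive (double loops, direct formulas) and share no
code with the package's implementations.
"""

from __future__ import annotations

import numpy as np

import thickpen as tp


def naive_pen_boundaries(wl: np.ndarray, y: np.ndarray, tau: float):
    """O(N*W) double-loop running extrema over [lam, lam + tau], truncated."""
    n = len(wl)
    lower = np.empty(n)
    upper = np.empty(n)
    for i in range(n):
        window = y[(wl >= wl[i]) & (wl <= wl[i] + tau)]
        lower[i] = window.min()
        upper[i] = window.max()
    return lower, upper


def bivariate_tpma(l1, u1, l2, u2):
    """Direct two-interval association formula, written out term by term."""
    num = np.minimum(u1, u2) - np.maximum(l1, l2)
    den = np.maximum(u1, u2) - np.minimum(l1, l2)
    rho = np.ones_like(np.asarray(num, dtype=float))
    np.divide(num, den, out=rho, where=den != 0)
    return rho


def random_curve(rng: np.random.Generator, n: int | None = None,
                 start: float = 300.0) -> tp.SpectralCurve:
    """Random non-negative curve on a random non-equispaced grid."""
    if n is None:
        n = int(rng.integers(10, 201))
    gaps = rng.uniform(0.2, 2.0, n - 1)
    wl = start + np.concatenate([[0.0], np.cumsum(gaps)])
    return tp.SpectralCurve(wl, rng.uniform(0.0, 2.0, n))
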