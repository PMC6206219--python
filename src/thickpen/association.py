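"""Thick pen measure of association (TPMA) between K >= 2 curves.

At each wavelength the pens of the K curves mark K vertical intervals
``[L_k, U_k]``.  The association is

    rho = (min_k U_k - max_k L_k) / (max_k U_k - min_k L_k)

When the K intervals share a common point, rho is positive and equals the
ratio of their intersection to (the shortest interval containing) their
union; otherwise rho is negative and its magnitude is the ratio of the gap
to that spanning interval.  rho is bounded above by 1 (attained exactly for
identical curves) and below by -1 (attained only in the degenerate case of
point-like pens; see the package methods note).

TPMA is defined on *normalized* curves so that shapes, not amplitudes, are
compared; normalization is the caller's responsibility (the analysis
pipeline always applies it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .curves import SpectralCurve
from .transform import PenBand, STUDY_TAUS, thick_pen_transform
from .transform import normalize as _normalize


@dataclass(frozen=True)
class TPMACurve:
    """Per-wavelength association of K curves at one thickness."""

    tau: float
    wavelengths: np.ndarray
    rho: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if self.wavelengths.shape != self.rho.shape:
            raise ValueError("wavelengths and rho must share one shape")
        if self.k < 2:
            raise ValueError("association needs at least two curves")

    def mean(self, mode: str = "unweighted") -> float:
        return mean_tpma(self, mode=mode)


def tpma_from_intervals(lowers: np.ndarray, uppers: np.ndarray) -> np.ndarray:
    """Association of K stacked pen intervals, vectorised over wavelength.

    `lowers` and `uppers` have shape (K, n).  Where all K intervals collapse
    to one identical point the ratio is 0/0; that is the limit of identical
    curves, so rho is set to 1 there.
    """
    lowers = np.asarray(lowers, dtype=float)
    uppers = np.asarray(uppers, dtype=float)
    if lowers.shape != uppers.shape or lowers.ndim != 2:
        raise ValueError("lowers and uppers must be 2-D arrays of equal shape")
    if lowers.shape[0] < 2:
        raise ValueError("association needs at least two curves")
    num = uppers.min(axis=0) - lowers.max(axis=0)
    den = uppers.max(axis=0) - lowers.min(axis=0)
    degenerate = den == 0
    rho = np.divide(num, den, out=np.ones_like(num), where=~degenerate)
    return rho


def tpma(bands: Sequence[PenBand]) -> TPMACurve:
    """TPMA of K >= 2 pen bands sharing one thickness and one grid."""
    bands = list(bands)
    if len(bands) < 2:
        raise ValueError("association needs at least two pen bands")
    tau = bands[0].tau
    grid = bands[0].wavelengths
    for b in bands[1:]:
        if b.tau != tau:
            raise ValueError(f"mixed thicknesses in one association ({tau} vs {b.tau})")
        if b.wavelengths.shape != grid.shape or not np.array_equal(b.wavelengths, grid):
            raise ValueError("pen bands are on different wavelength grids")
    lowers = np.stack([b.lower for b in bands])
    uppers = np.stack([b.upper for b in bands])
    return TPMACurve(tau, grid, tpma_from_intervals(lowers, uppers), len(bands))


def mean_tpma(curve: TPMACurve | np.ndarray, mode: str = "unweighted") -> float:
    """Wavelength-averaged association: the one-number summary per thickness.

    The default is the plain arithmetic mean over grid points, matching the
    definition of the measure even on a non-equispaced grid; ``mode=
    "trapezoid"`` instead weights points by trapezoid quadrature over
    wavelength.
    """
    if isinstance(curve, TPMACurve):
        rho, wl = curve.rho, curve.wavelengths
    else:
        rho, wl = np.asarray(curve, dtype=float), None
    if rho.size == 0:
        raise ValueError("empty association curve")
    if mode == "unweighted":
        return float(rho.mean())
    if mode == "trapezoid":
        if wl is None:
            raise ValueError("trapezoid mean needs a TPMACurve with its grid")
        return float(np.trapezoid(rho, wl) / (wl[-1] - wl[0]))
    raise ValueError(f"unknown mean mode {mode!r}")


def associate(
    curves: Sequence[SpectralCurve],
    taus: Sequence[float] = STUDY_TAUS,
    window: tuple[float, float] | None = None,
    edge: str = "truncate",
    normalize: bool = True,
    mean_mode: str = "unweighted",
) -> tuple[dict[float, TPMACurve], dict[float, float]]:
    """Normalize K curves, pen-transform each, and associate them per thickness.

    Returns ``(rho_by_tau, mean_rho_by_tau)``.  All curves must share one
    wavelength grid after restriction to `window`.
    """
    if len(curves) < 2:
        raise ValueError("association needs at least two curves")
    prepared = [(_normalize(c, window) if normalize else c) for c in curves]
    transforms = [thick_pen_transform(c, taus, edge=edge) for c in prepared]
    rho_by_tau: dict[float, TPMACurve] = {}
    mean_by_tau: dict[float, float] = {}
    for j, tau in enumerate(transforms[0].taus):
        curve = tpma([t.bands[j] for t in transforms])
        rho_by_tau[tau] = curve
        mean_by_tau[tau] = curve.mean(mode=mean_mode)
    return rho_by_tau, mean_by_tau
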