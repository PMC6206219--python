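"""Containers for measurements of spectral irradiance.

A measurement is a curve sampled on a strictly increasing — and in general
non-equispaced — wavelength grid, carrying the factor labels of the study
design (date, stand, understorey sunlight position, measurement point).
All downstream machinery (pen transforms, association measures, the
comparison pipeline) operates on these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

#: Analysis window used throughout: the calibrated, biologically relevant
#: part of the solar spectrum (nm).
DEFAULT_WINDOW: tuple[float, float] = (300.0, 800.0)

#: Understorey sunlight positions, ordered from darkest to brightest.
CANOPY_POSITIONS: tuple[str, ...] = ("shade", "semi-shade", "sunfleck")
FULL_SUN: str = "full-sun"
POSITIONS: tuple[str, ...] = CANOPY_POSITIONS + (FULL_SUN,)


def _as_float_array(x: Any, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class SpectralCurve:
    """One measurement of spectral irradiance.

    Parameters
    ----------
    wavelengths : array-like of float
        Strictly increasing wavelength grid in nm, length >= 2.
    values : array-like of float
        Spectral irradiance in W m^-2 nm^-1, same length as `wavelengths`,
        finite and non-negative.
    meta : mapping, optional
        Factor labels, e.g. ``{"date": "2015-05-22", "stand": "BetulaOld",
        "position": "semi-shade", "point": 1}``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelengths, "wavelengths")
        y = _as_float_array(self.values, "values")
        if wl.size < 2:
            raise ValueError("a spectral curve needs at least two grid points")
        if wl.size != y.size:
            raise ValueError(
                f"wavelengths and values differ in length ({wl.size} vs {y.size})"
            )
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelength grid contains non-finite entries")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("irradiance values contain non-finite entries")
        if np.any(y < 0):
            raise ValueError("irradiance values must be non-negative")
        wl.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", y)
        object.__setattr__(self, "meta", dict(self.meta))

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.wavelengths.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    @property
    def min_gap(self) -> float:
        return float(np.min(np.diff(self.wavelengths)))

    def restrict(self, window: tuple[float, float] = DEFAULT_WINDOW) -> "SpectralCurve":
        """Return the curve restricted to grid points inside `window` (inclusive)."""
        lo, hi = window
        if lo >= hi:
            raise ValueError(f"invalid window {window}")
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if np.count_nonzero(mask) < 2:
            raise ValueError(
                f"curve covers [{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm; "
                f"fewer than two grid points fall in window [{lo:g}, {hi:g}] nm"
            )
        return SpectralCurve(self.wavelengths[mask], self.values[mask], self.meta)

    def with_meta(self, **labels: Any) -> "SpectralCurve":
        meta = dict(self.meta)
        meta.update(labels)
        return replace(self, meta=meta)

    def label(self) -> str:
        """Compact human-readable identifier built from the factor labels."""
        keys = ("date", "stand", "position", "point", "replicate")
        parts = [str(self.meta[k]) for k in keys if k in self.meta]
        return "/".join(parts) if parts else "<unlabelled>"


class NormalizedCurve(SpectralCurve):
    """A min-max normalized curve: dimensionless values attaining 0 and 1."""

    #: absolute tolerance for the attainment of the bounds
    _ATOL = 1e-12

    def __post_init__(self) -> None:
        super().__post_init__()
        y = self.values
        if abs(float(y.min())) > self._ATOL or abs(float(y.max()) - 1.0) > self._ATOL:
            raise ValueError(
                "normalized curve must attain 0 and 1 "
                f"(got min={y.min():g}, max={y.max():g})"
            )


def check_shared_grid(curves) -> np.ndarray:
    """Return the common wavelength grid of `curves`; raise if grids differ.

    Association measures are defined point-wise on one grid; no interpolation
    is ever performed.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves given")
    grid = curves[0].wavelengths
    for c in curves[1:]:
        if c.wavelengths.shape != grid.shape or not np.array_equal(c.wavelengths, grid):
            raise ValueError(
                f"curves are on different wavelength grids "
                f"({curves[0].label()} vs {c.label()}); resample upstream or "
                "restrict to a common grid — no interpolation is performed"
            )
    return grid
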