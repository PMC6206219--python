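"""Thick pen transform: windowed running extrema on a wavelength grid.

Drawing a curve with a square pen of thickness ``tau`` traces out a band
whose lower and upper boundaries at wavelength ``lam`` are

    L(lam) = min{ X(l) : lam <= l <= lam + tau }
    U(lam) = max{ X(l) : lam <= l <= lam + tau }

Window membership is decided by wavelength *value*, not by index count, so
the transform applies unchanged to non-equispaced grids.  Small thicknesses
expose the rough, fine-scale content of the curve; large thicknesses retain
only trend-like features.

Two curve-wise operators are also exposed as scikit-learn transformers
(:class:`CurveNormalizer`, :class:`ThickPenTransform`) acting on rows of a
2-D array that share one wavelength grid; the module-level functions
:func:`normalize`, :func:`pen_boundaries` and :func:`thick_pen_transform`
are thin wrappers over them for single :class:`~thickpen.curves.SpectralCurve`
objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .curves import DEFAULT_WINDOW, NormalizedCurve, SpectralCurve

#: Thickness set (nm) used for the multi-scale comparisons of understorey
#: spectra: a representative cross-section from small to large scales.
STUDY_TAUS: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

#: Tolerance used when deciding whether a full window of width tau still
#: fits before the right end of the grid (edge="restrict").
_EDGE_ATOL = 1e-9


# ---------------------------------------------------------------------------
# range-extrema machinery
# ---------------------------------------------------------------------------
class _ExtremaIndex:
    """Sparse table answering range min/max queries over a value sequence.

    Build is O(n log n); each vectorised batch of inclusive-range queries is
    O(n).  Queries return the exact floats of the input (no arithmetic), so
    results match a brute-force scan bit for bit.
    """

    def __init__(self, values: np.ndarray) -> None:
        values = np.ascontiguousarray(values, dtype=float)
        self._min = [values]
        self._max = [values]
        k = 1
        while (1 << k) <= values.size:
            h = 1 << (k - 1)
            pmin, pmax = self._min[-1], self._max[-1]
            self._min.append(np.minimum(pmin[: pmin.size - h], pmin[h:]))
            self._max.append(np.maximum(pmax[: pmax.size - h], pmax[h:]))
            k += 1

    def query(self, starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Min and max over the inclusive index ranges [starts[i], ends[i]]."""
        lengths = ends - starts + 1
        if np.any(lengths < 1):
            raise ValueError("empty query range")
        # floor(log2(length)) computed exactly via frexp
        k = np.frexp(lengths.astype(float))[1] - 1
        lo = np.empty(starts.size)
        hi = np.empty(starts.size)
        for kk in np.unique(k):
            m = k == kk
            half = 1 << int(kk)
            s = starts[m]
            e = ends[m] - half + 1
            lo[m] = np.minimum(self._min[kk][s], self._min[kk][e])
            hi[m] = np.maximum(self._max[kk][s], self._max[kk][e])
        return lo, hi


def _window_ends(wavelengths: np.ndarray, tau: float) -> np.ndarray:
    """Inclusive end index of the window [lam, lam + tau] for every grid point."""
    return np.searchsorted(wavelengths, wavelengths + tau, side="right") - 1


def running_extrema(
    wavelengths: np.ndarray,
    values: np.ndarray,
    tau: float,
    edge: str = "truncate",
    index: _ExtremaIndex | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed running minimum and maximum over [lam, lam + tau].

    Returns ``(out_wavelengths, lower, upper)``.  With ``edge="truncate"``
    (default) every grid point gets a value and windows overrunning the grid
    are cut at the last point, so all outputs share the input grid.  With
    ``edge="restrict"`` only points whose full window fits, i.e.
    ``lam + tau <= lam_max``, are returned.
    """
    if tau <= 0:
        raise ValueError(f"thickness must be positive, got {tau}")
    if edge not in ("truncate", "restrict"):
        raise ValueError(f"edge must be 'truncate' or 'restrict', got {edge!r}")
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.asarray(values, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty curve")
    ends = _window_ends(wavelengths, tau)
    starts = np.arange(wavelengths.size)
    if edge == "restrict":
        keep = wavelengths + tau <= wavelengths[-1] + _EDGE_ATOL
        if not np.any(keep):
            raise ValueError(
                f"no window of width {tau} nm fits inside the grid span "
                f"[{wavelengths[0]:g}, {wavelengths[-1]:g}] nm"
            )
        starts, ends = starts[keep], ends[keep]
        out_wl = wavelengths[keep]
    else:
        out_wl = wavelengths
    if index is None:
        index = _ExtremaIndex(values)
    lower, upper = index.query(starts, ends)
    return out_wl, lower, upper


# ---------------------------------------------------------------------------
# band containers
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PenBand:
    """Lower/upper pen boundaries for one curve at one thickness."""

    tau: float
    wavelengths: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if not (self.wavelengths.shape == self.lower.shape == self.upper.shape):
            raise ValueError("wavelengths, lower and upper must share one shape")
        if np.any(self.lower > self.upper):
            raise ValueError("pen band has lower boundary above upper boundary")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


@dataclass(frozen=True)
class TPTResult:
    """Thick pen transform: one pen band per thickness, ordered by thickness."""

    taus: tuple[float, ...]
    bands: tuple[PenBand, ...]

    def __post_init__(self) -> None:
        if len(self.taus) != len(self.bands):
            raise ValueError("taus and bands differ in length")

    def __iter__(self) -> Iterator[PenBand]:
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def band(self, tau: float) -> PenBand:
        for t, b in zip(self.taus, self.bands):
            if t == tau:
                return b
        raise KeyError(f"no band for thickness {tau}")


def check_thicknesses(taus: Iterable[float], min_gap: float | None = None) -> np.ndarray:
    """Validate a thickness set: positive and strictly increasing.

    A thickness below the smallest sampling gap is legal but degenerate —
    the pen band collapses onto the curve itself — so it triggers a warning
    rather than an error.
    """
    t = np.atleast_1d(np.asarray(taus, dtype=float))
    if t.size == 0:
        raise ValueError("empty thickness set")
    if np.any(t <= 0):
        raise ValueError("thicknesses must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("thicknesses must be strictly increasing")
    if min_gap is not None and np.any(t < min_gap):
        warnings.warn(
            f"thickness below the smallest grid gap ({min_gap:g} nm): the pen "
            "band degenerates to the curve itself (L = U = X)",
            stacklevel=3,
        )
    return t


# ---------------------------------------------------------------------------
# curve-level API
# ---------------------------------------------------------------------------
def pen_boundaries(curve: SpectralCurve, tau: float, edge: str = "truncate") -> PenBand:
    """Pen boundaries of one curve at one thickness (nm)."""
    check_thicknesses([tau], min_gap=curve.min_gap)
    wl, lo, hi = running_extrema(curve.wavelengths, curve.values, tau, edge=edge)
    return PenBand(float(tau), wl, lo, hi)


def thick_pen_transform(
    curve: SpectralCurve, taus: Sequence[float] = STUDY_TAUS, edge: str = "truncate"
) -> TPTResult:
    """Thick pen transform of a curve over a strictly increasing thickness set."""
    t = check_thicknesses(taus, min_gap=curve.min_gap)
    index = _ExtremaIndex(curve.values)
    bands = []
    for tau in t:
        wl, lo, hi = running_extrema(
            curve.wavelengths, curve.values, float(tau), edge=edge, index=index
        )
        bands.append(PenBand(float(tau), wl, lo, hi))
    return TPTResult(tuple(float(x) for x in t), tuple(bands))


def normalize(
    curve: SpectralCurve, window: tuple[float, float] | None = DEFAULT_WINDOW
) -> NormalizedCurve:
    """Min-max normalize a curve over `window` so its values attain 0 and 1.

    The curve is first restricted to `window` (pass ``None`` to keep the full
    grid); the minimum and maximum are then taken over that restriction only.
    Comparing normalized curves compares their *shapes*: any positive affine
    rescaling of the raw curve yields the same normalized curve.
    """
    if window is not None:
        curve = curve.restrict(window)
    y = curve.values
    lo, hi = float(y.min()), float(y.max())
    if hi <= lo:
        raise ValueError(
            f"cannot normalize a constant curve ({curve.label()}): min == max == {lo:g}"
        )
    scaled = (y - lo) / (hi - lo)
    # guarantee exact attainment of the bounds despite rounding
    scaled = np.clip(scaled, 0.0, 1.0)
    return NormalizedCurve(curve.wavelengths, scaled, curve.meta)


# ---------------------------------------------------------------------------
# scikit-learn estimators over 2-D arrays (n_curves, n_wavelengths)
# ---------------------------------------------------------------------------
class CurveNormalizer(TransformerMixin, BaseEstimator):
    """Row-wise min-max scaling of curves over a wavelength window.

    Parameters
    ----------
    wavelengths : array-like of float or None
        Shared grid of the columns; defaults to ``0..n_features-1``.
    window : (float, float) or None
        Wavelength window over which the minimum and maximum are taken;
        columns outside it are dropped from the output.  ``None`` keeps all.
    """

    def __init__(self, wavelengths=None, window: tuple[float, float] | None = None):
        self.wavelengths = wavelengths
        self.window = window

    def fit(self, X, y=None):
        X = self._validate(X)
        n = X.shape[1]
        wl = (
            np.arange(n, dtype=float)
            if self.wavelengths is None
            else np.asarray(self.wavelengths, dtype=float)
        )
        if wl.size != n:
            raise ValueError(f"grid has {wl.size} points but X has {n} columns")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.window is None:
            mask = np.ones(n, dtype=bool)
        else:
            lo, hi = self.window
            mask = (wl >= lo) & (wl <= hi)
            if np.count_nonzero(mask) < 2:
                raise ValueError(f"fewer than two grid points in window {self.window}")
        self.wavelengths_ = wl
        self.mask_ = mask
        self.n_features_in_ = n
        return self

    def transform(self, X):
        check_is_fitted(self, "mask_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of columns than at fit time")
        W = X[:, self.mask_]
        lo = W.min(axis=1, keepdims=True)
        hi = W.max(axis=1, keepdims=True)
        if np.any(hi <= lo):
            raise ValueError("cannot normalize a constant curve (row min == max)")
        return np.clip((W - lo) / (hi - lo), 0.0, 1.0)

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_curves, n_wavelengths)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        return X


class ThickPenTransform(TransformerMixin, BaseEstimator):
    """Thick pen transform of each row of a 2-D array over one shared grid.

    ``transform`` returns an array of shape ``(n_curves, n_taus, 2, n_out)``
    whose third axis holds the lower and upper pen boundaries.

    Parameters
    ----------
    taus : sequence of float
        Strictly increasing pen thicknesses in grid units.
    wavelengths : array-like of float or None
        Shared grid of the columns; defaults to ``0..n_features-1``.
    edge : {"truncate", "restrict"}
        Right-edge rule: truncate windows at the last grid point (keeps all
        outputs on the input grid) or drop points whose window overruns it.
    """

    def __init__(
        self,
        taus: Sequence[float] = STUDY_TAUS,
        wavelengths=None,
        edge: str = "truncate",
    ):
        self.taus = taus
        self.wavelengths = wavelengths
        self.edge = edge

    def fit(self, X, y=None):
        X = CurveNormalizer._validate(X)
        n = X.shape[1]
        wl = (
            np.arange(n, dtype=float)
            if self.wavelengths is None
            else np.asarray(self.wavelengths, dtype=float)
        )
        if wl.size != n:
            raise ValueError(f"grid has {wl.size} points but X has {n} columns")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        taus = check_thicknesses(self.taus, min_gap=float(np.min(np.diff(wl))))
        if self.edge not in ("truncate", "restrict"):
            raise ValueError(f"edge must be 'truncate' or 'restrict', got {self.edge!r}")
        if self.edge == "restrict":
            keep = wl + taus[-1] <= wl[-1] + _EDGE_ATOL
            if not np.any(keep):
                raise ValueError("largest thickness exceeds the grid span")
            out_wl = wl[keep]
        else:
            out_wl = wl
        self.wavelengths_ = wl
        self.taus_ = tuple(float(t) for t in taus)
        # common output grid: for "restrict" the grid of the *largest* pen,
        # so all thicknesses stack into one rectangular array
        self.output_wavelengths_ = out_wl
        self.n_features_in_ = n
        return self

    def transform(self, X):
        check_is_fitted(self, "taus_")
        X = CurveNormalizer._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of columns than at fit time")
        wl = self.wavelengths_
        n_out = self.output_wavelengths_.size
        out = np.empty((X.shape[0], len(self.taus_), 2, n_out))
        for i, row in enumerate(X):
            index = _ExtremaIndex(row)
            for j, tau in enumerate(self.taus_):
                owl, lo, hi = running_extrema(wl, row, tau, edge="truncate", index=index)
                if self.edge == "restrict":
                    lo, hi = lo[:n_out], hi[:n_out]
                out[i, j, 0] = lo
                out[i, j, 1] = hi
        return out
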