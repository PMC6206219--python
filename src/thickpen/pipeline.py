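"""End-to-end comparison pipeline for understorey irradiance surveys.

The study procedure is: screen raw contiguous recordings for detector
saturation and UV accuracy, average them per measurement point and then per
stand x position cell, and compare the resulting cell curves with the thick
pen machinery, varying one factor (date, stand, sunlight position, or each
position against the open-area full-sun reference) while holding the others
fixed.  Summary optics (maximum irradiance, PAR, R:FR) are provided for the
same curves.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .association import TPMACurve, mean_tpma, tpma
from .curves import (
    CANOPY_POSITIONS,
    DEFAULT_WINDOW,
    FULL_SUN,
    SpectralCurve,
    check_shared_grid,
)
from .simulate import QualityFlags
from .transform import STUDY_TAUS, normalize, thick_pen_transform

logger = logging.getLogger("thickpen")

VARY_CHOICES = ("date", "stand", "position", "position-vs-fullsun")

#: fixed meta fields per varied factor, in cell-key order (date, stand, position)
_FIXED_FIELDS = {
    "date": ("stand", "position"),
    "stand": ("date", "position"),
    "position": ("date", "stand"),
}


# ---------------------------------------------------------------------------
# screening and averaging
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ScreeningReport:
    retained: tuple[SpectralCurve, ...]
    n_input: int
    n_saturated: int
    n_uv_low: int

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def screen_spectra(
    curves: Sequence[SpectralCurve],
    ceiling: float | None = None,
    uv_floor: float | None = None,
    flags: Sequence[QualityFlags] | None = None,
    uv_band: tuple[float, float] = (300.0, 400.0),
) -> ScreeningReport:
    """Drop spectra that saturate the detector or lack UV accuracy.

    A curve is removed iff any value exceeds `ceiling`, or the maximum of
    its signal inside `uv_band` falls below `uv_floor`.  Generator flags can
    be passed instead of (or in addition to) numeric thresholds.
    """
    curves = list(curves)
    if flags is not None and len(flags) != len(curves):
        raise ValueError("flags and curves differ in length")
    kept: list[SpectralCurve] = []
    n_sat = n_uv = 0
    for i, c in enumerate(curves):
        saturated = bool(flags[i].saturated) if flags is not None else False
        uv_low = bool(flags[i].uv_low) if flags is not None else False
        if ceiling is not None and float(c.values.max()) > ceiling:
            saturated = True
        if uv_floor is not None:
            uv = c.values[(c.wavelengths >= uv_band[0]) & (c.wavelengths <= uv_band[1])]
            if uv.size and float(uv.max()) < uv_floor:
                uv_low = True
        if saturated:
            n_sat += 1
        elif uv_low:
            n_uv += 1
        if not (saturated or uv_low):
            kept.append(c)
    if curves and not kept:
        raise ValueError(
            f"screening removed every spectrum in group {curves[0].label()}"
        )
    logger.info(
        "screening: %d of %d retained (%d saturated, %d below UV floor)",
        len(kept), len(curves), n_sat, n_uv,
    )
    return ScreeningReport(tuple(kept), len(curves), n_sat, n_uv)


def average_contiguous(curves: Sequence[SpectralCurve]) -> SpectralCurve:
    """Unweighted mean of replicate recordings sharing one grid."""
    curves = list(curves)
    grid = check_shared_grid(curves)
    mean = np.mean([c.values for c in curves], axis=0)
    meta = dict(curves[0].meta)
    meta.pop("replicate", None)
    return SpectralCurve(grid, mean, meta)


def average_hierarchy(
    point_sets: Mapping[Any, Sequence[SpectralCurve]]
) -> SpectralCurve:
    """Two-stage mean: replicates -> point mean, point means -> cell mean.

    With equal replicate counts per point this equals the grand mean over
    all recordings; with unequal counts each point still contributes equally.
    """
    if not point_sets:
        raise ValueError("no measurement points to average")
    point_means = [average_contiguous(curves) for curves in point_sets.values()]
    cell = average_contiguous(point_means)
    cell.meta.pop("point", None)
    return cell


# ---------------------------------------------------------------------------
# comparison layouts
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ComparisonSpec:
    """Which factor is varied, and the settings held fixed while doing so."""

    vary: str
    taus: tuple[float, ...] = STUDY_TAUS
    window: tuple[float, float] = DEFAULT_WINDOW
    edge: str = "truncate"
    mean_mode: str = "unweighted"
    fullsun_mode: str = "mean"  # or one of the open-area labels

    def __post_init__(self) -> None:
        if self.vary not in VARY_CHOICES:
            raise ValueError(f"vary must be one of {VARY_CHOICES}, got {self.vary!r}")


@dataclass(frozen=True)
class GroupResult:
    """Association curves for one fixed-factor combination."""

    key: tuple
    fixed: dict[str, Any]
    members: tuple[dict[str, Any], ...]
    rho: dict[float, TPMACurve]
    mean_rho: dict[float, float]

    @property
    def k(self) -> int:
        return len(self.members)


@dataclass
class ComparisonResult:
    spec: ComparisonSpec
    groups: dict[tuple, GroupResult] = field(default_factory=dict)
    skipped: list[tuple[tuple, str]] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        """Long table of mean association per group and thickness."""
        rows = []
        for g in self.groups.values():
            for tau, m in g.mean_rho.items():
                rows.append({**g.fixed, "tau_nm": tau, "mean_rho": m, "K": g.k})
        return pd.DataFrame(rows)

    def rho_frame(self) -> pd.DataFrame:
        """Long table of per-wavelength association."""
        rows = []
        for g in self.groups.values():
            gid = "|".join(str(v) for v in g.key)
            for tau, curve in g.rho.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "comparison": gid,
                            **{k: v for k, v in g.fixed.items()},
                            "tau_nm": tau,
                            "wavelength_nm": curve.wavelengths,
                            "rho": curve.rho,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    def mean_over_groups(self) -> float:
        """Grand mean of the per-group, per-thickness mean association."""
        values = [m for g in self.groups.values() for m in g.mean_rho.values()]
        if not values:
            raise ValueError("comparison produced no groups")
        return float(np.mean(values))


class _CellSet:
    """Cell-level curves with cached normalization and pen transforms.

    Raw curves are collapsed to one curve per (date, stand, position) cell
    (replicates and measurement points averaged); open-area recordings are
    collapsed per date according to `fullsun_mode`.  Pen bands are computed
    once per cell and thickness and shared across comparison layouts.
    """

    def __init__(
        self,
        curves: Sequence[SpectralCurve],
        taus: Sequence[float],
        window: tuple[float, float],
        edge: str,
        fullsun_mode: str = "mean",
    ) -> None:
        self.taus = tuple(float(t) for t in taus)
        self.edge = edge
        by_cell: dict[tuple, list[SpectralCurve]] = {}
        for c in curves:
            meta = c.meta
            position = meta.get("position")
            if position == FULL_SUN:
                if fullsun_mode != "mean" and meta.get("stand") != fullsun_mode:
                    continue
                key = (meta.get("date"), "Open", FULL_SUN)
            else:
                key = (meta.get("date"), meta.get("stand"), position)
            by_cell.setdefault(key, []).append(c.restrict(window))
        self.cells: dict[tuple, SpectralCurve] = {}
        for key, members in by_cell.items():
            cell = members[0] if len(members) == 1 else average_contiguous(members)
            date, stand, position = key
            self.cells[key] = normalize(
                cell.with_meta(date=date, stand=stand, position=position), window=None
            )
        check_shared_grid(self.cells.values())
        self._transforms: dict[tuple, Any] = {}

    def bands(self, key: tuple):
        if key not in self._transforms:
            self._transforms[key] = thick_pen_transform(
                self.cells[key], self.taus, edge=self.edge
            )
        return self._transforms[key]

    def levels(self, which: str) -> list:
        idx = {"date": 0, "stand": 1, "position": 2}[which]
        return sorted({k[idx] for k in self.cells})


def _associate_group(
    cellset: _CellSet,
    keys: Sequence[tuple],
    group_key: tuple,
    fixed: dict[str, Any],
    mean_mode: str,
) -> GroupResult:
    transforms = [cellset.bands(k) for k in keys]
    rho: dict[float, TPMACurve] = {}
    mean_rho: dict[float, float] = {}
    for j, tau in enumerate(cellset.taus):
        curve = tpma([t.bands[j] for t in transforms])
        rho[tau] = curve
        mean_rho[tau] = mean_tpma(curve, mode=mean_mode)
    members = tuple(dict(cellset.cells[k].meta) for k in keys)
    return GroupResult(group_key, fixed, members, rho, mean_rho)


def _compare(cellset: _CellSet, spec: ComparisonSpec) -> ComparisonResult:
    result = ComparisonResult(spec)
    canopy_keys = [k for k in cellset.cells if k[2] in CANOPY_POSITIONS]
    if spec.vary == "position-vs-fullsun":
        fullsun = {k[0]: k for k in cellset.cells if k[2] == FULL_SUN}
        for key in sorted(canopy_keys):
            date, stand, position = key
            if date not in fullsun:
                result.skipped.append((key, f"no full-sun reference for {date}"))
                logger.info("skipping %s: no full-sun reference", key)
                continue
            fixed = {"date": date, "stand": stand, "position": position}
            result.groups[key] = _associate_group(
                cellset, [key, fullsun[date]], key, fixed, spec.mean_mode
            )
        return result

    varied_idx = {"date": 0, "stand": 1, "position": 2}[spec.vary]
    fixed_fields = _FIXED_FIELDS[spec.vary]
    groups: dict[tuple, list[tuple]] = {}
    for key in canopy_keys:
        gkey = tuple(v for i, v in enumerate(key) if i != varied_idx)
        groups.setdefault(gkey, []).append(key)
    for gkey in sorted(groups):
        keys = sorted(groups[gkey], key=lambda k: k[varied_idx])
        fixed = dict(zip(fixed_fields, gkey))
        if len(keys) < 2:
            result.skipped.append((gkey, f"only {len(keys)} level(s) of {spec.vary}"))
            logger.info(
                "skipping group %s: fewer than two levels of %s available",
                gkey, spec.vary,
            )
            continue
        result.groups[gkey] = _associate_group(cellset, keys, gkey, fixed, spec.mean_mode)
    return result


def run_comparison(
    curves: Sequence[SpectralCurve], spec: ComparisonSpec
) -> ComparisonResult:
    """Group curves by the fixed factors of `spec` and associate each group.

    Member curves of a group are normalized, pen-transformed at every
    thickness of the spec, and their K-variate association and its
    wavelength mean computed.  Groups with fewer than two available levels
    (missing design cells) are skipped with a logged notice.
    """
    cellset = _CellSet(curves, spec.taus, spec.window, spec.edge, spec.fullsun_mode)
    return _compare(cellset, spec)


def factor_hierarchy(
    curves: Sequence[SpectralCurve],
    taus: Sequence[float] = STUDY_TAUS,
    window: tuple[float, float] = DEFAULT_WINDOW,
    edge: str = "truncate",
    mean_mode: str = "unweighted",
) -> dict[str, ComparisonResult]:
    """Run the vary-date, vary-stand and vary-position layouts on one design.

    Pen transforms are computed once per cell and shared across the three
    layouts, which is what makes the full-design analysis cheap.
    """
    cellset = _CellSet(curves, taus, window, edge)
    return {
        vary: _compare(cellset, ComparisonSpec(vary, tuple(float(t) for t in taus),
                                               window, edge, mean_mode))
        for vary in ("date", "stand", "position")
    }


def bivariate_position_pairs(
    curves: Sequence[SpectralCurve],
    spec: ComparisonSpec | None = None,
) -> ComparisonResult:
    """Pairwise position comparisons per (stand, date) cell.

    Pairs are shade/semi-shade, semi-shade/sunfleck and shade/sunfleck; a
    pair is skipped when either position is missing in that cell.
    """
    if spec is None:
        spec = ComparisonSpec("position")
    cellset = _CellSet(curves, spec.taus, spec.window, spec.edge)
    result = ComparisonResult(spec)
    cells = [k for k in cellset.cells if k[2] in CANOPY_POSITIONS]
    by_cell = {(k[0], k[1]): {} for k in cells}
    for k in cells:
        by_cell[(k[0], k[1])][k[2]] = k
    for (date, stand), positions in sorted(by_cell.items()):
        for p1, p2 in itertools.combinations(CANOPY_POSITIONS, 2):
            gkey = (date, stand, f"{p1}~{p2}")
            if p1 not in positions or p2 not in positions:
                result.skipped.append((gkey, "position missing in this cell"))
                logger.info("skipping pair %s: position missing", gkey)
                continue
            fixed = {"date": date, "stand": stand, "pair": f"{p1}~{p2}"}
            result.groups[gkey] = _associate_group(
                cellset, [positions[p1], positions[p2]], gkey, fixed, spec.mean_mode
            )
    return result


# ---------------------------------------------------------------------------
# summary optics
# ---------------------------------------------------------------------------
def band_integral(curve: SpectralCurve, band: tuple[float, float]) -> float:
    """Trapezoid integral of irradiance over a wavelength band (W m^-2).

    The band edges are included exactly by linear interpolation, so the
    integral is over precisely [band[0], band[1]] regardless of where the
    grid points fall.
    """
    lo, hi = band
    wl, y = curve.wavelengths, curve.values
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(
            f"band [{lo:g}, {hi:g}] nm not covered by grid "
            f"[{wl[0]:g}, {wl[-1]:g}] nm"
        )
    inner = (wl > lo) & (wl < hi)
    xs = np.concatenate([[lo], wl[inner], [hi]])
    ys = np.concatenate([[np.interp(lo, wl, y)], y[inner], [np.interp(hi, wl, y)]])
    return float(np.trapezoid(ys, xs))


def spectral_summaries(curve: SpectralCurve) -> dict[str, float]:
    """Maximum irradiance, PAR and R:FR of one spectral irradiance curve.

    PAR integrates 400-700 nm; R:FR divides the integral over [655, 665] nm
    by the one over [725, 735] nm.  A zero far-red integral makes R:FR
    undefined and raises.
    """
    par = band_integral(curve, (400.0, 700.0))
    red = band_integral(curve, (655.0, 665.0))
    far_red = band_integral(curve, (725.0, 735.0))
    if far_red == 0:
        raise ValueError(
            f"R:FR undefined for {curve.label()}: far-red integral is zero"
        )
    return {
        "max_irradiance": float(curve.values.max()),
        "par": par,
        "r_fr": red / far_red,
    }
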