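"""Synthetic solar spectral irradiance with the factor structure of a
forest-understorey light survey.

The generator emulates instantaneous spectroradiometer recordings taken at
marked points under five forest stands on three spring dates, at three
understorey sunlight positions (shade, semi-shade, sunfleck) plus open-area
full-sun references.  Each spectrum is built as

    smooth solar-like continuum
    x position/stand/date-dependent green-band attenuation
    x oxygen A-band absorption dip near 762 nm
    x small-scale multiplicative roughness (Fraunhofer-like)

scaled to a position-dependent maximum irradiance.  Shade and semi-shade
canopies absorb strongly between roughly 400 and 690 nm relative to the
far-red, which is what makes their normalized *shapes* differ from sunfleck
and full-sun spectra; the effect sizes are ordered so that position alters
the shape most, stand identity less, and date least.  All randomness is
driven by a single integer seed per scenario through named sub-streams, so
every output is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .curves import CANOPY_POSITIONS, FULL_SUN, POSITIONS, SpectralCurve

STANDS: tuple[str, ...] = ("BetulaOld", "BetulaOldMixed", "BetulaYoung", "Picea", "Quercus")
DATES: tuple[str, ...] = ("2015-04-25", "2015-05-22", "2015-06-05")
OPEN_LABELS: tuple[str, ...] = ("OpenBeg", "OpenCen", "OpenEnd")

#: (stand, date) cells without a semi-shade measurement: leaf-out had not
#: begun in April anywhere, and started late in the Quercus stand.
MISSING_SEMI_SHADE: frozenset[tuple[str, str]] = frozenset(
    {(stand, DATES[0]) for stand in STANDS} | {("Quercus", DATES[1])}
)

#: Range (W m^-2 nm^-1) from which the spectrum maximum is drawn, per position.
POSITION_AMPLITUDE: dict[str, tuple[float, float]] = {
    "shade": (0.12, 0.25),
    "semi-shade": (0.30, 0.50),
    "sunfleck": (0.65, 1.00),
    FULL_SUN: (1.00, 1.50),
}

#: Baseline depth of the 400-690 nm canopy attenuation band, per position.
POSITION_ATTENUATION: dict[str, float] = {
    "shade": 0.75,
    "semi-shade": 0.45,
    "sunfleck": 0.04,
    FULL_SUN: 0.0,
}

_WAVELENGTH_POINTS = 1091
_GAP_RANGE = (0.44, 0.48)
_DIP_CENTRE = 762.0  # oxygen A-band (nm)
_DIP_SIGMA = 2.3
_DIP_DEPTH = 0.55


@dataclass(frozen=True)
class SpectrumScenario:
    """Everything needed to draw one spectrum (or a contiguous set) reproducibly."""

    position: str = "sunfleck"
    stand: str = "BetulaOld"
    date: str = "2015-05-22"
    point: int = 1
    seed: int = 0
    window: tuple[float, float] = (300.0, 800.0)
    n_points: int = _WAVELENGTH_POINTS
    gap_range: tuple[float, float] = _GAP_RANGE
    roughness: float = 0.03
    noise: float = 0.01
    n_contiguous: int = 1
    saturation_fraction: float = 0.0
    uv_low_fraction: float = 0.0
    saturation_ceiling: float = 2.0
    uv_floor: float = 1e-4
    stand_effect: float = 0.25
    date_effect: float = 0.08

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(
                f"unknown position {self.position!r}; expected one of {POSITIONS}"
            )
        if self.n_points < 2 or self.n_contiguous < 1:
            raise ValueError("n_points must be >= 2 and n_contiguous >= 1")
        for name in ("roughness", "noise", "saturation_ceiling", "uv_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class QualityFlags:
    """Screening flags attached to one replicate of a contiguous set."""

    saturated: bool = False
    uv_low: bool = False

    @property
    def ok(self) -> bool:
        return not (self.saturated or self.uv_low)


# ---------------------------------------------------------------------------
# seeding helpers
# ---------------------------------------------------------------------------
def _tag(text: str) -> int:
    # stable across processes, unlike hash()
    return zlib.crc32(text.encode("utf-8"))


def _stream(seed: int, *tags: object) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF] + [_tag(str(t)) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _label_draws(kind: str, label: str, size: int) -> np.ndarray:
    """Reproducible uniform(-1, 1) draws attached to a factor level."""
    return _stream(0, "label", kind, label).uniform(-1.0, 1.0, size=size)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------
def make_grid(scenario: SpectrumScenario) -> np.ndarray:
    """Non-equispaced wavelength grid over the scenario window.

    The grid starts and ends exactly at the window limits and every
    consecutive gap lies inside ``gap_range``; jitter is drawn with zero sum
    so the gaps add up to the window length exactly.  Deterministic given
    the scenario seed.
    """
    lo, hi = scenario.window
    gmin, gmax = scenario.gap_range
    n = scenario.n_points
    base = (hi - lo) / (n - 1)
    if not (gmin <= base <= gmax):
        raise ValueError(
            f"infeasible grid: mean gap {base:g} nm outside [{gmin:g}, {gmax:g}] nm "
            f"for {n} points over [{lo:g}, {hi:g}] nm"
        )
    rng = _stream(scenario.seed, "grid")
    jitter = rng.uniform(-1.0, 1.0, size=n - 1)
    jitter -= jitter.mean()  # zero-sum: gaps total exactly hi - lo
    room = min(gmax - base, base - gmin)
    peak = float(np.max(np.abs(jitter)))
    if peak > 0:
        jitter *= 0.8 * room / peak
    gaps = base + jitter
    grid = lo + np.concatenate([[0.0], np.cumsum(gaps)])
    grid[-1] = hi
    return grid


# ---------------------------------------------------------------------------
# spectrum construction
# ---------------------------------------------------------------------------
def _continuum(wl: np.ndarray) -> np.ndarray:
    """Smooth quasi-blackbody continuum (T ~ 5800 K), max-normalized."""
    lam = wl * 1e-9
    b = lam**-5 / np.expm1(1.43877e-2 / (lam * 5800.0))
    return b / b.max()


def _attenuation(wl: np.ndarray, depth: float, lo_edge: float, hi_edge: float) -> np.ndarray:
    """Multiplicative canopy absorption band with soft logistic edges."""
    band = expit((wl - lo_edge) / 20.0) * expit((hi_edge - wl) / 20.0)
    return 1.0 - depth * band


def _shape_parameters(scenario: SpectrumScenario) -> tuple[float, float, float]:
    """(attenuation depth, low edge, high edge) for one factor cell.

    Stand and date perturb the baseline position shape through reproducible
    per-level draws scaled by the configured effect sizes.
    """
    base = POSITION_ATTENUATION[scenario.position]
    s = _label_draws("stand", scenario.stand, 2)
    d = _label_draws("date", scenario.date, 2)
    depth = base * (1.0 + scenario.stand_effect * s[0] + scenario.date_effect * d[0])
    depth = float(np.clip(depth, 0.0, 0.95))
    lo_edge = 410.0 + 40.0 * scenario.stand_effect * s[1] + 40.0 * scenario.date_effect * d[1]
    hi_edge = 690.0 - 30.0 * scenario.stand_effect * s[1]
    return depth, lo_edge, hi_edge


def _roughness(rng: np.random.Generator, n: int, scale: float, min_gap: float) -> np.ndarray:
    """Unit-free multiplicative roughness with ~3 nm correlation length."""
    if scale == 0:
        return np.ones(n)
    sigma = 3.0 / min_gap  # in grid points
    z = gaussian_filter1d(rng.standard_normal(n), sigma, mode="nearest")
    sd = z.std()
    if sd > 0:
        z /= sd
    return np.exp(scale * z)


def simulate_spectrum(
    scenario: SpectrumScenario, grid: np.ndarray | None = None
) -> SpectralCurve:
    """Draw one spectral irradiance curve for a scenario.

    `grid` overrides the scenario grid so that several curves (different
    seeds, different factor cells) can share one grid, as the association
    measures require.
    """
    if grid is None:
        grid = make_grid(scenario)
    depth, lo_edge, hi_edge = _shape_parameters(scenario)
    min_gap = float(np.min(np.diff(grid)))
    rough = _roughness(_stream(scenario.seed, "rough"), grid.size, scenario.roughness, min_gap)
    dip = 1.0 - _DIP_DEPTH * np.exp(-0.5 * ((grid - _DIP_CENTRE) / _DIP_SIGMA) ** 2)
    y = _continuum(grid) * _attenuation(grid, depth, lo_edge, hi_edge) * dip * rough
    amp_lo, amp_hi = POSITION_AMPLITUDE[scenario.position]
    amp = _stream(scenario.seed, "amp").uniform(amp_lo, amp_hi)
    y *= amp / y.max()
    meta = {
        "date": scenario.date,
        "stand": scenario.stand,
        "position": scenario.position,
        "point": scenario.point,
    }
    return SpectralCurve(grid, y, meta)


def simulate_contiguous_set(
    scenario: SpectrumScenario, grid: np.ndarray | None = None
) -> tuple[list[SpectralCurve], list[QualityFlags]]:
    """A contiguous burst of replicate recordings of one underlying spectrum.

    Replicates add multiplicative measurement noise (`scenario.noise`) to
    the base spectrum.  A configurable fraction is corrupted for screening
    tests: "saturated" replicates carry a value above the detector ceiling,
    "uv_low" replicates have their 300-400 nm signal crushed below the
    accuracy floor.  With one replicate and zero noise, the output equals
    :func:`simulate_spectrum` exactly.
    """
    base = simulate_spectrum(scenario, grid=grid)
    rng = _stream(scenario.seed, "replicates")
    curves: list[SpectralCurve] = []
    flags: list[QualityFlags] = []
    uv = base.wavelengths < 400.0
    for r in range(scenario.n_contiguous):
        if scenario.noise > 0:
            y = base.values * (1.0 + scenario.noise * rng.standard_normal(base.n))
            y = np.clip(y, 0.0, None)
        else:
            y = base.values.copy()
        saturated = bool(rng.random() < scenario.saturation_fraction)
        uv_low = bool(rng.random() < scenario.uv_low_fraction)
        if saturated:
            y[np.argmax(y)] = scenario.saturation_ceiling * 1.1
        if uv_low:
            y[uv] *= scenario.uv_floor / max(float(y[uv].max()), 1e-300) * 0.1
        meta = dict(base.meta, replicate=r)
        curves.append(SpectralCurve(base.wavelengths, y, meta))
        flags.append(QualityFlags(saturated=saturated, uv_low=uv_low))
    return curves, flags


# ---------------------------------------------------------------------------
# full study design
# ---------------------------------------------------------------------------
def cell_seed(seed: int, stand: str, date: str, position: str, point: int = 0) -> int:
    """Stable sub-seed (< 2^31) for one factor cell of the study design."""
    h = zlib.crc32(f"{seed}|{stand}|{date}|{position}|{point}".encode("utf-8"))
    return h & 0x7FFFFFFF


def simulate_study(
    seed: int = 0,
    stands: Sequence[str] = STANDS,
    dates: Sequence[str] = DATES,
    positions: Sequence[str] = CANOPY_POSITIONS,
    include_full_sun: bool = True,
    missing_cells: frozenset[tuple[str, str]] = MISSING_SEMI_SHADE,
    scenario: SpectrumScenario | None = None,
) -> list[SpectralCurve]:
    """One averaged curve per factor cell of the full study design.

    Generates the 5 stands x 3 dates x 3 positions layout (minus the cells
    where semi-shade did not exist) plus, when requested, the three open-area
    full-sun recordings per date.  All curves share one wavelength grid drawn
    from `seed`, as required for association.
    """
    template = scenario if scenario is not None else SpectrumScenario()
    grid = make_grid(replace(template, seed=seed))
    curves: list[SpectralCurve] = []
    for stand in stands:
        for date in dates:
            for position in positions:
                if position == "semi-shade" and (stand, date) in missing_cells:
                    continue
                sc = replace(
                    template,
                    stand=stand,
                    date=date,
                    position=position,
                    seed=cell_seed(seed, stand, date, position),
                )
                curves.append(simulate_spectrum(sc, grid=grid))
    if include_full_sun:
        for date in dates:
            for label in OPEN_LABELS:
                sc = replace(
                    template,
                    stand=label,
                    date=date,
                    position=FULL_SUN,
                    seed=cell_seed(seed, label, date, FULL_SUN),
                )
                curves.append(simulate_spectrum(sc, grid=grid))
    return curves
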