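"""Best-effort figures: pen ribbons, overlap plots and mean-association lines.

The numerical tables are the contract; these plots exist for inspection.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .association import tpma
from .curves import SpectralCurve
from .transform import STUDY_TAUS, normalize, thick_pen_transform


def plot_pen_bands(
    curve: SpectralCurve,
    taus: Sequence[float] = (15.0, 40.0, 80.0),
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """A curve drawn with pens of increasing thickness."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.plot(curve.wavelengths, curve.values, lw=0.6, color="k", label=curve.label())
    result = thick_pen_transform(curve, sorted(taus))
    for band in result:
        ax.fill_between(
            band.wavelengths, band.lower, band.upper, alpha=0.25,
            label=f"tau = {band.tau:g} nm",
        )
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("spectral irradiance (W m$^{-2}$ nm$^{-1}$)")
    ax.legend(fontsize=8)
    return ax


def plot_overlap(
    curves: Sequence[SpectralCurve],
    tau: float = 80.0,
    window: tuple[float, float] | None = (300.0, 800.0),
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Normalized curves, their pen bands at one thickness, and the association."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    bands = []
    for c in curves:
        nc = normalize(c, window)
        band = thick_pen_transform(nc, [tau]).bands[0]
        bands.append(band)
        ax.fill_between(band.wavelengths, band.lower, band.upper,
                        alpha=0.3, label=nc.label())
    rho = tpma(bands)
    ax.plot(rho.wavelengths, rho.rho, color="k", lw=1.0, label="TPMA")
    ax.axhline(rho.mean(), color="k", ls="--", lw=0.8, label="mean TPMA")
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel(f"normalized irradiance / rho (tau = {tau:g} nm)")
    ax.legend(fontsize=8)
    return ax


def plot_mean_tpma(
    summary: pd.DataFrame,
    by: str | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Mean association against thickness, one line per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    group_cols = [c for c in summary.columns if c not in ("tau_nm", "mean_rho", "K")]
    if by is not None:
        group_cols = [by]
    if group_cols:
        for key, block in summary.groupby(group_cols, sort=True):
            label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
            block = block.sort_values("tau_nm")
            ax.plot(block["tau_nm"], block["mean_rho"], marker="o", ms=3, label=label)
        ax.legend(fontsize=7)
    else:
        summary = summary.sort_values("tau_nm")
        ax.plot(summary["tau_nm"], summary["mean_rho"], marker="o", ms=3)
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("thickness tau (nm)")
    ax.set_ylabel("mean TPMA")
    return ax
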