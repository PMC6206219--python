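"""Delimited-text formats for spectra, results and configuration.

Spectra travel as long-format CSV (UTF-8, "." decimals, header required)
with one row per wavelength:

    wavelength_nm,irradiance,date,stand,position,point,replicate

One (date, stand, position, point, replicate) combination is one curve and
must carry a strictly increasing wavelength column.  Results are written as
a per-wavelength association table plus a companion summary of wavelength
means.  Round-trips are lossless: floats are serialised with full repr
precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .curves import SpectralCurve
from .pipeline import ComparisonResult
from .transform import STUDY_TAUS

SPECTRA_COLUMNS = ("wavelength_nm", "irradiance", "date", "stand", "position", "point")
_BLOCK_KEYS = ["date", "stand", "position", "point", "replicate"]

#: Default run configuration (thicknesses in nm, window in nm).
DEFAULT_CONFIG: dict[str, Any] = {
    "taus": list(STUDY_TAUS),
    "window": [300.0, 800.0],
    "edge": "truncate",
    "mean_mode": "unweighted",
    "screening": {"ceiling": None, "uv_floor": None},
    "generator": {"stand_effect": 0.25, "date_effect": 0.08,
                  "roughness": 0.03, "noise": 0.01},
}


def write_spectra(curves: Sequence[SpectralCurve], path: str | Path) -> None:
    """Write curves to long-format CSV; metadata columns come from `meta`."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "wavelength_nm": c.wavelengths,
                    "irradiance": c.values,
                    "date": c.meta.get("date", ""),
                    "stand": c.meta.get("stand", ""),
                    "position": c.meta.get("position", ""),
                    "point": c.meta.get("point", 0),
                    "replicate": c.meta.get("replicate", 0),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra(path: str | Path) -> list[SpectralCurve]:
    """Read curves from long-format CSV, validating each block's grid."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    df["_row"] = np.arange(len(df)) + 2  # 1-based file line numbers incl. header
    curves: list[SpectralCurve] = []
    for key, block in df.groupby(_BLOCK_KEYS, sort=False):
        label = "/".join(str(k) for k in key)
        wl = block["wavelength_nm"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(wl) <= 0)[0]
        if bad.size:
            rows = block["_row"].to_numpy()[bad + 1][:5]
            raise ValueError(
                f"{path}: wavelength grid of block {label} is not strictly "
                f"increasing (first offending line(s): {rows.tolist()})"
            )
        y = block["irradiance"].to_numpy(dtype=float)
        neg = np.nonzero(y < 0)[0]
        if neg.size:
            rows = block["_row"].to_numpy()[neg][:5]
            raise ValueError(
                f"{path}: negative irradiance in block {label} "
                f"(line(s) {rows.tolist()})"
            )
        meta = dict(zip(_BLOCK_KEYS, key))
        curves.append(SpectralCurve(wl, y, meta))
    if not curves:
        raise ValueError(f"{path}: no spectra found")
    return curves


def write_results(
    result: ComparisonResult,
    rho_path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write the per-wavelength association table and its mean summary."""
    result.rho_frame().to_csv(rho_path, index=False)
    if summary_path is not None:
        result.summary_frame().to_csv(summary_path, index=False)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Default configuration, shallowly overridden by a YAML file if given."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        for key, value in user.items():
            if key not in config:
                raise ValueError(f"{path}: unknown config key {key!r}")
            if isinstance(config[key], dict) and isinstance(value, dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def config_hash(config: dict[str, Any]) -> str:
    """Short stable digest of a configuration, for run logs."""
    blob = json.dumps(config, sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:12]
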