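"""Spectrum tables, trace persistence and fit reports.

Spectra travel as two-column numeric tables (ppm offset from water, real
intensity; '#' comments allowed, comma/whitespace separated) with an
optional JSON sidecar (<path>.meta.json) carrying acquisition metadata.
MCMC traces persist to HDF5.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc_fit import MCMCConfig, Trace
from .spectrum_sim import Spectrum

__all__ = [
    "read_spectrum_table",
    "write_spectrum_table",
    "save_trace",
    "load_trace",
]

log = logging.getLogger("gluchange")


def read_spectrum_table(path: str | Path, resample_tol: float = 1e-6) -> Spectrum:
    """Read a two-column spectrum table into a uniform-grid Spectrum.

    Rows are sorted by the ppm axis if needed (warning logged); non-uniform
    grids are resampled to a uniform grid with a warning.  Non-numeric rows,
    NaNs or fewer than 16 points are rejected with row-level diagnostics.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, comment="#", header=None, sep=r"[,\s]+", engine="python"
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"{path}: cannot parse spectrum table: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two numeric columns")
    df = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    bad = df.index[df.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"{path}: non-numeric or NaN values at rows {bad[:10]}")
    if len(df) < 16:
        raise ValueError(f"{path}: too few points ({len(df)} < 16)")
    axis = df.iloc[:, 0].to_numpy(float)
    intensity = df.iloc[:, 1].to_numpy(float)
    if np.any(np.diff(axis) < 0):
        log.warning("%s: rows out of order; sorting by ppm axis", path)
        order = np.argsort(axis)
        axis, intensity = axis[order], intensity[order]
    d = np.diff(axis)
    if np.any(d <= 0):
        raise ValueError(f"{path}: duplicate axis values")
    if (d.max() - d.min()) > resample_tol * d.mean():
        log.warning("%s: non-uniform grid; resampling to uniform spacing", path)
        uniform = np.linspace(axis[0], axis[-1], len(axis))
        intensity = np.interp(uniform, axis, intensity)
        axis = uniform
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Spectrum(axis_ppm=axis, intensity=intensity, metadata=meta)


def write_spectrum_table(spectrum: Spectrum, path: str | Path) -> None:
    """Write (ppm, intensity) CSV plus a JSON metadata sidecar."""
    path = Path(path)
    arr = np.column_stack([spectrum.axis_ppm, np.real(spectrum.intensity)])
    np.savetxt(
        path, arr, delimiter=",", fmt="%.17g",
        header="ppm_offset_from_water,intensity", comments="# ",
    )
    if spectrum.metadata:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(spectrum.metadata, indent=1, default=str))


def save_trace(trace: Trace, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("samples", data=trace.samples, compression="gzip")
        h5.create_dataset("errors", data=trace.errors, compression="gzip")
        h5.create_dataset("acceptance", data=trace.acceptance)
        h5.create_dataset("step_sizes", data=trace.step_sizes)
        h5.attrs["y_sem"] = trace.y_sem
        h5.attrs["names"] = json.dumps(trace.names)
        h5.attrs["n_forward_failures"] = trace.n_forward_failures
        for key, val in vars(trace.config).items():
            h5.attrs[f"config:{key}"] = val


def load_trace(path: str | Path) -> Trace:
    import h5py

    with h5py.File(path, "r") as h5:
        cfg_kwargs = {
            k.split(":", 1)[1]: v for k, v in h5.attrs.items() if k.startswith("config:")
        }
        if "y_sem" in cfg_kwargs and isinstance(cfg_kwargs["y_sem"], bytes):
            cfg_kwargs["y_sem"] = cfg_kwargs["y_sem"].decode()
        for key in ("n_adapt1", "n_adapt2", "n_production", "adapt_window", "seed"):
            if key in cfg_kwargs:
                cfg_kwargs[key] = int(cfg_kwargs[key])
        return Trace(
            samples=h5["samples"][...],
            errors=h5["errors"][...],
            acceptance=h5["acceptance"][...],
            step_sizes=h5["step_sizes"][...],
            config=MCMCConfig(**cfg_kwargs),
            y_sem=float(h5.attrs["y_sem"]),
            names=json.loads(h5.attrs["names"]),
            n_forward_failures=int(h5.attrs["n_forward_failures"]),
        )
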