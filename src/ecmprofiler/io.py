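"""Serialization of study artifacts.

Force volumes are written as a documented JSON header (probe calibration,
grid, units) plus a TSV block of curves with columns x_idx / y_idx /
z_piezo_m / deflection_m.  Micrographs go to 16-bit grayscale TIFF (masks
to 8-bit) with the pixel-size calibration in a sidecar JSON.  Tabular
artifacts (panels, fits, proteomics) are plain TSV.  All float formatting
is fixed-width scientific notation, so identical inputs serialize to
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .afm import ForceVolume, HertzFit
from .micrographs import Micrograph

__all__ = [
    "write_force_volume",
    "read_force_volume",
    "write_micrograph",
    "read_micrograph",
    "write_fits_tsv",
    "read_fits_tsv",
]

_FLOAT_FMT = "%.9e"


def write_force_volume(fv: ForceVolume, directory) -> Path:
    """Write ``header.json`` + ``curves.tsv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {
        "format": "ecmprofiler-force-volume/1",
        "units": {"z_piezo": "m", "deflection": "m"},
        "probe": {
            "spring_constant_n_per_m": fv.spring_constant,
            "radius_m": fv.probe_radius,
            "poisson_ratio": fv.poisson_ratio,
        },
        "grid": {"n_x": fv.n_x, "n_y": fv.n_y, "scan_size_m": fv.scan_size},
        "points_per_curve": int(fv.z_piezo.size),
        "condition": fv.condition,
    }
    (directory / "header.json").write_text(json.dumps(header, indent=2, sort_keys=True))

    n_pts = fv.z_piezo.size
    with open(directory / "curves.tsv", "w") as fh:
        fh.write("x_idx\ty_idx\tz_piezo_m\tdeflection_m\n")
        for iy in range(fv.n_y):
            for ix in range(fv.n_x):
                d = fv.deflection[iy, ix]
                for k in range(n_pts):
                    fh.write(
                        f"{ix}\t{iy}\t{_FLOAT_FMT % fv.z_piezo[k]}\t{_FLOAT_FMT % d[k]}\n"
                    )
    return directory


def read_force_volume(directory) -> ForceVolume:
    directory = Path(directory)
    header = json.loads((directory / "header.json").read_text())
    if header.get("format") != "ecmprofiler-force-volume/1":
        raise ValueError(f"not a force-volume directory: {directory}")
    grid = header["grid"]
    n_x, n_y = grid["n_x"], grid["n_y"]
    n_pts = header["points_per_curve"]
    df = pd.read_csv(directory / "curves.tsv", sep="\t")
    deflection = np.empty((n_y, n_x, n_pts))
    z = df["z_piezo_m"].values[:n_pts].astype(float)
    d = df["deflection_m"].values.reshape(n_y, n_x, n_pts)
    deflection[:] = d
    probe = header["probe"]
    return ForceVolume(
        z_piezo=z,
        deflection=deflection,
        spring_constant=probe["spring_constant_n_per_m"],
        probe_radius=probe["radius_m"],
        poisson_ratio=probe["poisson_ratio"],
        scan_size=grid["scan_size_m"],
        condition=header.get("condition"),
    )


def write_micrograph(m: Micrograph, path) -> Path:
    """TIFF (16-bit grayscale, or 8-bit for binary masks) + sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = np.asarray(m.intensity)
    if img.dtype == bool:
        data = (img * np.uint8(255)).astype(np.uint8)
        scale = {"kind": "binary"}
    else:
        lo, hi = float(img.min()), float(img.max())
        span = hi - lo if hi > lo else 1.0
        data = np.round((img - lo) / span * 65535).astype(np.uint16)
        scale = {"kind": "linear", "min": lo, "max": hi}
    tifffile.imwrite(path, data)
    sidecar = {
        "pixel_size": m.pixel_size,
        "pixel_size_unit": "um" if m.modality == "capillary-mask" else "nm",
        "modality": m.modality,
        "scale": scale,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_micrograph(path) -> Micrograph:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = tifffile.imread(path)
    scale = sidecar.get("scale", {"kind": "binary"})
    if scale["kind"] == "binary":
        intensity = data > 0
    else:
        intensity = data.astype(float) / 65535 * (scale["max"] - scale["min"]) + scale["min"]
    return Micrograph(
        intensity=intensity,
        pixel_size=sidecar["pixel_size"],
        modality=sidecar.get("modality", "sem"),
    )


def write_fits_tsv(fits: list[HertzFit], n_x: int, path) -> Path:
    """Per-curve fit results: x_idx, y_idx, E_pa, status, residual_rms."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("x_idx\ty_idx\tE_pa\tstatus\tresidual_rms\n")
        for i, fit in enumerate(fits):
            e = _FLOAT_FMT % fit.E if np.isfinite(fit.E) else "nan"
            r = _FLOAT_FMT % fit.residual_rms if np.isfinite(fit.residual_rms) else "nan"
            fh.write(f"{i % n_x}\t{i // n_x}\t{e}\t{fit.status}\t{r}\n")
    return path


def read_fits_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
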