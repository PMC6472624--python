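"""File I/O: ENVI raster cubes, plain TIFF rasters, band metadata sidecars
and on-disk LUTs.

ENVI support covers band-sequential (BSQ) float32/float64 and integer
cubes with the usual text header — the native exchange format of airborne
hyperspectral processing chains. TIFF goes through :mod:`tifffile` and
carries no georeferencing. LUTs are stored as a compressed ``.npz``
(columnar arrays) next to a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "write_envi",
    "read_envi",
    "write_tiff",
    "read_tiff",
    "write_band_metadata",
    "read_band_metadata",
    "save_lut",
    "load_lut",
]

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_envi(path, cube: np.ndarray, wavelengths=None, description: str = ""):
    """Write a (rows, cols, bands) cube as ENVI BSQ + text header.

    *path* is the data file; the header is written alongside as
    ``<path>.hdr``.
    """
    path = Path(path)
    cube = np.asarray(cube)
    if cube.ndim == 2:
        cube = cube[:, :, None]
    rows, cols, bands = cube.shape
    code = _DTYPE_CODES.get(cube.dtype)
    if code is None:
        cube = cube.astype(np.float32)
        code = 4
    # BSQ: band-major on disk
    cube.transpose(2, 0, 1).tofile(path)
    lines = [
        "ENVI",
        f"description = {{{description or 'opencanopy export'}}}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        "interleave = bsq",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.3f}" for w in np.asarray(wavelengths, float))
        lines.append(f"wavelength units = Nanometers")
        lines.append(f"wavelength = {{{wl}}}")
    Path(str(path) + ".hdr").write_text("\n".join(lines) + "\n")


def _parse_envi_header(text: str) -> dict:
    out = {}
    key = None
    buf = ""
    in_brace = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_brace:
            buf += " " + line
            if "}" in line:
                out[key] = buf.split("}")[0].strip()
                in_brace = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            in_brace = True
            buf = val[1:]
        elif val.startswith("{"):
            out[key] = val[1:].split("}")[0].strip()
        else:
            out[key] = val
    return out


def read_envi(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ENVI BSQ cube; returns (cube (rows, cols, bands),
    wavelengths or None)."""
    path = Path(path)
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    hdr = _parse_envi_header(hdr_path.read_text())
    if hdr.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    rows = int(hdr["lines"])
    cols = int(hdr["samples"])
    bands = int(hdr["bands"])
    dtype = _ENVI_DTYPES[int(hdr["data type"])]
    data = np.fromfile(path, dtype=dtype, count=rows * cols * bands)
    cube = data.reshape(bands, rows, cols).transpose(1, 2, 0)
    wl = None
    if "wavelength" in hdr:
        wl = np.array([float(x) for x in hdr["wavelength"].split(",")])
    return cube, wl


def write_tiff(path, raster: np.ndarray):
    tifffile.imwrite(path, np.asarray(raster))


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_band_metadata(path, sensor):
    """Band metadata sidecar (JSON): name, cwl, fwhm, resolution."""
    doc = {
        "sensor": sensor.name,
        "bands": [
            {
                "name": b.name,
                "cwl": b.cwl,
                "fwhm": b.fwhm,
                "resolution": None if np.isnan(b.native_resolution) else b.native_resolution,
            }
            for b in sensor.bands
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_band_metadata(path) -> dict:
    return json.loads(Path(path).read_text())


def save_lut(lut, path):
    """Store a LUT as ``<path>.npz`` (columnar arrays) + ``<path>.json``."""
    path = Path(path)
    arrays = {f"param__{c}": lut.params[c].to_numpy() for c in lut.params}
    arrays.update({f"resp__{c}": lut.responses[c].to_numpy() for c in lut.responses})
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = {k: v for k, v in lut.meta.items() if not k.startswith("_")}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_lut(path):
    from .retrieval import LUT

    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        params = pd.DataFrame(
            {k[7:]: z[k] for k in z.files if k.startswith("param__")}
        )
        responses = pd.DataFrame(
            {k[6:]: z[k] for k in z.files if k.startswith("resp__")}
        )
    meta = json.loads(path.with_suffix(".json").read_text())
    return LUT(params=params, responses=responses, meta=meta)
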