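"""Spectral types, sensor band models and spectral/spatial resampling.

Reflectance spectra are the lingua franca of the package: leaf and canopy
radiative-transfer models produce them, vegetation indices consume them, and
the satellite view of a scene is obtained by convolving them with sensor
spectral response functions (SRFs) and block-averaging pixels.

Only centre wavelength (CWL) and full width at half maximum (FWHM) are
published for the sensors modelled here, so bands use a Gaussian SRF
surrogate with sigma = FWHM/2.355, truncated at +/- 2*FWHM and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Spectrum",
    "BandDefinition",
    "SensorModel",
    "sentinel2a",
    "airborne_vnir",
    "spectral_resample",
    "srf_weight_matrix",
    "spatial_aggregate",
]

_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # FWHM = 2*sqrt(2 ln 2) * sigma

# fraction of truncated-SRF mass that must fall inside the spectrum's
# wavelength range for a band to be considered observable
DEFAULT_MIN_COVERAGE = 0.98


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed spectrum.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm, strictly increasing.
    values : array of float
        One value per wavelength. For ``kind='reflectance'`` values must
        lie in [0, 1].
    kind : str
        ``'reflectance'`` or ``'radiance'``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vv = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelengths must be a non-empty 1-D array")
        if vv.shape[-1] != wl.size:
            raise ValueError(
                f"values last axis ({vv.shape[-1]}) must match wavelengths ({wl.size})"
            )
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("reflectance", "radiance"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "reflectance":
            finite = vv[np.isfinite(vv)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("reflectance values must lie in [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vv)

    def value_at(self, wavelength: float, tol: float = 3.0) -> float:
        """Value at *wavelength*: nearest sample within *tol* nm, else linear
        interpolation (the airborne 1.85 nm grid never hits e.g. 710.0)."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[i] - wavelength) <= tol:
            return float(self.values[..., i])
        if wavelength < self.wavelengths[0] or wavelength > self.wavelengths[-1]:
            raise ValueError(f"wavelength {wavelength} nm outside spectrum range")
        return float(np.interp(wavelength, self.wavelengths, self.values))


@dataclass(frozen=True)
class BandDefinition:
    """A sensor band: name, centre wavelength and FWHM (nm), native ground
    resolution (m)."""

    name: str
    cwl: float
    fwhm: float
    native_resolution: float = np.nan

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError(f"band {self.name}: fwhm must be > 0")
        if self.cwl <= 0:
            raise ValueError(f"band {self.name}: cwl must be > 0")

    @property
    def sigma(self) -> float:
        return self.fwhm * _FWHM_TO_SIGMA

    def support(self, truncation: float = 2.0) -> tuple[float, float]:
        """SRF support [cwl - truncation*FWHM, cwl + truncation*FWHM]."""
        half = truncation * self.fwhm
        return self.cwl - half, self.cwl + half


@dataclass(frozen=True)
class SensorModel:
    """An ordered collection of bands with unique names."""

    name: str
    bands: tuple[BandDefinition, ...]

    def __post_init__(self):
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        object.__setattr__(self, "bands", tuple(self.bands))

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]

    def band(self, name: str) -> BandDefinition:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"no band named {name!r} in sensor {self.name}")

    def __len__(self) -> int:
        return len(self.bands)

    @classmethod
    def from_yaml(cls, path) -> "SensorModel":
        """Load a sensor from a YAML band table:
        ``name: ...`` and ``bands: [{name, cwl, fwhm, resolution}, ...]``."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        bands = tuple(
            BandDefinition(
                name=str(b["name"]),
                cwl=float(b["cwl"]),
                fwhm=float(b["fwhm"]),
                native_resolution=float(b.get("resolution", np.nan)),
            )
            for b in doc["bands"]
        )
        return cls(name=str(doc.get("name", "custom")), bands=bands)


# --- presets -----------------------------------------------------------------

# Sentinel-2A MSI: 13 bands; CWL/FWHM/native resolution of the instrument.
_S2A_TABLE = [
    # name, cwl (nm), fwhm (nm), resolution (m)
    ("B1", 443.9, 27.0, 60.0),
    ("B2", 496.6, 98.0, 10.0),
    ("B3", 560.0, 45.0, 10.0),
    ("B4", 664.5, 38.0, 10.0),
    ("B5", 703.9, 19.0, 20.0),
    ("B6", 740.2, 18.0, 20.0),
    ("B7", 782.5, 28.0, 20.0),
    ("B8", 835.1, 145.0, 10.0),
    ("B8A", 864.8, 33.0, 20.0),
    ("B9", 945.0, 26.0, 60.0),
    ("B10", 1373.5, 75.0, 60.0),
    ("B11", 1613.7, 143.0, 20.0),
    ("B12", 2202.4, 242.0, 20.0),
]

#: Sentinel-2A VNIR bands used for the chlorophyll LUT inversion (10/20 m).
S2_VNIR_BANDS = ["B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A"]
#: Sentinel-2A SWIR bands (20 m) used to constrain Cm/Cw/N.
S2_SWIR_BANDS = ["B11", "B12"]


def sentinel2a() -> SensorModel:
    """The 13-band Sentinel-2A MSI preset."""
    return SensorModel(
        name="Sentinel2A",
        bands=tuple(BandDefinition(n, c, f, r) for n, c, f, r in _S2A_TABLE),
    )


def airborne_vnir() -> SensorModel:
    """The airborne VNIR imager preset: 260 bands, 400-885 nm at 1.85 nm
    sampling, 6.4 nm FWHM, 0.4 m pixels."""
    bands = tuple(
        BandDefinition(f"b{i:03d}", 400.0 + 1.85 * i, 6.4, 0.4) for i in range(260)
    )
    return SensorModel(name="AirborneVNIR", bands=bands)


def airborne_wavelengths() -> np.ndarray:
    """Centre wavelengths of the airborne VNIR grid (nm)."""
    return 400.0 + 1.85 * np.arange(260)


# --- spectral resampling -----------------------------------------------------


def _band_weights(
    band: BandDefinition,
    wavelengths: np.ndarray,
    truncation: float,
    min_coverage: float,
    quad_step: float,
) -> np.ndarray | None:
    """Quadrature nodes/weights for one band on a fine grid, folded back onto
    the spectrum's wavelength samples via linear interpolation.

    Returns a weight vector w with sum(w) == 1 such that the band value is
    w @ values, or None if the band is unavailable on this grid.
    """
    lo, hi = band.support(truncation)
    wl0, wl1 = wavelengths[0], wavelengths[-1]
    grid = np.arange(lo, hi + quad_step / 2, quad_step)
    srf = np.exp(-0.5 * ((grid - band.cwl) / band.sigma) ** 2)
    total = srf.sum()
    inside = (grid >= wl0) & (grid <= wl1)
    if srf[inside].sum() < min_coverage * total:
        return None
    grid = grid[inside]
    srf = srf[inside]
    srf /= srf.sum()
    # distribute each quadrature node's weight onto the two bracketing samples
    idx = np.searchsorted(wavelengths, grid).clip(1, wavelengths.size - 1)
    left = wavelengths[idx - 1]
    right = wavelengths[idx]
    t = (grid - left) / (right - left)
    w = np.zeros(wavelengths.size)
    np.add.at(w, idx - 1, srf * (1.0 - t))
    np.add.at(w, idx, srf * t)
    return w


def srf_weight_matrix(
    sensor: SensorModel,
    wavelengths: np.ndarray,
    truncation: float = 2.0,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    quad_step: float = 0.1,
) -> tuple[np.ndarray, list[str]]:
    """SRF weight matrix W (n_available_bands x n_wavelengths) and the names
    of the available bands; band values = values @ W.T.

    Bands whose truncated SRF mass inside the wavelength range falls below
    *min_coverage* are dropped (reported absent, never zero-filled).
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    rows, names = [], []
    for band in sensor.bands:
        w = _band_weights(band, wavelengths, truncation, min_coverage, quad_step)
        if w is not None:
            rows.append(w)
            names.append(band.name)
    if rows:
        return np.vstack(rows), names
    return np.zeros((0, wavelengths.size)), names


def spectral_resample(
    spectrum: Spectrum,
    sensor: SensorModel,
    truncation: float = 2.0,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    quad_step: float = 0.1,
) -> dict[str, float]:
    """Convolve *spectrum* with each band's Gaussian SRF.

    Returns a band-name -> value mapping containing only the available bands:
    a band whose SRF support is not covered by the spectrum (e.g. Sentinel-2
    SWIR bands from the 400-885 nm airborne grid) is omitted.
    """
    if spectrum.kind != "reflectance":
        raise ValueError("spectral_resample expects a reflectance spectrum")
    W, names = srf_weight_matrix(
        sensor, spectrum.wavelengths, truncation, min_coverage, quad_step
    )
    vals = W @ spectrum.values
    return dict(zip(names, vals.tolist()))


# --- spatial aggregation -----------------------------------------------------


def spatial_aggregate(
    cube: np.ndarray,
    factor: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Pixel-aggregate a raster cube by an integer *factor*.

    ``cube`` has shape (rows, cols) or (rows, cols, bands), row-major with
    origin top-left. Each coarse cell is the unweighted mean of its
    factor x factor block of fine cells. Where ``mask`` is True the fine cell
    is excluded from the mean; a fully masked block yields NaN.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    cube = np.asarray(cube, dtype=float)
    r, c = cube.shape[:2]
    if r % factor or c % factor:
        raise ValueError(
            f"raster shape {(r, c)} is not divisible by aggregation factor {factor}"
        )
    rr, cc = r // factor, c // factor
    squeeze = cube.ndim == 2
    if squeeze:
        cube = cube[:, :, None]
    blocks = cube.reshape(rr, factor, cc, factor, cube.shape[2])
    if mask is None:
        out = blocks.mean(axis=(1, 3))
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (r, c):
            raise ValueError("mask shape must match raster shape")
        valid = (~mask).reshape(rr, factor, cc, factor).astype(float)
        n = valid.sum(axis=(1, 3))
        s = (blocks * valid[:, :, :, :, None]).sum(axis=(1, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = s / n[:, :, None]
        out[n == 0] = np.nan
    return out[:, :, 0] if squeeze else out
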