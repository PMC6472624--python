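"""Chlorophyll and structural vegetation indices.

Two families are registered:

* narrow-band indices computed from hyperspectral crown reflectance
  (CI = R750/R710 and its Sentinel-compatible variant CI740 = R740/R710,
  Macc, TCARI, OSAVI, TCARI/OSAVI);
* the Sentinel-2 red-edge set (CI_red_edge and CI_green of Gitelson, REP,
  MTCI, MCARI/OSAVI and TCARI/OSAVI in their 705/740 nm band forms, NDRE1,
  NDRE2) plus NDVI.

Indices accept either a :class:`~opencanopy.spectra.Spectrum` (bands are
resolved by wavelength: nearest sample within 3 nm, else linear
interpolation) or a band table mapping Sentinel-2 band names to values.
A zero denominator yields NaN (flagged undefined), never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .spectra import Spectrum

__all__ = ["IndexDefinition", "REGISTRY", "compute_index", "index_map"]

#: wavelength (nm) -> Sentinel-2A band providing it. Narrow-band index
#: wavelengths fall inside MSI bands; the assignment below fixes which band
#: stands in for each (e.g. the red-edge CI on Sentinel tables becomes
#: B6/B5, the study's Sentinel variant of R750/R710).
_S2_BAND_FOR_NM = {
    490: "B2",
    550: "B3",
    560: "B3",
    665: "B4",
    670: "B4",
    680: "B4",
    700: "B5",
    705: "B5",
    710: "B5",
    740: "B6",
    750: "B6",
    780: "B7",
    783: "B7",
    800: "B8",
    835: "B8",
    865: "B8A",
}


@dataclass(frozen=True)
class IndexDefinition:
    """A named index: required wavelengths (nm) and its closed form acting
    on a resolver ``R(nm) -> value``."""

    name: str
    required_nm: tuple[int, ...]
    formula: Callable
    description: str = ""

    def __call__(self, R: Callable):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.formula(R)
        return out


def _div(a, b):
    """Elementwise a/b with 0-denominator -> NaN."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(b == 0, np.nan, a / np.where(b == 0, 1.0, b))
    return out if out.ndim else float(out)


def _tcari_705(R):
    return 3.0 * ((R(740) - R(705)) - 0.2 * (R(740) - R(560)) * _div(R(740), R(705)))


def _mcari_705(R):
    return ((R(740) - R(705)) - 0.2 * (R(740) - R(560))) * _div(R(740), R(705))


def _osavi_705(R):
    return 1.16 * _div(R(740) - R(705), R(740) + R(705) + 0.16)


REGISTRY: dict[str, IndexDefinition] = {
    d.name: d
    for d in [
        # --- narrow-band crown indices -------------------------------------
        IndexDefinition(
            "CI", (750, 710), lambda R: _div(R(750), R(710)),
            "red-edge chlorophyll index R750/R710",
        ),
        IndexDefinition(
            "CI740", (740, 710), lambda R: _div(R(740), R(710)),
            "CI with the 750 nm band replaced by Sentinel-2's 740 nm band",
        ),
        IndexDefinition(
            "MACC", (780, 710, 680),
            lambda R: _div(R(780) - R(710), R(780) - R(680)),
            "Maccioni index, robust to directional effects",
        ),
        IndexDefinition(
            "TCARI", (700, 670, 550),
            lambda R: 3.0
            * ((R(700) - R(670)) - 0.2 * (R(700) - R(550)) * _div(R(700), R(670))),
            "transformed chlorophyll absorption in reflectance index",
        ),
        IndexDefinition(
            "OSAVI", (800, 670),
            lambda R: 1.16 * _div(R(800) - R(670), R(800) + R(670) + 0.16),
            "optimized soil-adjusted vegetation index",
        ),
        IndexDefinition(
            "TCARI_OSAVI", (700, 670, 550, 800),
            lambda R: _div(
                3.0 * ((R(700) - R(670)) - 0.2 * (R(700) - R(550)) * _div(R(700), R(670))),
                1.16 * _div(R(800) - R(670), R(800) + R(670) + 0.16),
            ),
            "TCARI normalized by OSAVI",
        ),
        # --- Sentinel-2 red-edge set ---------------------------------------
        IndexDefinition(
            "CI_RED_EDGE", (783, 705), lambda R: _div(R(783), R(705)) - 1.0,
            "Gitelson red-edge chlorophyll index B7/B5 - 1",
        ),
        IndexDefinition(
            "CI_GREEN", (783, 560), lambda R: _div(R(783), R(560)) - 1.0,
            "Gitelson green chlorophyll index B7/B3 - 1",
        ),
        IndexDefinition(
            "REP", (665, 783, 705, 740),
            lambda R: 705.0
            + 35.0 * _div((R(665) + R(783)) / 2.0 - R(705), R(740) - R(705)),
            "red-edge inflection point (nm), linear four-band interpolation",
        ),
        IndexDefinition(
            "MTCI", (740, 705, 665),
            lambda R: _div(R(740) - R(705), R(705) - R(665)),
            "MERIS terrestrial chlorophyll index",
        ),
        IndexDefinition(
            "MCARI_OSAVI_705", (740, 705, 560),
            lambda R: _div(_mcari_705(R), _osavi_705(R)),
            "MCARI/OSAVI in the 705/740 nm band form",
        ),
        IndexDefinition(
            "TCARI_OSAVI_705", (740, 705, 560),
            lambda R: _div(_tcari_705(R), _osavi_705(R)),
            "TCARI/OSAVI in the 705/740 nm band form",
        ),
        IndexDefinition(
            "NDRE1", (740, 705),
            lambda R: _div(R(740) - R(705), R(740) + R(705)),
            "normalized difference red edge, bands 6/5",
        ),
        IndexDefinition(
            "NDRE2", (783, 705),
            lambda R: _div(R(783) - R(705), R(783) + R(705)),
            "normalized difference red edge, bands 7/5",
        ),
        IndexDefinition(
            "NDVI", (835, 665),
            lambda R: _div(R(835) - R(665), R(835) + R(665)),
            "normalized difference vegetation index, bands 8/4",
        ),
    ]
}


def _resolver_for(values) -> Callable:
    if isinstance(values, Spectrum):
        return lambda nm: values.value_at(float(nm))
    if isinstance(values, Mapping):

        def resolve(nm):
            nm = int(nm)
            band = _S2_BAND_FOR_NM.get(nm)
            if band is not None and band in values:
                return values[band]
            if nm in values:
                return values[nm]
            if str(nm) in values:
                return values[str(nm)]
            raise KeyError(
                f"band for {nm} nm (Sentinel-2 {band or '?'}) missing from band table"
            )

        return resolve
    raise TypeError("values must be a Spectrum or a band-name mapping")


def compute_index(values, index: IndexDefinition | str) -> float:
    """Evaluate *index* on a Spectrum or a band table.

    Missing bands raise KeyError naming the band; an undefined value (zero
    denominator) returns NaN.
    """
    if isinstance(index, str):
        index = REGISTRY[index.upper()]
    out = index(_resolver_for(values))
    return float(out) if np.ndim(out) == 0 else out


def index_map(
    cube: np.ndarray,
    wavelengths: np.ndarray,
    index: IndexDefinition | str,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel index raster from a (rows, cols, bands) cube sampled at
    *wavelengths* (nm). Masked pixels (mask True) propagate as NaN."""
    if isinstance(index, str):
        index = REGISTRY[index.upper()]
    wavelengths = np.asarray(wavelengths, float)

    def R(nm):
        i = int(np.argmin(np.abs(wavelengths - nm)))
        if abs(wavelengths[i] - nm) <= 3.0:
            return cube[..., i]
        if nm < wavelengths[0] or nm > wavelengths[-1]:
            raise KeyError(f"wavelength {nm} nm outside cube range")
        j = int(np.searchsorted(wavelengths, nm))
        t = (nm - wavelengths[j - 1]) / (wavelengths[j] - wavelengths[j - 1])
        return (1 - t) * cube[..., j - 1] + t * cube[..., j]

    out = np.asarray(index(R), dtype=float)
    if mask is not None:
        out = np.where(mask, np.nan, out)
    return out
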