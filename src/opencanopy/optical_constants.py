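"""Synthetic leaf optical constants for the plate model (400-2500 nm, 1 nm).

SYNTHETIC DATA. The specific absorption coefficients and refractive index
used here are not the published laboratory calibration tables; they are an
analytic surrogate built from Gaussian absorption features placed at the
known feature locations of the real constituents:

* chlorophyll a+b: Soret band near 430 nm and the red absorption maximum
  near 665 nm, decaying to zero across the red edge (700-750 nm);
* carotenoids: blue absorption at 450/485 nm, zero beyond ~560 nm;
* anthocyanins: green absorption centred near 545 nm;
* water: overtone bands at 970, 1200, 1450, 1940 and 2500 nm, negligible
  below 900 nm;
* dry matter: weak VNIR baseline with cellulose/lignin features at 1730,
  2100 and 2300 nm;
* refractive index: smooth decay from ~1.54 (blue) to ~1.36 (SWIR).

Peak magnitudes are calibrated so that a nominal conifer needle
(Cab=40 ug/cm2, Car=10, Cw=0.012 cm, Cm=0.012 g/cm2, N=1.8) yields a
realistic reflectance spectrum (green peak ~0.1, red trough ~0.05, NIR
plateau 0.4-0.5, strong 1450/1940 nm water absorption). Every consumer in
the package treats the table as data, so swapping in measured coefficients
is a drop-in replacement.
"""

from __future__ import annotations

import numpy as np

__all__ = ["WAVELENGTHS", "optical_constants"]

#: the common 1 nm wavelength grid of the leaf model, nm. The grid starts
#: at 380 nm so that sensor bands centred near 400 nm keep full SRF support.
WAVELENGTHS = np.arange(380.0, 2501.0, 1.0)


def _gauss(wl: np.ndarray, centre: float, width: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((wl - centre) / width) ** 2)


def optical_constants(wavelengths: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Return the synthetic coefficient table.

    Keys: ``n`` (refractive index, unitless), ``k_cab``/``k_car``/``k_anth``
    (cm2/ug), ``k_w`` (1/cm), ``k_m`` (cm2/g). All sampled on *wavelengths*
    (default: the 400-2500 nm, 1 nm grid).
    """
    wl = WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)

    n = 1.36 + 0.18 * np.exp(-(wl - 400.0) / 900.0)

    k_cab = (
        _gauss(wl, 430.0, 32.0, 0.090)
        + _gauss(wl, 665.0, 23.0, 0.072)
        + _gauss(wl, 620.0, 40.0, 0.020)  # chl-b shoulder
        + _gauss(wl, 470.0, 60.0, 0.035)
    )
    # the red absorption edge ends by ~745 nm; taper to exactly zero so the
    # 750/780 nm reference bands of the red-edge indices stay pigment-free
    k_cab *= np.clip((745.0 - wl) / 15.0, 0.0, 1.0)

    k_car = _gauss(wl, 450.0, 28.0, 0.085) + _gauss(wl, 485.0, 24.0, 0.075)
    k_car[wl > 600.0] = 0.0

    k_anth = _gauss(wl, 545.0, 35.0, 0.065)
    k_anth[wl > 650.0] = 0.0

    k_w = (
        _gauss(wl, 970.0, 35.0, 0.55)
        + _gauss(wl, 1200.0, 55.0, 1.2)
        + _gauss(wl, 1450.0, 55.0, 32.0)
        + _gauss(wl, 1790.0, 60.0, 6.0)
        + _gauss(wl, 1940.0, 70.0, 85.0)
        + _gauss(wl, 2270.0, 90.0, 28.0)
        + _gauss(wl, 2500.0, 120.0, 70.0)
    )
    k_w[wl < 850.0] = 0.0

    k_m = (
        4.0 * np.clip((wl - 800.0) / 1700.0, 0.0, None) ** 2 * 18.0
        + _gauss(wl, 1730.0, 50.0, 9.0)
        + _gauss(wl, 2100.0, 70.0, 22.0)
        + _gauss(wl, 2300.0, 60.0, 18.0)
        # cellulose/lignin are almost transparent in the visible; residual
        # structural absorption ramps in beyond the red edge and keeps the
        # NIR single-scattering albedo of a needle realistic (~0.9-0.96)
        + 0.08
        + 2.5 * np.clip((wl - 720.0) / 280.0, 0.0, 1.0)
    )

    return {
        "wavelengths": wl,
        "n": n,
        "k_cab": k_cab,
        "k_car": k_car,
        "k_anth": k_anth,
        "k_w": k_w,
        "k_m": k_m,
    }
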