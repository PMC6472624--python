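"""PROSPECT-D style leaf radiative transfer (generalized plate model).

A leaf is modelled as N homogeneous plates with rough surfaces. Constituent
contents set the absorption coefficient per elementary layer; the refractive
index sets the interface reflectivities through the average-transmissivity
function ``tav``; the Stokes system propagates reflectance/transmittance
from one layer to N layers. Output is directional-hemispherical reflectance
and transmittance on the 400-2500 nm grid at 1 nm.

The specific absorption coefficients used by default are the synthetic
surrogate table of :mod:`opencanopy.optical_constants`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import exp1

from .optical_constants import WAVELENGTHS, optical_constants
from .spectra import Spectrum

__all__ = ["LeafParams", "LeafOptics", "prospect_d", "tav"]


@dataclass(frozen=True)
class LeafParams:
    """Leaf biochemical/structural parameters.

    N : mesophyll structure parameter (number of elementary plates, >= 1)
    cab : chlorophyll a+b (ug/cm2)
    car : carotenoids (ug/cm2)
    canth : anthocyanins (ug/cm2)
    cw : equivalent water thickness (cm, i.e. g/cm2 of water)
    cm : dry matter (g/cm2)
    """

    N: float = 1.8
    cab: float = 40.0
    car: float = 10.0
    canth: float = 1.0
    cw: float = 0.012
    cm: float = 0.012

    def __post_init__(self):
        if self.N < 1.0:
            raise ValueError(f"N must be >= 1 (got {self.N})")
        for name in ("cab", "car", "canth", "cw", "cm"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative (got {v})")


@dataclass(frozen=True)
class LeafOptics:
    """Directional-hemispherical leaf reflectance and transmittance."""

    reflectance: Spectrum
    transmittance: Spectrum

    @property
    def wavelengths(self) -> np.ndarray:
        return self.reflectance.wavelengths


def tav(theta_deg: float, n: np.ndarray) -> np.ndarray:
    """Average transmissivity of a dielectric interface for isotropic light
    restricted to incidence angles [0, theta_deg], refractive index *n*
    (Stern's integral in closed form)."""
    n = np.asarray(n, dtype=float)
    if theta_deg == 0:
        return 4.0 * n / (n + 1.0) ** 2
    theta = np.radians(theta_deg)
    n2 = n**2
    npl = n2 + 1.0
    nm = n2 - 1.0
    a = (n + 1.0) ** 2 / 2.0
    k = -(nm**2) / 4.0
    ds = np.sin(theta)

    if abs(theta_deg - 90.0) < 1e-12:
        b1 = np.zeros_like(n)
    else:
        b1 = np.sqrt((ds**2 - npl / 2.0) ** 2 + k)
    b2 = ds**2 - npl / 2.0
    b = b1 - b2
    b3 = b**3
    a3 = a**3
    k2 = k**2
    nm2 = nm**2

    ts = (k2 / (6.0 * b3) + k / b - b / 2.0) - (k2 / (6.0 * a3) + k / a - a / 2.0)
    tp1 = -2.0 * n2 * (b - a) / npl**2
    tp2 = -2.0 * n2 * npl * np.log(b / a) / nm2
    tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
    tp4 = (
        16.0
        * n2**2
        * (n2**2 + 1.0)
        * np.log((2.0 * npl * b - nm2) / (2.0 * npl * a - nm2))
        / (npl**3 * nm2)
    )
    tp5 = (
        16.0
        * n2**3
        * (1.0 / (2.0 * npl * b - nm2) - 1.0 / (2.0 * npl * a - nm2))
        / npl**3
    )
    tp = tp1 + tp2 + tp3 + tp4 + tp5
    return (ts + tp) / (2.0 * ds**2)


def _layer_transmission(k: np.ndarray) -> np.ndarray:
    """Isotropic transmission through one absorbing elementary layer,
    theta(k) = (1-k) e^-k + k^2 E1(k); theta(0) = 1."""
    k = np.asarray(k, dtype=float)
    out = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    out[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    return np.clip(out, 0.0, 1.0)


def prospect_d(
    params: LeafParams,
    constants: dict | None = None,
) -> LeafOptics:
    """Compute leaf reflectance and transmittance for *params*.

    Deterministic; returns spectra on the 400-2500 nm grid. ``constants``
    may override the coefficient table (same keys as
    :func:`opencanopy.optical_constants.optical_constants`).
    """
    R, T, wl = _prospect_arrays(
        np.array([params.N]),
        np.array([params.cab]),
        np.array([params.car]),
        np.array([params.canth]),
        np.array([params.cw]),
        np.array([params.cm]),
        constants,
    )
    return LeafOptics(
        reflectance=Spectrum(wl, np.clip(R[0], 0.0, 1.0)),
        transmittance=Spectrum(wl, np.clip(T[0], 0.0, 1.0)),
    )


def prospect_batch(
    N,
    cab,
    car,
    canth,
    cw,
    cm,
    constants: dict | None = None,
    chunk: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chunked vectorized plate model over parameter arrays of shape (n,).

    Returns (R, T, wavelengths) with R, T of shape (n, n_wavelengths).
    Chunking keeps the working set cache resident on the 2101-point grid.
    """
    N = np.asarray(N, float)
    args = [np.broadcast_to(np.asarray(a, float), N.shape) for a in (cab, car, canth, cw, cm)]
    n = N.shape[0]
    R = None
    for i in range(0, n, chunk):
        s = slice(i, min(i + chunk, n))
        r, t, wl = _prospect_arrays(N[s], *[a[s] for a in args], constants)
        if R is None:
            R = np.empty((n, wl.size))
            T = np.empty((n, wl.size))
        R[s] = r
        T[s] = t
    return R, T, wl


def _prospect_arrays(
    N: np.ndarray,
    cab: np.ndarray,
    car: np.ndarray,
    canth: np.ndarray,
    cw: np.ndarray,
    cm: np.ndarray,
    constants: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized plate model over a batch of parameter vectors.

    All parameter arrays share shape (n,); returns (R, T, wavelengths) with
    R, T of shape (n, n_wavelengths). This is the hot path for LUT builds.
    """
    cc = optical_constants() if constants is None else constants
    wl = cc["wavelengths"]
    n_re = cc["n"][None, :]

    N = np.asarray(N, float)[:, None]
    absorb = (
        cab[:, None] * cc["k_cab"][None, :]
        + car[:, None] * cc["k_car"][None, :]
        + canth[:, None] * cc["k_anth"][None, :]
        + cw[:, None] * cc["k_w"][None, :]
        + cm[:, None] * cc["k_m"][None, :]
    )
    k = absorb / N
    theta = _layer_transmission(k)

    # interface transmissivities: alpha=40 deg for the upper surface of the
    # first layer, 90 deg (diffuse) elsewhere
    talf = tav(40.0, n_re)
    ralf = 1.0 - talf
    t12 = tav(90.0, n_re)
    r12 = 1.0 - t12
    t21 = t12 / n_re**2
    r21 = 1.0 - t21

    denom = 1.0 - r21**2 * theta**2
    Ta = talf * theta * t21 / denom
    Ra = ralf + r21 * theta * Ta
    t = t12 * theta * t21 / denom
    r = r12 + r21 * theta * t

    # Stokes solution for the remaining N-1 layers
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.sqrt(
            np.clip((1 + r + t) * (1 + r - t) * (1 - r + t) * (1 - r - t), 0, None)
        )
        rq = r**2
        tq = t**2
        a = (1 + rq - tq + D) / (2 * r)
        b = (1 - rq + tq + D) / (2 * t)

        bNm1 = b ** (N - 1.0)
        bN2 = bNm1**2
        a2 = a**2
        denom2 = a2 * bN2 - 1.0
        Rsub = a * (bN2 - 1.0) / denom2
        Tsub = bNm1 * (a2 - 1.0) / denom2

    # non-absorbing limit (r + t -> 1): Stokes system degenerates
    cons = (r + t) >= 1.0 - 1e-12
    if np.any(cons):
        Tsub_c = t / (t + (1.0 - t) * (N - 1.0))
        Tsub = np.where(cons, Tsub_c, Tsub)
        Rsub = np.where(cons, 1.0 - Tsub_c, Rsub)

    denom3 = 1.0 - Rsub * r
    RN = Ra + Ta * Rsub * t / denom3
    TN = Ta * Tsub / denom3
    return RN, TN, wl
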