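"""Canopy and stand reflectance: 4SAIL, PROSAIL and a FLIM/INFORM hybrid.

Three scales are modelled:

* **4SAIL** — bidirectional reflectance of a horizontally homogeneous turbid
  medium of leaves (four-stream; hotspot correction on the single-scattering
  term). Used directly for the understory and, at saturating LAI, for the
  "infinite crown" reflectance of the stand model.
* **PROSAIL** — the composition ``foursail(prospect_d(leaf), canopy)``.
* **INFORM/FLIM hybrid** — sparse-stand reflectance as an area mixture of
  sunlit/shaded crown, background seen through crown gaps, shadowed
  background and open sunlit background. Crown cover follows a Boolean
  (Poisson disc) model; crown shadows are the sun-projected ellipses of
  ellipsoidal crown envelopes; crown transparency in the sun/view directions
  follows the same ellipsoidal leaf-angle distribution used by 4SAIL.

Leaf angle statistics use Campbell's ellipsoidal distribution parametrized
by the average leaf angle (ALA), discretized in 18 bins of 5 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .leaf_rt import LeafOptics, LeafParams, _prospect_arrays, prospect_d
from .spectra import Spectrum

__all__ = [
    "CanopyParams",
    "StandParams",
    "SceneComponentSet",
    "StandDiagnostics",
    "foursail",
    "sail_batch",
    "prosail",
    "flim_geometry",
    "inform_forward",
    "mix_components",
    "extinction_coefficient",
    "diffuse_fraction",
    "SATURATING_LAI",
]

#: LAI at which the crown medium is optically semi-infinite; doubling it
#: changes the modelled reflectance by < 1e-4.
SATURATING_LAI = 15.0

_HA = 1.0e4  # m2 per hectare


@dataclass(frozen=True)
class CanopyParams:
    """Turbid-medium canopy: LAI, average leaf angle (deg), hotspot size,
    soil spectrum below the canopy and (sun, view, azimuth) geometry in
    degrees."""

    lai: float
    soil: Spectrum
    ala: float = 57.0
    hotspot: float = 0.01
    tts: float = 26.0
    tto: float = 0.0
    psi: float = 0.0

    def __post_init__(self):
        if self.lai < 0:
            raise ValueError("LAI must be >= 0")
        if not 0.0 < self.ala < 90.0:
            raise ValueError("ALA must be in (0, 90) degrees")
        if self.hotspot < 0:
            raise ValueError("hotspot must be >= 0")
        for ang, nm in ((self.tts, "tts"), (self.tto, "tto")):
            if not 0.0 <= ang < 90.0:
                raise ValueError(f"{nm} must be in [0, 90) degrees")


@dataclass(frozen=True)
class StandParams:
    """Sparse forest stand.

    td : tree density (trees/ha); cd : crown diameter (m); ch : crown height
    (m); c_lai : leaf area index inside a crown envelope; ala : crown
    average leaf angle (deg); background : spectrum of the surface between
    crowns (soil or understory); geometry in degrees.
    """

    td: float
    cd: float
    ch: float
    c_lai: float
    background: Spectrum
    ala: float = 60.0
    hotspot: float = 0.01
    tts: float = 26.0
    tto: float = 0.0
    psi: float = 0.0
    #: surface beneath/behind the crowns (light-limited, usually bare
    #: soil); None -> same as the between-crown background
    crown_substrate: Spectrum | None = None

    def __post_init__(self):
        if self.td < 0:
            raise ValueError("tree density must be >= 0")
        if self.cd <= 0 or self.ch <= 0:
            raise ValueError("crown diameter and height must be > 0")
        if self.c_lai < 0:
            raise ValueError("crown LAI must be >= 0")
        if not 0.0 <= self.tts < 90.0:
            raise ValueError("solar zenith must be in [0, 90) degrees")


@dataclass(frozen=True)
class SceneComponentSet:
    """Per-pixel fractions and mean spectra of the four scene components."""

    fractions: dict  # keys: crown, understory, bare_soil, shadow
    spectra: dict  # same keys -> Spectrum or None (empty component)

    KEYS = ("crown", "understory", "bare_soil", "shadow")

    def __post_init__(self):
        fr = {k: float(self.fractions.get(k, 0.0)) for k in self.KEYS}
        total = sum(fr.values())
        if not 0.98 <= total <= 1.02:
            raise ValueError(
                f"component fractions sum to {total:.4f}, outside [0.98, 1.02]"
            )
        fr = {k: v / total for k, v in fr.items()}
        for k, v in fr.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {k} = {v} outside [0, 1]")
        object.__setattr__(self, "fractions", fr)


@dataclass(frozen=True)
class StandDiagnostics:
    """Geometric stand descriptors: crown cover, ground shadow fraction and
    crown gap transparencies along the sun (Ts) and view (To) directions."""

    crown_cover: float
    shadow_fraction: float
    crown_transparency_sun: float
    crown_transparency_view: float
    sunlit_crown_fraction: float = 1.0


# --- leaf angle distribution -------------------------------------------------

_LEAF_ANGLES = np.arange(2.5, 90.0, 5.0)  # bin centres, deg


def ellipsoidal_lidf(ala: float | np.ndarray) -> np.ndarray:
    """Campbell's ellipsoidal leaf inclination distribution.

    Returns bin frequencies over 18 bins of 5 deg (centres 2.5..87.5) for
    average leaf angle *ala* in degrees; vectorizes over an array of ALAs
    (output shape (..., 18)).
    """
    ala = np.asarray(ala, dtype=float)
    scalar = ala.ndim == 0
    ala = np.atleast_1d(ala)[..., None]  # (..., 1)
    excent = np.exp(
        -1.6184e-5 * ala**3 + 2.1145e-3 * ala**2 - 1.2390e-1 * ala + 3.2491
    )
    edges = np.radians(np.arange(0.0, 91.0, 5.0))
    tan_e = np.tan(edges)[None, :]
    x = excent / np.sqrt(1.0 + excent**2 * tan_e**2)  # (..., 19)
    x = np.where(np.isfinite(tan_e), x, 0.0)

    alpha = excent / np.sqrt(np.abs(1.0 - excent**2))
    alpha2 = alpha**2
    x2 = x**2
    with np.errstate(invalid="ignore"):
        # prolate (excent > 1) and oblate (excent < 1) antiderivatives
        alpx = np.sqrt(np.clip(alpha2 + x2, 0, None))
        f_pro = x * alpx + alpha2 * np.log(np.clip(x + alpx, 1e-300, None))
        almx = np.sqrt(np.clip(alpha2 - x2, 0, None))
        f_obl = x * almx + alpha2 * np.arcsin(np.clip(x / alpha, -1.0, 1.0))
    f = np.where(excent > 1.0, f_pro, f_obl)
    freq = np.abs(np.diff(f, axis=-1))
    # spherical special case (excent == 1): freq = |cos e1 - cos e2|
    sph = np.isclose(excent[..., 0], 1.0)
    if np.any(sph):
        fsph = np.abs(np.diff(np.cos(edges)))
        freq[sph] = fsph
    freq = freq / freq.sum(axis=-1, keepdims=True)
    return freq[0] if scalar else freq


def _volscatt(tts: float, tto: float, psi: float, ttl: float):
    """SAIL volume-scattering geometry factors for one leaf inclination.

    Returns (chi_s, chi_o, frho, ftau): interception cross-sections in the
    sun/view directions and the bidirectional scattering fractions that
    multiply leaf reflectance and transmittance.
    """
    rd = np.pi / 180.0
    costs, costo = np.cos(rd * tts), np.cos(rd * tto)
    sints, sinto = np.sin(rd * tts), np.sin(rd * tto)
    cospsi = np.cos(rd * psi)
    psir = rd * psi
    costl, sintl = np.cos(rd * ttl), np.sin(rd * ttl)
    cs = costl * costs
    co = costl * costo
    ss = sintl * sints
    so = sintl * sinto

    cosbts = 5.0 if abs(ss) <= 1e-6 else -cs / ss
    cosbto = 5.0 if abs(so) <= 1e-6 else -co / so

    if abs(cosbts) < 1.0:
        bts = np.arccos(cosbts)
        ds = ss
    else:
        bts = np.pi
        ds = cs
    chi_s = 2.0 / np.pi * ((bts - np.pi * 0.5) * cs + np.sin(bts) * ss)

    if abs(cosbto) < 1.0:
        bto = np.arccos(cosbto)
        do_ = so
    elif tto < 90.0:
        bto = np.pi
        do_ = co
    else:
        bto = 0.0
        do_ = -co
    chi_o = 2.0 / np.pi * ((bto - np.pi * 0.5) * co + np.sin(bto) * so)

    btran1 = abs(bts - bto)
    btran2 = np.pi - abs(bts + bto - np.pi)
    if psir <= btran1:
        bt1, bt2, bt3 = psir, btran1, btran2
    elif psir <= btran2:
        bt1, bt2, bt3 = btran1, psir, btran2
    else:
        bt1, bt2, bt3 = btran1, btran2, psir

    t1 = 2.0 * cs * co + ss * so * cospsi
    t2 = 0.0
    if bt2 > 0.0:
        t2 = np.sin(bt2) * (2.0 * ds * do_ + ss * so * np.cos(bt1) * np.cos(bt3))
    denom = 2.0 * np.pi**2
    frho = ((np.pi - bt2) * t1 + t2) / denom
    ftau = (-bt2 * t1 + t2) / denom
    return chi_s, chi_o, max(frho, 0.0), max(ftau, 0.0)


def _sail_geom_factors(ala, tts: float, tto: float, psi: float):
    """LIDF-weighted geometric factors (ks, ko, bf, sob, sof); each is a
    scalar or an array over a batch of ALAs."""
    lidf = ellipsoidal_lidf(ala)  # (..., 18)
    cts = np.cos(np.radians(tts))
    cto = np.cos(np.radians(tto))
    ctscto = cts * cto
    ksl = np.empty(18)
    kol = np.empty(18)
    sobl = np.empty(18)
    sofl = np.empty(18)
    bfl = np.empty(18)
    for i, ttl in enumerate(_LEAF_ANGLES):
        chi_s, chi_o, frho, ftau = _volscatt(tts, tto, psi, ttl)
        ksl[i] = chi_s / cts
        kol[i] = chi_o / cto
        sobl[i] = frho * np.pi / ctscto
        sofl[i] = ftau * np.pi / ctscto
        bfl[i] = np.cos(np.radians(ttl)) ** 2
    ks = lidf @ ksl
    ko = lidf @ kol
    bf = lidf @ bfl
    sob = lidf @ sobl
    sof = lidf @ sofl
    return ks, ko, bf, sob, sof


def extinction_coefficient(ala: float, theta: float) -> float:
    """Directional extinction coefficient k(theta) = G(theta)/cos(theta) for
    the ellipsoidal LIDF with average leaf angle *ala*; crown gap fraction
    along that direction is exp(-k * LAI)."""
    ks, *_ = _sail_geom_factors(ala, theta, 0.0, 0.0)
    return float(ks)


# --- 4SAIL -------------------------------------------------------------------


def _j1(k, m, t):
    """J1(k, m, t) = (e^{-mt} - e^{-kt}) / (k - m), series near k = m."""
    delta = (k - m) * t
    safe = np.abs(delta) > 1e-3
    with np.errstate(invalid="ignore", divide="ignore"):
        gen = (np.exp(-m * t) - np.exp(-k * t)) / (k - m)
    ser = 0.5 * t * (np.exp(-k * t) + np.exp(-m * t)) * (1.0 - delta**2 / 12.0)
    return np.where(safe, gen, ser)


def _j2(k, m, t):
    """J2(k, m, t) = (1 - e^{-(k+m)t}) / (k + m)."""
    return (1.0 - np.exp(-(k + m) * t)) / (k + m)


def _sail_arrays(rho, tau, rsoil, lai, ala, hotspot, tts, tto, psi):
    """Vectorized 4SAIL bidirectional reflectance.

    rho, tau : (B, L) leaf reflectance/transmittance
    rsoil    : (L,) or (B, L) soil spectrum
    lai, ala : scalars or (B,) arrays
    Returns the directional reflectance for direct sun, shape (B, L).
    """
    rho = np.atleast_2d(np.asarray(rho, float))
    tau = np.atleast_2d(np.asarray(tau, float))
    B, L = rho.shape
    rsoil = np.asarray(rsoil, float)
    if rsoil.ndim == 1:
        rsoil = np.broadcast_to(rsoil, (B, L))
    lai = np.broadcast_to(np.asarray(lai, float), (B,)).astype(float)
    ala_arr = np.broadcast_to(np.asarray(ala, float), (B,))

    ks, ko, bf, sob, sof = _sail_geom_factors(ala_arr, tts, tto, psi)
    ks = ks[:, None]
    ko = ko[:, None]
    bf = bf[:, None]
    sob = sob[:, None]
    sof = sof[:, None]

    sdb = 0.5 * (ks + bf)
    sdf = 0.5 * (ks - bf)
    dob = 0.5 * (ko + bf)
    dof = 0.5 * (ko - bf)
    ddb = 0.5 * (1.0 + bf)
    ddf = 0.5 * (1.0 - bf)

    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    att = 1.0 - sigf
    m = np.sqrt(np.clip((att + sigb) * (att - sigb), 0.0, None))
    sb = sdb * rho + sdf * tau
    sf = sdf * rho + sdb * tau
    vb = dob * rho + dof * tau
    vf = dof * rho + dob * tau
    w = sob * rho + sof * tau

    laic = np.clip(lai, 1e-9, None)[:, None]

    e1 = np.exp(-m * laic)
    e2 = e1**2
    sigb_safe = np.where(np.abs(sigb) < 1e-30, 1e-30, sigb)
    rinf = (att - m) / sigb_safe
    rinf2 = rinf**2
    re = rinf * e1
    denom = 1.0 - rinf2 * e2

    J1ks = _j1(ks, m, laic)
    J2ks = _j2(ks, m, laic)
    J1ko = _j1(ko, m, laic)
    J2ko = _j2(ko, m, laic)

    Ps = (sf + sb * rinf) * J1ks
    Qs = (sf * rinf + sb) * J2ks
    Pv = (vf + vb * rinf) * J1ko
    Qv = (vf * rinf + vb) * J2ko

    tdd = (1.0 - rinf2) * e1 / denom
    rdd = rinf * (1.0 - e2) / denom
    tsd = (Ps - re * Qs) / denom
    rsd = (Qs - re * Ps) / denom
    tdo = (Pv - re * Qv) / denom
    rdo = (Qv - re * Pv) / denom

    tss = np.exp(-ks * laic)
    too = np.exp(-ko * laic)
    z = _j2(ks, ko, laic)
    g1 = (z - J1ks * too) / (ko + m)
    g2 = (z - J1ko * tss) / (ks + m)
    Tv1 = (vf * rinf + vb) * g1
    Tv2 = (vf + vb * rinf) * g2
    T1 = Tv1 * (sf + sb * rinf)
    T2 = Tv2 * (sf * rinf + sb)
    T3 = (rdo * Qs + tdo * Ps) * rinf
    rsod = (T1 + T2 - T3) / (1.0 - rinf2)

    # hotspot: joint gap probability along sun and view paths
    rd = np.pi / 180.0
    tants, tanto = np.tan(rd * tts), np.tan(rd * tto)
    cospsi = np.cos(rd * psi)
    dso = np.sqrt(max(tants**2 + tanto**2 - 2.0 * tants * tanto * cospsi, 0.0))

    ks1 = ks[:, 0]
    ko1 = ko[:, 0]
    lai1 = laic[:, 0]
    if hotspot > 0:
        alf = np.minimum((dso / hotspot) * 2.0 / (ks1 + ko1), 200.0)
    else:
        alf = np.full(B, 200.0)
    sumint = np.zeros(B)
    tsstoo = np.zeros(B)
    hot = alf == 0.0  # exact hotspot direction
    if np.any(hot):
        tsstoo[hot] = np.exp(-ks1[hot] * lai1[hot])
        sumint[hot] = (1.0 - np.exp(-ks1[hot] * lai1[hot])) / (ks1[hot] * lai1[hot])
    gen = ~hot
    if np.any(gen):
        a = alf[gen]
        fhot = lai1[gen] * np.sqrt(ko1[gen] * ks1[gen])
        fint = (1.0 - np.exp(-a)) * 0.05
        x1 = np.zeros_like(a)
        y1 = np.zeros_like(a)
        f1 = np.ones_like(a)
        s = np.zeros_like(a)
        for istep in range(1, 21):
            if istep < 20:
                x2 = -np.log(1.0 - istep * fint) / a
            else:
                x2 = np.ones_like(a)
            y2 = -(ko1[gen] + ks1[gen]) * lai1[gen] * x2 + fhot * (
                1.0 - np.exp(-a * x2)
            ) / a
            f2 = np.exp(y2)
            s = s + (f2 - f1) * (x2 - x1) / np.where(y2 - y1 == 0, 1e-30, y2 - y1)
            x1, y1, f1 = x2, y2, f2
        tsstoo[gen] = f1
        sumint[gen] = s
    rsos = w * (laic * sumint[:, None])
    rso = rsos + rsod

    # coupling with the soil lower boundary
    dn = 1.0 - rsoil * rdd
    rsodt = ((tss + tsd) * tdo + (tsd + tss * rsoil * rdd) * too) * rsoil / dn + rsod
    rsost = rsos + tsstoo[:, None] * rsoil
    rsot = rsost + rsodt

    # empty canopy: exact passthrough of the soil
    empty = lai <= 0.0
    if np.any(empty):
        rsot = rsot.copy()
        rsot[empty] = rsoil[empty]
    return rsot


def sail_batch(
    rho,
    tau,
    rsoil,
    lai,
    ala,
    hotspot,
    tts,
    tto,
    psi,
    chunk: int = 100,
) -> np.ndarray:
    """Chunked batch 4SAIL over (B, L) leaf optics.

    Row chunks are kept small enough for the working set to stay cache
    resident, which matters on long wavelength grids.
    """
    rho = np.atleast_2d(np.asarray(rho, float))
    tau = np.atleast_2d(np.asarray(tau, float))
    B = rho.shape[0]
    rsoil = np.asarray(rsoil, float)
    lai = np.broadcast_to(np.asarray(lai, float), (B,))
    ala = np.broadcast_to(np.asarray(ala, float), (B,))
    out = np.empty_like(rho)
    for i in range(0, B, chunk):
        s = slice(i, min(i + chunk, B))
        soil_s = rsoil if rsoil.ndim == 1 else rsoil[s]
        out[s] = _sail_arrays(
            rho[s], tau[s], soil_s, lai[s], ala[s], hotspot, tts, tto, psi
        )
    return out


def foursail(leaf: LeafOptics, canopy: CanopyParams) -> Spectrum:
    """Bidirectional top-of-canopy reflectance of a turbid leaf medium over
    the given soil, for direct solar illumination."""
    wl = leaf.wavelengths
    if wl.shape != canopy.soil.wavelengths.shape or np.any(
        wl != canopy.soil.wavelengths
    ):
        raise ValueError("leaf and soil spectra must share the wavelength grid")
    out = _sail_arrays(
        leaf.reflectance.values,
        leaf.transmittance.values,
        canopy.soil.values,
        canopy.lai,
        canopy.ala,
        canopy.hotspot,
        canopy.tts,
        canopy.tto,
        canopy.psi,
    )
    return Spectrum(wl, np.clip(out[0], 0.0, 1.0))


def prosail(leaf_params: LeafParams, canopy: CanopyParams) -> Spectrum:
    """PROSPECT-D coupled to 4SAIL: ``foursail(prospect_d(p), canopy)``."""
    return foursail(prospect_d(leaf_params), canopy)


# --- FLIM/INFORM stand model -------------------------------------------------


def diffuse_fraction(wavelengths: np.ndarray) -> np.ndarray:
    """Irradiance reaching shaded surfaces relative to sunlit ones: 0.25 in
    the visible rising linearly to 0.35 in the NIR (700-1000 nm ramp)."""
    wl = np.asarray(wavelengths, float)
    return 0.25 + 0.10 * np.clip((wl - 700.0) / 300.0, 0.0, 1.0)


def _disc_ellipse_overlap(a, ay, d, nx: int = 64):
    """Area of intersection between the crown disc (radius a, centred at the
    origin) and its own ground-shadow ellipse (semi-axes a, ay, centre
    (0, d)); vectorized over arrays. 1-D quadrature over x."""
    a = np.atleast_1d(np.asarray(a, float))
    ay = np.broadcast_to(np.asarray(ay, float), a.shape)
    d = np.broadcast_to(np.asarray(d, float), a.shape)
    x = (np.arange(nx) + 0.5) / nx  # x/a in (0, 1)
    half = np.sqrt(1.0 - x**2)  # in units of a / ay respectively
    ylo_c = -a[:, None] * half
    yhi_c = a[:, None] * half
    ylo_e = d[:, None] - ay[:, None] * half
    yhi_e = d[:, None] + ay[:, None] * half
    seg = np.clip(np.minimum(yhi_c, yhi_e) - np.maximum(ylo_c, ylo_e), 0.0, None)
    # factor 2: symmetric in x; dx = a/nx
    return 2.0 * seg.sum(axis=1) * a / nx


def _stand_geometry(td, cd, ch, c_lai, ala, tts, tto):
    """Boolean-model stand geometry; vectorizes over (td, cd, c_lai) arrays.

    A tree's shading region is its sun-projected ellipse minus its own
    crown disc (the region where its shadow falls on *other* surfaces).

    Returns (co, shadow, ts, to, s_sun):
    co     : crown cover 1 - exp(-Td * crown area / 1e4)
    shadow : ground fraction shaded by crowns but not covered by them
    ts, to : crown gap transparency along sun / view directions
    s_sun  : probability that a viewed crown point escapes the shading
             regions of neighbouring trees
    """
    td = np.asarray(td, float)
    cd = np.asarray(cd, float)
    c_lai = np.asarray(c_lai, float)
    a = cd / 2.0
    b = np.asarray(ch, float) / 2.0
    area_crown = np.pi * a**2
    tan_s = np.tan(np.radians(tts))
    # ground shadow of an ellipsoid (semi-axes a, a, b) lit at zenith tts
    ay = np.sqrt(a**2 + b**2 * tan_s**2)
    offset = b * tan_s
    area_shadow = np.pi * a * ay
    area_overlap = _disc_ellipse_overlap(a, ay, offset)
    area_excess = np.clip(area_shadow - area_overlap, 0.0, None)
    lam_c = td * area_crown / _HA
    lam_ex = np.squeeze(td * area_excess / _HA) if np.ndim(td) == 0 else td * area_excess / _HA
    co = 1.0 - np.exp(-lam_c)
    # union of crown discs and shading regions (disjoint per tree)
    total = 1.0 - np.exp(-(lam_c + lam_ex))
    shadow = np.clip(total - co, 0.0, 1.0)
    ks = extinction_coefficient(float(ala), float(tts))
    ko = extinction_coefficient(float(ala), float(tto))
    ts = np.exp(-ks * c_lai)
    to = np.exp(-ko * c_lai)
    s_sun = np.exp(-lam_ex)
    return co, shadow, ts, to, s_sun


def flim_geometry(stand: StandParams) -> StandDiagnostics:
    """Geometric diagnostics of a stand under the Boolean crown model."""
    co, sh, ts, to, s_sun = _stand_geometry(
        stand.td, stand.cd, stand.ch, stand.c_lai, stand.ala, stand.tts, stand.tto
    )
    return StandDiagnostics(
        crown_cover=float(co),
        shadow_fraction=float(sh),
        crown_transparency_sun=float(ts),
        crown_transparency_view=float(to),
        sunlit_crown_fraction=float(s_sun),
    )


def _inform_mix(rc_inf, background, wl, co, shadow, ts, to, s_sun, crown_sub=None):
    """Area mixture of the INFORM hybrid; broadcasts over a batch axis.

    rc_inf : (B, L) infinite-crown reflectance; background: (L,) or (B, L).
    co, shadow, ts, to, s_sun : scalars or (B,) arrays. ``crown_sub`` is the
    surface seen through crown gaps (defaults to the background).
    """
    omega = diffuse_fraction(wl)[None, :]
    bg = np.atleast_2d(background)
    sub = bg if crown_sub is None else np.atleast_2d(crown_sub)
    c = np.atleast_1d(np.asarray(co, float))[:, None]
    sh = np.atleast_1d(np.asarray(shadow, float))[:, None]
    tsto = (np.atleast_1d(np.asarray(ts, float)) * np.atleast_1d(np.asarray(to, float)))[
        :, None
    ]
    s = np.atleast_1d(np.asarray(s_sun, float))[:, None]
    # a shaded crown pixel (incl. the substrate seen through its gaps) only
    # receives the diffuse irradiance fraction
    crown = (s + (1.0 - s) * omega) * ((1.0 - tsto) * rc_inf + tsto * sub)
    lit_open = np.clip(1.0 - c - sh, 0.0, 1.0)
    return c * crown + sh * omega * bg + lit_open * bg


def inform_forward(
    leaf_params: LeafParams,
    stand: StandParams,
    saturating_lai: float = SATURATING_LAI,
) -> tuple[Spectrum, StandDiagnostics]:
    """Stand-level reflectance of a sparse forest.

    The crown medium contributes its semi-infinite 4SAIL reflectance on the
    sunlit part of the viewed crowns and a diffuse-floor level on the shaded
    part; the background is seen through crown gaps (attenuated by Ts*To),
    in cast shadows (diffuse floor) and in the open. ``td = 0`` returns the
    background exactly.
    """
    leaf = prospect_d(leaf_params)
    wl = leaf.wavelengths
    if wl.shape != stand.background.wavelengths.shape or np.any(
        wl != stand.background.wavelengths
    ):
        raise ValueError("background spectrum must be on the leaf wavelength grid")
    diag = flim_geometry(stand)
    if stand.td == 0:
        return Spectrum(wl, stand.background.values.copy()), diag
    sub = (
        stand.background.values
        if stand.crown_substrate is None
        else stand.crown_substrate.values
    )
    rc_inf = _sail_arrays(
        leaf.reflectance.values,
        leaf.transmittance.values,
        sub,
        saturating_lai,
        stand.ala,
        stand.hotspot,
        stand.tts,
        stand.tto,
        stand.psi,
    )
    mixed = _inform_mix(
        rc_inf,
        stand.background.values,
        wl,
        diag.crown_cover,
        diag.shadow_fraction,
        diag.crown_transparency_sun,
        diag.crown_transparency_view,
        diag.sunlit_crown_fraction,
        crown_sub=sub,
    )
    return Spectrum(wl, np.clip(mixed[0], 0.0, 1.0)), diag


def mix_components(components: SceneComponentSet) -> Spectrum:
    """Area-weighted linear mixture of the four component spectra."""
    fr = components.fractions
    wl = None
    acc = None
    for key in SceneComponentSet.KEYS:
        f = fr[key]
        sp = components.spectra.get(key)
        if sp is None:
            if f > 0:
                raise ValueError(f"component {key} has fraction {f} but no spectrum")
            continue
        if wl is None:
            wl = sp.wavelengths
            acc = np.zeros_like(sp.values, dtype=float)
        elif sp.wavelengths.shape != wl.shape or np.any(sp.wavelengths != wl):
            raise ValueError("component spectra must share a wavelength grid")
        acc = acc + f * sp.values
    if wl is None:
        raise ValueError("no component spectra given")
    return Spectrum(wl, acc)
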