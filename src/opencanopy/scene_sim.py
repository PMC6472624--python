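"""Synthetic open-canopy scene generator with known ground truth.

Builds high-resolution (default 0.4 m) hyperspectral scenes of sparse
conifer stands: trees are placed by a seeded Poisson process, circular
crowns and sun-cast elliptical shadows are rasterized, understory patches
are carved from thresholded smooth noise, and every component's spectrum
comes from the package's own radiative-transfer models (so a noise-free
scene is exactly consistent with the forward models used for retrieval).

The generator's defaults emulate the study landscape: 61 sites of
120 m x 120 m, crown cover ~3-34%, understory 23-73%, bare soil 6-69%,
shadow 1-27%, crown chlorophyll ~16-53 ug/cm2, understory chlorophyll
~2-47 ug/cm2, sun zenith 26 deg (June) or 73 deg (December), airborne
VNIR sensor (260 bands, 400-885 nm) plus a coincident Sentinel-2A view
computed per 20 m cell from the full 400-2500 nm component spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .canopy_rt import (
    CanopyParams,
    diffuse_fraction,
    extinction_coefficient,
    foursail,
    sail_batch,
    SATURATING_LAI,
)
from .components import CLASS_IDS
from .leaf_rt import LeafParams, prospect_batch, prospect_d
from .optical_constants import WAVELENGTHS
from .spectra import (
    Spectrum,
    airborne_vnir,
    sentinel2a,
    srf_weight_matrix,
)

__all__ = ["SceneConfig", "SyntheticScene", "generate_scene", "truth_for_grid",
           "soil_spectrum", "study_site_configs"]

log = logging.getLogger(__name__)


def soil_spectrum(brightness: float = 1.0) -> Spectrum:
    """Smooth dry-soil reflectance on the 400-2500 nm grid: a brightening
    linear ramp with weak water features, scaled by *brightness*."""
    wl = WAVELENGTHS
    base = 0.10 + 0.22 * (wl - 400.0) / 2100.0
    dips = 0.03 * np.exp(-0.5 * ((wl - 1940.0) / 80.0) ** 2) + 0.02 * np.exp(
        -0.5 * ((wl - 1450.0) / 60.0) ** 2
    )
    return Spectrum(wl, np.clip(brightness * (base - dips), 0.0, 1.0))


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one synthetic site.

    Defaults reproduce a June study site; ``replace(cfg, sun_zenith=73.0)``
    gives its December counterpart on the same layout seed.
    """

    extent: tuple[float, float] = (120.0, 120.0)  # m
    resolution: float = 0.4  # m
    td: float = 150.0  # trees/ha
    cd_mean: float = 4.5  # crown diameter, m
    cd_sd: float = 0.25
    cd_range: tuple[float, float] = (4.0, 5.0)
    ch: float = 7.0  # crown height, m
    crown_cab: tuple[float, float, tuple[float, float]] = (35.0, 10.0, (16.0, 53.0))
    crown_clai_range: tuple[float, float] = (1.0, 4.0)
    crown_ala: float = 60.0
    understory_lai_range: tuple[float, float] = (1.0, 4.0)
    understory_cab_range: tuple[float, float] = (2.0, 47.0)
    understory_cover: float = 0.5  # target fraction of the scene
    soil_brightness: float = 1.0
    sun_zenith: float = 26.0  # deg; 26 = June, 73 = December
    noise_sd: float = 0.01  # multiplicative, airborne cube
    sentinel_noise_sd: float = 0.0  # multiplicative, Sentinel band table
    seed: int = 0

    def __post_init__(self):
        cell = 20.0
        n = cell / self.resolution
        if abs(n - round(n)) > 1e-9:
            raise ValueError("resolution must divide the 20 m grid cell")
        ex, ey = self.extent
        if ex < self.cd_range[1] or ey < self.cd_range[1]:
            raise ValueError("extent too small to hold a single crown")
        if not 0.0 <= self.understory_cover <= 1.0:
            raise ValueError("understory cover must be in [0, 1]")
        if not 0.0 <= self.sun_zenith < 90.0:
            raise ValueError("sun zenith must be in [0, 90) deg")


@dataclass
class SyntheticScene:
    """A generated site: airborne cube + labels + per-tree/per-cell truth."""

    config: SceneConfig
    cube: np.ndarray  # (rows, cols, 260) float32, airborne VNIR grid
    wavelengths: np.ndarray  # (260,) nm
    labels: np.ndarray  # (rows, cols) int, CLASS_IDS
    substrate: np.ndarray  # (rows, cols) int, surface class beneath shadow/crown
    tree_ids: np.ndarray  # (rows, cols) int, 0 = no tree
    crown_shaded: np.ndarray  # (rows, cols) bool, crown pixels shaded by neighbours
    trees: pd.DataFrame  # id, x, y, cd, ch, cab, c_lai
    understory_cab: float
    understory_lai: float
    component_full: dict  # name -> full-grid spectrum values (400-2500 nm)
    crown_full: np.ndarray  # (n_trees, L) full-grid sunlit-crown spectra
    sentinel: pd.DataFrame  # per 20 m cell Sentinel-2A band table
    truth: pd.DataFrame  # per 20 m cell fractions + chlorophyll truth


def _rasterize_site(cfg: SceneConfig, rng: np.random.Generator):
    """Place trees and rasterize crown / shadow / understory labels."""
    ex, ey = cfg.extent
    res = cfg.resolution
    nrow = int(round(ey / res))
    ncol = int(round(ex / res))
    area_ha = ex * ey / 1.0e4

    n_trees = int(rng.poisson(cfg.td * area_ha))
    xs = rng.uniform(0, ex, n_trees)
    ys = rng.uniform(0, ey, n_trees)
    cds = np.clip(rng.normal(cfg.cd_mean, cfg.cd_sd, n_trees), *cfg.cd_range)
    mu, sd, (lo, hi) = cfg.crown_cab
    cabs = np.clip(rng.normal(mu, sd, n_trees), lo, hi)
    clais = rng.uniform(*cfg.crown_clai_range, n_trees)

    # pixel-centre coordinates (row-major, origin top-left)
    yy = (np.arange(nrow) + 0.5) * res
    xx = (np.arange(ncol) + 0.5) * res

    tree_ids = np.zeros((nrow, ncol), dtype=int)
    for i in range(n_trees):
        r = cds[i] / 2.0
        r0 = max(int((ys[i] - r) / res) - 1, 0)
        r1 = min(int((ys[i] + r) / res) + 2, nrow)
        c0 = max(int((xs[i] - r) / res) - 1, 0)
        c1 = min(int((xs[i] + r) / res) + 2, ncol)
        if r0 >= r1 or c0 >= c1:
            continue
        dy = yy[r0:r1, None] - ys[i]
        dx = xx[None, c0:c1] - xs[i]
        inside = dx**2 + dy**2 <= r**2
        block = tree_ids[r0:r1, c0:c1]
        block[inside] = i + 1  # later-placed tree wins
    crown = tree_ids > 0

    # cast shadows: sun along +y, shadows towards increasing y; per tree an
    # ellipse centred (Ch/2)*tan(theta_s) down-sun with the ellipsoid's
    # projected semi-axes (Cd/2, sqrt((Cd/2)^2 + (Ch/2)^2 tan^2 theta_s))
    tan_s = np.tan(np.radians(cfg.sun_zenith))
    shadow = np.zeros((nrow, ncol), dtype=bool)
    crown_shaded = np.zeros((nrow, ncol), dtype=bool)
    b = cfg.ch / 2.0
    for i in range(n_trees):
        a = cds[i] / 2.0
        ay = np.sqrt(a**2 + b**2 * tan_s**2)
        cy = ys[i] + b * tan_s  # shadow centre, down-sun of the trunk
        r0 = max(int((cy - ay) / res) - 1, 0)
        r1 = min(int((cy + ay) / res) + 2, nrow)
        c0 = max(int((xs[i] - a) / res) - 1, 0)
        c1 = min(int((xs[i] + a) / res) + 2, ncol)
        if r0 >= r1 or c0 >= c1:
            continue
        dy = (yy[r0:r1, None] - cy) / ay
        dx = (xx[None, c0:c1] - xs[i]) / a
        inside = dx**2 + dy**2 <= 1.0
        # the shading region excludes the caster's own crown disc
        dyc = yy[r0:r1, None] - ys[i]
        dxc = xx[None, c0:c1] - xs[i]
        inside &= dxc**2 + dyc**2 > a**2
        tid = tree_ids[r0:r1, c0:c1]
        shadow[r0:r1, c0:c1] |= inside & (tid == 0)
        # neighbouring crowns caught by this tree's shadow are shaded too
        crown_shaded[r0:r1, c0:c1] |= inside & (tid != 0)
    shadow &= ~crown

    # understory patches from thresholded smooth noise
    fieldn = ndimage.gaussian_filter(rng.standard_normal((nrow, ncol)), sigma=12.0)
    thresh = np.quantile(fieldn, 1.0 - cfg.understory_cover)
    under = fieldn > thresh

    labels = np.full((nrow, ncol), CLASS_IDS["bare_soil"], dtype=int)
    labels[under] = CLASS_IDS["understory"]
    substrate = labels.copy()  # what lies beneath shadows/crowns
    labels[shadow] = CLASS_IDS["shadow"]
    labels[crown] = CLASS_IDS["crown"]

    trees = pd.DataFrame(
        {
            "id": np.arange(1, n_trees + 1),
            "x": xs,
            "y": ys,
            "cd": cds,
            "ch": cfg.ch,
            "cab": cabs,
            "c_lai": clais,
        }
    )
    return labels, substrate, tree_ids, crown_shaded, trees


def generate_labels(cfg: SceneConfig):
    """Fast geometry-only path: rasterize a site and return
    (labels, tree table, per-cell truth) without synthesizing spectra.
    Uses the same random stream as :func:`generate_scene`, so the layout is
    identical to the full scene for the same config."""
    rng = np.random.default_rng(cfg.seed)
    labels, substrate, tree_ids, crown_shaded, trees = _rasterize_site(cfg, rng)
    scene = SyntheticScene(
        config=cfg,
        cube=np.zeros((0, 0, 0), dtype=np.float32),
        wavelengths=np.zeros(0),
        labels=labels,
        substrate=substrate,
        tree_ids=tree_ids,
        crown_shaded=crown_shaded,
        trees=trees,
        understory_cab=float("nan"),
        understory_lai=float("nan"),
        component_full={},
        crown_full=np.zeros((0, 0)),
        sentinel=pd.DataFrame(),
        truth=pd.DataFrame(),
    )
    scene.truth = truth_for_grid(scene, 20.0)
    return labels, trees, scene.truth


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Generate one synthetic site; bit-identical for a fixed config."""
    rng = np.random.default_rng(cfg.seed)
    labels, substrate, tree_ids, crown_shaded, trees = _rasterize_site(cfg, rng)
    nrow, ncol = labels.shape
    wl_full = WAVELENGTHS

    soil = soil_spectrum(cfg.soil_brightness)

    # understory: herbaceous cover drawn from the understory parameter box
    # (thin grass leaves: low water and dry matter per area)
    u_lai = float(rng.uniform(*cfg.understory_lai_range))
    u_cab = float(rng.uniform(*cfg.understory_cab_range))
    u_car = float(rng.uniform(3.0, 12.0))
    u_canth = float(rng.uniform(0.1, 4.0))
    u_N = float(rng.uniform(1.5, 2.2))
    u_ala = float(rng.uniform(30.0, 70.0))
    understory = foursail(
        prospect_d(
            LeafParams(
                N=u_N, cab=u_cab, car=u_car, canth=u_canth, cw=0.005, cm=0.0022
            )
        ),
        CanopyParams(lai=u_lai, soil=soil, ala=u_ala, hotspot=0.01, tts=cfg.sun_zenith),
    )

    omega = diffuse_fraction(wl_full)
    full = {
        "bare_soil": soil.values,
        "understory": understory.values,
        "shadow_soil": np.clip(omega * soil.values, 0, 1),
        "shadow_understory": np.clip(omega * understory.values, 0, 1),
    }

    # sunlit crown spectra per tree: semi-infinite crown medium blended with
    # the below-crown background through the crown gap fraction Ts*To
    n_trees = len(trees)
    if n_trees:
        R, T, _ = prospect_batch(
            np.full(n_trees, 1.8),
            trees["cab"].to_numpy(),
            np.full(n_trees, 10.0),
            np.full(n_trees, 1.0),
            np.full(n_trees, 0.012),
            np.full(n_trees, 0.012),
        )
        rc_inf = sail_batch(
            R, T, soil.values, SATURATING_LAI, cfg.crown_ala, 0.01,
            cfg.sun_zenith, 0.0, 0.0,
        )
        ks = extinction_coefficient(cfg.crown_ala, cfg.sun_zenith)
        ko = extinction_coefficient(cfg.crown_ala, 0.0)
        tsto = np.exp(-(ks + ko) * trees["c_lai"].to_numpy())[:, None]
        crown_full = (1.0 - tsto) * rc_inf + tsto * soil.values[None, :]
    else:
        log.warning("no trees placed (Td=%s on %.2f ha)", cfg.td,
                    np.prod(cfg.extent) / 1e4)
        crown_full = np.zeros((0, wl_full.size))

    # airborne cube: resample every distinct full-grid spectrum to the
    # 260-band VNIR grid, then paint by label
    sensor = airborne_vnir()
    Wmat, names = srf_weight_matrix(sensor, wl_full)
    assert len(names) == 260
    wl_air = np.array([sensor.band(n).cwl for n in names])

    cube = np.zeros((nrow, ncol, 260), dtype=np.float32)
    comp_air = {k: (Wmat @ v).astype(np.float32) for k, v in full.items()}
    is_soil_sub = substrate == CLASS_IDS["bare_soil"]
    sel = labels == CLASS_IDS["bare_soil"]
    cube[sel] = comp_air["bare_soil"]
    sel = labels == CLASS_IDS["understory"]
    cube[sel] = comp_air["understory"]
    sel = (labels == CLASS_IDS["shadow"]) & is_soil_sub
    cube[sel] = comp_air["shadow_soil"]
    sel = (labels == CLASS_IDS["shadow"]) & ~is_soil_sub
    cube[sel] = comp_air["shadow_understory"]
    if n_trees:
        crown_air = (crown_full @ Wmat.T).astype(np.float32)
        omega_air = (Wmat @ omega).astype(np.float32)
        sel = labels == CLASS_IDS["crown"]
        cube[sel] = crown_air[tree_ids[sel] - 1]
        # crowns caught in a neighbour's shadow see diffuse light only
        sel = (labels == CLASS_IDS["crown"]) & crown_shaded
        cube[sel] = crown_air[tree_ids[sel] - 1] * omega_air

    if cfg.noise_sd > 0:
        cube *= (1.0 + cfg.noise_sd * rng.standard_normal(cube.shape)).astype(
            np.float32
        )
        np.clip(cube, 0.0, 1.0, out=cube)

    scene = SyntheticScene(
        config=cfg,
        cube=cube,
        wavelengths=wl_air,
        labels=labels,
        substrate=substrate,
        tree_ids=tree_ids,
        crown_shaded=crown_shaded,
        trees=trees,
        understory_cab=u_cab,
        understory_lai=u_lai,
        component_full=full,
        crown_full=crown_full,
        sentinel=pd.DataFrame(),
        truth=pd.DataFrame(),
    )
    scene.truth = truth_for_grid(scene, 20.0)
    scene.sentinel = _sentinel_view(scene, rng)
    return scene


def truth_for_grid(scene: SyntheticScene, cell: float = 20.0) -> pd.DataFrame:
    """Exact per-cell component fractions and chlorophyll truth.

    Columns: cell row/col, the four fractions, area-weighted crown
    chlorophyll cCab, understory chlorophyll uCab and the pixel-level
    composite pCab = %c*cCab + %u*uCab (fractions of the whole cell).
    """
    cfg = scene.config
    px = cell / cfg.resolution
    if abs(px - round(px)) > 1e-9:
        raise ValueError("cell must be a multiple of the scene resolution")
    px = int(round(px))
    nrow, ncol = scene.labels.shape
    if nrow % px or ncol % px:
        raise ValueError("scene extent is not divisible by the cell size")
    cab_by_tree = np.concatenate([[np.nan], scene.trees["cab"].to_numpy()])
    rows = []
    for i in range(0, nrow, px):
        for j in range(0, ncol, px):
            lab = scene.labels[i : i + px, j : j + px]
            tid = scene.tree_ids[i : i + px, j : j + px]
            n = lab.size
            fc = float((lab == CLASS_IDS["crown"]).sum()) / n
            fu = float((lab == CLASS_IDS["understory"]).sum()) / n
            fb = float((lab == CLASS_IDS["bare_soil"]).sum()) / n
            fs = float((lab == CLASS_IDS["shadow"]).sum()) / n
            crown_sel = tid > 0
            ccab = float(np.mean(cab_by_tree[tid[crown_sel]])) if crown_sel.any() else 0.0
            ucab = scene.understory_cab if fu > 0 else 0.0
            rows.append(
                {
                    "cell_row": i // px,
                    "cell_col": j // px,
                    "f_crown": fc,
                    "f_understory": fu,
                    "f_bare_soil": fb,
                    "f_shadow": fs,
                    "ccab": ccab,
                    "ucab": ucab,
                    "pcab": fc * ccab + fu * ucab,
                }
            )
    return pd.DataFrame(rows)


def _sentinel_view(scene: SyntheticScene, rng: np.random.Generator) -> pd.DataFrame:
    """Coincident Sentinel-2A observation: per 20 m cell, the area mixture
    of the full-grid component spectra convolved with the 13 MSI bands."""
    cfg = scene.config
    px = int(round(20.0 / cfg.resolution))
    nrow, ncol = scene.labels.shape
    s2 = sentinel2a()
    Wmat, names = srf_weight_matrix(s2, WAVELENGTHS)
    shadow_soil = (scene.labels == CLASS_IDS["shadow"]) & (
        scene.substrate == CLASS_IDS["bare_soil"]
    )
    shadow_under = (scene.labels == CLASS_IDS["shadow"]) & ~(
        scene.substrate == CLASS_IDS["bare_soil"]
    )
    rows = []
    for i in range(0, nrow, px):
        for j in range(0, ncol, px):
            lab = scene.labels[i : i + px, j : j + px]
            tid = scene.tree_ids[i : i + px, j : j + px]
            n = lab.size
            spec = np.zeros_like(WAVELENGTHS, dtype=float)
            shd = scene.crown_shaded[i : i + px, j : j + px]
            sunlit_sel = (tid > 0) & ~shd
            shaded_sel = (tid > 0) & shd
            if sunlit_sel.any():
                counts = np.bincount(tid[sunlit_sel] - 1, minlength=len(scene.trees))
                spec += (counts @ scene.crown_full) / n
            if shaded_sel.any():
                omega = diffuse_fraction(WAVELENGTHS)
                counts = np.bincount(tid[shaded_sel] - 1, minlength=len(scene.trees))
                spec += (counts @ scene.crown_full) * omega / n
            for name, key in (
                ("understory", "understory"),
                ("bare_soil", "bare_soil"),
            ):
                fsel = (lab == CLASS_IDS[name]).sum() / n
                spec += fsel * scene.component_full[key]
            fss = shadow_soil[i : i + px, j : j + px].sum() / n
            fsu = shadow_under[i : i + px, j : j + px].sum() / n
            spec += fss * scene.component_full["shadow_soil"]
            spec += fsu * scene.component_full["shadow_understory"]
            vals = Wmat @ np.clip(spec, 0, 1)
            if cfg.sentinel_noise_sd > 0:
                vals = vals * (1.0 + cfg.sentinel_noise_sd * rng.standard_normal(vals.shape))
            row = {"cell_row": i // px, "cell_col": j // px}
            row.update(dict(zip(names, np.clip(vals, 0, 1))))
            rows.append(row)
    return pd.DataFrame(rows)


def study_site_configs(
    n: int = 61,
    seed: int = 0,
    sun_zenith: float = 26.0,
    noise_sd: float = 0.01,
) -> list[SceneConfig]:
    """Draw *n* site configurations spanning the study's landscape
    variability (tree density, understory cover, soil brightness)."""
    rng = np.random.default_rng(seed)
    cfgs = []
    for i in range(n):
        # sites sit on a decline gradient: the site-level needle chlorophyll
        # mean varies widely while trees within a site are similar
        site_cab = float(rng.uniform(20.0, 50.0))
        cfgs.append(
            SceneConfig(
                td=float(rng.uniform(20.0, 280.0)),
                understory_cover=float(rng.uniform(0.23, 0.73)),
                soil_brightness=float(rng.uniform(0.7, 1.3)),
                crown_cab=(site_cab, 4.0, (16.0, 53.0)),
                sun_zenith=sun_zenith,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return cfgs
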