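"""Scene-component extraction from high-resolution imagery.

The decomposition pipeline mirrors standard practice for open-canopy
forests: a local threshold (Niblack or Sauvola) separates bright vegetation
crowns from soil on a single channel (default: the NIR sample near 800 nm,
where the vegetation/soil contrast is largest); touching crowns are split
by a Euclidean-distance-transform watershed; a per-class Gaussian
maximum-likelihood classifier assigns every pixel to one of the four scene
components (crown, understory, bare soil, shadow); intersecting the crown
objects with the crown class yields pure-crown objects; finally component
fractions and mean spectra are accumulated per coarse (e.g. 20 m) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.linalg import solve_triangular
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .canopy_rt import SceneComponentSet
from .spectra import Spectrum

__all__ = [
    "CLASS_IDS",
    "TrainingSet",
    "niblack_mask",
    "sauvola_mask",
    "watershed_separate",
    "ml_classify",
    "extract_component_stats",
    "segment_pipeline",
]

#: fixed class ids of the four scene components
CLASS_IDS = {"crown": 0, "understory": 1, "bare_soil": 2, "shadow": 3}
_ID_TO_NAME = {v: k for k, v in CLASS_IDS.items()}


@dataclass(frozen=True)
class TrainingSet:
    """Labelled training pixels: ``coords`` (n, 2) row/col indices and
    ``classes`` (n,) ids from :data:`CLASS_IDS` (all four present, >= 2
    pixels each)."""

    coords: np.ndarray
    classes: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, int)
        classes = np.asarray(self.classes, int)
        if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) != len(classes):
            raise ValueError("coords must be (n, 2) matching classes (n,)")
        present, counts = np.unique(classes, return_counts=True)
        if set(present.tolist()) != set(CLASS_IDS.values()):
            raise ValueError("training set must cover all four classes")
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 training pixels")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "classes", classes)


def _local_mean_std(gray: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(gray.shape):
        raise ValueError("window larger than raster")
    m = ndimage.uniform_filter(gray, size=window, mode="reflect")
    m2 = ndimage.uniform_filter(gray * gray, size=window, mode="reflect")
    var = np.clip(m2 - m * m, 0.0, None)
    return m, np.sqrt(var)


def niblack_mask(gray: np.ndarray, window: int = 25, k: float = 0.2) -> np.ndarray:
    """Niblack local threshold: foreground iff value > m + k*s over the
    window (local mean m, local sd s); reflected borders; ties background.

    The default k = +0.2 targets bright objects (sunlit vegetation) on a
    darker background; the classical k = -0.2 of document binarization
    picks dark foreground instead and floods textured background regions
    when used for bright-object detection."""
    gray = np.asarray(gray, float)
    m, s = _local_mean_std(gray, window)
    return gray > m + k * s


def sauvola_mask(
    gray: np.ndarray, window: int = 25, k: float = -0.2, R: float = 0.5
) -> np.ndarray:
    """Sauvola local threshold: foreground iff value > m*(1 + k*(s/R - 1));
    R is the expected dynamic range of the local sd.

    As with :func:`niblack_mask` the default k is chosen for bright-object
    detection: k = -0.2 raises the threshold above the local mean in flat
    regions (keeping uniform soil as background) and lowers it inside
    textured crown/soil transitions."""
    if R <= 0:
        raise ValueError("dynamic range R must be > 0")
    gray = np.asarray(gray, float)
    m, s = _local_mean_std(gray, window)
    return gray > m * (1.0 + k * (s / R - 1.0))


def watershed_separate(mask: np.ndarray, min_distance: int = 5) -> np.ndarray:
    """Split touching foreground blobs at Euclidean-distance-transform
    watershed lines; returns an object label raster (0 = background,
    objects numbered 1..n). An empty mask yields an all-zero labelling."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=int)
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # degenerate: single-pixel blobs
        markers, _ = ndimage.label(mask)
    labels = watershed(-dist, markers, mask=mask)
    # renumber 1..n contiguously
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def ml_classify(
    cube: np.ndarray,
    train: TrainingSet,
    shrinkage: bool = True,
) -> np.ndarray:
    """Per-pixel Gaussian maximum-likelihood classification.

    Class means and covariances are estimated from the training pixels
    (equal priors). ``shrinkage`` adds diagonal loading
    delta = 1e-6 * trace/bands, needed for hyperspectral cubes with small
    training sets; without it a singular covariance raises. Ties break to
    the lowest class id.
    """
    cube = np.asarray(cube, float)
    if cube.ndim == 2:
        cube = cube[:, :, None]
    rows, cols, bands = cube.shape
    X = cube.reshape(-1, bands)
    class_ids = sorted(set(train.classes.tolist()))
    n_classes = len(class_ids)
    ll = np.full((X.shape[0], n_classes), -np.inf)
    for j, cid in enumerate(class_ids):
        sel = train.classes == cid
        pix = cube[train.coords[sel, 0], train.coords[sel, 1], :]
        mu = pix.mean(axis=0)
        if pix.shape[0] > 1:
            cov = np.cov(pix, rowvar=False).reshape(bands, bands)
        else:
            cov = np.zeros((bands, bands))
        if shrinkage:
            cov = cov + np.eye(bands) * (1e-6 * max(np.trace(cov), 1e-30) / bands)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular covariance for class {_ID_TO_NAME.get(cid, cid)}; "
                "enable shrinkage or add training pixels"
            ) from None
        diff = X - mu
        y = solve_triangular(chol, diff.T, lower=True)
        maha = np.sum(y * y, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        ll[:, j] = -0.5 * (maha + logdet)
    # argmax returns the first (lowest class id) on ties
    best = np.argmax(ll, axis=1)
    out = np.array(class_ids, dtype=int)[best]
    return out.reshape(rows, cols)


def extract_component_stats(
    labels: np.ndarray,
    cube: np.ndarray,
    cell_px: int,
    wavelengths: np.ndarray | None = None,
) -> list[list[SceneComponentSet]]:
    """Per coarse cell (cell_px x cell_px fine pixels): component fractions
    and per-component mean spectra.

    Returns a nested list [row][col] of SceneComponentSet; a component with
    zero pixels in a cell gets fraction 0 and spectrum None (flagged
    absent).
    """
    labels = np.asarray(labels, int)
    cube = np.asarray(cube, float)
    if labels.shape != cube.shape[:2]:
        raise ValueError("label raster and cube grids are not congruent")
    r, c = labels.shape
    if r % cell_px or c % cell_px:
        raise ValueError("raster not divisible by cell size")
    if wavelengths is None:
        wavelengths = np.arange(cube.shape[2], dtype=float) + 1.0
    out = []
    for i in range(0, r, cell_px):
        row = []
        for j in range(0, c, cell_px):
            lab = labels[i : i + cell_px, j : j + cell_px]
            pix = cube[i : i + cell_px, j : j + cell_px, :]
            n = lab.size
            fractions = {}
            spectra = {}
            for name, cid in CLASS_IDS.items():
                sel = lab == cid
                cnt = int(sel.sum())
                fractions[name] = cnt / n
                spectra[name] = (
                    Spectrum(wavelengths, np.clip(pix[sel].mean(axis=0), 0, 1))
                    if cnt
                    else None
                )
            row.append(SceneComponentSet(fractions=fractions, spectra=spectra))
        out.append(row)
    return out


def segment_pipeline(
    cube: np.ndarray,
    wavelengths: np.ndarray,
    train: TrainingSet,
    cell_px: int,
    method: str = "sauvola",
    window: int = 25,
    k: float | None = None,
    min_distance: int = 5,
    class_band_stride: int = 1,
):
    """Full decomposition of a high-resolution cube.

    1. local threshold on the NIR channel -> vegetation mask
    2. distance-transform watershed -> candidate objects
    3. Gaussian ML classification -> 4-class map
    4. object mask intersected with the crown class -> pure-crown objects
       (used for object-level crown spectra; component fractions come from
       the per-pixel classification itself)
    5. per-cell component stats

    Returns (crown_objects, class map, nested SceneComponentSet).
    """
    wavelengths = np.asarray(wavelengths, float)
    nir = cube[..., int(np.argmin(np.abs(wavelengths - 800.0)))]
    if method == "sauvola":
        mask = sauvola_mask(nir, window=window, k=-0.2 if k is None else k)
    elif method == "niblack":
        mask = niblack_mask(nir, window=window, k=0.2 if k is None else k)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    objects = watershed_separate(mask, min_distance=min_distance)
    # classification may run on a band subset: 260-band cubes carry heavy
    # spectral redundancy and a stride-4 subset classifies equally well
    class_cube = cube[..., ::class_band_stride] if class_band_stride > 1 else cube
    classes = ml_classify(class_cube, train)
    crown_objects = np.where(classes == CLASS_IDS["crown"], objects, 0)
    stats = extract_component_stats(classes, cube, cell_px, wavelengths)
    return crown_objects, classes, stats
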