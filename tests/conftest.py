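import numpy as np
import pytest

from opencanopy.leaf_rt import LeafParams, prospect_d
from opencanopy.optical_constants import WAVELENGTHS
from opencanopy.scene_sim import soil_spectrum
from opencanopy.spectra import Spectrum


@pytest.fixture(scope="session")
def wl_full():
    return WAVELENGTHS.copy()


@pytest.fixture(scope="session")
def soil(wl_full):
    return soil_spectrum(1.0)


@pytest.fixture(scope="session")
def nominal_leaf():
    return prospect_d(LeafParams())


@pytest.fixture(scope="session")
def black_soil(wl_full):
    return Spectrum(wl_full, np.zeros_like(wl_full))


def mc_crown_cover(td, cd, rng, ext=300.0, res=0.5, reps=4):
    """Monte-Carlo crown cover: drop Poisson discs on a torus and count
    covered grid cells (independent oracle for the Boolean model)."""
    n_cells = int(ext / res)
    r = cd / 2.0
    rpx = int(np.ceil(r / res)) + 1
    axis = (np.arange(n_cells) + 0.5) * res
    fracs = []
    for _ in range(reps):
        covered = np.zeros((n_cells, n_cells), bool)
        n = rng.poisson(td * ext * ext / 1e4)
        xs = rng.uniform(0, ext, n)
        ys = rng.uniform(0, ext, n)
        for x, y in zip(xs, ys):
            ci = int(x / res)
            ri = int(y / res)
            cols = (np.arange(ci - rpx, ci + rpx + 1)) % n_cells
            rows = (np.arange(ri - rpx, ri + rpx + 1)) % n_cells
            dx = np.abs(axis[cols] - x)
            dx = np.minimum(dx, ext - dx)
            dy = np.abs(axis[rows] - y)
            dy = np.minimum(dy, ext - dy)
            disc = dy[:, None] ** 2 + dx[None, :] ** 2 <= r * r
            covered[np.ix_(rows, cols)] |= disc
        fracs.append(covered.mean())
    return float(np.mean(fracs))


@pytest.fixture(scope="session")
def june_inform_lut():
    """Shared 1e4-row June INFORM LUT (expensive; built once)."""
    from opencanopy.retrieval import build_lut_inform

    return build_lut_inform(n=10_000, seed=11, tts=26.0)


@pytest.fixture(scope="session")
def december_inform_lut():
    from opencanopy.retrieval import build_lut_inform

    return build_lut_inform(n=10_000, seed=11, tts=73.0)


@pytest.fixture(scope="session")
def stand_observations():
    """200 independent stands from the stand parameter box (June and
    December responses for identical parameter draws)."""
    from opencanopy.retrieval import build_lut_inform

    return {
        26.0: build_lut_inform(n=200, seed=77, tts=26.0),
        73.0: build_lut_inform(n=200, seed=77, tts=73.0),
    }
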