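"""Scene-component extraction: thresholding, watershed, ML classification."""

import numpy as np
import pytest
from scipy import ndimage

from opencanopy.components import (
    CLASS_IDS,
    TrainingSet,
    extract_component_stats,
    ml_classify,
    niblack_mask,
    sauvola_mask,
    watershed_separate,
)


def two_level_image(seed=0, size=120, n_discs=8, r=9, lo=0.2, hi=0.6):
    """Bright discs (crowns) on a dark background, plus the truth mask."""
    rng = np.random.default_rng(seed)
    img = np.full((size, size), lo)
    truth = np.zeros((size, size), bool)
    yy, xx = np.indices((size, size))
    for _ in range(n_discs):
        cy, cx = rng.integers(r, size - r, 2)
        d = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        truth |= d
    img[truth] = hi
    return img, truth


class TestLocalThresholds:
    def test_niblack_constant_image_all_background(self):
        # s = 0 so the threshold equals the local mean; strict '>' loses
        assert not niblack_mask(np.full((40, 40), 0.3), window=9, k=-0.2).any()

    def test_sauvola_constant_algebra(self):
        # with positive k the threshold is v*(1 - k) < v: all foreground
        assert sauvola_mask(np.full((40, 40), 0.3), window=9, k=0.2).all()
        # the bright-object default k = -0.2 keeps a flat raster background
        assert not sauvola_mask(np.full((40, 40), 0.3), window=9).any()

    @pytest.mark.parametrize("method", ["niblack", "sauvola"])
    def test_two_level_image_recovers_crowns(self, method):
        img, truth = two_level_image()
        if method == "niblack":
            mask = niblack_mask(img, window=25)
        else:
            mask = sauvola_mask(img, window=25, R=0.5)
        err = np.mean(mask != truth)
        assert err < 0.01

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(size=(50, 50))
        window, k = 7, -0.2
        out = niblack_mask(img, window=window, k=k)
        pad = window // 2
        # scipy's 'reflect' duplicates the edge sample = numpy 'symmetric'
        padded = np.pad(img, pad, mode="symmetric")
        for i in range(0, 50, 7):  # subsample for speed; full rows checked
            for j in range(50):
                win = padded[i : i + window, j : j + window]
                expect = img[i, j] > win.mean() + k * win.std()
                assert out[i, j] == expect

    def test_niblack_shift_invariant_for_any_k(self):
        # adding a constant shifts both value and local mean; s is unchanged
        rng = np.random.default_rng(5)
        img = rng.uniform(0.1, 0.5, (40, 40))
        for k in (-0.2, 0.0, 0.3):
            assert np.array_equal(
                niblack_mask(img, 9, k), niblack_mask(img + 0.2, 9, k)
            )

    def test_sauvola_shift_invariant_only_for_k_zero(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(0.1, 0.5, (40, 40))
        assert np.array_equal(sauvola_mask(img, 9, 0.0), sauvola_mask(img + 0.2, 9, 0.0))
        assert not np.array_equal(
            sauvola_mask(img, 9, 0.3), sauvola_mask(img + 0.2, 9, 0.3)
        )

    def test_window_validation(self):
        with pytest.raises(ValueError):
            niblack_mask(np.ones((10, 10)), window=4)
        with pytest.raises(ValueError):
            niblack_mask(np.ones((10, 10)), window=21)
        with pytest.raises(ValueError):
            sauvola_mask(np.ones((10, 10)), window=5, R=0.0)


class TestWatershed:
    def disc(self, size, cy, cx, r):
        yy, xx = np.indices((size, size))
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    def test_single_disc_single_object(self):
        labels = watershed_separate(self.disc(60, 30, 30, 12))
        assert labels.max() == 1

    def test_two_overlapping_discs_are_split(self):
        mask = self.disc(60, 30, 22, 10) | self.disc(60, 30, 37, 10)
        labels = watershed_separate(mask)
        assert labels.max() == 2

    def test_translation_equivariance(self):
        mask = self.disc(80, 30, 25, 10) | self.disc(80, 30, 40, 10)
        shifted = np.roll(np.roll(mask, 7, axis=0), 5, axis=1)
        assert watershed_separate(mask).max() == watershed_separate(shifted).max()

    def test_empty_mask_is_fine(self):
        labels = watershed_separate(np.zeros((30, 30), bool))
        assert labels.max() == 0


class TestMlClassify:
    def make_training(self, cube, labels, n=30, seed=0):
        rng = np.random.default_rng(seed)
        coords, classes = [], []
        for cid in CLASS_IDS.values():
            rs, cs = np.nonzero(labels == cid)
            sel = rng.choice(rs.size, size=min(n, rs.size), replace=False)
            coords.append(np.column_stack([rs[sel], cs[sel]]))
            classes.append(np.full(sel.size, cid))
        return TrainingSet(np.concatenate(coords), np.concatenate(classes))

    def gaussian_scene(self, sep=6.0, seed=0, size=40, bands=5):
        rng = np.random.default_rng(seed)
        means = np.array(
            [[0, 0, 0, 0, 0], [1, 0, 1, 0, 1], [0, 1, 0, 1, 0], [1, 1, 1, 1, 1]],
            float,
        ) * sep
        labels = rng.integers(0, 4, (size, size))
        cube = means[labels] + rng.standard_normal((size, size, bands))
        return cube, labels

    def test_well_separated_classes_recovered(self):
        cube, labels = self.gaussian_scene(sep=6.0)
        train = self.make_training(cube, labels, n=125)
        out = ml_classify(cube, train)
        assert np.mean(out == labels) >= 0.99

    def test_pixel_at_class_mean_goes_to_that_class(self):
        cube, labels = self.gaussian_scene(sep=8.0, seed=1)
        train = self.make_training(cube, labels, n=60, seed=1)
        # plant a pixel exactly at the class-2 training mean
        sel = train.classes == 2
        mu = cube[train.coords[sel, 0], train.coords[sel, 1]].mean(axis=0)
        cube[0, 0] = mu
        assert ml_classify(cube, train)[0, 0] == 2

    def test_tie_breaks_to_lowest_class_id(self):
        # two classes with identical training statistics: every pixel ties
        rng = np.random.default_rng(2)
        cube = rng.standard_normal((8, 8, 3))
        pts = rng.standard_normal((4, 3))
        cube[0, :4] = pts
        cube[1, :4] = pts  # class 1 training identical to class 0
        cube[2, :4] = pts + 50
        cube[3, :4] = pts - 50
        coords = [(0, j) for j in range(4)] + [(1, j) for j in range(4)] + [
            (2, j) for j in range(4)
        ] + [(3, j) for j in range(4)]
        classes = [0] * 4 + [1] * 4 + [2] * 4 + [3] * 4
        train = TrainingSet(np.array(coords), np.array(classes))
        out = ml_classify(cube, train)
        near = np.abs(cube).max(axis=2) < 10
        assert np.all(out[near] == 0)

    def test_reduces_to_mahalanobis_with_shared_covariance(self):
        # classes built with the same covariance: ML argmax == min Mahalanobis
        rng = np.random.default_rng(3)
        A = rng.standard_normal((3, 3))
        cov = A @ A.T + np.eye(3)
        L = np.linalg.cholesky(cov)
        means = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]], float)
        n = 200
        cube = np.empty((4, n, 3))
        for c in range(4):
            cube[c] = means[c] + (L @ rng.standard_normal((3, n))).T
        coords = [(c, j) for c in range(4) for j in range(n)]
        classes = [c for c in range(4) for _ in range(n)]
        train = TrainingSet(np.array(coords), np.array(classes))
        out = ml_classify(cube, train)

        # oracle: pooled-covariance Mahalanobis on estimated class means
        mus = np.array([cube[c].mean(axis=0) for c in range(4)])
        covs = [np.cov(cube[c], rowvar=False) for c in range(4)]
        X = cube.reshape(-1, 3)
        d = np.empty((X.shape[0], 4))
        for c in range(4):
            diff = X - mus[c]
            ic = np.linalg.inv(covs[c] + np.eye(3) * 1e-6 * np.trace(covs[c]) / 3)
            d[:, c] = np.einsum("ij,jk,ik->i", diff, ic, diff) + np.linalg.slogdet(
                covs[c] + np.eye(3) * 1e-6 * np.trace(covs[c]) / 3
            )[1]
        oracle = d.argmin(axis=1).reshape(4, n)
        assert np.mean(out == oracle) > 0.999

    def test_training_validation(self):
        with pytest.raises(ValueError):
            TrainingSet(np.array([[0, 0], [1, 1]]), np.array([0, 1]))  # 2 classes only


class TestComponentStats:
    def test_half_crown_half_soil_cell(self):
        labels = np.zeros((10, 10), int)
        labels[:, 5:] = CLASS_IDS["bare_soil"]
        labels[:, :5] = CLASS_IDS["crown"]
        cube = np.random.default_rng(0).uniform(0.1, 0.5, (10, 10, 4))
        (cells,) = extract_component_stats(labels, cube, 10)
        cell = cells[0]
        assert cell.fractions["crown"] == pytest.approx(0.5)
        assert cell.fractions["bare_soil"] == pytest.approx(0.5)
        assert cell.fractions["understory"] == 0.0
        assert cell.spectra["understory"] is None  # absent, flagged

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, (40, 40))
        cube = rng.uniform(0.1, 0.4, (40, 40, 3))
        stats = extract_component_stats(labels, cube, 20)
        for row in stats:
            for cell in row:
                assert sum(cell.fractions.values()) == pytest.approx(1.0)

    def test_mean_spectra_match_loop_oracle(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 4, (20, 20))
        cube = rng.uniform(0.0, 1.0, (20, 20, 5))
        (cells,) = [r for r in extract_component_stats(labels, cube, 20)]
        for name, cid in CLASS_IDS.items():
            sel = labels == cid
            if sel.any():
                assert np.allclose(
                    cells[0].spectra[name].values, cube[sel].mean(axis=0)
                )

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_component_stats(np.zeros((10, 10), int), np.zeros((9, 10, 2)), 5)
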