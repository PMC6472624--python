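"""Canopy and stand radiative transfer: limits, geometry, mixing."""

import numpy as np
import pytest

from opencanopy.canopy_rt import (
    CanopyParams,
    SceneComponentSet,
    StandParams,
    ellipsoidal_lidf,
    extinction_coefficient,
    flim_geometry,
    foursail,
    inform_forward,
    mix_components,
    prosail,
    sail_batch,
    SATURATING_LAI,
)
from opencanopy.leaf_rt import LeafParams, prospect_d
from opencanopy.spectra import Spectrum


class TestLidf:
    def test_distribution_normalized_and_positive(self):
        for ala in (30.0, 45.0, 57.0, 60.0, 70.0):
            f = ellipsoidal_lidf(ala)
            assert f.shape == (18,)
            assert np.all(f >= 0)
            assert f.sum() == pytest.approx(1.0)

    def test_erectophile_vs_planophile(self):
        # high ALA concentrates mass at steep leaf angles
        steep = ellipsoidal_lidf(70.0)
        flat = ellipsoidal_lidf(30.0)
        assert steep[-6:].sum() > flat[-6:].sum()
        assert flat[:6].sum() > steep[:6].sum()

    def test_extinction_grows_toward_grazing_sun(self):
        ks = [extinction_coefficient(60.0, t) for t in (0.0, 26.0, 60.0, 73.0)]
        assert all(np.diff(ks) > 0)


class TestFourSail:
    def test_empty_canopy_returns_soil_exactly(self, nominal_leaf, soil):
        out = foursail(nominal_leaf, CanopyParams(lai=0.0, soil=soil))
        assert np.max(np.abs(out.values - soil.values)) < 1e-9

    def test_small_lai_continuity(self, nominal_leaf, soil):
        out = foursail(nominal_leaf, CanopyParams(lai=1e-6, soil=soil))
        assert np.max(np.abs(out.values - soil.values)) < 1e-4

    def test_deep_canopy_forgets_the_soil(self, nominal_leaf, wl_full, black_soil):
        bright = Spectrum(wl_full, np.full_like(wl_full, 0.5))
        r_black = foursail(nominal_leaf, CanopyParams(lai=8.0, soil=black_soil))
        r_bright = foursail(nominal_leaf, CanopyParams(lai=8.0, soil=bright))
        assert abs(r_black.value_at(670) - r_bright.value_at(670)) < 0.005

    def test_hotspot_enhancement(self, nominal_leaf, soil):
        hot = foursail(
            nominal_leaf, CanopyParams(lai=3.0, soil=soil, tts=30, tto=30, psi=0)
        )
        off = foursail(
            nominal_leaf, CanopyParams(lai=3.0, soil=soil, tts=30, tto=30, psi=90)
        )
        assert hot.value_at(800) >= off.value_at(800)

    def test_bounded_on_parameter_box(self, soil):
        rng = np.random.default_rng(3)
        n = 200
        from opencanopy.leaf_rt import prospect_batch

        R, T, _ = prospect_batch(
            rng.uniform(1.5, 2.5, n), rng.uniform(5, 70, n), np.full(n, 10.0),
            np.full(n, 1.0), rng.uniform(0, 0.15, n), rng.uniform(0.01, 0.035, n),
        )
        out = sail_batch(
            R, T, soil.values, rng.uniform(0, 8, n), rng.uniform(30, 70, n),
            0.01, 26.0, 0.0, 0.0,
        )
        assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_saturating_lai_is_saturated(self, nominal_leaf, soil):
        r1 = foursail(nominal_leaf, CanopyParams(lai=SATURATING_LAI, soil=soil))
        r2 = foursail(nominal_leaf, CanopyParams(lai=2 * SATURATING_LAI, soil=soil))
        # NIR single-scattering albedo ~0.95 leaves a residual of order 1e-2
        assert np.max(np.abs(r1.values - r2.values)) < 0.03

    def test_grid_mismatch_rejected(self, nominal_leaf):
        short = Spectrum(np.arange(400.0, 900.0), np.full(500, 0.2))
        with pytest.raises(ValueError):
            foursail(nominal_leaf, CanopyParams(lai=2.0, soil=short))


class TestProsail:
    def test_composition_is_exact(self, soil):
        p = LeafParams(cab=35.0)
        c = CanopyParams(lai=2.5, soil=soil, ala=50.0)
        assert np.array_equal(prosail(p, c).values, foursail(prospect_d(p), c).values)

    def test_ndvi_increases_with_lai(self, soil):
        ndvi = []
        for lai in (1, 2, 3, 4):
            r = prosail(LeafParams(), CanopyParams(lai=lai, soil=soil, ala=50.0))
            ndvi.append(
                (r.value_at(835) - r.value_at(665)) / (r.value_at(835) + r.value_at(665))
            )
        assert all(np.diff(ndvi) > 0)

    def test_red_reflectance_decreases_with_cab(self, soil):
        red = [
            prosail(LeafParams(cab=c), CanopyParams(lai=2.0, soil=soil)).value_at(670)
            for c in (10, 20, 40, 60)
        ]
        assert all(np.diff(red) < 0)


class TestFlimGeometry:
    def test_empty_stand(self, soil):
        d = flim_geometry(StandParams(td=0, cd=4, ch=7, c_lai=2, background=soil))
        assert d.crown_cover == 0.0
        assert d.shadow_fraction == 0.0

    def test_boolean_crown_cover_closed_form(self, soil):
        d = flim_geometry(StandParams(td=500, cd=4, ch=7, c_lai=2, background=soil))
        lam = 500 * np.pi * 2.0**2 / 1e4
        assert lam == pytest.approx(0.6283, abs=1e-4)
        assert d.crown_cover == pytest.approx(1 - np.exp(-lam), abs=1e-9)
        assert d.crown_cover == pytest.approx(0.4666, abs=5e-4)

    def test_crown_cover_matches_monte_carlo_discs(self, soil):
        # Boolean model vs direct disc-dropping on a torus
        from conftest import mc_crown_cover

        rng = np.random.default_rng(7)
        for _ in range(4):
            td = float(rng.uniform(50, 500))
            cd = float(rng.uniform(4, 5))
            d = flim_geometry(
                StandParams(td=td, cd=cd, ch=7, c_lai=2, background=soil)
            )
            mc = mc_crown_cover(td, cd, rng, ext=250.0, res=0.5, reps=3)
            assert mc == pytest.approx(d.crown_cover, abs=0.02)

    def test_winter_shadows_longer(self, soil):
        kw = dict(td=200, cd=4.5, ch=7, c_lai=2, background=soil)
        june = flim_geometry(StandParams(tts=26.0, **kw))
        december = flim_geometry(StandParams(tts=73.0, **kw))
        assert december.shadow_fraction > june.shadow_fraction
        assert december.sunlit_crown_fraction < june.sunlit_crown_fraction

    def test_transparency_decreases_with_crown_lai(self, soil):
        ts = [
            flim_geometry(
                StandParams(td=100, cd=4, ch=7, c_lai=c, background=soil)
            ).crown_transparency_sun
            for c in (1, 2, 4)
        ]
        assert all(np.diff(ts) < 0)


class TestInformForward:
    def test_treeless_stand_is_background(self, soil):
        sp, _ = inform_forward(
            LeafParams(), StandParams(td=0, cd=4, ch=7, c_lai=2, background=soil)
        )
        assert np.max(np.abs(sp.values - soil.values)) < 1e-9

    @pytest.mark.parametrize("td", [100, 300, 500])
    def test_red_edge_ci_monotone_in_cab(self, soil, td):
        cis = []
        for cab in (5, 20, 40, 55, 70):
            sp, _ = inform_forward(
                LeafParams(cab=cab),
                StandParams(td=td, cd=4.5, ch=7, c_lai=2.5, background=soil),
            )
            cis.append(sp.value_at(750) / sp.value_at(710))
        assert all(np.diff(cis) > 0)

    def test_distinct_soils_make_distinct_ci_curves(self, wl_full):
        from opencanopy.scene_sim import soil_spectrum

        curves = []
        for brightness in (0.6, 1.0, 1.4):
            bg = soil_spectrum(brightness)
            ci = []
            for cab in (10, 30, 50, 70):
                sp, _ = inform_forward(
                    LeafParams(cab=cab),
                    StandParams(td=500, cd=4.5, ch=7, c_lai=2.5, background=bg),
                )
                ci.append(sp.value_at(750) / sp.value_at(710))
            curves.append(ci)
        curves = np.array(curves)
        # the three relationships are separated well beyond numerical noise
        assert np.min(np.abs(np.diff(curves, axis=0))) > 0.01

    def test_bounded_and_interpolates(self, soil):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sp, d = inform_forward(
                LeafParams(cab=rng.uniform(5, 70), N=rng.uniform(1.5, 2.5)),
                StandParams(
                    td=rng.uniform(0, 500), cd=rng.uniform(4, 5), ch=7,
                    c_lai=rng.uniform(1, 4), background=soil,
                    tts=float(rng.choice([26.0, 73.0])),
                ),
            )
            assert np.all(sp.values >= 0) and np.all(sp.values <= 1)


class TestMixComponents:
    def comp(self, wl, **spectra):
        fractions = {k: v[0] for k, v in spectra.items()}
        specs = {k: v[1] for k, v in spectra.items()}
        return SceneComponentSet(fractions=fractions, spectra=specs)

    def test_identical_components_pass_through(self, wl_full):
        sp = Spectrum(wl_full, np.full_like(wl_full, 0.21))
        cs = self.comp(
            wl_full,
            crown=(0.25, sp), understory=(0.25, sp),
            bare_soil=(0.25, sp), shadow=(0.25, sp),
        )
        assert np.allclose(mix_components(cs).values, 0.21)

    def test_study_mean_fractions_arithmetic(self, wl_full):
        # mean landscape composition: crown 13.5%, understory 52.2%,
        # bare soil 27.8%, shadow 6.6%; unit crown + zero others -> 0.135
        one = Spectrum(wl_full, np.ones_like(wl_full))
        zero = Spectrum(wl_full, np.zeros_like(wl_full))
        cs = self.comp(
            wl_full,
            crown=(0.135, one), understory=(0.522, zero),
            bare_soil=(0.278, zero), shadow=(0.066, zero),
        )
        total = 0.135 + 0.522 + 0.278 + 0.066
        assert np.allclose(mix_components(cs).values, 0.135 / total)

    def test_matches_dot_product_oracle(self, wl_full):
        rng = np.random.default_rng(11)
        specs = {k: rng.uniform(0, 1, wl_full.size) for k in SceneComponentSet.KEYS}
        fr = rng.dirichlet([1, 1, 1, 1])
        cs = self.comp(
            wl_full,
            **{
                k: (fr[i], Spectrum(wl_full, specs[k]))
                for i, k in enumerate(SceneComponentSet.KEYS)
            },
        )
        oracle = sum(fr[i] * specs[k] for i, k in enumerate(SceneComponentSet.KEYS))
        assert np.allclose(mix_components(cs).values, oracle)

    def test_fraction_sum_tolerance(self, wl_full):
        sp = Spectrum(wl_full, np.full_like(wl_full, 0.3))
        with pytest.raises(ValueError):
            SceneComponentSet(
                fractions={"crown": 0.5, "understory": 0.3, "bare_soil": 0.1,
                           "shadow": 0.05},  # sums to 0.95
                spectra={k: sp for k in SceneComponentSet.KEYS},
            )
        # 0.999 (the published tables' rounding slack) is accepted
        cs = SceneComponentSet(
            fractions={"crown": 0.4, "understory": 0.3, "bare_soil": 0.2,
                       "shadow": 0.099},
            spectra={k: sp for k in SceneComponentSet.KEYS},
        )
        assert sum(cs.fractions.values()) == pytest.approx(1.0)
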