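"""LUT construction/inversion, calibration, composition and evaluation."""

import numpy as np
import pandas as pd
import pytest

from opencanopy.retrieval import (
    INFORM_STAND_RANGES,
    InversionConfig,
    LUT,
    build_lut_inform,
    build_lut_prosail,
    calibrate_index,
    evaluate,
    invert_inform_two_stage,
    invert_lut,
    pixel_cab,
)
from opencanopy.spectra import S2_SWIR_BANDS, S2_VNIR_BANDS

BANDS10 = S2_VNIR_BANDS + S2_SWIR_BANDS


@pytest.fixture(scope="module")
def small_prosail_lut():
    return build_lut_prosail(n=3000, seed=7)


@pytest.fixture(scope="module")
def small_inform_lut():
    return build_lut_inform(n=3000, seed=7, tts=26.0)


class TestLutBuilders:
    def test_same_seed_identical(self):
        a = build_lut_inform(n=200, seed=3)
        b = build_lut_inform(n=200, seed=3)
        assert a.params.equals(b.params)
        assert a.responses.equals(b.responses)

    def test_row_counts_and_alignment(self, small_prosail_lut):
        assert len(small_prosail_lut) == 3000
        assert len(small_prosail_lut.responses) == 3000

    def test_parameters_fill_declared_ranges(self, small_prosail_lut):
        # uniform order statistics: 3000 draws approach the bounds within
        # ~range/n; 2% of the range is a conservative band
        ranges = small_prosail_lut.meta["ranges"]
        for name, (lo, hi) in ranges.items():
            if hi == lo:
                assert (small_prosail_lut.params[name] == lo).all()
                continue
            col = small_prosail_lut.params[name]
            span = hi - lo
            assert col.min() <= lo + 0.02 * span
            assert col.max() >= hi - 0.02 * span
            assert col.min() >= lo and col.max() <= hi

    def test_inform_lower_td_bound_respected(self, small_inform_lut):
        assert (small_inform_lut.params["td"] >= 50.0).all()

    def test_seasonal_geometry_changes_responses(self):
        june = build_lut_inform(n=100, seed=5, tts=26.0)
        december = build_lut_inform(n=100, seed=5, tts=73.0)
        assert june.params.equals(december.params)
        assert not np.allclose(
            june.responses.to_numpy(), december.responses.to_numpy()
        )

    def test_cab_coverage_has_no_gaps(self, small_inform_lut):
        cab = np.sort(small_inform_lut.params["cab"].to_numpy())
        assert np.max(np.diff(cab)) < 1.0  # ug/cm2

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            build_lut_prosail(n=0)


class TestInvertLut:
    def test_lut_row_recovered(self, small_inform_lut):
        row = 123
        obs = small_inform_lut.responses.iloc[row].to_dict()
        res = invert_lut(obs, small_inform_lut, InversionConfig(k=500))
        # the zero-cost row carries weight 1/eps = 1e9 against ~1e3 for its
        # k-1 companions, so their contamination is of order k*eps/cost
        for p in ("cab", "td", "cm"):
            ref = small_inform_lut.params[p].iloc[row]
            scale = max(abs(ref), 1.0)
            assert res.estimates[p] == pytest.approx(ref, abs=5e-3 * scale)
        assert res.best_row == row

    def test_k1_equals_linear_scan_oracle(self, small_inform_lut):
        rng = np.random.default_rng(8)
        obs_vec = small_inform_lut.responses.iloc[42].to_numpy() * (
            1 + 0.03 * rng.standard_normal(13)
        )
        obs = dict(zip(small_inform_lut.responses.columns, obs_vec))
        res = invert_lut(obs, small_inform_lut, InversionConfig(k=1))
        cost = np.sqrt(
            np.mean((small_inform_lut.responses.to_numpy() - obs_vec) ** 2, axis=1)
        )
        assert res.best_row == int(np.argmin(cost))
        assert res.estimates["cab"] == pytest.approx(
            small_inform_lut.params["cab"].iloc[int(np.argmin(cost))]
        )

    def test_estimates_stay_in_parameter_hull(self, small_inform_lut):
        rng = np.random.default_rng(9)
        obs_vec = np.clip(
            small_inform_lut.responses.iloc[7].to_numpy()
            + 0.05 * rng.standard_normal(13),
            0,
            1,
        )
        obs = dict(zip(small_inform_lut.responses.columns, obs_vec))
        res = invert_lut(obs, small_inform_lut, InversionConfig(k=200))
        for name, (lo, hi) in INFORM_STAND_RANGES.items():
            assert lo - 1e-9 <= res.estimates[name] <= hi + 1e-9

    def test_k_larger_than_lut_rejected(self, small_inform_lut):
        obs = small_inform_lut.responses.iloc[0].to_dict()
        with pytest.raises(ValueError):
            invert_lut(obs, small_inform_lut, InversionConfig(k=10_000))

    def test_missing_band_named(self, small_inform_lut):
        obs = small_inform_lut.responses.iloc[0].to_dict()
        obs.pop("B5")
        with pytest.raises(KeyError) as err:
            invert_lut(obs, small_inform_lut, InversionConfig(k=10))
        assert "B5" in str(err.value)


class TestTwoStage:
    def test_missing_swir_refused_with_guidance(self, small_inform_lut):
        obs = {b: 0.2 for b in S2_VNIR_BANDS}
        with pytest.raises(KeyError) as err:
            invert_inform_two_stage(obs, small_inform_lut)
        assert "SWIR" in str(err.value)

    def test_lut_row_exact_with_filter_stage(self, small_inform_lut):
        row = 321
        obs = small_inform_lut.responses.iloc[row][BANDS10].to_dict()
        out = invert_inform_two_stage(
            obs, small_inform_lut, InversionConfig(k=50), stage2="filter"
        )
        assert out["cab"] == small_inform_lut.params["cab"].iloc[row]

    def test_lut_row_near_exact_with_regenerated_stage(self, small_inform_lut):
        row = 321
        obs = small_inform_lut.responses.iloc[row][BANDS10].to_dict()
        out = invert_inform_two_stage(obs, small_inform_lut, InversionConfig(k=50))
        assert out["cab"] == pytest.approx(
            small_inform_lut.params["cab"].iloc[row], abs=2.5
        )


class TestCalibration:
    def test_exact_linear_fit(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = 3.0 + 2.0 * x
        model = calibrate_index(x, y)
        assert model.r2 == pytest.approx(1.0)
        assert model.rmse == pytest.approx(0.0, abs=1e-10)
        assert model.predict(10.0) == pytest.approx(23.0)

    def test_slope_within_sampling_error(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 10, 100)
        sigma = 0.5
        y = 2.0 * x + rng.normal(0, sigma, 100)
        model = calibrate_index(x, y)
        se = sigma / (np.std(x) * np.sqrt(100))
        assert abs(model.coef[1] - 2.0) < 3 * se

    def test_power_form(self):
        x = np.linspace(1, 5, 30)
        y = 2.0 * x**1.5
        model = calibrate_index(x, y, form="power")
        assert model.coef[0] == pytest.approx(2.0, rel=1e-6)
        assert model.coef[1] == pytest.approx(1.5, rel=1e-6)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            calibrate_index([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])


class TestPixelCab:
    def test_pure_crown(self):
        value, veg = pixel_cab({"crown": 1.0, "understory": 0.0}, 50.0, 0.0)
        assert value == 50.0 and veg

    def test_study_mean_composition(self):
        # mean June landscape: 13.5% crown at 47.9, 52.2% understory at 40.1
        value, veg = pixel_cab({"crown": 0.135, "understory": 0.522}, 47.9, 40.1)
        assert value == pytest.approx(27.4, abs=0.05)
        assert veg

    def test_no_vegetation_flag(self):
        value, veg = pixel_cab({"crown": 0.0, "understory": 0.0}, 30.0, 20.0)
        assert value == 0.0 and not veg

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            pixel_cab({"crown": 0.5, "understory": 0.2}, -1.0, 5.0)


class TestEvaluate:
    def test_perfect_agreement(self):
        rep = evaluate([1, 2, 3, 4], [1, 2, 3, 4])
        assert rep.r2 == pytest.approx(1.0)
        assert rep.rmse == 0.0
        assert rep.bias == 0.0

    def test_four_point_closed_form(self):
        est = np.array([1.1, 1.9, 3.2, 3.8])
        tru = np.array([1.0, 2.0, 3.0, 4.0])
        rep = evaluate(est, tru)
        # pencil-and-paper: rmse = sqrt(mean of [.1,.1,.2,.2]^2)
        assert rep.rmse == pytest.approx(np.sqrt(np.mean([0.01, 0.01, 0.04, 0.04])))
        sxy = np.sum((est - est.mean()) * (tru - tru.mean()))
        r2 = sxy**2 / (np.sum((est - est.mean()) ** 2) * np.sum((tru - tru.mean()) ** 2))
        assert rep.r2 == pytest.approx(r2)
        assert rep.n == 4

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(11)
        est = rng.uniform(0, 50, 20)
        tru = est + rng.normal(0, 3, 20)
        rep1 = evaluate(est, tru)
        perm = rng.permutation(20)
        rep2 = evaluate(est[perm], tru[perm])
        assert rep1.r2 == pytest.approx(rep2.r2)
        assert rep1.rmse == pytest.approx(rep2.rmse)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([1, 2, 3], [1, 2])


class TestLutIO:
    def test_round_trip(self, tmp_path, small_inform_lut):
        from opencanopy.io import load_lut, save_lut

        save_lut(small_inform_lut, tmp_path / "lut")
        back = load_lut(tmp_path / "lut")
        assert np.allclose(
            back.responses.to_numpy(), small_inform_lut.responses.to_numpy()
        )
        assert np.allclose(back.params.to_numpy(), small_inform_lut.params.to_numpy())
        assert back.meta["tts"] == 26.0
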