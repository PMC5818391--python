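from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import nemaquant as nq
from conftest import toy_image


@pytest.fixture(scope="module")
def nb_sweep(geometry, pet_nb_noiseless, nb_activity):
    return nq.sweep_thresholds(pet_nb_noiseless, geometry, "threshold", activity=nb_activity)


class TestCalibration:
    def test_roundtrip_recovers_factor(self, spect_calibration):
        _, acq = nq.preset("spect-in111")
        assert spect_calibration.factor == pytest.approx(acq.sensitivity_factor, rel=1e-3)

    def test_factor_inverse_in_concentration(self, geometry, spect_setup):
        grid, acq = spect_setup
        acq0 = replace(acq, noise=nq.NoiseModel("none"))
        img = nq.simulate(nq.uniform_geometry(), grid, nq.ActivityConfig(0.0, 5.0), acq0)
        one = nq.sensitivity_factor(img, 5.0 / 1000, acq.duration, grid)
        two = nq.sensitivity_factor(img, 10.0 / 1000, acq.duration, grid)
        assert two.factor == pytest.approx(one.factor / 2)

    def test_noisy_calibration_within_tolerance(self, spect_setup):
        grid, acq = spect_setup
        factors = []
        for seed in range(1, 21):
            img = nq.simulate(
                nq.uniform_geometry(), grid, nq.ActivityConfig(0.0, 5.0), acq, seed=seed
            )
            factors.append(nq.sensitivity_factor(img, 5.0 / 1000, acq.duration, grid).factor)
        assert np.mean(factors) == pytest.approx(acq.sensitivity_factor, rel=0.02)

    def test_zero_concentration_rejected(self, spect_setup):
        grid, acq = spect_setup
        img = nq.ImageVolume(np.ones(grid.dims), grid, value_unit="counts")
        with pytest.raises(nq.InvalidArgumentError):
            nq.sensitivity_factor(img, 0.0, acq.duration, grid)

    def test_wrong_unit_rejected(self, spect_setup):
        grid, acq = spect_setup
        img = nq.ImageVolume(np.ones(grid.dims), grid, value_unit="kBq/mL")
        with pytest.raises(nq.InvalidArgumentError):
            nq.sensitivity_factor(img, 1.0, acq.duration, grid)
        with pytest.raises(nq.InvalidArgumentError):
            nq.counts_to_concentration(img, nq.CalibrationResult(5.0), acq.duration)

    def test_counts_roundtrip(self, geometry, spect_fractions, spect_calibration, nb_activity):
        grid, acq = nq.preset("spect-in111")
        acq0 = replace(acq, psf_fwhm=(0.0,) * 3, noise=nq.NoiseModel("none"))
        img = nq.simulate(geometry, grid, nb_activity, acq0, fractions=spect_fractions)
        conc = nq.counts_to_concentration(img, spect_calibration, acq.duration)
        assert conc.value_unit == "kBq/mL"
        truth = nq.compose_activity(spect_fractions, nb_activity)
        assert np.allclose(conc.values, truth.values, atol=1e-9)

    def test_zero_image_maps_to_zero(self, spect_setup, spect_calibration):
        grid, acq = spect_setup
        img = nq.ImageVolume(np.zeros(grid.dims), grid, value_unit="counts")
        conc = nq.counts_to_concentration(img, spect_calibration, acq.duration)
        assert np.all(conc.values == 0.0)

    def test_double_factor_halves_concentration(self, spect_setup):
        grid, acq = spect_setup
        img = nq.ImageVolume(np.full(grid.dims, 50.0), grid, value_unit="counts")
        a = nq.counts_to_concentration(img, nq.CalibrationResult(2.0), acq.duration)
        b = nq.counts_to_concentration(img, nq.CalibrationResult(4.0), acq.duration)
        assert np.allclose(b.values, a.values / 2)


class TestQuantify:
    def test_toy_mask_statistics(self):
        values = np.zeros((2, 1, 1))
        values[0, 0, 0], values[1, 0, 0] = 4.0, 8.0
        img = toy_image(values)
        mask = nq.VOIMask(np.ones((2, 1, 1), dtype=bool), img.grid, "threshold", "s")
        ac_max, ac_mean, _ = nq.quantify(img, mask)
        assert (ac_max, ac_mean) == (8.0, 6.0)

    def test_volume_is_count_times_voxel(self):
        grid = nq.GridSpec.centered((6, 6, 6), (9.3, 9.3, 9.3))
        img = nq.ImageVolume(np.ones(grid.dims), grid)
        mask = np.zeros(grid.dims, dtype=bool)
        mask.flat[:33] = True
        voi = nq.VOIMask(mask, grid, "threshold", "s")
        _, _, volume = nq.quantify(img, voi)
        assert round(volume, 1) == 26.5  # 33 x 0.804 cm^3

    def test_uniform_values(self):
        img = toy_image(np.full((4, 4, 4), 2.5))
        mask = nq.VOIMask(np.ones((4, 4, 4), dtype=bool), img.grid, "ct", "s")
        ac_max, ac_mean, _ = nq.quantify(img, mask)
        assert ac_max == ac_mean == 2.5

    def test_empty_mask_infeasible(self):
        img = toy_image(np.ones((3, 3, 3)))
        mask = nq.VOIMask(np.zeros((3, 3, 3), dtype=bool), img.grid, "ct", "s")
        with pytest.raises(nq.SegmentationInfeasibleError):
            nq.quantify(img, mask)


class TestRecoveryCoefficient:
    @pytest.mark.parametrize(
        "measured, true, expected", [(100.0, 100.0, 1.0), (93.0, 100.0, 0.93), (0.0, 5.0, 0.0)]
    )
    def test_ratio(self, measured, true, expected):
        assert nq.recovery_coefficient(measured, true) == pytest.approx(expected)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(nq.InvalidArgumentError):
            nq.recovery_coefficient(1.0, 0.0)


class TestSweepThresholds:
    def test_cardinality(self, nb_sweep):
        assert len(nb_sweep) == 6 * 9  # 6 spheres x 9 thresholds

    def test_volume_non_increasing_in_threshold(self, nb_sweep):
        for _, grp in nb_sweep[nb_sweep["feasible"]].groupby("sphere_id"):
            vols = grp.sort_values("threshold")["volume_cm3"].to_numpy()
            assert np.all(np.diff(vols) <= 0)

    def test_ct_sweep_single_row_per_sphere(self, geometry, pet_nb_noiseless, nb_activity):
        table = nq.sweep_thresholds(pet_nb_noiseless, geometry, "ct", activity=nb_activity)
        assert len(table) == 6
        assert table["threshold"].isna().all()

    def test_infeasible_rows_kept(self, geometry, spect_fractions, spect_calibration):
        grid, acq = nq.preset("spect-in111")
        activity = nq.ActivityConfig.from_sbr("1.25:1", 20.0)
        img = nq.simulate(geometry, grid, activity, acq, seed=1, fractions=spect_fractions)
        img = nq.counts_to_concentration(img, spect_calibration, acq.duration)
        table = nq.sweep_thresholds(img, geometry, "threshold", activity=activity)
        assert len(table) == 6 * 9
        small = table[table["sphere_id"] == "sphere_10mm"]
        assert not small["feasible"].any()
        assert (small["reason"] != "").all()

    def test_bad_threshold_grid_rejected(self, geometry, pet_nb_noiseless):
        with pytest.raises(nq.InvalidArgumentError):
            nq.sweep_thresholds(pet_nb_noiseless, geometry, "threshold", t_grid=[0.5, 1.0])


class TestSelectBestThreshold:
    def test_dominant_row(self):
        rows = []
        for sphere, diam in [("a", 10), ("b", 20), ("c", 30), ("d", 35), ("e", 37)]:
            for t in (0.3, 0.4, 0.5):
                rc = 1.0 if (t == 0.4 and sphere != "e") else 0.7
                rows.append(
                    {
                        "sphere_id": sphere,
                        "diameter_mm": diam,
                        "method": "threshold",
                        "threshold": t,
                        "feasible": True,
                        "rc_mean": rc,
                        "volume_cm3": 1.0,
                        "true_volume_cm3": 1.0,
                    }
                )
        best = nq.select_best_threshold(pd.DataFrame(rows), "concentration")
        assert best["best_threshold"].tolist() == [0.4]

    def test_tie_goes_to_lower_threshold(self):
        rows = [
            {
                "sphere_id": "a",
                "diameter_mm": 20,
                "method": "threshold",
                "threshold": t,
                "feasible": True,
                "rc_mean": 1.1,
                "volume_cm3": 2.0,
                "true_volume_cm3": 1.0,
            }
            for t in (0.3, 0.6)
        ]
        best = nq.select_best_threshold(pd.DataFrame(rows), "concentration")
        assert best["best_threshold"].tolist() == [0.3]

    def test_no_feasible_rows_infeasible(self):
        rows = [
            {
                "sphere_id": "a",
                "diameter_mm": 20,
                "method": "threshold",
                "threshold": 0.4,
                "feasible": False,
                "rc_mean": None,
                "volume_cm3": None,
                "true_volume_cm3": 1.0,
            }
        ]
        with pytest.raises(nq.SegmentationInfeasibleError):
            nq.select_best_threshold(pd.DataFrame(rows), "concentration")

    def test_fine_sweep_best_volume_threshold_37mm(
        self, geometry, pet_nb_noiseless, nb_activity
    ):
        # brute-force fine sweep: best T for the 37-mm volume sits near 40%
        t_grid = np.round(np.arange(0.20, 0.61, 0.01), 2)
        table = nq.sweep_thresholds(
            pet_nb_noiseless,
            geometry,
            "threshold",
            activity=nb_activity,
            sphere_ids=["sphere_37mm"],
            t_grid=t_grid,
        )
        best = nq.select_best_threshold(table, "volume")
        assert 0.35 <= best["best_threshold"].iloc[0] <= 0.45

    def test_threshold_for_correct_volume_grows_as_diameter_shrinks(self, nb_sweep):
        best = nq.select_best_threshold(nb_sweep, "volume").sort_values("diameter_mm")
        t_star = best["best_threshold"].to_numpy()
        assert np.all(np.diff(t_star) <= 0)  # larger sphere -> lower (or equal) T
        assert t_star[0] > t_star[-1]  # strictly higher for the smallest sphere

    def test_unknown_criterion(self, nb_sweep):
        with pytest.raises(nq.InvalidArgumentError):
            nq.select_best_threshold(nb_sweep, "entropy")


class TestRecoveryCurve:
    def test_structure_sorted_by_diameter(self, nb_sweep):
        curve = nq.recovery_curve(nb_sweep, "threshold", "mean", threshold=0.4)
        assert len(curve) == 6
        assert list(curve["diameter_mm"]) == sorted(curve["diameter_mm"])

    def test_ct_curve_monotone_partial_volume(self, geometry, pet_nb_noiseless, nb_activity):
        table = nq.sweep_thresholds(pet_nb_noiseless, geometry, "ct", activity=nb_activity)
        curve = nq.recovery_curve(table, "ct", "mean")
        rc = curve["rc"].to_numpy()
        assert np.all(np.diff(rc) > 0)  # strictly increasing with diameter
        assert np.all(rc < 1.0)  # spill-out only, never above truth

    def test_ct_rc_higher_with_background(self, geometry, pet_fractions, nb_activity, pet_nb_noiseless):
        grid, acq = nq.preset("pet-ga68")
        acq = replace(acq, noise=nq.NoiseModel("none"), extra_blur_fwhm=0.0)
        act5 = nq.ActivityConfig.from_sbr("5:1", 20.0)
        img5 = nq.simulate(geometry, grid, act5, acq, fractions=pet_fractions)
        nb = nq.sweep_thresholds(pet_nb_noiseless, geometry, "ct", activity=nb_activity)
        t5 = nq.sweep_thresholds(img5, geometry, "ct", activity=act5)
        nb_rc = nq.recovery_curve(nb, "ct", "mean")["rc"].to_numpy()
        t5_rc = nq.recovery_curve(t5, "ct", "mean")["rc"].to_numpy()
        assert np.all(t5_rc >= nb_rc)  # spill-in raises recovery

    def test_max_in_voi_table(self, geometry, pet_nb_noiseless, nb_activity):
        table = nq.max_in_voi_table(pet_nb_noiseless, geometry, activity=nb_activity)
        assert len(table) == 6
        assert (table["method"] == "max").all()
        big = table.loc[table["sphere_id"] == "sphere_37mm", "rc_max"].iloc[0]
        assert big == pytest.approx(1.0, abs=0.03)
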