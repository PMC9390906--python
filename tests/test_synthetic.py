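"""Contracts of the synthetic film-reading generator."""

import numpy as np
import pytest

import filmdose as fd
from filmdose import synthetic as syn
from filmdose.exceptions import FilmDoseError, OutOfRangeError

CALIBRATION_DOSES = [50, 100, 150, 200, 250, 300, 350, 400, 450, 800]
HOURLY = np.arange(0.0, 6481.0, 60.0)


class TestGrowthSeries:
    def test_saturates_at_the_plateau(self):
        model = fd.GrowthModel.for_dose(200.0)
        series = syn.generate_growth_series(
            200.0, [20 * model.tau], model=model, noise_sd_od=0.0, quantize=True
        )
        assert abs(series[0] - model.plateau_nod) <= 0.01

    def test_higher_dose_has_higher_plateau_and_slower_kinetics(self):
        low = fd.GrowthModel.for_dose(50.0)
        high = fd.GrowthModel.for_dose(800.0)
        assert high.plateau_nod > low.plateau_nod
        assert high.tau > low.tau
        series_low = syn.generate_growth_series(50.0, HOURLY, seed=0)
        series_high = syn.generate_growth_series(800.0, HOURLY, seed=0)
        assert series_high[-1] > series_low[-1]

    def test_noiseless_unquantised_series_is_non_decreasing(self):
        series = syn.generate_growth_series(
            400.0, HOURLY, noise_sd_od=0.0, quantize=False
        )
        assert np.all(np.diff(series) >= 0)

    def test_unsorted_times_rejected(self):
        with pytest.raises(FilmDoseError):
            syn.generate_growth_series(200.0, [60.0, 30.0, 90.0])


class TestStabilizationTime:
    def test_constant_series_stabilises_immediately(self):
        times = [0.0, 60.0, 120.0, 180.0]
        assert syn.stabilization_time([0.2] * 4, times) == 0.0

    @pytest.mark.parametrize("dose", [50.0, 200.0, 400.0, 800.0])
    def test_all_doses_stabilise_within_24_hours(self, dose):
        series = syn.generate_growth_series(dose, HOURLY, seed=0)
        result = syn.stabilization_time(series, HOURLY)
        assert result is not None and result <= 1440.0

    def test_steadily_darkening_series_never_stabilises(self):
        times = np.arange(0.0, 600.0, 60.0)
        series = 0.02 * np.arange(times.size)
        assert syn.stabilization_time(series, times) is None


class TestCalibrationDataset:
    def test_noiseless_dataset_closes_with_the_fit(self):
        scenario = fd.ResponseScenario(noise_sd_od=0.0, quantize=False, seed=0)
        points = syn.generate_calibration_dataset(scenario, CALIBRATION_DOSES)
        fit = fd.fit_calibration(points)
        for est, true in zip(fit.coefficients, scenario.true_curve.coefficients):
            assert est == pytest.approx(true, rel=1e-5)

    def test_noisy_refit_retains_high_correlation(self):
        scenario = fd.ResponseScenario(noise_sd_od=0.005, quantize=False, seed=0)
        points = syn.generate_calibration_dataset(scenario, CALIBRATION_DOSES)
        assert fd.fit_calibration(points).r_fit > 0.995

    def test_bias_vanishes_as_noise_shrinks(self):
        errors = []
        for sigma in (0.004, 0.001, 0.0):
            scenario = fd.ResponseScenario(noise_sd_od=sigma, quantize=False, seed=0)
            points = syn.generate_calibration_dataset(scenario, CALIBRATION_DOSES)
            fit = fd.fit_calibration(points)
            errors.append(abs(fit.c - scenario.true_curve.c))
        assert errors[-1] == pytest.approx(0.0, abs=1e-6)
        assert errors[-1] <= errors[0]

    def test_empty_dose_list_gives_empty_dataset(self, scenario):
        assert syn.generate_calibration_dataset(scenario, []) == []

    def test_out_of_range_dose_rejected(self, scenario):
        with pytest.raises(OutOfRangeError):
            syn.generate_calibration_dataset(scenario, [5000.0])


class TestCfLandscape:
    @pytest.fixture()
    def noiseless(self):
        return fd.ResponseScenario(noise_sd_od=0.0, quantize=False, seed=0)

    def test_reference_condition_normalises_to_one(self, noiseless):
        landscape = syn.generate_cf_landscape(noiseless)
        for parameter, series in landscape.items():
            reference = fd.REFERENCE_CONDITIONS[parameter]
            pairs = dict(syn.normalized_response(series["unencapsulated"], reference))
            assert pairs[reference] == pytest.approx(1.0)

    def test_unencapsulated_field_size_response_strictly_increases(self, noiseless):
        landscape = syn.generate_cf_landscape(noiseless)
        pairs = syn.normalized_response(landscape["field_size_cm"]["unencapsulated"], 10.0)
        responses = [r for _, r in pairs]
        assert np.all(np.diff(responses) > 0)

    def test_unencapsulated_response_falls_with_ssd_and_wedge(self, noiseless):
        landscape = syn.generate_cf_landscape(noiseless)
        for parameter, reference in (("ssd_cm", 100.0), ("wedge_deg", 0.0)):
            responses = [r for _, r in syn.normalized_response(
                landscape[parameter]["unencapsulated"], reference
            )]
            assert np.all(np.diff(responses) < 0)

    def test_encapsulated_gantry_response_flat_within_one_percent(self, noiseless):
        landscape = syn.generate_cf_landscape(noiseless)
        for parameter in ("gantry_deg", "field_size_cm"):
            reference = fd.REFERENCE_CONDITIONS[parameter]
            responses = [r for _, r in syn.normalized_response(
                landscape[parameter]["encapsulated"], reference
            )]
            assert max(abs(r - 1.0) for r in responses) < 0.01

    def test_cf_recovery_within_one_percent_at_low_noise(self):
        scenario = fd.ResponseScenario(noise_sd_od=0.001, quantize=False, seed=0)
        estimated = syn.estimate_cf_set(syn.generate_cf_landscape(scenario))
        for parameter, table in estimated.tables.items():
            truth = scenario.cf_truth.tables[parameter]
            for value, cf in table.knots:
                assert cf == pytest.approx(truth.lookup(value), rel=0.01)


class TestDeterminism:
    def test_identical_seeds_give_identical_datasets(self):
        a = fd.ResponseScenario(seed=123)
        b = fd.ResponseScenario(seed=123)
        assert syn.generate_calibration_dataset(a, CALIBRATION_DOSES) == (
            syn.generate_calibration_dataset(b, CALIBRATION_DOSES)
        )
        ta = syn.simulate_treatment_readings(a, [{"field_size_cm": 15.0}])
        tb = syn.simulate_treatment_readings(b, [{"field_size_cm": 15.0}])
        assert [r.od_post for r in ta[0].readings] == [r.od_post for r in tb[0].readings]

    def test_different_seeds_differ(self):
        a = syn.generate_calibration_dataset(
            fd.ResponseScenario(seed=1, quantize=False), [200.0]
        )
        b = syn.generate_calibration_dataset(
            fd.ResponseScenario(seed=2, quantize=False), [200.0]
        )
        assert a != b


class TestTreatmentSimulation:
    def test_noiseless_reference_reconstruction_is_exact(self):
        scenario = fd.ResponseScenario(noise_sd_od=0.0, quantize=False, seed=0)
        (treatment,) = syn.simulate_treatment_readings(
            scenario, [dict(fd.REFERENCE_CONDITIONS)], 200.0
        )
        for reading in treatment.readings:
            df = fd.od_to_dose(scenario.true_curve, reading.nod)
            dent = df * scenario.fcal_entrance * scenario.cf_truth.product(
                treatment.conditions
            )
            assert dent == pytest.approx(200.0, abs=0.1)

    def test_low_noise_sweep_recovers_prescription_within_3_percent(self):
        scenario = fd.ResponseScenario(noise_sd_od=0.001, quantize=False, seed=0)
        estimated = syn.estimate_cf_set(syn.generate_cf_landscape(scenario))
        conditions = syn.sweep_conditions(20, seed=0)
        treatments = syn.simulate_treatment_readings(scenario, conditions, 200.0)
        deviations = []
        for t in treatments:
            df = float(np.mean(
                [fd.od_to_dose(scenario.true_curve, r.nod) for r in t.readings]
            ))
            dent = df * scenario.fcal_entrance * estimated.product(t.conditions)
            deviations.append(100 * abs(dent - 200.0) / 200.0)
        assert max(deviations) <= 3.0

    def test_ground_truth_attached(self, scenario):
        (t,) = syn.simulate_treatment_readings(scenario, [{"ssd_cm": 110.0}], 200.0)
        assert t.prescribed == 200.0
        assert t.true_cf_product == scenario.cf_truth.product({"ssd_cm": 110.0})
        assert t.true_film_dose == pytest.approx(
            200.0 / (scenario.fcal_entrance * t.true_cf_product)
        )

    def test_unknown_condition_key_rejected(self, scenario):
        with pytest.raises(FilmDoseError):
            syn.simulate_treatment_readings(scenario, [{"couch_deg": 10.0}])


class TestPddGeneration:
    def test_table_has_unit_pdd_at_dmax_and_decays(self):
        table = syn.generate_pdd_table()
        assert table.pdd(table.dmax_depth) == pytest.approx(100.0)
        doses = [table.pdd(d) for d in np.arange(0.5, 20.0, 0.5)]
        assert all(d2 < d1 for d1, d2 in zip(doses, doses[1:]))
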