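"""Entrance dose, depth dose and skin dose."""

import pytest
from hypothesis import given, settings, strategies as st

import filmdose as fd
from filmdose.dose_engine import (
    FOUR_FILM_STACK_ACTIVE_DEPTH_MM,
    SINGLE_FILM_ACTIVE_DEPTH_MM,
    SKIN_REFERENCE_DEPTH_MM,
)
from filmdose.exceptions import FilmDoseError, InvalidReadingError, OutOfRangeError


class TestEntranceCalibrationFactor:
    def test_identity_when_film_matches_chamber(self):
        assert fd.entrance_calibration_factor(150.0, 150.0) == 1.0

    def test_reference_pair_reproduces_measured_factor(self):
        assert fd.entrance_calibration_factor(200.0, 48.38) == pytest.approx(
            4.134, abs=1e-3
        )

    def test_plain_ratio(self):
        assert fd.entrance_calibration_factor(100.0, 50.0) == 2.0

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidReadingError):
            fd.entrance_calibration_factor(200.0, 0.0)


class TestEntranceDose:
    def test_identity_factors(self):
        factors = fd.CalibrationFactors(fcal_entrance=1.0)
        assert fd.entrance_dose(48.38, factors, 1.0) == pytest.approx(48.38)

    def test_surface_film_chain(self, co60_curve):
        df = fd.od_to_dose(co60_curve, 0.05)
        dent = fd.entrance_dose(df, fd.CalibrationFactors(4.134), 1.0)
        assert dent == pytest.approx(197.245, abs=1e-3)
        deviation = 100 * abs(dent - 200.0) / 200.0
        assert deviation == pytest.approx(1.38, abs=0.01)
        assert deviation < 3.0

    def test_reference_film_dose_recovers_prescription(self):
        dent = fd.entrance_dose(48.38, fd.CalibrationFactors(4.134), 1.0)
        assert dent == pytest.approx(200.0, abs=0.1)


class TestDoseAtDepth:
    @pytest.fixture()
    def pdd(self):
        return fd.DepthDoseTable(
            knots=((0.0, 40.0), (0.5, 100.0), (5.0, 80.0), (10.0, 50.0)),
            dmax_depth=0.5,
        )

    def test_unchanged_at_dmax(self, pdd):
        assert fd.dose_at_depth(200.0, pdd, 0.5) == pytest.approx(200.0)

    def test_scales_by_pdd(self, pdd):
        assert fd.dose_at_depth(200.0, pdd, 10.0) == pytest.approx(100.0)

    def test_depth_beyond_table_rejected(self, pdd):
        with pytest.raises(OutOfRangeError):
            fd.dose_at_depth(200.0, pdd, 11.0)

    def test_non_increasing_beyond_dmax(self, pdd):
        depths = [0.5 + 0.1 * i for i in range(95)]
        doses = [fd.dose_at_depth(200.0, pdd, d) for d in depths]
        assert all(d2 <= d1 for d1, d2 in zip(doses, doses[1:]))

    def test_pdd_must_be_100_at_dmax(self):
        with pytest.raises(FilmDoseError):
            fd.DepthDoseTable(knots=((0.5, 95.0), (5.0, 80.0)), dmax_depth=0.5)


class TestDepthExtrapolation:
    def test_stack_measurement_extrapolates_to_skin_depth(self):
        p1 = fd.DepthODPoint(SINGLE_FILM_ACTIVE_DEPTH_MM, 0.03)
        p2 = fd.DepthODPoint(FOUR_FILM_STACK_ACTIVE_DEPTH_MM, 0.08)
        raw, displayed = fd.extrapolate_od_to_depth(p1, p2, SKIN_REFERENCE_DEPTH_MM)
        assert raw == pytest.approx(0.0294, abs=1e-4)
        assert displayed == pytest.approx(0.03)

    def test_endpoint_is_exact(self):
        p1 = fd.DepthODPoint(0.080, 0.03)
        p2 = fd.DepthODPoint(0.935, 0.08)
        raw, _ = fd.extrapolate_od_to_depth(p1, p2, p1.depth)
        assert raw == pytest.approx(p1.od)

    def test_linear_midpoint(self):
        raw, _ = fd.extrapolate_od_to_depth(
            fd.DepthODPoint(1.0, 0.05), fd.DepthODPoint(3.0, 0.09), 2.0
        )
        assert raw == pytest.approx(0.07)

    def test_equal_depths_rejected(self):
        with pytest.raises(FilmDoseError):
            fd.extrapolate_od_to_depth(
                fd.DepthODPoint(0.08, 0.03), fd.DepthODPoint(0.08, 0.05), 0.07
            )


class TestSkinCalibrationFactor:
    def test_displayed_precision_gives_unity(self, co60_curve):
        assert fd.skin_calibration_factor(0.0294152, 0.03, co60_curve) == pytest.approx(
            1.00
        )

    def test_identical_raw_ods_give_unity(self, co60_curve):
        assert fd.skin_calibration_factor(
            0.042, 0.042, co60_curve, round_to_precision=False
        ) == pytest.approx(1.0)

    def test_raw_extrapolated_ratio(self, co60_curve):
        assert fd.skin_calibration_factor(
            0.0294152, 0.03, co60_curve, round_to_precision=False
        ) == pytest.approx(0.979, abs=1e-3)


class TestSkinDose:
    def test_unit_factor_is_identity(self):
        assert fd.skin_dose(139.4528, 1.0) == pytest.approx(139.4528)

    def test_encapsulated_film_gives_70_percent(self, co60_curve):
        df = fd.od_to_dose(co60_curve, 0.14)
        percent = 100 * fd.skin_dose(df, 1.0) / 200.0
        assert round(percent) == 70

    def test_unencapsulated_film_gives_24_percent(self, co60_curve):
        df = fd.od_to_dose(co60_curve, 0.05)
        percent = 100 * fd.skin_dose(df, 1.0) / 200.0
        assert round(percent) == 24


class TestPercentSkinDose:
    def test_reference_conditions(self):
        percent = fd.percent_skin_dose(4.134, 1.0, 1.0)
        assert percent == pytest.approx(24.19, abs=0.01)
        assert round(percent) == 24

    def test_unit_factors_give_100(self):
        assert fd.percent_skin_dose(1.0, 1.0, 1.0) == pytest.approx(100.0)

    def test_cf_product_halves_percentage(self):
        assert fd.percent_skin_dose(4.134, 2.0, 1.0) == pytest.approx(12.10, abs=0.01)

    @settings(derandomize=True, max_examples=50)
    @given(
        df=st.floats(min_value=1.0, max_value=500.0),
        fcal=st.floats(min_value=0.5, max_value=10.0),
        cf=st.floats(min_value=0.5, max_value=2.0),
    )
    def test_consistent_with_entrance_and_skin_dose(self, df, fcal, cf):
        """percent_skin * D_entrance / 100 equals D_skin algebraically."""
        dent = fd.entrance_dose(df, fd.CalibrationFactors(fcal), cf)
        lhs = fd.percent_skin_dose(fcal, cf, 1.0) * dent / 100.0
        assert lhs == pytest.approx(fd.skin_dose(df, 1.0), rel=1e-9)
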