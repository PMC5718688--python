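"""Calibration, piecewise correction functions, dose-weighted CF, fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mosdose as m
from mosdose.errors import (
    FittingError,
    InvalidParameterError,
    OutOfRangeError,
    UndefinedDoseError,
)


class TestCalibration:
    def test_raw_dose_from_printed_sensitivity(self):
        cal = m.CalibrationFactor.from_sensitivity(0.72)
        assert m.raw_dose(144.0, cal) == pytest.approx(200.0, rel=1e-12)

    @pytest.mark.parametrize("reading,fcalib,expected", [(0.0, 2.0, 0.0), (1.0, 1.0, 1.0)])
    def test_raw_dose_simple(self, reading, fcalib, expected):
        assert m.raw_dose(reading, m.CalibrationFactor(fcalib)) == expected

    def test_negative_reading_rejected(self):
        with pytest.raises(InvalidParameterError):
            m.raw_dose(-1.0, m.CalibrationFactor(1.0))

    def test_reciprocal_invariant(self):
        cal = m.CalibrationFactor.from_sensitivity(0.72)
        assert cal.fcalib * cal.sensitivity == pytest.approx(1.0, abs=1e-9)


class TestPiecewiseTables:
    # expected values frozen from direct evaluation of the printed segments
    @pytest.mark.parametrize(
        "d,expected",
        [(50.0, 1.0), (120.0, 1.042525), (160.0, 1.254866), (0.0, 1.0)],
    )
    def test_cf_mono_values(self, d, expected):
        assert m.cf_mono(d) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "d,expected",
        [(20.0, 1.0), (100.0, 1.080415), (160.0, 1.2760580)],
    )
    def test_cf_sobp_values(self, d, expected):
        assert m.cf_sobp(d) == pytest.approx(expected, abs=1e-6)

    def test_interval_closure_lower_closed(self):
        # at a breakpoint, the deeper segment applies (lower-closed)
        assert m.cf_mono(100.421) == pytest.approx(
            0.781885 + 0.002172 * 100.421, abs=1e-12
        )
        assert m.cf_sobp(40.0) == pytest.approx(0.94639 + 0.00134025 * 40.0, abs=1e-12)

    @pytest.mark.parametrize("table", [m.MOSFET_CF_MONO, m.MOSFET_CF_SOBP])
    def test_continuity_at_breakpoints(self, table):
        assert table.continuity_mismatch().max() < 1e-4
        table.validate(max_mismatch=1e-4)

    def test_negative_depth_rejected(self):
        with pytest.raises(OutOfRangeError):
            m.cf_mono(-1.0)

    def test_first_segment_must_be_unity(self):
        with pytest.raises(InvalidParameterError):
            m.PiecewiseCorrection(
                lowers=np.array([0.0, 50.0]),
                coeffs=(np.array([1.1]), np.array([1.0])),
            )

    def test_linear_extrapolation_beyond_domain(self):
        pw = m.PiecewiseCorrection(
            lowers=np.array([0.0, 100.0]),
            coeffs=(np.array([1.0]), np.array([0.0, 0.01])),  # cf = 0.01 d
            domain_max=150.0,
        )
        # tangent continuation of the last (linear) segment: unchanged slope
        assert pw(170.0) == pytest.approx(1.7, rel=1e-12)


class TestAngularCorrection:
    # frozen from direct evaluation of the printed polynomial
    @pytest.mark.parametrize(
        "theta,expected", [(0.0, 1.0), (90.0, 0.91099), (180.0, 0.99856)]
    )
    def test_printed_polynomial(self, theta, expected):
        assert m.angular_cv(theta) == pytest.approx(expected, abs=1e-9)

    def test_range_and_unity_only_near_zero(self):
        th = np.linspace(0.0, 180.0, 1801)
        cv = m.angular_cv(th)
        assert np.all((cv >= 0.90) & (cv <= 1.0))
        assert np.all(cv[(th >= 1.0) & (th <= 179.0)] < 1.0)
        assert abs(m.angular_cv(180.0) - 1.0) < 2e-3

    @pytest.mark.parametrize("theta", [-1.0, 181.0])
    def test_out_of_range_rejected(self, theta):
        with pytest.raises(OutOfRangeError):
            m.angular_cv(theta)


def two_wet_pencils(fluences=(1.0, 1.0), wets=(0.0, 150.0)):
    """Two coincident-axis pencils with controllable dose ratio via fluence;
    a flat depth-dose and bolus-independent sigma keep doses proportional."""
    pencils = m.PencilBeamSet(
        x0=[0.0, 0.0], y0=[0.0, 0.0], fluence=list(fluences), wet_offset=list(wets)
    )
    model = m.SigmaModel(sigma0=5.0, growth_coeff=0.0, bolus_coeff=0.0)
    step_cf = m.PiecewiseCorrection(
        lowers=np.array([0.0, 100.0]),
        coeffs=(np.array([1.0]), np.array([1.2])),  # 1 below 100 mm, 1.2 beyond
    )
    return pencils, model, step_cf


class TestCorrectionField:
    def test_equal_effective_depths_give_plain_cf(self, pristine, sigma_model):
        pencils = m.decompose_broad_beam(30.0, 2.0, geometry=m.BolusGeometry.uniform(50.0))
        cf = m.correction_field(
            np.array([[0.0, 0.0, 110.0]]), pencils, m.MOSFET_CF_MONO, pristine, sigma_model
        )
        assert cf[0] == pytest.approx(m.cf_mono(160.0), rel=1e-12)

    def test_equal_dose_arithmetic_mean(self, flat_dd):
        pencils, model, step_cf = two_wet_pencils()
        cf = m.correction_field(np.array([[0.0, 0.0, 5.0]]), pencils, step_cf, flat_dd, model)
        assert cf[0] == pytest.approx(1.1, rel=1e-12)

    def test_three_to_one_dose_ratio(self, flat_dd):
        pencils, model, step_cf = two_wet_pencils(fluences=(3.0, 1.0))
        cf = m.correction_field(np.array([[0.0, 0.0, 5.0]]), pencils, step_cf, flat_dd, model)
        assert cf[0] == pytest.approx((3 * 1.0 + 1 * 1.2) / 4.0, rel=1e-12)

    @given(
        fluences=st.lists(st.floats(0.1, 10.0), min_size=2, max_size=6),
        depth=st.floats(0.0, 160.0),
    )
    def test_weighted_mean_bounds(self, fluences, depth):
        """CF lies between the extreme per-pencil cf values (exact)."""
        n = len(fluences)
        wets = np.linspace(0.0, 60.0, n)
        pencils = m.PencilBeamSet(
            x0=np.zeros(n), y0=np.zeros(n), fluence=fluences, wet_offset=wets
        )
        model = m.SigmaModel(sigma0=4.0, growth_coeff=0.0, bolus_coeff=0.0)
        z = np.arange(0.0, 400.0, 1.0)
        dd = m.DepthDoseCurve(depths=z, outputs=np.ones_like(z), kind="pristine")
        cf = m.correction_field(
            np.array([[1.0, -2.0, depth]]), pencils, m.MOSFET_CF_MONO, dd, model
        )[0]
        cfdd = m.cf_mono(depth + wets)
        assert cfdd.min() - 1e-12 <= cf <= cfdd.max() + 1e-12

    def test_zero_dose_point_rejected(self, pristine, sigma_model):
        pencils = m.PencilBeamSet(x0=[0.0], y0=[0.0], fluence=[1.0], wet_offset=[50.0])
        # effective depth far beyond distal extinction -> zero dose
        with pytest.raises(UndefinedDoseError):
            m.correction_field(
                np.array([[0.0, 0.0, 170.0]]), pencils, m.MOSFET_CF_MONO, pristine, sigma_model
            )

    def test_shallow_region_needs_no_correction(self, pristine, sigma_model, field_pencils):
        """At slab depth 0 both bolus branches stay below the first
        breakpoint (10 and 50 < 100.421 mm), so CF = 1 across the field."""
        x = np.arange(-60.0, 61.0, 5.0)
        pts = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        cf = m.correction_field(pts, field_pencils, m.MOSFET_CF_MONO, pristine, sigma_model)
        np.testing.assert_allclose(cf, 1.0, atol=1e-14)


class TestCorrectedDose:
    @pytest.mark.parametrize(
        "cf,draw,expected", [(1.0, 37.2, 37.2), (1.35, 74.0, 99.9), (1.1, 0.0, 0.0)]
    )
    def test_product(self, cf, draw, expected):
        assert m.corrected_dose(cf, draw) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_cf_rejected(self):
        with pytest.raises(InvalidParameterError):
            m.corrected_dose(0.0, 10.0)


class TestFitPiecewise:
    depths = np.arange(0.0, 171.0, 2.0)

    def test_noise_free_recovery_of_mono_table(self):
        ratios = np.asarray(m.cf_mono(self.depths))
        fit = m.fit_piecewise_correction(
            self.depths, ratios, breakpoint_hints=[100.421, 154.784], degrees=[1, 1]
        )
        np.testing.assert_allclose(fit(self.depths), ratios, atol=1e-6)
        np.testing.assert_allclose(fit.coeffs[1], [0.781885, 0.002172], atol=1e-6)
        np.testing.assert_allclose(fit.coeffs[2], [-2.94139, 0.0262266], atol=1e-6)
        # the recovered segments inherit the printed coefficients' own
        # rounding mismatch at the breakpoints (~1e-5), nothing more
        assert fit.metadata["continuity_residuals"].max() < 1e-4

    def test_noisy_recovery_within_2pct(self):
        rng = np.random.default_rng(42)
        d = np.linspace(0.0, 170.0, 30)
        ratios = np.asarray(m.cf_mono(d)) * (1.0 + rng.normal(0.0, 0.01, d.size))
        fit = m.fit_piecewise_correction(d, ratios, [100.421, 154.784], degrees=[1, 1])
        true = np.asarray(m.cf_mono(self.depths))
        assert np.abs(fit(self.depths) / true - 1.0).max() < 0.02

    def test_constant_unit_ratio_gives_single_segment(self):
        fit = m.fit_piecewise_correction(
            self.depths, np.ones_like(self.depths), breakpoint_hints=[]
        )
        assert len(fit.coeffs) == 1
        assert fit(123.0) == 1.0

    def test_insufficient_samples_rejected(self):
        with pytest.raises(FittingError):
            m.fit_piecewise_correction(
                np.array([0.0, 50.0, 120.0]), np.array([1.0, 1.0, 1.05]),
                breakpoint_hints=[100.0, 150.0], degrees=[1, 1],
            )


class TestDeriveCfSobp:
    def test_unity_mono_gives_unity_sobp(self, pristine, sobp_spec):
        derived = m.derive_cf_sobp(m.PiecewiseCorrection.unity(), pristine, sobp_spec)
        z = np.arange(0.0, 170.0, 1.0)
        np.testing.assert_allclose(derived(z), 1.0, atol=1e-12)

    def test_single_zero_shift_component_returns_mono(self, pristine):
        spec = m.SOBPSpec(shifts=[0.0], weights=[1.0], modulation_width=0.0)
        derived = m.derive_cf_sobp(m.MOSFET_CF_MONO, pristine, spec)
        z = np.arange(0.0, 170.0, 0.5)
        np.testing.assert_allclose(derived(z), m.cf_mono(z), atol=1e-9)

    def test_derived_cf_non_decreasing_on_plateau(self, pristine, sobp_spec, sobp):
        derived = m.derive_cf_sobp(m.MOSFET_CF_MONO, pristine, sobp_spec)
        lo, hi = sobp.plateau
        z = np.arange(lo, hi, 0.25)
        assert np.all(np.diff(derived(z)) >= -1e-12)

    def test_derived_fit_is_continuous(self, pristine, sobp_spec):
        derived = m.derive_cf_sobp(m.MOSFET_CF_MONO, pristine, sobp_spec)
        assert derived.continuity_mismatch().max() < 1e-9
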