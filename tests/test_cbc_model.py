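import numpy as np
import pytest
from numpy.polynomial import Polynomial

import slurrycbc as s
from slurrycbc.cbc_model import (
    CBCCurve,
    CurveFit,
    FitRange,
    integrate_cbc,
)
from slurrycbc.titration_io import Direction

from conftest import make_record


def linear_fit(slope, intercept=7.0, a_max=1.0, direction=Direction.ACIDIFY):
    """CurveFit with an exactly linear titration curve (test double)."""
    poly = Polynomial([intercept, slope])
    return CurveFit(
        poly=poly,
        degree=1,
        fit_window=(min(intercept, intercept + slope * a_max),
                    max(intercept, intercept + slope * a_max)),
        amount_window=(0.0, a_max),
        n_points=50,
        rmse_ph=0.0,
        direction=direction,
        monotone=True,
    )


class TestSelectFitRange:
    def test_acidify_window_3_to_7(self):
        phs = np.linspace(8.2, 2.5, 80)
        rec = make_record(np.linspace(0, 20, 80), phs)
        sel = s.select_fit_range(rec)
        assert sel.ph.min() >= 3.0 and sel.ph.max() <= 7.0
        assert sel.window == (3.0, 7.0)
        # every raw point inside the window is retained
        assert len(sel.ph) == np.sum((phs >= 3.0) & (phs <= 7.0))

    def test_alkalize_standard_window(self):
        phs = np.linspace(7.0, 12.0, 80)
        rec = make_record(np.linspace(0, 20, 80), phs, direction="alkalize")
        sel = s.select_fit_range(rec)
        assert sel.ph.min() >= 7.8 and sel.ph.max() <= 11.5

    def test_alkalize_alkaline_start_uses_nearest_to_78(self):
        """A fresh sow-like sample starting at pH 8.9 is fitted from its
        first reading (the value nearest 7.8)."""
        phs = np.linspace(8.9, 12.0, 60)
        rec = make_record(np.linspace(0, 15, 60), phs, direction="alkalize")
        sel = s.select_fit_range(rec)
        assert sel.ph[0] == pytest.approx(8.9)
        assert sel.amount[0] == 0.0
        assert sel.ph.max() <= 11.5

    def test_alkalize_after_acid_window_7_to_115(self):
        phs = np.linspace(2.5, 12.0, 120)
        rec = make_record(
            np.linspace(0, 25, 120), phs, direction="alkalize_after_acid"
        )
        sel = s.select_fit_range(rec)
        assert sel.ph.min() >= 7.0 and sel.ph.max() <= 11.5
        assert sel.window == (7.0, 11.5)

    def test_too_few_points_in_window(self):
        # alkalization stuck below 7.8 except 8 readings
        phs = np.concatenate([np.linspace(6.0, 7.7, 42), np.linspace(7.9, 8.6, 8)])
        rec = make_record(np.linspace(0, 12, 50), phs, direction="alkalize")
        with pytest.raises(s.InsufficientDataError):
            s.select_fit_range(rec)


class TestFitTitrationCurve:
    def test_nested_model_exactness(self):
        """Degree 6 reproduces data from a cubic pH(amount) exactly."""
        a = np.linspace(0, 0.3, 40)
        ph = 7.0 - 20 * a + 30 * a**2 - 40 * a**3
        sel = FitRange(a, ph, (float(ph.min()), 7.0), Direction.ACIDIFY)
        fit = s.fit_titration_curve(sel, degree=6)
        assert fit.rmse_ph < 1e-8

    def test_too_few_points_raises(self):
        a = np.linspace(0, 1, 8)
        sel = FitRange(a, 7 - a, (6.0, 7.0), Direction.ACIDIFY)
        with pytest.raises(s.InsufficientDataError):
            s.fit_titration_curve(sel, degree=6)

    def test_constant_amounts_raise(self):
        sel = FitRange(np.full(20, 0.1), np.linspace(7, 3, 20), (3, 7), Direction.ACIDIFY)
        with pytest.raises(s.FitError):
            s.fit_titration_curve(sel)

    def test_refit_is_idempotent(self, pig_acid_record):
        fit = s.fit_titration_curve(s.select_fit_range(pig_acid_record))
        a = np.linspace(*fit.amount_window, 200)
        refit = s.fit_titration_curve(
            FitRange(a, fit.poly(a), fit.fit_window, fit.direction)
        )
        np.testing.assert_allclose(
            refit.poly.convert().coef, fit.poly.convert().coef, rtol=1e-6, atol=1e-9
        )

    def test_simulated_acetate_fit_quality(self, acetate_record):
        """The acid window includes the weakly buffered pH 3-3.8 stretch, so a
        global degree-6 fit of a lone acetate buffer carries a few-hundredths
        residual; it must stay monotone and below 0.08 pH RMSE."""
        fit = s.fit_titration_curve(s.select_fit_range(acetate_record))
        assert fit.monotone
        assert fit.rmse_ph < 0.08


class TestSlopeCurve:
    def test_linear_fit_has_constant_slope(self):
        slope = s.slope_curve(linear_fit(-2.0))
        assert slope(0.1) == pytest.approx(-2.0)
        assert slope(0.9) == pytest.approx(-2.0)

    def test_derivative_degree_drops_by_one(self, pig_acid_record):
        fit = s.fit_titration_curve(s.select_fit_range(pig_acid_record))
        assert s.slope_curve(fit).degree() == fit.degree - 1

    def test_acidification_slope_is_negative_mid_window(self, acetate_record):
        fit = s.fit_titration_curve(s.select_fit_range(acetate_record))
        mid = 0.5 * sum(fit.amount_window)
        assert s.slope_curve(fit)(mid) < 0


class TestComputeCbc:
    def test_constant_slope_gives_exact_reciprocal(self):
        curve = s.compute_cbc(linear_fit(-4.0))
        np.testing.assert_allclose(curve.cbc, 0.25, rtol=1e-12)
        assert curve.n_dropped == 0

    def test_flat_stretch_is_degenerate(self):
        # p(a) = 5 + 0.02 (a - 0.5)^3: |p'| < 1e-3 over ~26% of [0, 1]
        poly = Polynomial([5 - 0.02 * 0.125, 0.015, -0.03, 0.02])
        fit = CurveFit(
            poly=poly, degree=3, fit_window=(4.9, 5.1), amount_window=(0.0, 1.0),
            n_points=50, rmse_ph=0.0, direction=Direction.ALKALIZE, monotone=True,
        )
        with pytest.raises(s.DegenerateFitError):
            s.compute_cbc(fit)

    def test_narrow_singularity_dropped_with_count(self):
        # slope crosses zero once: a wiggle, not a degenerate fit
        poly = Polynomial([5.0, 0.0, 0.01])  # p' = 0.02a, zero at a=0
        fit = CurveFit(
            poly=poly, degree=2, fit_window=(4.5, 6.5), amount_window=(-0.5, 1.0),
            n_points=50, rmse_ph=0.0, direction=Direction.ALKALIZE, monotone=False,
        )
        curve = s.compute_cbc(fit)
        assert 0 < curve.n_dropped <= 0.10 * 512
        assert np.all(curve.cbc > 0)

    def test_cbc_positive_and_inside_window(self, pig_acid_record):
        _, curve, _ = s.analyze_record(pig_acid_record)
        assert np.all(curve.cbc > 0)
        lo, hi = curve.fit.fit_window
        assert curve.ph.min() >= lo and curve.ph.max() <= hi

    def test_water_alkalization_yields_nonmonotone_flagged_fit(self):
        """Zero-buffer water has a step-like titration curve; the degree-6
        polynomial cannot track it monotonically and the fit is flagged."""
        rec = s.simulate_titration(s.BufferMixture(), s.base_protocol(12.0))
        fit = s.fit_titration_curve(s.select_fit_range(rec))
        assert not fit.monotone
        assert fit.rmse_ph > 0.05


class TestFindPeak:
    def make_curve(self, ph, cbc, direction=Direction.ACIDIFY):
        return CBCCurve(
            amount=np.linspace(0, 1, len(ph)),
            ph=np.asarray(ph, float),
            cbc=np.asarray(cbc, float),
            direction=direction,
            n_dropped=0,
            fit=linear_fit(-1.0),
        )

    def test_quadratic_refinement_recovers_vertex(self):
        ph = np.linspace(4.0, 6.0, 41)
        cbc = 0.2 - (ph - 5.13) ** 2 * 0.05
        peak = s.find_peak(self.make_curve(ph, cbc), (4.5, 5.5))
        assert peak.is_local_max
        assert peak.peak_ph == pytest.approx(5.13, abs=1e-6)
        assert peak.max_cbc == pytest.approx(0.2, abs=1e-8)

    def test_monotone_window_reports_boundary_supremum(self):
        ph = np.linspace(4.0, 6.0, 41)
        cbc = 0.1 + 0.05 * ph
        peak = s.find_peak(self.make_curve(ph, cbc), (4.5, 5.5))
        assert not peak.is_local_max
        assert peak.peak_ph == pytest.approx(5.5, abs=0.05)

    def test_disjoint_window_raises(self):
        ph = np.linspace(4.0, 6.0, 41)
        with pytest.raises(s.CoverageError):
            s.find_peak(self.make_curve(ph, np.full(41, 0.1)), (9.0, 10.0))

    def test_find_peaks_skips_uncovered_windows(self, pig_acid_record):
        _, _, peaks = s.analyze_record(pig_acid_record)
        assert "NH3" not in peaks  # alkaline window unreachable during acidification
        assert {"VFA", "HCO3"} <= set(peaks)


class TestIntegrateCbc:
    def test_constant_cbc_integrates_linearly(self):
        curve = s.compute_cbc(linear_fit(-4.0, intercept=7.0, a_max=1.0))
        # CBC = 0.25 over pH in [3, 7]; integral over one pH unit = 0.25
        assert integrate_cbc(curve, 4.0, 5.0) == pytest.approx(0.25, rel=1e-9)

    def test_integral_equals_fitted_amount_difference(self, pig_acid_record):
        """Area under CBC between two pH values equals the titrant amount the
        fitted curve spends between them."""
        fit, curve, _ = s.analyze_record(pig_acid_record)
        lo, hi = 4.0, 6.5
        area = integrate_cbc(curve, lo, hi)
        order = np.argsort(curve.ph)
        a_at = np.interp([lo, hi], curve.ph[order], curve.amount[order])
        assert area == pytest.approx(abs(a_at[0] - a_at[1]), rel=2e-3)

    def test_bounds_outside_coverage_raise(self, pig_acid_record):
        _, curve, _ = s.analyze_record(pig_acid_record)
        with pytest.raises(s.CoverageError):
            integrate_cbc(curve, 1.0, 2.0)
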