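import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotassay import (
    AbsorbanceRecord,
    CurvePoint,
    DoseResponseCurve,
    SpotMeasurement,
    aggregate_curve,
    blank_correct_extract,
    csc50_derivative,
    csc50_halfmax,
    derivative_curve,
    percent_scavenging,
    sc50_from_absorbance,
)
from spotassay.errors import (
    DegenerateRangeError,
    InsufficientDataError,
    InvalidControlError,
    MissingBlankError,
    UnitError,
)


def colour_curve(points, blank=None, max_response=None, unit="uM"):
    return DoseResponseCurve(
        sample_id="s",
        response_kind="colour_value",
        points=tuple(CurvePoint(c, m, 0.0, 1) for c, m in points),
        blank_response=blank,
        max_response=max_response,
        unit=unit,
    )


def absorbance_curve(points, blank=None):
    return DoseResponseCurve(
        sample_id="s",
        response_kind="absorbance",
        points=tuple(CurvePoint(c, m, 0.0, 1) for c, m in points),
        blank_response=blank,
    )


def spot(conc, value, rep=0, role="reaction", unit="uM"):
    return SpotMeasurement(
        sample_id="s", concentration=conc, replicate=rep, role=role,
        centre=(10.0, 10.0), radius=5.0, colour_value=value, n_pixels=69,
        unit=unit,
    )


def dense_crossing_oracle(concs, means, target, n=200_001):
    """Dense linear resampling of the piecewise-linear mean curve followed by
    an exact solve inside the first dense interval that brackets the target.
    Independent of the production interpolation path."""
    grid = np.linspace(concs[0], concs[-1], n)
    resampled = np.interp(grid, concs, means)
    if resampled[0] == target:
        return float(grid[0])
    for i in range(n - 1):
        lo, hi = resampled[i], resampled[i + 1]
        if hi == target:
            return float(grid[i + 1])
        if (lo - target) * (hi - target) < 0:
            return float(grid[i] + (target - lo) / (hi - lo) * (grid[i + 1] - grid[i]))
    return None


class TestAggregateCurve:
    def test_triplicate_mean_and_sd(self):
        records = [spot(100, v, rep=i) for i, v in enumerate([90, 100, 110])]
        records += [spot(200, v, rep=i) for i, v in enumerate([150, 150, 150])]
        curve = aggregate_curve(records, "colour_value")
        p = curve.points[0]
        assert (p.concentration, p.mean, p.n_replicates) == (100, 100, 3)
        assert p.sd == pytest.approx(statistics.stdev([90, 100, 110]))
        assert p.sd == pytest.approx(10.0)

    def test_single_replicates_zero_sd(self):
        curve = aggregate_curve([spot(10, 50), spot(20, 60)], "colour_value")
        assert all(p.sd == 0.0 and p.n_replicates == 1 for p in curve.points)

    def test_sorted_ascending(self):
        curve = aggregate_curve([spot(200, 80), spot(100, 40)], "colour_value")
        assert curve.concentrations == [100, 200]

    def test_blank_from_reagent_blank(self):
        records = [spot(10, 50), spot(20, 60), spot(0, 30, role="reagent_blank")]
        curve = aggregate_curve(records, "colour_value")
        assert curve.blank_response == 30.0

    def test_insufficient_concentrations(self):
        with pytest.raises(InsufficientDataError):
            aggregate_curve([spot(10, 50), spot(10, 51, rep=1)], "colour_value")

    def test_mixed_units_rejected(self):
        with pytest.raises(UnitError):
            aggregate_curve(
                [spot(10, 50, unit="uM"), spot(20, 60, unit="ug/mL")], "colour_value"
            )

    def test_absorbance_records(self):
        recs = [
            AbsorbanceRecord("s", 10, 0, "reaction", 0.8),
            AbsorbanceRecord("s", 20, 0, "reaction", 0.4),
            AbsorbanceRecord("s", 0, 0, "reagent_blank", 1.0),
        ]
        curve = aggregate_curve(recs, "absorbance")
        assert curve.means == [0.8, 0.4]
        assert curve.blank_response == 1.0


class TestBlankCorrectExtract:
    def test_colourless_standard_unchanged(self):
        curve = colour_curve([(10, 50), (20, 60)])
        corrected = blank_correct_extract(curve, 220.0, plate_baseline=220.0)
        assert corrected.means == curve.means

    def test_constant_self_colour(self):
        curve = colour_curve([(10, 50), (20, 60)])
        corrected = blank_correct_extract(curve, 230.0, plate_baseline=220.0)
        assert corrected.means == [40, 50]
        assert "extract_blank_corrected" in corrected.notes

    def test_per_level_blanks(self):
        curve = colour_curve([(10, 50), (20, 60), (40, 80)])
        blanks = {10: 222.0, 20: 225.0, 40: 230.0}
        corrected = blank_correct_extract(curve, blanks, plate_baseline=220.0)
        # hand-computed: response - (blank - baseline)
        assert corrected.means == [50 - 2, 60 - 5, 80 - 10]

    def test_missing_level_blank(self):
        curve = colour_curve([(10, 50), (20, 60)])
        with pytest.raises(MissingBlankError):
            blank_correct_extract(curve, {10: 222.0}, plate_baseline=220.0)


class TestPercentScavenging:
    @pytest.mark.parametrize(
        "control,sample,expected",
        [(1.0, 0.5, 50.0), (1.0, 1.0, 0.0), (0.8, 0.0, 100.0)],
    )
    def test_examples(self, control, sample, expected):
        assert percent_scavenging(control, sample) == expected

    def test_invalid_control(self):
        with pytest.raises(InvalidControlError):
            percent_scavenging(0.0, 0.5)

    @given(
        a0=st.floats(min_value=0.01, max_value=10),
        p=st.floats(min_value=0, max_value=100),
    )
    def test_inverse_identity(self, a0, p):
        assert percent_scavenging(a0, a0 * (1 - p / 100)) == pytest.approx(p, abs=1e-9)


class TestSc50FromAbsorbance:
    def test_interpolated_example(self):
        curve = absorbance_curve([(50, 0.6), (100, 0.2)], blank=1.0)
        result = sc50_from_absorbance(curve)
        # oracle: 50 + ((0.6-0.5)/(0.6-0.2))*50
        assert result.value == pytest.approx(62.5)
        assert result.status == "ok"
        assert result.bracketing_points == ((50, 0.6), (100, 0.2))

    def test_exact_hit(self):
        curve = absorbance_curve([(40, 0.8), (80, 0.5), (160, 0.1)], blank=1.0)
        result = sc50_from_absorbance(curve)
        assert result.value == 80
        assert result.status == "ok"

    def test_censored_high(self):
        curve = absorbance_curve([(10, 0.9), (20, 0.8)], blank=1.0)
        result = sc50_from_absorbance(curve)
        assert result.status == "censored_high"
        assert result.value is None

    def test_censored_low(self):
        curve = absorbance_curve([(10, 0.3), (20, 0.1)], blank=1.0)
        result = sc50_from_absorbance(curve)
        assert result.status == "censored_low"
        assert result.value is None

    def test_missing_blank(self):
        curve = absorbance_curve([(10, 0.9), (20, 0.2)])
        with pytest.raises(MissingBlankError):
            sc50_from_absorbance(curve)

    def test_non_monotone_warning_first_crossing(self):
        curve = absorbance_curve([(10, 0.9), (20, 0.4), (40, 0.6), (80, 0.1)], blank=1.0)
        result = sc50_from_absorbance(curve)
        assert result.status == "non_monotone_warning"
        # first crossing from low concentration: between 10 and 20
        assert 10 <= result.value <= 20

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            concs = np.cumsum(rng.uniform(5, 50, size=n)).tolist()
            means = np.sort(rng.uniform(0, 1, size=n))[::-1].tolist()
            curve = absorbance_curve(list(zip(concs, means)), blank=1.0)
            result = sc50_from_absorbance(curve)
            oracle = dense_crossing_oracle(concs, means, 0.5)
            if result.value is None:
                assert oracle is None
            else:
                assert result.value == pytest.approx(oracle, abs=1e-6)

    def test_status_ok_value_in_range(self):
        curve = absorbance_curve([(50, 0.6), (100, 0.2)], blank=1.0)
        result = sc50_from_absorbance(curve)
        assert 50 <= result.value <= 100


class TestCsc50Halfmax:
    def test_linear_curve_midpoint(self):
        curve = colour_curve([(0, 0), (100, 50), (200, 100)], blank=0, max_response=100)
        assert csc50_halfmax(curve).value == pytest.approx(100)

    def test_interpolated_example(self):
        curve = colour_curve(
            [(25, 5), (50, 20), (100, 60), (200, 95), (400, 100)],
            blank=0, max_response=100,
        )
        result = csc50_halfmax(curve)
        # oracle: 50 + ((50-20)/(60-20))*(100-50)
        assert result.value == pytest.approx(87.5)
        assert result.status == "ok"

    def test_flat_curve_censored_high(self):
        curve = colour_curve([(10, 5), (20, 5), (40, 5)], blank=5, max_response=100)
        result = csc50_halfmax(curve)
        assert result.status == "censored_high"
        assert result.value is None

    def test_degenerate_range(self):
        curve = colour_curve([(10, 5), (20, 6)], blank=50, max_response=40)
        with pytest.raises(DegenerateRangeError):
            csc50_halfmax(curve)

    def test_defaults_flagged(self):
        curve = colour_curve([(10, 10), (20, 60), (40, 100)])
        result = csc50_halfmax(curve)
        assert "blank_defaulted_to_min_observed" in result.diagnostics
        assert "max_defaulted_to_max_observed" in result.diagnostics


class TestDerivativeCurve:
    def test_finite_difference_oracle(self):
        curve = colour_curve([(0, 0), (100, 10), (200, 60), (300, 70)])
        deriv = derivative_curve(curve)
        assert deriv.points == ((50, 0.1), (150, 0.5), (250, 0.1))

    def test_linear_curve_constant_slope(self):
        curve = colour_curve([(0, 0), (50, 25), (100, 50), (150, 75)])
        deriv = derivative_curve(curve)
        slopes = {s for _, s in deriv.points}
        assert slopes == {0.5}

    def test_two_points_rejected(self):
        curve = colour_curve([(0, 0), (100, 10)])
        with pytest.raises(InsufficientDataError):
            derivative_curve(curve)

    def test_length_contract(self, model):
        curve = colour_curve([(c, c * 0.1) for c in (10, 20, 40, 80, 160)])
        assert len(derivative_curve(curve).points) == 4


class TestCsc50Derivative:
    def test_argmax_example(self):
        curve = colour_curve([(0, 0), (100, 10), (200, 60), (300, 70)])
        result = csc50_derivative(curve)
        assert result.value == 150
        assert result.bracketing_points == ((100, 10), (200, 60))

    def test_dense_logistic_agrees_with_halfmax(self):
        # symmetric logistic on a dense uniform grid
        c50, step = 100.0, 2.0
        concs = np.arange(0, 200 + step, step)
        f = 1 / (1 + np.exp(-0.08 * (concs - c50)))
        pts = list(zip(concs.tolist(), (100 * f).tolist()))
        curve = colour_curve(pts, blank=100 / (1 + np.exp(0.08 * c50)), max_response=100 * f[-1])
        hm = csc50_halfmax(curve).value
        dv = csc50_derivative(curve).value
        assert abs(hm - dv) <= step

    def test_tie_goes_to_lowest(self):
        curve = colour_curve([(0, 0), (10, 10), (20, 20), (30, 25)])
        result = csc50_derivative(curve)
        assert result.value == 5  # first of the two equal maximal slopes
        assert "tie_broken_to_lowest_concentration" in result.diagnostics

    def test_propagates_insufficient_data(self):
        curve = colour_curve([(0, 0), (100, 50)])
        with pytest.raises(InsufficientDataError):
            csc50_derivative(curve)


class TestInterpolationProperties:
    def test_random_monotone_curves_match_dense_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            concs = np.cumsum(rng.uniform(5, 50, size=n))
            means = np.sort(rng.uniform(0, 100, size=n))
            blank, maxr = 0.0, 100.0
            curve = colour_curve(
                list(zip(concs.tolist(), means.tolist())), blank=blank, max_response=maxr
            )
            result = csc50_halfmax(curve)
            oracle = dense_crossing_oracle(concs.tolist(), means.tolist(), 50.0)
            if result.value is None:
                assert oracle is None
            else:
                assert result.value == pytest.approx(oracle, abs=1e-6)

    def test_shift_scaling_property(self):
        # resampling the same response shape at scaled concentrations scales
        # both CSC50 estimates by the same factor
        base = [(10, 5), (20, 20), (40, 60), (80, 95), (160, 100)]
        for k in (2.0, 5.0):
            c1 = colour_curve(base, blank=0, max_response=100)
            c2 = colour_curve([(k * c, m) for c, m in base], blank=0, max_response=100)
            assert csc50_halfmax(c2).value == pytest.approx(k * csc50_halfmax(c1).value)
            assert csc50_derivative(c2).value == pytest.approx(
                k * csc50_derivative(c1).value
            )

    def test_censoring_soundness(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            concs = np.cumsum(rng.uniform(1, 30, size=n)).tolist()
            means = rng.uniform(0, 100, size=n).tolist()
            curve = colour_curve(list(zip(concs, means)), blank=0, max_response=100)
            result = csc50_halfmax(curve)
            if result.value is not None:
                assert concs[0] <= result.value <= concs[-1]
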