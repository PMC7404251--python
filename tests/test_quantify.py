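"""Calibration fitting, linear range, LLOQ, back-calculation, fold-changes."""

import math

import numpy as np
import pytest

from mrmquant.quantify import (
    CalibrationCurve,
    QuantResult,
    calibrate,
    fit_calibration,
    fold_change,
    linear_range,
    lloq,
    quantify_area,
    strain_report,
    supernatant_conc,
)
from mrmquant.synthetic import SampleRow, SampleSheet

LEVELS = [0.0033, 0.0165, 0.033, 0.165, 0.33, 1.65, 3.3]


def test_exact_line_fit():
    curve = fit_calibration([1, 2, 3], [2, 4, 6], target="t")
    assert curve.slope == pytest.approx(2.0, abs=1e-12)
    assert curve.intercept == pytest.approx(0.0, abs=1e-9)
    assert curve.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fit_validation():
    with pytest.raises(ValueError, match="3 distinct"):
        fit_calibration([1, 2], [2, 4])
    with pytest.raises(ValueError, match="identical"):
        fit_calibration([1, 2, 3], [5, 5, 5])


def test_weighted_fit_tracks_low_end():
    # heteroscedastic data: big absolute error at the top level only
    levels = [0.01, 0.1, 1.0, 10.0]
    areas = [10.0, 100.0, 1000.0, 10500.0]
    unweighted = fit_calibration(levels, areas)
    weighted = fit_calibration(levels, areas, weighting="1/x")
    # the 1/x fit should back-calculate the lowest standard more accurately
    back_u = (10.0 - unweighted.intercept) / unweighted.slope
    back_w = (10.0 - weighted.intercept) / weighted.slope
    assert abs(back_w - 0.01) < abs(back_u - 0.01)
    with pytest.raises(ValueError):
        fit_calibration(levels, areas, weighting="1/x2")


def test_linear_range_full_when_linear():
    areas = [1e5 * lv for lv in LEVELS]
    assert linear_range(LEVELS, areas) == (0.0033, 3.3)


def test_linear_range_trims_saturated_top():
    areas = [1e5 * min(lv, 1.65) for lv in LEVELS]
    low, high = linear_range(LEVELS, areas)
    assert (low, high) == (0.0033, 1.65)


def test_linear_range_errors_when_nothing_linear():
    areas = [1.0] * len(LEVELS)  # fully saturated everywhere
    with pytest.raises(ValueError, match="no linear range"):
        linear_range(LEVELS, areas)
    with pytest.raises(ValueError, match="distinct"):
        linear_range([1, 1, 2], [1, 1, 2])


def test_lloq_noiseless_is_lowest_level():
    reps = {lv: [1e5 * lv] * 3 for lv in LEVELS}
    assert lloq(reps) == 0.0033


def test_lloq_moves_up_when_bottom_cv_fails():
    rng = np.random.default_rng(0)
    reps = {lv: list(1e5 * lv + rng.normal(0, 1, 3)) for lv in LEVELS}
    # bottom level: mean right but 25 % CV
    reps[0.0033] = [330 * (1 + f) for f in (-0.25, 0.0, 0.25)]
    assert lloq(reps, cv_max=0.20) == 0.0165


def test_lloq_none_when_no_level_qualifies():
    # constant areas: back-calculation is wildly inaccurate at every level
    reps = {lv: [500.0, 510.0] for lv in LEVELS[:4]}
    assert lloq(reps) is None


def test_calibrate_composes_range_and_lloq():
    rng = np.random.default_rng(1)
    reps = {
        lv: list(1e5 * min(lv, 1.65) * (1 + rng.normal(0, 0.01, 3)))
        for lv in LEVELS
    }
    curve = calibrate(reps, target="GseBp", weighting="1/x")
    assert curve.linear_range[1] == 1.65
    assert curve.lloq == 0.0033
    assert curve.slope == pytest.approx(1e5, rel=0.03)
    assert curve.r_squared > 0.99


def test_quantify_area_inverse_identity():
    curve = CalibrationCurve("t", 1e5, 250.0, 1.0, (0.0033, 3.3), 0.0033)
    for conc in (0.01, 0.5, 3.0):
        back, flags = quantify_area(curve, curve.predict_area(conc))
        assert back == pytest.approx(conc, abs=1e-12)
        assert not flags


def test_quantify_area_flags():
    curve = CalibrationCurve("t", 1e5, 0.0, 1.0, (0.0033, 3.3), 0.0033)
    conc, flags = quantify_area(curve, 100.0)  # 0.001 ug/mL
    assert flags == {"below_lloq"}
    conc, flags = quantify_area(curve, -50.0)
    assert conc == 0.0 and "below_lloq" in flags
    conc, flags = quantify_area(curve, 5e5)
    assert flags == {"above_linear_range"}
    with pytest.raises(ValueError):
        CalibrationCurve("t", -1.0, 0.0, 1.0, (0.0033, 3.3), 0.0033)


@pytest.mark.parametrize(
    "vial, total, vial_total, expected",
    [
        (6.0, 4.5, 16.5, 1.636),
        (0.005, 1.2, 16.5, 0.00036),
        (0.0, 7.7, 16.5, 0.0),
    ],
)
def test_supernatant_conc_examples(vial, total, vial_total, expected):
    assert supernatant_conc(vial, total, vial_total) == pytest.approx(expected, abs=5e-4)


def test_supernatant_conc_homogeneity():
    base = supernatant_conc(2.0, 3.0, 16.5)
    assert supernatant_conc(4.0, 3.0, 16.5) == pytest.approx(2 * base)
    assert supernatant_conc(2.0, 6.0, 16.5) == pytest.approx(2 * base)
    with pytest.raises(ValueError):
        supernatant_conc(1.0, 1.0, 0.0)


@pytest.mark.parametrize(
    "a, b, expected",
    [(0.06, 0.005, 12.0), (1.5, 0.03, 50.0), (0.7, 0.7, 1.0)],
)
def test_fold_change_values(a, b, expected):
    assert fold_change(a, b) == pytest.approx(expected, rel=1e-12)


def test_fold_change_zero_denominator():
    assert math.isinf(fold_change(0.5, 0.0))
    assert math.isnan(fold_change(0.0, 0.0))
    with pytest.raises(ValueError):
        fold_change(-1.0, 1.0)


def _sheet_and_results():
    sheet = SampleSheet(
        (
            SampleRow("m-", "MRB046", False, 1.3, {"AprBp": 0.064}),
            SampleRow("m+", "MRB046", True, 1.8, {"AprBp": 0.278}),
            SampleRow("at1", "AT1", False, 0.32, {"AprBp": 0.0}),
        )
    )
    results = [
        QuantResult("m-", "AprBp", 6400.0, 0.064, 0.005, frozenset()),
        QuantResult("m+", "AprBp", 27800.0, 0.278, 0.030, frozenset()),
        QuantResult("at1", "AprBp", 0.0, 0.0, 0.0, frozenset({"not_detected"})),
    ]
    return sheet, results


def test_strain_report_induction_fold():
    sheet, results = _sheet_and_results()
    report = strain_report(results, sheet)
    ind = report.fold_changes[report.fold_changes["kind"] == "induction"]
    assert len(ind) == 1
    assert ind["fold"].iloc[0] == pytest.approx(6.0, rel=1e-9)


def test_strain_report_not_computable_reference_ratio():
    sheet, results = _sheet_and_results()
    report = strain_report(results, sheet, reference_strains={"AprBp": "AT1"})
    vs = report.fold_changes[report.fold_changes["kind"] == "vs_reference"]
    assert math.isinf(vs["fold"].iloc[0])  # nonzero strain over zero control
    assert "not computable" in report.render()


def test_strain_report_lists_missing_samples():
    sheet, results = _sheet_and_results()
    report = strain_report(results[:2], sheet)
    assert report.missing == (("at1", "AprBp"),)


def test_strain_report_single_sample():
    sheet = SampleSheet((SampleRow("s", "X", False, 1.0, {"AprBp": 0.1}),))
    results = [QuantResult("s", "AprBp", 1e4, 0.1, 0.006, frozenset())]
    report = strain_report(results, sheet)
    assert len(report.samples) == 1
    assert len(report.fold_changes) == 0
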