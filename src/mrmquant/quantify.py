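"""Calibration curves, LLOQ, concentration back-calculation and fold-changes.

The quantification model is the standard bioanalytical one: the quantifier
transition's peak area responds linearly to analyte concentration,
``area = slope * conc + intercept``, over a linear range whose upper end is
found by iteratively dropping the highest calibration level until the fit is
acceptably linear, and whose lower end (the LLOQ) is the lowest level still
back-calculating accurately (within +-20 % of nominal) and precisely
(replicate CV <= 20 %). Measured areas invert through the curve to the
concentration in the measurement vial; the concentration in the culture
supernatant follows by rescaling the target's mass fraction of the loaded
total protein:

    sn_conc = vial_conc * total_protein_sn / vial_total_conc

where ``vial_total_conc`` is the total-protein concentration at which every
sample is presented to the instrument (all samples are prepared from the
same amount of loaded total protein, so it is one constant per study).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import Transition
from .peaks import detect_peptide, integrate_peak
from .reference_data import QUANTIFIER_PEPTIDES, VIAL_TOTAL_CONC
from .synthetic import ChromatogramTrace, SampleSheet, target_of


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted calibration line with its validated working range."""

    target: str
    slope: float  # area per (ug/mL)
    intercept: float  # area
    r_squared: float
    linear_range: tuple[float, float]  # (low, high) ug/mL
    lloq: float  # ug/mL
    weighting: str = "none"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        low, high = self.linear_range
        if not (low <= self.lloq <= high):
            raise ValueError("LLOQ must lie inside the linear range")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared outside [0, 1]")

    def predict_area(self, conc: float) -> float:
        return self.slope * conc + self.intercept


def _r_squared(x: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> float:
    resid = y - (slope * x + intercept)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        return 1.0
    return 1.0 - float(np.sum(resid**2)) / sstot


def _fit_line(
    levels: np.ndarray, areas: np.ndarray, weighting: str
) -> tuple[float, float, float]:
    if weighting == "none":
        slope, intercept = np.polyfit(levels, areas, 1)
    elif weighting == "1/x":
        # np.polyfit weights multiply the residuals, so w = sqrt(1/x)
        slope, intercept = np.polyfit(levels, areas, 1, w=1.0 / np.sqrt(levels))
    else:
        raise ValueError(f"weighting must be 'none' or '1/x', got {weighting!r}")
    return float(slope), float(intercept), _r_squared(levels, areas, slope, intercept)


def fit_calibration(
    levels: Sequence[float],
    areas: Sequence[float],
    weighting: str = "none",
    target: str = "",
    linear_range: tuple[float, float] | None = None,
    lloq_value: float | None = None,
) -> CalibrationCurve:
    """Least-squares calibration line over levels inside ``linear_range``.

    ``levels``/``areas`` are parallel (replicates appear as repeated
    levels). When no range is given the full span of the data is used; the
    reported r-squared refers to the fitted points.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.shape != y.shape:
        raise ValueError("levels and areas must have equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("calibration needs >= 3 distinct levels")
    if np.all(y == y[0]):
        raise ValueError("all areas identical; no calibration response")
    if linear_range is None:
        linear_range = (float(x.min()), float(x.max()))
    low, high = linear_range
    keep = (x >= low) & (x <= high)
    slope, intercept, r2 = _fit_line(x[keep], y[keep], weighting)
    return CalibrationCurve(
        target=target,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        linear_range=(low, high),
        lloq=low if lloq_value is None else lloq_value,
        weighting=weighting,
    )


def linear_range(
    levels: Sequence[float],
    areas: Sequence[float],
    r2_min: float = 0.99,
    weighting: str = "none",
) -> tuple[float, float]:
    """Find the linear range by trimming saturated top levels.

    Iteratively drops the highest level while the fit's r-squared is below
    ``r2_min``; errors out if fewer than three levels would remain. The low
    end is the lowest level (LLOQ refinement is a separate criterion).
    """
    order = np.argsort(np.asarray(levels, dtype=float))
    x = np.asarray(levels, dtype=float)[order]
    y = np.asarray(areas, dtype=float)[order]
    if len(np.unique(x)) != len(x):
        raise ValueError("linear_range expects distinct levels (mean replicates first)")
    while True:
        if len(x) < 3:
            raise ValueError(
                f"no linear range: fewer than 3 levels reach r2 >= {r2_min}"
            )
        if np.all(y == y[0]):  # flat response (fully saturated) -> keep trimming
            r2 = -math.inf
        else:
            _, _, r2 = _fit_line(x, y, weighting)
        if r2 >= r2_min:
            return float(x[0]), float(x[-1])
        x, y = x[:-1], y[:-1]


def lloq(
    replicate_areas: Mapping[float, Sequence[float]],
    accuracy_tol: float = 0.20,
    cv_max: float = 0.20,
    weighting: str = "none",
) -> float | None:
    """Lowest level quantifiable with acceptable accuracy and precision.

    ``replicate_areas`` maps calibration level -> replicate areas (levels
    already restricted to the linear range). A provisional curve is fitted
    on the level means; the LLOQ is the lowest level whose back-calculated
    mean concentration is within ``accuracy_tol`` of nominal and whose
    replicate CV is at most ``cv_max``. Returns None when no level
    qualifies (the caller flags the curve).
    """
    levels = sorted(replicate_areas)
    if len(levels) < 3:
        raise ValueError("lloq needs >= 3 levels")
    low_levels = levels[:2]
    if all(len(replicate_areas[lv]) < 2 for lv in low_levels):
        raise ValueError("lloq needs >= 2 replicates at the low levels")
    means = np.array([np.mean(replicate_areas[lv]) for lv in levels])
    slope, intercept, _ = _fit_line(np.asarray(levels, dtype=float), means, weighting)
    for lv in levels:
        areas = np.asarray(replicate_areas[lv], dtype=float)
        back = (areas.mean() - intercept) / slope
        accurate = abs(back - lv) <= accuracy_tol * lv
        mean = areas.mean()
        if len(areas) >= 2 and mean > 0:
            cv = float(areas.std(ddof=1)) / mean
        else:
            cv = 0.0 if len(areas) < 2 else math.inf
        if accurate and cv <= cv_max:
            return float(lv)
    return None


def calibrate(
    replicate_areas: Mapping[float, Sequence[float]],
    target: str = "",
    weighting: str = "none",
    r2_min: float = 0.99,
    accuracy_tol: float = 0.20,
    cv_max: float = 0.20,
) -> CalibrationCurve:
    """Full calibration workflow: linear range, LLOQ, final fit."""
    levels = sorted(replicate_areas)
    means = [float(np.mean(replicate_areas[lv])) for lv in levels]
    low, high = linear_range(levels, means, r2_min, weighting)
    retained = {lv: replicate_areas[lv] for lv in levels if low <= lv <= high}
    q = lloq(retained, accuracy_tol, cv_max, weighting)
    flags: tuple[str, ...] = ()
    if q is None:
        q = low
        flags = ("no_level_meets_lloq_criteria",)
    flat_levels = [lv for lv in retained for _ in retained[lv]]
    flat_areas = [a for lv in retained for a in retained[lv]]
    curve = fit_calibration(
        flat_levels, flat_areas, weighting, target, linear_range=(q, high), lloq_value=q
    )
    if flags:
        curve = CalibrationCurve(
            curve.target, curve.slope, curve.intercept, curve.r_squared,
            curve.linear_range, curve.lloq, curve.weighting, flags,
        )
    return curve


# ---------------------------------------------------------------------------
# back-calculation


@dataclass(frozen=True)
class QuantResult:
    """Back-calculated concentrations for one target in one sample."""

    sample_id: str
    target: str
    area: float
    vial_conc: float  # ug/mL in the measurement vial
    sn_conc: float | None  # ug/mL in the supernatant (needs total protein)
    flags: frozenset[str] = frozenset()


def quantify_area(curve: CalibrationCurve, area: float) -> tuple[float, frozenset[str]]:
    """Invert the calibration line: area -> vial concentration with flags."""
    conc = (area - curve.intercept) / curve.slope
    flags: set[str] = set()
    if conc < 0:
        conc = 0.0
        flags.add("below_lloq")
    elif conc < curve.lloq:
        flags.add("below_lloq")
    if conc > curve.linear_range[1]:
        flags.add("above_linear_range")
    return float(conc), frozenset(flags)


def supernatant_conc(
    vial_conc: float, total_protein_sn: float, vial_total_conc: float
) -> float:
    """Rescale a vial concentration to the culture supernatant.

    The target's mass fraction of loaded total protein
    (``vial_conc / vial_total_conc``) times the supernatant's total-protein
    concentration. Homogeneous of degree 1 in both numerator arguments.
    """
    if vial_conc < 0 or total_protein_sn < 0:
        raise ValueError("concentrations must be >= 0")
    if vial_total_conc <= 0:
        raise ValueError("vial_total_conc must be positive")
    return vial_conc * total_protein_sn / vial_total_conc


def fold_change(conc_a: float, conc_b: float) -> float:
    """Ratio conc_a / conc_b.

    Returns ``inf`` when the denominator is zero with a nonzero numerator
    (rendered as "not computable" in reports) and ``nan`` when both are
    zero.
    """
    if conc_a < 0 or conc_b < 0:
        raise ValueError("concentrations must be >= 0")
    if conc_b == 0:
        return math.nan if conc_a == 0 else math.inf
    return conc_a / conc_b


# ---------------------------------------------------------------------------
# study-level orchestration


def calibration_areas(
    traces: Sequence[ChromatogramTrace],
    rt_window: tuple[float, float],
    smooth_window: int = 7,
    smooth_order: int = 2,
) -> dict[float, list[float]]:
    """Integrate a simulated/measured calibration series into level -> areas.

    Levels are parsed from the ``cal_<level>_r<rep>`` sample ids written by
    the calibration simulator.
    """
    out: dict[float, list[float]] = {}
    for tr in traces:
        if not tr.sample_id.startswith("cal_"):
            raise ValueError(f"not a calibration trace: {tr.sample_id!r}")
        level = float(tr.sample_id.split("_")[1])
        res = integrate_peak(tr, rt_window, smooth_window, smooth_order)
        out.setdefault(level, []).append(res.area)
    return out


def quantify_study(
    traces: Sequence[ChromatogramTrace],
    assay: Sequence[Transition],
    curves: Mapping[str, CalibrationCurve],
    sheet: SampleSheet,
    vial_total_conc: float = VIAL_TOTAL_CONC,
    quantifier_peptides: Mapping[str, str] | None = None,
    rt_halfwidth: float = 0.25,
    sn_min: float = 3.0,
    rt_tolerance: float = 0.1,
) -> list[QuantResult]:
    """Turn study traces into per-sample target concentrations.

    For each sample and target: the target's quantifier peptide must be
    *detected* (all transitions co-eluting at adequate S/N); the quantifier
    transition's area then inverts through the target's calibration curve,
    and the vial concentration is rescaled to the supernatant using the
    sample's total-protein concentration.
    """
    quantifier_peptides = dict(QUANTIFIER_PEPTIDES if quantifier_peptides is None else quantifier_peptides)
    by_key: dict[tuple[str, str, str], ChromatogramTrace] = {
        (tr.sample_id, *tr.transition_key): tr for tr in traces
    }
    quant_transition = {}
    rt_window = {}
    for t in assay:
        tgt = target_of(t)
        if t.quantifier and t.peptide.sequence == quantifier_peptides.get(tgt):
            quant_transition[tgt] = t
            center = t.retention_time if t.retention_time is not None else 0.0
            rt_window[tgt] = (center - rt_halfwidth, center + rt_halfwidth)

    results = []
    for sample in sheet:
        for tgt in sample.vial_conc:
            qt = quant_transition.get(tgt)
            if qt is None:
                raise ValueError(f"no quantifier transition for target {tgt!r}")
            pep = qt.peptide.sequence
            pep_traces = [
                by_key[(sample.sample_id, pep, t.product.label)]
                for t in assay
                if t.peptide.sequence == pep
                and (sample.sample_id, pep, t.product.label) in by_key
            ]
            if not pep_traces:
                raise ValueError(
                    f"no traces for sample {sample.sample_id!r} peptide {pep!r}"
                )
            report = detect_peptide(
                pep_traces, rt_window[tgt], sn_min=sn_min, rt_tolerance=rt_tolerance
            )
            if not report.detected:
                results.append(
                    QuantResult(
                        sample.sample_id, tgt, area=0.0, vial_conc=0.0, sn_conc=0.0,
                        flags=frozenset({"not_detected"}),
                    )
                )
                continue
            area = float(
                report.transitions.set_index("product_ion").loc[
                    qt.product.label, "area"
                ]
            )
            vial, flags = quantify_area(curves[tgt], area)
            vial *= sample.dilution_factor
            sn = supernatant_conc(vial, sample.total_protein_sn, vial_total_conc)
            results.append(
                QuantResult(sample.sample_id, tgt, area, vial, sn, flags)
            )
    return results


# ---------------------------------------------------------------------------
# strain report


def _fmt_fold(value: float) -> str:
    if math.isinf(value) or math.isnan(value):
        return "not computable"
    return f"{value:.2f}"


@dataclass(frozen=True)
class StrainReport:
    """Tabular study summary: concentrations plus fold-changes."""

    samples: pd.DataFrame
    fold_changes: pd.DataFrame
    missing: tuple[tuple[str, str], ...] = ()

    def render(self) -> str:
        lines = ["Per-sample quantification:"]
        lines.append(self.samples.to_string(index=False))
        lines.append("")
        lines.append("Fold-changes:")
        if len(self.fold_changes):
            shown = self.fold_changes.copy()
            shown["fold"] = shown["fold"].map(_fmt_fold)
            lines.append(shown.to_string(index=False))
        if self.missing:
            lines.append("")
            lines.append("Missing sample/target pairs: " + ", ".join(
                f"{s}:{t}" for s, t in self.missing
            ))
        return "\n".join(lines)


def strain_report(
    results: Sequence[QuantResult],
    sheet: SampleSheet,
    reference_strains: Mapping[str, str] | None = None,
) -> StrainReport:
    """Summarise a study per strain and inducer state.

    Induction fold-changes compare induced vs uninduced supernatant
    concentration per strain and target; cross-strain ratios compare each
    strain against the per-target reference strain (matched inducer state
    preferred, induced if available). Samples present in the sheet but
    missing from the results are listed, not dropped silently.
    """
    by_key = {(r.sample_id, r.target): r for r in results}
    rows = []
    missing = []
    for sample in sheet:
        for tgt in sample.vial_conc:
            r = by_key.get((sample.sample_id, tgt))
            if r is None:
                missing.append((sample.sample_id, tgt))
                continue
            rows.append(
                {
                    "strain": sample.strain,
                    "induced": sample.induced,
                    "target": tgt,
                    "total_protein_sn": sample.total_protein_sn,
                    "area": r.area,
                    "vial_conc": r.vial_conc,
                    "sn_conc": r.sn_conc,
                    "flags": ";".join(sorted(r.flags)),
                }
            )
    samples_df = pd.DataFrame(rows)

    folds = []
    if len(samples_df):
        by_state = samples_df.set_index(["strain", "target", "induced"])["sn_conc"]

        def _get(strain: str, tgt: str, induced: bool) -> float | None:
            try:
                return float(by_state.loc[(strain, tgt, induced)])
            except KeyError:
                return None

        for (strain, tgt), grp in samples_df.groupby(["strain", "target"], sort=False):
            plus, minus = _get(strain, tgt, True), _get(strain, tgt, False)
            if plus is not None and minus is not None:
                folds.append(
                    {
                        "kind": "induction",
                        "target": tgt,
                        "strain": strain,
                        "reference": strain,
                        "fold": fold_change(plus, minus),
                    }
                )
        if reference_strains:
            for tgt, ref in reference_strains.items():
                sub = samples_df[samples_df["target"] == tgt]
                for strain in sub["strain"].unique():
                    if strain == ref:
                        continue
                    for induced in (True, False):
                        a, b = _get(strain, tgt, induced), _get(ref, tgt, induced)
                        if a is None or b is None:
                            continue
                        folds.append(
                            {
                                "kind": "vs_reference",
                                "target": tgt,
                                "strain": f"{strain}{'+' if induced else '-'}",
                                "reference": f"{ref}{'+' if induced else '-'}",
                                "fold": fold_change(a, b),
                            }
                        )
    folds_df = pd.DataFrame(
        folds, columns=["kind", "target", "strain", "reference", "fold"]
    )
    return StrainReport(samples_df, folds_df, tuple(missing))
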