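"""Chromatographic peak integration and peptide-level detection.

Quantification in MRM is peak-area based: for each transition the trace is
smoothed, the apex located inside an expected retention-time window, peak
boundaries found where the smoothed signal returns to the baseline estimate,
and the area integrated above baseline. A peptide counts as *detected* in a
sample when every one of its transitions shows adequate signal-to-noise and
all apexes co-elute — co-elution of confirmatory transitions is what
separates the analyte from an interfering isobar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .synthetic import ChromatogramTrace


@dataclass(frozen=True)
class PeakResult:
    """Integration result for one transition in one sample."""

    apex_rt: float  # minutes
    area: float  # intensity * minutes, baseline-subtracted
    height: float  # counts above baseline at apex
    signal_to_noise: float
    boundaries: tuple[float, float]  # minutes
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.area < 0 or self.signal_to_noise < 0:
            raise ValueError("area and S/N must be >= 0")
        if not (self.boundaries[0] < self.apex_rt < self.boundaries[1]):
            raise ValueError("boundaries must bracket the apex")


def _robust_sd(values: np.ndarray) -> float:
    if len(values) == 0:
        return 0.0
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def integrate_peak(
    trace: ChromatogramTrace,
    rt_window: tuple[float, float],
    smooth_window: int = 7,
    smooth_order: int = 2,
) -> PeakResult:
    """Integrate the largest peak inside ``rt_window``.

    Baseline is the median intensity outside the window (robust to one
    interference peak elsewhere); noise is the scaled median absolute
    deviation of the off-window residuals. Boundaries are searched outward
    from the apex until the smoothed trace returns to the baseline estimate;
    the area is the trapezoidal integral of the raw signal above baseline
    between them.
    """
    lo, hi = rt_window
    times, raw = trace.times, trace.intensities
    if lo >= hi:
        raise ValueError("rt_window must satisfy min < max")
    if lo < times[0] or hi > times[-1]:
        raise ValueError(
            f"rt_window {rt_window} outside trace range "
            f"({times[0]:.3f}, {times[-1]:.3f})"
        )
    in_window = (times >= lo) & (times <= hi)
    if in_window.sum() < smooth_window:
        raise ValueError("rt_window contains too few points")
    off_window = ~in_window
    if not off_window.any():
        raise ValueError("rt_window covers the whole trace; no baseline region")

    baseline = float(np.median(raw[off_window]))
    noise_sd = _robust_sd(raw[off_window] - baseline)
    smoothed = savgol_filter(raw, smooth_window, smooth_order)

    window_idx = np.flatnonzero(in_window)
    apex_i = window_idx[int(np.argmax(smoothed[window_idx]))]
    flags: list[str] = []
    if apex_i == window_idx[0] or apex_i == window_idx[-1]:
        flags.append("apex_on_window_edge")

    height = float(smoothed[apex_i] - baseline)
    # return-to-baseline threshold: half the noise, but never exactly zero so
    # that a noiseless Gaussian still terminates (at ~1e-6 of its height)
    threshold = baseline + max(0.5 * noise_sd, 1e-6 * max(height, 1.0))
    left = apex_i
    while left > 0 and smoothed[left] > threshold:
        left -= 1
    right = apex_i
    while right < len(times) - 1 and smoothed[right] > threshold:
        right += 1
    # keep the invariant start < apex < end even for flat traces
    left = min(left, apex_i - 1) if apex_i > 0 else 0
    right = max(right, apex_i + 1) if apex_i < len(times) - 1 else len(times) - 1

    area = float(np.trapezoid(raw[left : right + 1] - baseline, times[left : right + 1]))
    area = max(area, 0.0)
    if noise_sd > 0:
        sn = max(height, 0.0) / noise_sd
    else:
        # noiseless trace: infinite S/N for any real peak, zero for float dust
        sn = float("inf") if height > 1e-9 * max(1.0, abs(baseline)) else 0.0
    return PeakResult(
        apex_rt=float(times[apex_i]),
        area=area,
        height=height,
        signal_to_noise=sn,
        boundaries=(float(times[left]), float(times[right])),
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class DetectionReport:
    """Per-transition evidence behind a peptide-level detection call."""

    detected: bool
    peptide: str
    sample_id: str
    transitions: pd.DataFrame  # product_ion, apex_rt, area, sn, passed_sn

    def __bool__(self) -> bool:  # allows `if report:` at call sites
        return self.detected


def detect_peptide(
    traces: Sequence[ChromatogramTrace],
    rt_window: tuple[float, float],
    sn_min: float = 3.0,
    rt_tolerance: float = 0.1,
    smooth_window: int = 7,
    smooth_order: int = 2,
) -> DetectionReport:
    """Decide whether a peptide is present from all its transitions.

    Requires at least two transitions (co-elution is undefined otherwise).
    Detected iff every transition reaches ``sn_min`` and the apexes agree
    within ``rt_tolerance`` minutes.
    """
    traces = list(traces)
    if len(traces) < 2:
        raise ValueError("detect_peptide needs >= 2 transitions of one peptide")
    peptides = {t.transition_key[0] for t in traces}
    if len(peptides) != 1:
        raise ValueError(f"traces span multiple peptides: {sorted(peptides)}")
    samples = {t.sample_id for t in traces}
    if len(samples) != 1:
        raise ValueError(f"traces span multiple samples: {sorted(samples)}")

    rows = []
    results = []
    for tr in traces:
        res = integrate_peak(tr, rt_window, smooth_window, smooth_order)
        results.append(res)
        rows.append(
            {
                "product_ion": tr.transition_key[1],
                "apex_rt": res.apex_rt,
                "area": res.area,
                "sn": res.signal_to_noise,
                "passed_sn": res.signal_to_noise >= sn_min,
            }
        )
    apexes = [r.apex_rt for r in results]
    coeluting = (max(apexes) - min(apexes)) <= rt_tolerance
    detected = coeluting and all(row["passed_sn"] for row in rows)
    return DetectionReport(
        detected=detected,
        peptide=next(iter(peptides)),
        sample_id=next(iter(samples)),
        transitions=pd.DataFrame(rows),
    )


def peak_report(
    traces: Iterable[ChromatogramTrace],
    rt_windows: dict[str, tuple[float, float]],
    sn_min: float = 3.0,
    rt_tolerance: float = 0.1,
    smooth_window: int = 7,
    smooth_order: int = 2,
) -> pd.DataFrame:
    """Integrate many traces and add peptide-level detection calls.

    ``rt_windows`` maps peptide sequence -> (min, max) minutes. Returns one
    row per trace: sample_id, peptide, product_ion, apex_rt, area, sn,
    detected (peptide-level call repeated on each of its transitions).
    """
    grouped: dict[tuple[str, str], list[ChromatogramTrace]] = {}
    order: list[tuple[str, str]] = []
    for tr in traces:
        key = (tr.sample_id, tr.transition_key[0])
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(tr)

    frames = []
    for sample_id, peptide in order:
        group = grouped[(sample_id, peptide)]
        window = rt_windows[peptide]
        if len(group) >= 2:
            report = detect_peptide(
                group, window, sn_min, rt_tolerance, smooth_window, smooth_order
            )
            df = report.transitions.copy()
            df["detected"] = report.detected
        else:  # single-transition peptide: S/N call only, no co-elution
            res = integrate_peak(group[0], window, smooth_window, smooth_order)
            df = pd.DataFrame(
                [
                    {
                        "product_ion": group[0].transition_key[1],
                        "apex_rt": res.apex_rt,
                        "area": res.area,
                        "sn": res.signal_to_noise,
                        "passed_sn": res.signal_to_noise >= sn_min,
                        "detected": res.signal_to_noise >= sn_min,
                    }
                ]
            )
        df.insert(0, "peptide", peptide)
        df.insert(0, "sample_id", sample_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
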