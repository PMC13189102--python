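"""Depolarization-evoked calcium response features from fluorescence traces.

A raw trace F(t) is baseline-normalized to dF/F0 with F0 the mean prestimulus
fluorescence. Stimulus onset t0 is either supplied or detected as the time of
maximal first difference of the cross-ROI mean dF/F0 trace. Per-ROI features
are measured in a 0-20 s poststimulus window: peak dF/F0, baseline-subtracted
AUC (trapezoidal), peak latency, 10-90% rise time (linear interpolation on the
rising segment), and a responder flag (peak strictly exceeding baseline mean
plus three baseline standard deviations). Genotype groups are compared with
two-sided Wilcoxon rank-sum tests, each ROI treated as an independent
observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import StatResult, rank_sum

__all__ = [
    "CalciumFeatures",
    "dff",
    "detect_stimulus_onset",
    "extract_features",
    "classify_responder",
    "compare_groups",
    "features_table",
]

#: default poststimulus response window, seconds
RESPONSE_WINDOW = (0.0, 20.0)
#: baseline ends this long before stimulus onset, seconds
BASELINE_GAP_S = 1.0


@dataclass
class CalciumFeatures:
    peak: float                 # max dF/F0 in the response window
    auc: float                  # baseline-subtracted trapezoidal integral, dF/F0 * s
    latency_s: float            # stimulus onset to peak
    rise_time_s: float          # 10% -> 90% of peak; NaN when peak <= 0
    responder: bool
    baseline_mean: float
    baseline_sd: float
    quality_flag: str = "ok"    # "flat" when the trace never leaves baseline


def dff(f: np.ndarray, times: np.ndarray, baseline_window: tuple[float, float]) -> tuple[np.ndarray, float]:
    """Baseline-normalize a fluorescence trace: returns ((F - F0)/F0, F0).

    F0 is the mean of F over ``baseline_window`` (inclusive, >= 2 frames).
    Raises if F0 <= 0 (trace rejected).
    """
    f = np.asarray(f, dtype=float)
    times = np.asarray(times, dtype=float)
    if f.shape != times.shape:
        raise ValueError("trace and time axis differ in length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    sel = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if sel.sum() < 2:
        raise ValueError("baseline window must contain at least 2 frames")
    f0 = float(f[sel].mean())
    if f0 <= 0:
        raise ValueError(f"non-positive baseline fluorescence F0={f0}; trace rejected")
    return (f - f0) / f0, f0


def detect_stimulus_onset(mean_dff: np.ndarray, times: np.ndarray) -> float:
    """Onset = time of the maximal first difference of the mean dF/F0 trace.

    Ties are broken to the earliest frame; the onset is the time of the frame
    at which the maximal rise lands. A constant trace has no defined onset.
    """
    mean_dff = np.asarray(mean_dff, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(mean_dff) < 3:
        raise ValueError("need at least 3 frames to detect an onset")
    diffs = np.diff(mean_dff)
    if np.ptp(mean_dff) == 0:
        raise ValueError("constant mean trace: onset undefined, supply t0 explicitly")
    top = diffs.max()
    tied = np.flatnonzero(diffs >= top - 1e-9 * max(1.0, abs(top)))
    return float(times[int(tied[0]) + 1])


def _crossing_time(times, values, level, i_end):
    # last upward crossing of `level` at or before index i_end, linearly interpolated
    for i in range(i_end, 0, -1):
        if values[i - 1] <= level <= values[i]:
            if values[i] == values[i - 1]:
                return times[i - 1]
            frac = (level - values[i - 1]) / (values[i] - values[i - 1])
            return times[i - 1] + frac * (times[i] - times[i - 1])
    return times[0] if values[0] >= level else float("nan")


def extract_features(dff_series: np.ndarray, times: np.ndarray, t0: float,
                     window: tuple[float, float] = RESPONSE_WINDOW,
                     baseline_window: tuple[float, float] | None = None) -> CalciumFeatures:
    """Measure peak, AUC, latency, rise time and responder status for one ROI.

    ``window`` is relative to stimulus onset ``t0``. The baseline defaults to
    all frames up to ``t0 - 1 s``. Events outside the window are ignored by
    every feature. An all-baseline (flat) trace reports peak 0, AUC 0 and
    latency 0 with a ``"flat"`` quality flag.
    """
    y = np.asarray(dff_series, dtype=float)
    t = np.asarray(times, dtype=float)
    if baseline_window is None:
        baseline_window = (float(t[0]), t0 - BASELINE_GAP_S)
    base = y[(t >= baseline_window[0]) & (t <= baseline_window[1])]
    if len(base) < 2:
        raise ValueError("baseline window must contain at least 2 frames")
    b_mean, b_sd = float(base.mean()), float(base.std(ddof=1))

    lo, hi = t0 + window[0], t0 + window[1]
    sel = (t >= lo) & (t <= hi)
    if not sel.any():
        raise ValueError("response window lies outside the recording")
    tw, yw = t[sel], y[sel]
    i_peak = int(np.argmax(yw))
    peak = float(yw[i_peak])
    auc = float(np.trapezoid(yw - b_mean, tw))
    flat = np.ptp(y) == 0
    latency = 0.0 if flat else float(tw[i_peak] - t0)
    if peak <= 0:
        rise = float("nan")
    else:
        lvl10 = b_mean + 0.10 * (peak - b_mean)
        lvl90 = b_mean + 0.90 * (peak - b_mean)
        t10 = _crossing_time(tw, yw, lvl10, i_peak)
        t90 = _crossing_time(tw, yw, lvl90, i_peak)
        rise = float(t90 - t10) if np.isfinite(t10) and np.isfinite(t90) else float("nan")
    responder = classify_responder(peak, b_mean, b_sd)
    return CalciumFeatures(peak, auc, latency, rise, responder, b_mean, b_sd,
                           quality_flag="flat" if flat else "ok")


def classify_responder(peak: float, baseline_mean: float, baseline_sd: float) -> bool:
    """Responder iff peak dF/F0 strictly exceeds baseline mean + 3 x baseline SD."""
    return bool(peak > baseline_mean + 3.0 * baseline_sd)


def compare_groups(features_a, features_b, metric: str = "peak") -> StatResult:
    """Two-sided rank-sum comparison of a feature between two genotype groups."""
    get = lambda fs: [getattr(f, metric) if isinstance(f, CalciumFeatures) else f for f in fs]
    return rank_sum(get(features_a), get(features_b))


def features_table(traces: pd.DataFrame, t0: float | None = None,
                   window: tuple[float, float] = RESPONSE_WINDOW) -> pd.DataFrame:
    """Run the full per-ROI feature extraction on a tidy trace table.

    ``traces`` has columns ``roi_id, group, t, f`` (long form). When ``t0`` is
    None it is detected from the cross-ROI mean dF/F0 trace. Returns one row
    per ROI: peak, auc, latency_s, rise_time_s, responder, group.
    """
    wide = traces.pivot_table(index="t", columns="roi_id", values="f", sort=True)
    times = wide.index.to_numpy(dtype=float)
    # provisional baseline (first quarter of the recording) just for onset detection
    prov = (times[0], times[0] + 0.25 * (times[-1] - times[0]))
    dmat = {}
    for roi in wide.columns:
        series, _ = dff(wide[roi].to_numpy(), times, prov)
        dmat[roi] = series
    if t0 is None:
        t0 = detect_stimulus_onset(np.mean(list(dmat.values()), axis=0), times)
    rows = []
    groups = traces.drop_duplicates("roi_id").set_index("roi_id")["group"]
    for roi in wide.columns:
        series, _ = dff(wide[roi].to_numpy(), times, (times[0], t0 - BASELINE_GAP_S))
        fx = extract_features(series, times, t0, window)
        rows.append({"roi_id": roi, "group": groups[roi], "peak": fx.peak,
                     "auc": fx.auc, "latency_s": fx.latency_s,
                     "rise_time_s": fx.rise_time_s, "responder": fx.responder})
    return pd.DataFrame(rows)
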