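"""Simulated depolarization-evoked calcium fluorescence traces.

Each ROI's raw fluorescence is a constant baseline F0 plus one stimulus-locked
transient and Gaussian acquisition noise. The transient kernel is a difference
of exponentials normalized to unit peak,

    k(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / k_max,   t >= 0,

whose maximum sits at t* = tau_r * tau_d / (tau_d - tau_r) * ln(tau_d / tau_r)
after onset -- a closed form the feature extractor can be checked against.
Per-ROI peak amplitudes (in dF/F0 units) are drawn from a normal distribution
truncated at zero, so configured group means are the target means of the
extracted peak dF/F0.

``d7_depolarization_config`` reproduces the study conditions for day-7 neurons: group
mean peak dF/F0 of 1.222 (wild type) versus 1.383 (homozygous mutant) under
KCl depolarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CalciumSimConfig", "TraceSet", "generate_calcium_traces", "d7_depolarization_config", "kernel_peak_time"]


@dataclass
class CalciumSimConfig:
    n_rois: dict[str, int] = field(default_factory=lambda: {"wildtype": 30, "hom_mutant": 30})
    frame_rate_hz: float = 10.0
    duration_s: float = 40.0
    baseline_f0: float = 100.0
    #: per-group mean peak amplitude in dF/F0 units
    amplitude_mean: dict[str, float] = field(default_factory=lambda: {"wildtype": 1.0, "hom_mutant": 1.2})
    amplitude_sd: float = 0.3
    onset_time_s: float = 10.0
    rise_tau_s: float = 0.5
    decay_tau_s: float = 4.0
    noise_sd: float = 1.0  # in raw fluorescence units
    rng_seed: int = 0

    def validate(self):
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("time constants must be positive")
        if self.decay_tau_s <= self.rise_tau_s:
            raise ValueError("decay tau must exceed rise tau (degenerate kernel)")
        if self.amplitude_sd < 0:
            raise ValueError("amplitude SD must be non-negative")
        if set(self.n_rois) != set(self.amplitude_mean):
            raise ValueError("n_rois and amplitude_mean must cover the same groups")


@dataclass
class TraceSet:
    """Simulated raw traces plus the planted per-ROI ground truth."""

    traces: pd.DataFrame      # tidy: roi_id, group, t, f
    times: np.ndarray
    ground_truth: pd.DataFrame  # roi_id, group, true_amplitude, true_onset_s


def kernel_peak_time(rise_tau_s: float, decay_tau_s: float) -> float:
    """Time after onset at which the difference-of-exponentials kernel peaks."""
    tr, td = rise_tau_s, decay_tau_s
    return tr * td / (td - tr) * np.log(td / tr)


def _kernel(t_after_onset: np.ndarray, tr: float, td: float) -> np.ndarray:
    t = np.clip(t_after_onset, 0, None)
    raw = np.exp(-t / td) - np.exp(-t / tr)
    tp = kernel_peak_time(tr, td)
    peak = np.exp(-tp / td) - np.exp(-tp / tr)
    out = raw / peak
    out[t_after_onset < 0] = 0.0
    return out


def generate_calcium_traces(config: CalciumSimConfig) -> TraceSet:
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    times = np.arange(0.0, config.duration_s, 1.0 / config.frame_rate_hz)
    k = _kernel(times - config.onset_time_s, config.rise_tau_s, config.decay_tau_s)
    rows, gt = [], []
    roi = 0
    for group in sorted(config.n_rois):
        for _ in range(config.n_rois[group]):
            amp = -1.0
            while amp < 0:  # truncated-at-zero normal amplitude
                amp = rng.normal(config.amplitude_mean[group], config.amplitude_sd)
                if config.amplitude_sd == 0:
                    amp = max(amp, 0.0)
            f = config.baseline_f0 * (1.0 + amp * k) + rng.normal(0, config.noise_sd, len(times))
            rid = f"roi{roi:04d}"
            rows.append(pd.DataFrame({"roi_id": rid, "group": group, "t": times, "f": f}))
            gt.append({"roi_id": rid, "group": group, "true_amplitude": amp,
                       "true_onset_s": config.onset_time_s})
            roi += 1
    return TraceSet(pd.concat(rows, ignore_index=True), times, pd.DataFrame(gt))


def d7_depolarization_config(n_per_group: int = 40, seed: int = 0) -> CalciumSimConfig:
    """Study conditions for day-7 neurons: wild-type vs homozygous-mutant peaks."""
    return CalciumSimConfig(
        n_rois={"wildtype": n_per_group, "hom_mutant": n_per_group},
        amplitude_mean={"wildtype": 1.222, "hom_mutant": 1.383},
        amplitude_sd=0.25,
        noise_sd=1.0,
        rng_seed=seed,
    )
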