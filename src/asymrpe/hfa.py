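"""Feedback-locked high-frequency activity (HFA) power extraction.

Pipeline, per channel:

1. multitaper time-frequency power in 10 Hz sub-bands centered 70–150 Hz
   with 50 ms windows, sampled on a 25 ms grid;
2. natural-log transform (band power is approximately log-normal);
3. baseline normalization: mean and SD of pre-stimulus log power
   (−0.25 to −0.05 s) computed over bootstrap resamples of trials
   (sampling trials with replacement) and averaged across resamples, then
   used to z-score the feedback-locked log power per sub-band — the
   bootstrap average makes the baseline statistics robust to a few
   outlier trials;
4. sub-bands averaged into a single HFA z-series;
5. optional sliding-window means (50 ms windows stepping 25 ms over
   0–0.6 s post-feedback → 23 windows) for regression modeling.
"""

from __future__ import annotations

import numpy as np
from mne.time_frequency import tfr_array_multitaper

__all__ = [
    "SUBBAND_CENTERS",
    "extract_hfa_power",
    "bootstrap_baseline_normalize",
    "window_average",
    "window_starts",
]

#: 10 Hz sub-band centers spanning the high-frequency band
SUBBAND_CENTERS = np.arange(70.0, 150.1, 10.0)

#: analysis window length / step (s)
WINDOW_S = 0.050
STEP_S = 0.025


def extract_hfa_power(
    data: np.ndarray,
    fs: float,
    times: np.ndarray,
    freqs: np.ndarray | None = None,
    time_bandwidth: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-band log power of trials × time voltage epochs.

    Power at each sub-band center is estimated with DPSS-tapered 50 ms
    windows (``n_cycles = 0.05 * f``) and decimated onto a 25 ms grid.
    Returns ``(log_power, grid_times)`` with log_power shaped
    trials × sub-bands × grid points.
    """
    data = np.atleast_2d(np.asarray(data, float))
    freqs = SUBBAND_CENTERS if freqs is None else np.asarray(freqs, float)
    if data.shape[1] / fs < WINDOW_S:
        raise ValueError("epoch shorter than one analysis window")
    decim = int(round(fs * STEP_S))
    if abs(decim - fs * STEP_S) > 1e-9:
        raise ValueError(f"sampling rate {fs} does not tile the 25 ms grid")
    power = tfr_array_multitaper(
        data[:, None, :], sfreq=fs, freqs=freqs, n_cycles=freqs * WINDOW_S,
        time_bandwidth=time_bandwidth, output="power", decim=decim,
        verbose="error",
    )[:, 0]  # trials x bands x time
    grid = np.asarray(times, float)[::decim]
    return np.log(power), grid


def bootstrap_baseline_normalize(
    feedback_logpow: np.ndarray,
    baseline_logpow: np.ndarray,
    n_boot: int = 500,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Bootstrap-baseline z-scoring, then sub-band averaging.

    Both inputs are trials × sub-bands × time. For each sub-band, ``n_boot``
    resamples of trials (with replacement) each yield a mean and SD of the
    pooled baseline log power; the resample-averaged statistics z-score the
    feedback-locked series, and the sub-band z-series are averaged into one
    HFA series (trials × time).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    if baseline_logpow.size == 0:
        raise ValueError("baseline segment is empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_trials, n_bands, _ = baseline_logpow.shape
    means = np.empty((n_boot, n_bands))
    sds = np.empty((n_boot, n_bands))
    for b in range(n_boot):
        idx = rng.integers(0, n_trials, n_trials)
        sample = baseline_logpow[idx]  # trials x bands x time
        means[b] = sample.mean(axis=(0, 2))
        sds[b] = sample.std(axis=(0, 2))
    mean_bar = means.mean(axis=0)
    sd_bar = sds.mean(axis=0)
    if np.any(sd_bar <= 0):
        raise ValueError("baseline has zero variance in at least one sub-band")
    z = (feedback_logpow - mean_bar[None, :, None]) / sd_bar[None, :, None]
    return z.mean(axis=1)


def window_starts(t_min: float = 0.0, t_max: float = 0.6) -> np.ndarray:
    """Start times of the sliding analysis windows: 50 ms windows stepping
    25 ms whose span fits in [t_min, t_max] — 23 windows for 0–0.6 s."""
    n = int(np.floor((t_max - t_min - WINDOW_S) / STEP_S + 1e-9)) + 1
    return np.round(t_min + np.arange(n) * STEP_S, 6)


def window_average(
    hfa: np.ndarray,
    times: np.ndarray,
    t_min: float = 0.0,
    t_max: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean HFA in each half-open window [start, start + 50 ms).

    ``hfa`` is trials × time on the 25 ms grid; returns (trials × windows,
    window start times). Raises if the grid does not align with the
    requested windows.
    """
    times = np.asarray(times, float)
    starts = window_starts(t_min, t_max)
    out = np.empty((hfa.shape[0], len(starts)))
    for k, s in enumerate(starts):
        mask = (times >= s - 1e-9) & (times < s + WINDOW_S - 1e-9)
        aligned = np.any(np.abs(times - s) < 1e-9)
        if not aligned or mask.sum() != int(round(WINDOW_S / STEP_S)):
            raise ValueError(
                f"time grid misaligned with analysis window at {s:.3f} s"
            )
        out[:, k] = hfa[:, mask].mean(axis=1)
    return out, starts
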