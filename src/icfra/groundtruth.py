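"""Spike-to-fluorescence forward model and juxtacellular ground truth.

A GCaMP6s fluorescence trace is modelled as a linear convolution of the
binned spike count n(t) with a per-spike impulse response ("ramp-decay"
kernel) plus a constant offset::

    F(t) = F0 + (n * g)(t)
    g(t) = F_1AP * t / t_rise            for 0 <= t < t_rise
    g(t) = F_1AP * exp(-(t - t_rise) / tau_decay)   for t >= t_rise

F0 is the minimal fluorescence at zero spike rate, F_1AP the fluorescence
increment per action potential, t_rise the zero-to-peak rise time and
tau_decay the decay time constant.  Spike counts are binned at the imaging
frame interval (114.4 ms), and the kernel is sampled at frame offsets so a
spike contributes from its own frame onward.

Spikes are extracted from juxtacellular voltage (25 kHz) by a moving-average
DC-removal filter (+-1 ms window), blanking of current-injection artifacts
(2 ms before to 3 ms after each injection edge), and simple thresholding
with peak-time spike placement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

__all__ = [
    "KernelParams",
    "SpikeTrain",
    "dc_remove",
    "blank_artifacts",
    "detect_spikes",
    "kernel_value",
    "kernel_samples",
    "predict_fluorescence",
    "fit_kernel",
]


@dataclass(frozen=True)
class KernelParams:
    """Four parameters of the per-spike fluorescence impulse response."""

    f0: float           # minimal fluorescence at zero spike rate (a.u.)
    f_1ap: float        # fluorescence increment per action potential (a.u.)
    t_rise_ms: float    # zero-to-peak rise time (ms)
    tau_decay_ms: float # decay time constant (ms)

    def __post_init__(self):
        if self.f0 < 0:
            raise ValueError("f0 must be >= 0")
        if self.f_1ap <= 0:
            raise ValueError("f_1ap must be > 0")
        if self.t_rise_ms <= 0 or self.tau_decay_ms <= 0:
            raise ValueError("t_rise_ms and tau_decay_ms must be > 0")


@dataclass
class SpikeTrain:
    spike_times_s: np.ndarray
    counts: np.ndarray          # spikes per imaging frame
    frame_interval_s: float
    blank_intervals_s: list[tuple[float, float]]


def kernel_value(params: KernelParams, t_ms) -> np.ndarray:
    """Evaluate g(t) (a.u.) at times in milliseconds; g = 0 for t < 0."""
    t = np.asarray(t_ms, float)
    g = np.zeros_like(t)
    rising = (t >= 0) & (t < params.t_rise_ms)
    g[rising] = params.f_1ap * t[rising] / params.t_rise_ms
    decaying = t >= params.t_rise_ms
    g[decaying] = params.f_1ap * np.exp(
        -(t[decaying] - params.t_rise_ms) / params.tau_decay_ms
    )
    return g


def kernel_samples(
    params: KernelParams, frame_interval_s: float, n_frames: int | None = None
) -> np.ndarray:
    """Kernel sampled at frame offsets g(0), g(dt), g(2*dt), ...

    The length defaults to rise time plus eight decay constants, enough for
    the tail to fall below 3e-4 of the peak.
    """
    dt_ms = frame_interval_s * 1000.0
    if n_frames is None:
        n_frames = int(np.ceil((params.t_rise_ms + 8 * params.tau_decay_ms) / dt_ms)) + 1
    return kernel_value(params, np.arange(n_frames) * dt_ms)


def predict_fluorescence(
    params: KernelParams, counts: np.ndarray, frame_interval_s: float = 0.1144
) -> np.ndarray:
    """F(t) = F0 + (n * g)(t) at frame resolution, same length as ``counts``."""
    counts = np.asarray(counts, float)
    g = kernel_samples(params, frame_interval_s)
    return params.f0 + np.convolve(counts, g)[: len(counts)]


# --------------------------------------------------------------------------
# Juxtacellular preprocessing
# --------------------------------------------------------------------------

def dc_remove(
    voltage: np.ndarray, fs_hz: float = 25000.0, half_window_ms: float = 1.0
) -> np.ndarray:
    """Subtract the local mean within +-half_window_ms at every sample.

    Edges use truncated (shorter) windows.  Removes DC offset and slow
    drift while leaving millisecond-scale action potentials nearly intact.
    """
    half = int(round(half_window_ms * 1e-3 * fs_hz))
    win = 2 * half + 1
    if win < 3:
        raise ValueError("window must span at least 3 samples")
    local_mean = (
        pd.Series(np.asarray(voltage, float))
        .rolling(window=win, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return np.asarray(voltage, float) - local_mean


def blank_artifacts(
    trace: np.ndarray,
    injection_intervals_s: list[tuple[float, float]],
    fs_hz: float = 25000.0,
    pre_ms: float = 2.0,
    post_ms: float = 3.0,
) -> np.ma.MaskedArray:
    """Mask samples around current-injection edges (start and end of each
    injection, from pre_ms before to post_ms after the edge)."""
    trace = np.asarray(trace, float)
    mask = np.zeros(len(trace), bool)
    for start_s, end_s in injection_intervals_s:
        for edge_s in (start_s, end_s):
            lo = int(np.floor((edge_s - pre_ms * 1e-3) * fs_hz))
            hi = int(np.ceil((edge_s + post_ms * 1e-3) * fs_hz))
            mask[max(lo, 0): min(hi, len(trace))] = True
    return np.ma.MaskedArray(trace, mask=mask)


def detect_spikes(
    filtered: np.ndarray,
    threshold: float | None = None,
    fs_hz: float = 25000.0,
    frame_interval_s: float = 0.1144,
    n_frames: int | None = None,
    refractory_ms: float = 1.0,
) -> SpikeTrain:
    """Threshold the filtered voltage and place one spike per supra-threshold
    excursion at its local maximum; peaks closer than the refractory window
    are merged.  Masked (blanked) samples never yield spikes.

    The default threshold is 5x the robust standard deviation of the trace
    (1.4826 x the median absolute deviation); at 25 kHz sampling a laxer
    default would admit thousands of noise crossings per minute.
    """
    arr = np.ma.asarray(filtered, float)
    data = arr.filled(0.0)
    mask = np.ma.getmaskarray(arr)
    if threshold is None:
        valid = arr.compressed() if mask.any() else data
        mad = float(np.median(np.abs(valid - np.median(valid))))
        threshold = 5.0 * 1.4826 * mad
    if threshold <= 0:
        raise ValueError("threshold must be > 0")

    above = (data > threshold) & ~mask
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(data)]
    peaks = np.array(
        [s + int(np.argmax(data[s:e])) for s, e in zip(starts, ends)], dtype=int
    )
    # refractory merge: keep the larger of peaks closer than refractory_ms
    if len(peaks) > 1:
        min_gap = refractory_ms * 1e-3 * fs_hz
        kept = [peaks[0]]
        for p in peaks[1:]:
            if p - kept[-1] < min_gap:
                if data[p] > data[kept[-1]]:
                    kept[-1] = p
            else:
                kept.append(p)
        peaks = np.asarray(kept)
    spike_times_s = peaks / fs_hz

    total_s = len(data) / fs_hz
    if n_frames is None:
        n_frames = int(np.ceil(total_s / frame_interval_s))
    counts = np.bincount(
        np.minimum((spike_times_s / frame_interval_s).astype(int), n_frames - 1),
        minlength=n_frames,
    )
    return SpikeTrain(
        spike_times_s=spike_times_s,
        counts=counts,
        frame_interval_s=frame_interval_s,
        blank_intervals_s=[],
    )


# --------------------------------------------------------------------------
# Model fitting
# --------------------------------------------------------------------------

def fit_kernel(
    counts: np.ndarray,
    fluorescence: np.ndarray,
    frame_interval_s: float = 0.1144,
    bounds: dict | None = None,
    seed: int = 0,
    maxiter: int = 60,
    popsize: int = 10,
) -> tuple[KernelParams, float]:
    """Fit the 4-parameter kernel model to an observed fluorescence trace.

    A seeded differential-evolution global search (population ~ popsize*4,
    with a final local polish) minimizes the squared error between
    F0 + n*g and the observation.  Returns the parameters and the variance
    explained, 1 - RSS/var(F).

    Default bounds: F0 in [0, max F]; F_1AP in (0, range F]; t_rise in
    [50, 3000] ms; tau_decay in [100, 10000] ms.
    """
    counts = np.asarray(counts, float)
    fluo = np.asarray(fluorescence, float)
    if len(counts) != len(fluo):
        raise ValueError("counts and fluorescence must be aligned")
    if counts.sum() < 1:
        raise ValueError("need at least one spike to constrain the kernel")

    fmax = float(np.max(fluo))
    frange = float(np.ptp(fluo))
    b = {
        "f0": (0.0, max(fmax, 1e-9)),
        "f_1ap": (1e-6, max(frange, 1e-6)),
        "t_rise_ms": (50.0, 3000.0),
        "tau_decay_ms": (100.0, 10000.0),
    }
    if bounds:
        b.update(bounds)

    def loss(theta):
        params = KernelParams(*theta)
        pred = predict_fluorescence(params, counts, frame_interval_s)
        return float(np.sum((pred - fluo) ** 2))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = differential_evolution(
            loss,
            [b["f0"], b["f_1ap"], b["t_rise_ms"], b["tau_decay_ms"]],
            seed=seed,
            maxiter=maxiter,
            popsize=popsize,
            tol=1e-10,
            polish=True,
        )
    params = KernelParams(*res.x)
    rss = res.fun
    tss = float(np.sum((fluo - fluo.mean()) ** 2))
    variance_explained = 1.0 - rss / tss if tss > 0 else np.nan
    return params, variance_explained
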