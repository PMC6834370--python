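"""Movement-correlated activity detection.

Facial movement is quantified as the RMS pixel-intensity change between
consecutive video frames in a rectangle at the whisker pad, resampled to
the imaging clock.  A cell is flagged as movement-responsive when, during
the spontaneous (tone-free) recording period, its fluorescence correlates
positively with the facial metric (Pearson r > 0.25), its transients show
the ~1 s exponential decay expected of GCaMP6s (ruling out brief image
shifts), and its FRA is not excitatory or offset (ruling out responses to
self-generated sound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import get_logger
from .response import FraResult, fit_decay_kinetics

__all__ = [
    "MovementResult",
    "facial_movement_metric",
    "resample_to_imaging",
    "spontaneous_mask",
    "movement_correlation",
    "detect_transients",
    "kinetics_filter",
    "fra_excludes_movement",
    "flag_movement_cells",
]

logger = get_logger(__name__)


@dataclass
class MovementResult:
    roi_id: str
    r_move: float
    kinetics_ok: bool
    fra_excluded: bool
    flagged: bool


def facial_movement_metric(
    frames: np.ndarray, rect: tuple[int, int, int, int]
) -> np.ndarray:
    """Per-frame RMS of pixel change within a rectangle (y0, y1, x0, x1);
    the first frame has no predecessor and gets 0."""
    frames = np.asarray(frames, float)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 video frames")
    y0, y1, x0, x1 = rect
    patch = frames[:, y0:y1, x0:x1]
    if patch.shape[1] == 0 or patch.shape[2] == 0:
        raise ValueError("empty rectangle")
    diff = np.diff(patch, axis=0)
    rms = np.sqrt((diff ** 2).mean(axis=(1, 2)))
    return np.r_[0.0, rms]


def resample_to_imaging(
    metric: np.ndarray,
    video_rate_hz: float,
    n_imaging_frames: int,
    frame_interval_s: float,
) -> np.ndarray:
    """Linear interpolation of the video-rate metric onto imaging frames."""
    t_video = np.arange(len(metric)) / video_rate_hz
    t_img = np.arange(n_imaging_frames) * frame_interval_s
    return np.interp(t_img, t_video, np.asarray(metric, float))


def spontaneous_mask(
    n_frames: int,
    stim_onset_frames: np.ndarray,
    duration_s: float,
    frame_interval_s: float,
    guard_after_s: float = 3.0,
    guard_before_s: float = 1.0,
) -> np.ndarray:
    """Frames at least guard_after_s after every tone offset and
    guard_before_s before every onset (the spontaneous recording period)."""
    mask = np.ones(n_frames, bool)
    g_pre = int(np.ceil(guard_before_s / frame_interval_s))
    g_post = int(np.ceil((duration_s + guard_after_s) / frame_interval_s))
    for onset in np.asarray(stim_onset_frames, int):
        mask[max(onset - g_pre, 0): min(onset + g_post, n_frames)] = False
    return mask


def movement_correlation(
    trace: np.ndarray,
    facial_rms: np.ndarray,
    mask: np.ndarray | None = None,
    frame_interval_s: float = 0.1144,
    min_duration_s: float = 60.0,
) -> tuple[float, bool]:
    """Pearson r between fluorescence and the facial metric over the
    spontaneous mask.  Returns (r, valid); constant inputs give (0, False).
    """
    trace = np.asarray(trace, float)
    facial = np.asarray(facial_rms, float)
    if mask is None:
        mask = np.ones(len(trace), bool)
    a, b = trace[mask], facial[mask]
    if len(a) * frame_interval_s < min_duration_s:
        raise ValueError("spontaneous period must cover at least 60 s")
    if a.std() == 0 or b.std() == 0:
        logger.warning("constant input; movement correlation undefined, set to 0")
        return 0.0, False
    r = float(np.corrcoef(a, b)[0, 1])
    return r, True


def detect_transients(
    trace: np.ndarray, n_mad: float = 4.0, n_mad_low: float = 1.0
) -> np.ndarray:
    """Peak frames of threshold-crossing fluorescence transients.

    Hysteresis detection: an event is a contiguous span above the lower
    threshold (median + n_mad_low robust s.d.) that also reaches the upper
    threshold (median + n_mad robust s.d., with 1.4826 x MAD as the robust
    s.d.).  One peak - the span maximum - is reported per event, so noise
    re-crossings during a slow decay do not fragment one transient into
    many."""
    trace = np.asarray(trace, float)
    med = np.median(trace)
    sd = 1.4826 * np.median(np.abs(trace - med))
    hi = trace > med + n_mad * sd
    lo = trace > med + n_mad_low * sd
    d = np.diff(lo.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if lo[0]:
        starts = np.r_[0, starts]
    if lo[-1]:
        ends = np.r_[ends, len(trace)]
    peaks = [
        s + int(np.argmax(trace[s:e]))
        for s, e in zip(starts, ends)
        if hi[s:e].any()
    ]
    return np.asarray(peaks, int)


def kinetics_filter(
    trace: np.ndarray,
    frame_interval_s: float = 0.1144,
    tau_bounds_ms: tuple[float, float] = (300.0, 3000.0),
    fit_window_s: float = 4.0,
    n_mad: float = 4.0,
) -> tuple[bool, float]:
    """Check that detected transients decay with roughly GCaMP6s kinetics.

    Fits a single-exponential decay to the falling phase after each
    transient peak; the cell passes iff the median time constant lies in
    ``tau_bounds_ms`` (operationalizing "about 1 s").  One-frame artifacts
    (image shifts) fit far below the lower bound; slow drift far above the
    upper.  Returns (kinetics_ok, median tau in ms; nan without
    transients).
    """
    trace = np.asarray(trace, float)
    peaks = detect_transients(trace, n_mad=n_mad)
    if len(peaks) == 0:
        return False, float("nan")
    n_fit = int(round(fit_window_s / frame_interval_s))
    taus = []
    for k, p in enumerate(peaks):
        end = min(p + n_fit, len(trace))
        if k + 1 < len(peaks):
            end = min(end, peaks[k + 1])
        seg = trace[p:end]
        if len(seg) < 4:
            # too brief to show any decay: treat as artifact-like
            taus.append(0.0)
            continue
        t = np.arange(len(seg)) * frame_interval_s
        tau = fit_decay_kinetics(t, seg)
        if np.isfinite(tau):
            taus.append(tau)
    if not taus:
        return False, float("nan")
    med = float(np.median(taus))
    return tau_bounds_ms[0] <= med <= tau_bounds_ms[1], med


def fra_excludes_movement(fra) -> bool:
    """True when the FRA bars a movement call (excitatory or offset
    component, which self-generated sound could explain).

    Accepts an FraResult (mixed FRAs are inspected for an excitatory or
    offset component) or a plain FRA label, where "mixed" is excluded
    conservatively because its components are unknown.
    """
    if isinstance(fra, FraResult):
        if fra.fra_class in ("onset", "sustained", "excitation", "offset"):
            return True
        if fra.fra_class == "mixed":
            comp = set().union(*fra.class_sets) if fra.class_sets else set()
            return bool(comp & {"excitation", "offset"})
        return False
    return str(fra) in ("onset", "sustained", "excitation", "offset", "mixed")


def flag_movement_cells(
    correlations: dict[str, float],
    kinetics: dict[str, bool],
    fra_by_roi: dict,
    r_threshold: float = 0.25,
) -> list[MovementResult]:
    """Combine the three criteria into the final movement-cell call.

    flagged = (r_move > threshold) AND kinetics_ok AND NOT fra_excluded.
    Pure function of its inputs; iteration order does not matter.
    """
    out = []
    for roi_id in sorted(correlations):
        r = correlations[roi_id]
        k_ok = bool(kinetics.get(roi_id, False))
        excl = fra_excludes_movement(fra_by_roi.get(roi_id, "none"))
        out.append(
            MovementResult(
                roi_id=roi_id,
                r_move=float(r),
                kinetics_ok=k_ok,
                fra_excluded=excl,
                flagged=(r > r_threshold) and k_ok and not excl,
            )
        )
    return out
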