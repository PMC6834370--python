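"""Detection and classification of tone-evoked fluorescence responses.

For each ROI and each stimulus in the frequency x intensity grid, the
reliability of the response across repetitions is measured by the *signal
autocorrelation* rho-auto: the average Pearson correlation among the
per-trial fluorescence waveforms (-1 s to +2 s around tone onset),

    rho_auto = 2 / (n (n-1)) * sum_{i<j} rho_ij .

Its significance is assessed against a bootstrap null built from random
trace segments of the same session, followed by Holm-Bonferroni correction
over the 114 stimuli.  Significant stimuli whose responses also resemble a
grid neighbour (signal crosscorrelation rho-cross > 0.12 to any of up to 8
neighbours) are classified as excitatory / inhibitory / offset from window
means of the trial-averaged response, and the ROI-level FRA class is the
class (or classes -> mixed) reached by at least 25% of significant
responses.  Excitatory FRAs are split into onset vs sustained by the onset
time constant of an exponential fit (tau > 1 s -> sustained).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.optimize import curve_fit
from statsmodels.stats.multitest import multipletests

from .core_io import AnalysisConfig, RoiSession, StimulusProtocol, get_logger

__all__ = [
    "TrialSegmentSet",
    "WindowMeans",
    "FraResult",
    "extract_segments",
    "qc_trials",
    "signal_autocorrelation",
    "bootstrap_null",
    "p_value",
    "holm_bonferroni",
    "signal_crosscorrelation",
    "grid_neighbors",
    "gate_for_classification",
    "window_means",
    "classify_stimulus_response",
    "classify_fra",
    "determine_cf",
    "fit_onset_kinetics",
    "fit_decay_kinetics",
    "background_subtract",
    "pixelwise_correlation_map",
    "analyze_roi",
    "analyze_session",
]

logger = get_logger(__name__)


# --------------------------------------------------------------------------
# Trial segments and QC
# --------------------------------------------------------------------------

def _frame(t_s: float, dt: float) -> int:
    """Map a time (s, relative to onset) to a frame offset by floor."""
    return math.floor(t_s / dt + 1e-9)


@dataclass
class TrialSegmentSet:
    """Per-presentation fluorescence segments around tone onset.

    Rows align with the presentation schedule; excluded presentations stay
    in the array (flagged, never dropped) so provenance is preserved.
    """

    segments: np.ndarray        # (n_presentations, T)
    baselines: np.ndarray       # per-presentation mean over the pre window
    excluded: np.ndarray        # bool, True -> not used in analysis
    stim_index: np.ndarray
    pre_frames: int             # frames before onset (onset at column pre_frames)
    frame_interval_s: float
    baseline_mu: float = np.nan
    baseline_sigma: float = np.nan


def extract_segments(
    session: RoiSession, pre_s: float = 1.0, post_s: float = 2.0
) -> TrialSegmentSet:
    """Cut the trace into [-pre_s, +post_s) windows around each onset.

    Window bounds map to frames by floor at the frame interval (half-open),
    so at 114.4 ms the default segment spans frames -9 .. +17 (26 frames).
    Presentations whose window leaves the trace are flagged excluded.
    """
    dt = session.frame_interval_s
    lo = _frame(-pre_s, dt)
    hi = _frame(post_s, dt)
    T = hi - lo
    n = len(session.stim_onset_frames)
    segments = np.zeros((n, T))
    excluded = np.zeros(n, bool)
    for k, onset in enumerate(session.stim_onset_frames):
        a, b = onset + lo, onset + hi
        if a < 0 or b > len(session.trace):
            excluded[k] = True
            continue
        segments[k] = session.trace[a:b]
    pre_frames = -lo
    baselines = segments[:, :pre_frames].mean(axis=1)
    baselines[excluded] = np.nan
    return TrialSegmentSet(
        segments=segments,
        baselines=baselines,
        excluded=excluded,
        stim_index=session.stim_index.copy(),
        pre_frames=pre_frames,
        frame_interval_s=dt,
    )


def qc_trials(segset: TrialSegmentSet, n_sigma: float = 3.0) -> TrialSegmentSet:
    """Exclude trials whose baseline lies outside mu +- 3 sigma of the ROI's
    per-trial baseline distribution (Gaussian fitted as sample mean/s.d.)."""
    b = segset.baselines[~segset.excluded]
    if len(b) < 10:
        raise ValueError("need >= 10 trials for a stable baseline fit")
    mu, sigma = float(np.mean(b)), float(np.std(b))
    segset.baseline_mu, segset.baseline_sigma = mu, sigma
    if sigma == 0:
        logger.warning("baseline sigma is 0; no QC exclusions possible")
        return segset
    with np.errstate(invalid="ignore"):
        out = np.abs(segset.baselines - mu) > n_sigma * sigma
    segset.excluded |= np.nan_to_num(out.astype(float)).astype(bool)
    return segset


# --------------------------------------------------------------------------
# Correlation statistics
# --------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray, warn: bool = False) -> np.ndarray:
    """Z-score each row; constant rows become all-zero (their Pearson pairs
    then contribute 0, the documented degenerate-pair policy)."""
    x = np.asarray(x, float)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    bad = sd[..., 0] == 0
    if warn and np.any(bad):
        logger.warning("constant segment(s): pair correlations treated as 0")
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd
    z[bad] = 0.0
    return z


def signal_autocorrelation(segments: np.ndarray) -> float:
    """Average Pearson correlation over all n(n-1)/2 unordered trial pairs."""
    seg = np.asarray(segments, float)
    n, T = seg.shape
    if n < 2:
        raise ValueError("need at least 2 repetitions")
    z = _standardize_rows(seg, warn=True)
    s = z.sum(axis=0)
    ssq = float((z ** 2).sum())
    return float((s @ s - ssq) / (n * (n - 1) * T))


def signal_crosscorrelation(segments_a: np.ndarray, segments_b: np.ndarray) -> float:
    """Average Pearson correlation over all n x m cross pairs."""
    za = _standardize_rows(np.asarray(segments_a, float))
    zb = _standardize_rows(np.asarray(segments_b, float))
    n, T = za.shape
    m, _ = zb.shape
    if n < 1 or m < 1:
        raise ValueError("both stimuli need at least one trial")
    return float(za.sum(axis=0) @ zb.sum(axis=0) / (n * m * T))


def bootstrap_null(
    trace: np.ndarray, segment_len: int, n: int, B: int = 30000, seed: int = 0
) -> np.ndarray:
    """Null distribution of rho-auto from random session segments.

    Each of the B draws takes n segments starting at independent
    uniform-random frames (overlap allowed, stimulus periods not excluded)
    and computes rho-auto exactly as for observed repetitions.
    """
    trace = np.asarray(trace, float)
    if B < 1000:
        raise ValueError("B must be >= 1000")
    n_starts = len(trace) - segment_len + 1
    if n_starts < 1:
        raise ValueError("segment length exceeds session length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n_starts, size=(B, n))
    windows = np.lib.stride_tricks.sliding_window_view(trace, segment_len)
    z = _standardize_rows(windows[starts])          # (B, n, T)
    s = z.sum(axis=1)                               # (B, T)
    ssq = (z ** 2).sum(axis=(1, 2))
    return ((s * s).sum(axis=1) - ssq) / (n * (n - 1) * segment_len)


def p_value(rho_auto: float, null: np.ndarray) -> float:
    """One-sided bootstrap p from the fraction of null draws strictly
    greater than the observed statistic (ties count as not greater).

    The finite-sample estimator (k + 1) / (B + 1) is used: it is a valid
    p-value at any number of draws B (the plain fraction k/B is downward
    biased, which breaks family-wise error control once B is small relative
    to the Holm threshold alpha/m), converges to k/B as B grows, and never
    returns an exact zero - an observation exceeding every null draw
    reports as 1/(B+1), i.e. below 1/B.
    """
    null = np.asarray(null, float)
    k = int((null > rho_auto).sum())
    return float((k + 1) / (len(null) + 1))


def holm_bonferroni(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm significance flags at family-wise level alpha."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


def grid_neighbors(protocol: StimulusProtocol) -> list[np.ndarray]:
    """Flat indices of the up-to-8 grid neighbours (incl. diagonals) of each
    stimulus in the frequency x intensity grid."""
    nf, ni = protocol.n_freqs, protocol.n_intensities
    out = []
    for s in range(nf * ni):
        fi, ii = divmod(s, ni)
        nb = [
            (fi + df) * ni + (ii + di)
            for df in (-1, 0, 1)
            for di in (-1, 0, 1)
            if not (df == 0 and di == 0)
            and 0 <= fi + df < nf
            and 0 <= ii + di < ni
        ]
        out.append(np.asarray(nb, int))
    return out


def gate_for_classification(
    segments_by_stim: list[np.ndarray],
    protocol: StimulusProtocol,
    threshold: float = 0.12,
) -> np.ndarray:
    """A stimulus passes the gate iff its maximum rho-cross against its grid
    neighbours exceeds the threshold (FRA continuity check)."""
    # Sum of standardized trials per stimulus makes every pairwise block mean
    # a single dot product.
    sums, counts = [], []
    T = None
    for seg in segments_by_stim:
        if seg is None or len(seg) == 0:
            sums.append(None)
            counts.append(0)
            continue
        z = _standardize_rows(seg)
        T = z.shape[1]
        sums.append(z.sum(axis=0))
        counts.append(len(z))
    included = np.zeros(len(segments_by_stim), bool)
    for s, nbs in enumerate(grid_neighbors(protocol)):
        if counts[s] == 0:
            continue
        best = -np.inf
        for u in nbs:
            if u >= len(counts) or counts[u] == 0:
                continue
            r = float(sums[s] @ sums[u] / (counts[s] * counts[u] * T))
            best = max(best, r)
        included[s] = best > threshold
    return included


# --------------------------------------------------------------------------
# Response windows and classification
# --------------------------------------------------------------------------

@dataclass
class WindowMeans:
    """Means of the trial-averaged response in the five analysis windows
    (baseline -1-0 s re onset; onset 0-500 ms and steady 500-1000 ms re
    onset; offset 0-500 ms and off-late 500-1000 ms re tone offset), plus
    the baseline dispersion used by the 2 x s.d. criteria."""

    f_baseline: float
    f_onset: float
    f_steady: float
    f_offset: float
    f_offlate: float
    baseline_sd: float


def window_means(
    segments: np.ndarray,
    baselines: np.ndarray,
    pre_frames: int,
    frame_interval_s: float,
    duration_s: float = 1.0,
    baseline_sd_mode: str = "trials",
) -> WindowMeans:
    """Window means of the trial-averaged segment of one stimulus.

    Windows are half-open [start, end) in seconds, mapped to frames by
    floor; at 114.4 ms this makes 500 ms spans of 4 frames and the 1 s tone
    8 frames.  ``baseline_sd_mode`` picks the dispersion: s.d. across the
    per-trial baseline means ("trials", default) or across baseline-window
    frames of the average ("frames").
    """
    dt = frame_interval_s
    avg = np.asarray(segments, float).mean(axis=0)

    def wmean(a_s, b_s):
        sl = slice(pre_frames + _frame(a_s, dt), pre_frames + _frame(b_s, dt))
        return float(avg[sl].mean())

    if baseline_sd_mode == "trials":
        sd = float(np.std(np.asarray(baselines, float)))
    elif baseline_sd_mode == "frames":
        sd = float(np.std(avg[:pre_frames]))
    else:
        raise ValueError("baseline_sd_mode must be 'trials' or 'frames'")
    return WindowMeans(
        f_baseline=wmean(-1.0, 0.0),
        f_onset=wmean(0.0, 0.5),
        f_steady=wmean(0.5, 1.0),
        f_offset=wmean(duration_s, duration_s + 0.5),
        f_offlate=wmean(duration_s + 0.5, duration_s + 1.0),
        baseline_sd=sd,
    )


def classify_stimulus_response(w: WindowMeans) -> frozenset[str]:
    """Non-exclusive excitation / inhibition / offset call for one stimulus.

    Excitation: onset or steady rises more than 2 s.d. above baseline.
    Inhibition: steady or offset falls more than 2 s.d. below baseline.
    Offset: depends on the other calls - after excitation, the off-late
    window must exceed the offset window; after inhibition additionally the
    off-late level must exceed baseline (rebound); otherwise a rise of
    either post-tone window above the steady level suffices.
    """
    sd = w.baseline_sd
    if sd == 0:
        logger.warning("zero baseline s.d.; response unclassifiable")
        return frozenset()
    classes = set()
    exc = (w.f_onset - w.f_baseline > 2 * sd) or (w.f_steady - w.f_baseline > 2 * sd)
    inh = (w.f_steady - w.f_baseline < -2 * sd) or (w.f_offset - w.f_baseline < -2 * sd)
    if exc:
        classes.add("excitation")
    if inh:
        classes.add("inhibition")
    if exc:
        off = w.f_offlate - w.f_offset > 2 * sd
    elif inh:
        off = (w.f_offlate - w.f_offset > 2 * sd) and (w.f_offlate > w.f_baseline)
    else:
        off = (w.f_offset - w.f_steady > 2 * sd) or (w.f_offlate - w.f_steady > 2 * sd)
    if off:
        classes.add("offset")
    return frozenset(classes)


def classify_fra(
    class_sets: list[frozenset[str]], class_fraction: float = 0.25
) -> tuple[str, float]:
    """ROI-level FRA class from the per-stimulus classes of its significant
    (and gate-passing) responses.

    Returns (class, dominant fraction); class is "excitation",
    "inhibition", "offset", "mixed" or "none".  A class must cover at least
    ``class_fraction`` of the responses to name the FRA; two or more
    qualifying classes give "mixed".  Order of stimuli is irrelevant.
    """
    n = len(class_sets)
    if n == 0:
        return "none", 0.0
    fractions = {
        c: sum(c in s for s in class_sets) / n
        for c in ("excitation", "inhibition", "offset")
    }
    winners = [c for c, f in fractions.items() if f >= class_fraction]
    dominant = max(fractions.values())
    if not winners:
        return "none", dominant
    if len(winners) > 1:
        return "mixed", dominant
    return winners[0], fractions[winners[0]]


def determine_cf(
    significant: np.ndarray, protocol: StimulusProtocol
) -> float:
    """Characteristic frequency: at the lowest intensity evoking any
    significant response, the significant frequency - or the geometric mean
    when several frequencies are significant at that intensity."""
    sig = np.asarray(significant, bool).reshape(
        protocol.n_freqs, protocol.n_intensities
    )
    order = np.argsort(np.asarray(protocol.intensities_db))
    for ii in order:
        freqs = np.asarray(protocol.frequencies_khz)[sig[:, ii]]
        if len(freqs):
            return float(np.exp(np.mean(np.log(freqs))))
    return float("nan")


# --------------------------------------------------------------------------
# Kinetics
# --------------------------------------------------------------------------

def _multistart_fit(f, t, y, p0_list, bounds):
    best, best_err = None, np.inf
    for p0 in p0_list:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=5000)
            err = float(np.sum((f(t, *popt) - y) ** 2))
            if err < best_err:
                best, best_err = popt, err
        except (RuntimeError, ValueError):
            continue
    return best


def fit_onset_kinetics(
    t_s: np.ndarray, response: np.ndarray, sustained_tau_s: float = 1.0
) -> tuple[float, str]:
    """Fit A (1 - exp(-t/tau)) over the 0-1 s onset period of the mean
    baseline-subtracted excitatory response.

    Returns (tau in ms, "onset" or "sustained"); tau above the sustained
    threshold (1 s) designates the response sustained.  A failed fit
    returns (nan, "excitation") so the caller can flag it.
    """
    t = np.asarray(t_s, float)
    y = np.asarray(response, float)
    sel = (t >= 0) & (t < 1.0)
    t, y = t[sel], y[sel]

    def f(t, a, tau):
        return a * (1.0 - np.exp(-t / tau))

    amp = max(float(np.max(y)), 1e-9)
    p0s = [(amp, tau0) for tau0 in (0.1, 0.3, 1.0, 3.0)]
    popt = _multistart_fit(f, t, y, p0s, ([0.0, 1e-3], [np.inf, 60.0]))
    if popt is None:
        return float("nan"), "excitation"
    tau = float(popt[1])
    return tau * 1000.0, ("sustained" if tau > sustained_tau_s else "onset")


def fit_decay_kinetics(t_s: np.ndarray, response: np.ndarray) -> float:
    """Single-exponential decay time constant (ms) fitted over the decay
    window (0.5-4 s re tone offset): y = A exp(-t/tau) + C."""
    t = np.asarray(t_s, float)
    y = np.asarray(response, float)
    if len(t) < 4:
        return float("nan")
    t0 = t[0]

    def f(t, a, tau, c):
        return a * np.exp(-(t - t0) / tau) + c

    amp = float(y[0] - y[-1])
    p0s = [(amp, tau0, float(y[-1])) for tau0 in (0.3, 1.0, 3.0)]
    popt = _multistart_fit(
        f, t, y, p0s, ([-np.inf, 1e-3, -np.inf], [np.inf, 60.0, np.inf])
    )
    if popt is None:
        return float("nan")
    return float(popt[1]) * 1000.0


# --------------------------------------------------------------------------
# Pixel-level utilities
# --------------------------------------------------------------------------

def background_subtract(
    pixel_stack: np.ndarray,
    roi_mask: np.ndarray,
    all_masks: np.ndarray | None = None,
    annulus_um: float = 2.0,
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """ROI trace minus local background.

    Background is the mean over a contour of width ``annulus_um`` around
    the ROI (morphological dilation minus the ROI), excluding any pixel
    directly belonging to another ROI.  If the exclusions empty the
    annulus, the frame median over non-ROI pixels is used instead (logged).
    """
    stack = np.asarray(pixel_stack, float)
    roi = np.asarray(roi_mask, bool)
    n_iter = max(int(round(annulus_um / pixel_size_um)), 1)
    annulus = binary_dilation(roi, iterations=n_iter) & ~roi
    if all_masks is not None:
        others = np.asarray(all_masks, bool).any(axis=0) & ~roi
        annulus &= ~others
    roi_trace = stack[:, roi].mean(axis=1)
    if annulus.sum() == 0:
        logger.warning(
            "empty annulus after exclusions; falling back to frame-median background"
        )
        non_roi = ~roi if all_masks is None else ~np.asarray(all_masks, bool).any(axis=0)
        background = np.median(stack[:, non_roi], axis=1)
    else:
        background = stack[:, annulus].mean(axis=1)
    return roi_trace - background


def pixelwise_correlation_map(
    pixel_stack: np.ndarray, soma_trace: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every pixel's time series against the soma trace.

    Returns (r map, validity mask); constant pixels get r = 0 and False in
    the mask.
    """
    stack = np.asarray(pixel_stack, float)
    T = stack.shape[0]
    flat = stack.reshape(T, -1).T          # (n_pix, T)
    sd = flat.std(axis=1)
    valid = sd > 0
    z_pix = _standardize_rows(flat)
    z_soma = _standardize_rows(np.asarray(soma_trace, float)[None, :])[0]
    r = z_pix @ z_soma / T
    r[~valid] = 0.0
    shape = stack.shape[1:]
    return r.reshape(shape), valid.reshape(shape)


# --------------------------------------------------------------------------
# Per-ROI pipeline
# --------------------------------------------------------------------------

@dataclass
class FraResult:
    """Per-stimulus statistics and the ROI-level FRA summary."""

    roi_id: str
    rho_auto: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    included: np.ndarray                 # significant AND rho-cross gate
    class_sets: list = field(repr=False)
    fra_class: str = "none"
    cf_khz: float = np.nan
    tau_onset_ms: float = np.nan
    tau_decay_ms: float = np.nan
    dominant_fraction: float = 0.0
    n_excluded_trials: int = 0
    flags: list = field(default_factory=list)


def _isolated_trial_mask(
    stim_index: np.ndarray, sig_stimuli: np.ndarray
) -> np.ndarray:
    """Trials not immediately preceded or followed (in presentation order)
    by a presentation of a significant stimulus."""
    is_sig = sig_stimuli[stim_index]
    prev_sig = np.r_[False, is_sig[:-1]]
    next_sig = np.r_[is_sig[1:], False]
    return ~prev_sig & ~next_sig


def analyze_roi(
    session: RoiSession,
    protocol: StimulusProtocol,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
) -> FraResult:
    """Run the full detection/classification cascade for one ROI."""
    cfg = cfg or AnalysisConfig()
    dt = session.frame_interval_s
    n_stim = protocol.n_stimuli

    segset = extract_segments(session)
    segset = qc_trials(segset)
    n_excluded = int(segset.excluded.sum())

    by_stim: list[np.ndarray | None] = [None] * n_stim
    trials_of: list[np.ndarray] = [np.empty(0, int)] * n_stim
    for s in range(n_stim):
        idx = np.flatnonzero((segset.stim_index == s) & ~segset.excluded)
        trials_of[s] = idx
        if len(idx):
            by_stim[s] = segset.segments[idx]

    # observed rho-auto per stimulus
    rho = np.full(n_stim, np.nan)
    for s in range(n_stim):
        if by_stim[s] is not None and len(by_stim[s]) >= 2:
            rho[s] = signal_autocorrelation(by_stim[s])

    # bootstrap null, shared across stimuli with equal rep counts
    T = segset.segments.shape[1]
    pvals = np.ones(n_stim)
    reps = np.array([len(t) for t in trials_of])
    for n in np.unique(reps[reps >= 2]):
        null = bootstrap_null(session.trace, T, int(n), cfg.bootstrap_n, seed)
        for s in np.flatnonzero(reps == n):
            if not np.isnan(rho[s]):
                pvals[s] = p_value(rho[s], null)

    significant = holm_bonferroni(pvals, cfg.alpha)
    gate = gate_for_classification(by_stim, protocol, cfg.rho_cross_threshold)
    included = significant & gate

    class_sets = [frozenset()] * n_stim
    for s in np.flatnonzero(included):
        w = window_means(
            by_stim[s],
            segset.baselines[trials_of[s]],
            segset.pre_frames,
            dt,
            duration_s=protocol.duration_s,
            baseline_sd_mode=cfg.baseline_sd_mode,
        )
        class_sets[s] = classify_stimulus_response(w)

    classified = [class_sets[s] for s in np.flatnonzero(included)]
    fra_class, dominant = classify_fra(classified, cfg.class_fraction)
    cf = determine_cf(significant, protocol) if significant.any() else np.nan

    result = FraResult(
        roi_id=session.roi_id,
        rho_auto=rho,
        p_values=pvals,
        significant=significant,
        included=included,
        class_sets=class_sets,
        fra_class=fra_class,
        cf_khz=cf,
        dominant_fraction=dominant,
        n_excluded_trials=n_excluded,
    )

    # onset/sustained split and decay kinetics from isolated excitatory trials
    if fra_class == "excitation":
        exc_stims = np.zeros(n_stim, bool)
        for s in np.flatnonzero(included):
            if "excitation" in class_sets[s]:
                exc_stims[s] = True
        iso = _isolated_trial_mask(segset.stim_index, significant)
        take = (
            exc_stims[segset.stim_index] & iso & ~segset.excluded
        )
        if not take.any():
            take = exc_stims[segset.stim_index] & ~segset.excluded
            result.flags.append("kinetics_without_isolation")
        mean_long, t_long = _mean_extended_response(
            session, np.flatnonzero(take), post_s=protocol.duration_s + 4.0
        )
        if mean_long is not None:
            base = mean_long[t_long < 0].mean()
            y = mean_long - base
            tau_on, subclass = fit_onset_kinetics(
                t_long, y, cfg.sustained_tau_ms / 1000.0
            )
            result.tau_onset_ms = tau_on
            result.fra_class = subclass if subclass != "excitation" else "excitation"
            if subclass == "excitation":
                result.flags.append("onset_fit_failed")
            decay_sel = (t_long >= protocol.duration_s + 0.5) & (
                t_long < protocol.duration_s + 4.0
            )
            result.tau_decay_ms = fit_decay_kinetics(t_long[decay_sel], y[decay_sel])
    elif fra_class == "inhibition":
        result.fra_class = "inhibited"
    return result


def _mean_extended_response(
    session: RoiSession, presentation_idx: np.ndarray, pre_s: float = 1.0,
    post_s: float = 5.0,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Average an extended window (for kinetics fits) over given trials."""
    dt = session.frame_interval_s
    lo, hi = _frame(-pre_s, dt), _frame(post_s, dt)
    rows = []
    for k in presentation_idx:
        a = session.stim_onset_frames[k] + lo
        b = session.stim_onset_frames[k] + hi
        if a >= 0 and b <= len(session.trace):
            rows.append(session.trace[a:b])
    if not rows:
        return None, None
    mean = np.mean(rows, axis=0)
    t = (np.arange(lo, hi) + 0.5) * dt
    return mean, t


def analyze_session(
    sessions: list[RoiSession],
    protocol: StimulusProtocol,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[FraResult]]:
    """Run analyze_roi over a list of ROIs; returns a summary table (one row
    per ROI, deposited-table style) and the full per-ROI results."""
    cfg = cfg or AnalysisConfig()
    results, rows = [], []
    ss = np.random.SeedSequence(seed)
    for session, child in zip(sessions, ss.spawn(len(sessions))):
        roi_seed = int(child.generate_state(1)[0] % (2 ** 31))
        res = analyze_roi(session, protocol, cfg, roi_seed)
        results.append(res)
        rows.append(
            {
                "roi_id": res.roi_id,
                "x_um": session.x_um,
                "y_um": session.y_um,
                "depth_um": session.depth_um,
                "area_um2": session.area_um2,
                "genotype": session.genotype,
                "fra_type": _public_class(res.fra_class),
                "cf_khz": res.cf_khz,
                "tau_onset_ms": res.tau_onset_ms,
                "tau_decay_ms": res.tau_decay_ms,
                "n_significant": int(res.significant.sum()),
                "dominant_fraction": res.dominant_fraction,
            }
        )
    return pd.DataFrame(rows), results


def _public_class(fra_class: str) -> str:
    """Map internal per-response class names onto the deposited FRA labels."""
    return {
        "excitation": "onset",      # unsplit excitatory default
        "inhibition": "inhibited",
    }.get(fra_class, fra_class)
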