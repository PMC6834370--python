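"""Synthetic two-photon sessions with known ground truth.

Every downstream stage (response classification, tonotopy fitting, kernel
fitting, movement analysis) is exercised against data from this generator:
neurons with Gaussian log-frequency tuning and class-specific Poisson rate
templates are laid out on a tonotopic map (log10 CF polynomial in the
projected coordinate r = x cos(theta) + y sin(theta)), their spikes are
convolved with the ramp-decay GCaMP6s kernel, and measurement noise, slow
baseline drift and movement-coupled events are added.

Rate templates and tuning shapes are simulator conventions chosen as the
simplest forms that produce the four tone-evoked fluorescence phenotypes
(onset / sustained / inhibited / offset); all of them are configurable.
Default kernel parameters follow published GCaMP6s kinetics (about half a
second rise, about one second decay, single-spike amplitude about a third
of baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core_io import RoiSession, StimulusProtocol
from .groundtruth import KernelParams, kernel_samples

__all__ = [
    "NeuronSpec",
    "SceneConfig",
    "CLASS_RATE_DEFAULTS",
    "PAPER_TONOTOPY_COEFFS",
    "generate_population",
    "simulate_spikes",
    "render_fluorescence",
    "simulate_movement",
    "render_pixel_stack",
    "simulate_session",
    "truth_table",
]

#: Published best-fit tonotopy model: log10(CF in Hz) as a polynomial in the
#: projected distance r (um), axis at 0.875 rad from the medial-lateral axis.
PAPER_TONOTOPY_COEFFS = (6.95, -0.0135, 1.95e-5, -1.11e-8, 2.17e-12)
PAPER_TONOTOPY_THETA_RAD = 0.875

#: Per-class spontaneous and evoked rates (Hz).  Inhibited cells need
#: nonzero spontaneous rate for suppression to be observable.
CLASS_RATE_DEFAULTS: dict[str, dict[str, float]] = {
    "onset": {"spont_rate_hz": 1.0, "evoked_rate_hz": 40.0},
    "sustained": {"spont_rate_hz": 1.0, "evoked_rate_hz": 25.0},
    "inhibited": {"spont_rate_hz": 8.0, "evoked_rate_hz": 0.0},
    "offset": {"spont_rate_hz": 1.0, "evoked_rate_hz": 40.0},
    "mixed": {"spont_rate_hz": 8.0, "evoked_rate_hz": 30.0},
    "none": {"spont_rate_hz": 2.0, "evoked_rate_hz": 0.0},
    "movement": {"spont_rate_hz": 2.0, "evoked_rate_hz": 0.0},
}

TRUE_CLASSES = tuple(CLASS_RATE_DEFAULTS)

#: Onset-class firing adapts with this time constant after tone onset (s).
TAU_ADAPT_S = 0.15
#: Offset-class transient duration after tone end (s).
OFFSET_TRANSIENT_S = 0.3
#: Intensity sigmoid slope (dB per e-fold).
INTENSITY_SLOPE_DB = 5.0

DEFAULT_KERNEL = KernelParams(f0=30.0, f_1ap=10.0, t_rise_ms=480.0, tau_decay_ms=1040.0)


@dataclass
class NeuronSpec:
    roi_id: str
    true_class: str
    true_cf_khz: float
    bandwidth_oct: float = 0.5
    threshold_db: float = 40.0
    spont_rate_hz: float = 1.0
    evoked_rate_hz: float = 40.0
    kernel: KernelParams = DEFAULT_KERNEL
    x_um: float = 0.0
    y_um: float = 0.0
    depth_um: float = 50.0
    area_um2: float = 125.0
    genotype: str = "GP4.3"

    def __post_init__(self):
        if self.true_class not in TRUE_CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.spont_rate_hz < 0:
            raise ValueError("spont_rate_hz must be >= 0")
        if self.bandwidth_oct <= 0:
            raise ValueError("bandwidth_oct must be > 0")
        if self.true_class in ("inhibited", "mixed") and self.spont_rate_hz <= 0:
            raise ValueError("inhibited cells need spont_rate_hz > 0")


@dataclass
class SceneConfig:
    """Ground-truth description of one simulated field of view."""

    n_neurons: int = 100
    class_probabilities: dict[str, float] = field(
        default_factory=lambda: {
            "onset": 0.25,
            "sustained": 0.20,
            "inhibited": 0.20,
            "offset": 0.10,
            "none": 0.25,
        }
    )
    theta_deg: float = np.degrees(PAPER_TONOTOPY_THETA_RAD)
    tonotopy_coeffs: tuple[float, ...] = PAPER_TONOTOPY_COEFFS
    cf_jitter_oct: float = 0.3
    footprint_um: tuple[float, float, float, float] = (200.0, 1000.0, 200.0, 1000.0)
    depth_range_um: tuple[float, float] = (15.0, 155.0)
    noise_sd: float = 0.10          # in units of F0
    drift_amplitude: float = 0.05   # in units of F0
    drift_timescale_s: float = 60.0
    movement_event_rate_hz: float = 0.05
    movement_event_duration_s: float = 1.5
    movement_coupling_hz: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        total = sum(self.class_probabilities.values())
        if not np.isclose(total, 1.0):
            raise ValueError("class_probabilities must sum to 1")
        unknown = set(self.class_probabilities) - set(TRUE_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")


# --------------------------------------------------------------------------
# Population on the tonotopic map
# --------------------------------------------------------------------------

def _log10_cf_hz(coeffs, r_um):
    return np.polynomial.polynomial.polyval(np.asarray(r_um, float), coeffs)


def generate_population(config: SceneConfig) -> list[NeuronSpec]:
    """Sample neurons uniformly over the footprint; CF follows the tonotopy
    polynomial along the projected axis with log-normal jitter."""
    rng = np.random.default_rng(config.seed)
    x0, x1, y0, y1 = config.footprint_um
    x = rng.uniform(x0, x1, config.n_neurons)
    y = rng.uniform(y0, y1, config.n_neurons)
    theta = np.radians(config.theta_deg)
    r = x * np.cos(theta) + y * np.sin(theta)
    log_cf_hz = _log10_cf_hz(config.tonotopy_coeffs, r)
    cf_khz_clean = 10.0 ** log_cf_hz / 1000.0
    if np.any((cf_khz_clean <= 0.5) | (cf_khz_clean > 128.0)):
        raise ValueError(
            "tonotopy polynomial yields CF outside (0.5, 128] kHz over the "
            "footprint; adjust coefficients or footprint"
        )
    # jitter is specified in octaves; the polynomial lives in decades
    eps_dec = rng.normal(0.0, config.cf_jitter_oct * np.log10(2.0), config.n_neurons)
    cf_khz = 10.0 ** (log_cf_hz + eps_dec) / 1000.0

    classes = list(config.class_probabilities)
    probs = np.array([config.class_probabilities[c] for c in classes])
    labels = rng.choice(classes, size=config.n_neurons, p=probs)
    depth = rng.uniform(*config.depth_range_um, config.n_neurons)
    diameter = rng.normal(12.6, 2.0, config.n_neurons).clip(6.0, 25.0)
    area = np.pi * (diameter / 2.0) ** 2
    # per-cell indicator variability around the GCaMP6s defaults
    f_1ap = rng.lognormal(np.log(DEFAULT_KERNEL.f_1ap), 0.2, config.n_neurons)
    tau = rng.lognormal(np.log(DEFAULT_KERNEL.tau_decay_ms), 0.1, config.n_neurons)

    neurons = []
    for i in range(config.n_neurons):
        rates = CLASS_RATE_DEFAULTS[labels[i]]
        neurons.append(
            NeuronSpec(
                roi_id=f"roi{i:04d}",
                true_class=str(labels[i]),
                true_cf_khz=float(cf_khz[i]),
                x_um=float(x[i]),
                y_um=float(y[i]),
                depth_um=float(depth[i]),
                area_um2=float(area[i]),
                spont_rate_hz=rates["spont_rate_hz"],
                evoked_rate_hz=rates["evoked_rate_hz"],
                kernel=replace(
                    DEFAULT_KERNEL, f_1ap=float(f_1ap[i]), tau_decay_ms=float(tau[i])
                ),
            )
        )
    return neurons


# --------------------------------------------------------------------------
# Spiking
# --------------------------------------------------------------------------

def _stimulus_drive(neuron: NeuronSpec, freq_khz, intensity_db) -> np.ndarray:
    """Multiplicative drive in [0, 1): Gaussian tuning in log2 frequency
    times a sigmoid of intensity above threshold."""
    d_oct = np.log2(np.asarray(freq_khz, float) / neuron.true_cf_khz)
    tuning = np.exp(-(d_oct ** 2) / (2.0 * neuron.bandwidth_oct ** 2))
    inten = 1.0 / (
        1.0 + np.exp(-(np.asarray(intensity_db, float) - neuron.threshold_db)
                     / INTENSITY_SLOPE_DB)
    )
    return tuning * inten


def firing_rate(
    neuron: NeuronSpec,
    protocol: StimulusProtocol,
    frame_interval_s: float = 0.1144,
    n_frames: int | None = None,
) -> np.ndarray:
    """Expected firing rate (Hz) per imaging frame over the whole session."""
    onsets = protocol.onset_frames(frame_interval_s)
    dur_f = int(round(protocol.duration_s / frame_interval_s))
    off_f = int(round(OFFSET_TRANSIENT_S / frame_interval_s))
    if n_frames is None:
        n_frames = int(onsets[-1] + (protocol.period_s / frame_interval_s) + 50)
    rate = np.full(n_frames, neuron.spont_rate_hz, float)
    if neuron.true_class in ("none", "movement"):
        return rate
    drive = _stimulus_drive(
        neuron,
        protocol.stimulus_freq_khz(protocol.order),
        protocol.stimulus_intensity_db(protocol.order),
    )
    t_tone = np.arange(dur_f) * frame_interval_s
    adapt = np.exp(-t_tone / TAU_ADAPT_S)
    for onset, d in zip(onsets, drive):
        tone = slice(onset, min(onset + dur_f, n_frames))
        post = slice(min(onset + dur_f, n_frames), min(onset + dur_f + off_f, n_frames))
        if neuron.true_class == "onset":
            rate[tone] += neuron.evoked_rate_hz * d * adapt[: tone.stop - tone.start]
        elif neuron.true_class == "sustained":
            rate[tone] += neuron.evoked_rate_hz * d
        elif neuron.true_class == "inhibited":
            rate[tone] -= neuron.spont_rate_hz * d
        elif neuron.true_class == "offset":
            rate[post] += neuron.evoked_rate_hz * d
        elif neuron.true_class == "mixed":
            # suppression during the tone plus a rebound transient after it
            rate[tone] -= neuron.spont_rate_hz * d
            rate[post] += neuron.evoked_rate_hz * d
    return rate.clip(0.0)


def simulate_spikes(
    neuron: NeuronSpec,
    protocol: StimulusProtocol,
    seed: int,
    frame_interval_s: float = 0.1144,
    n_frames: int | None = None,
) -> np.ndarray:
    """Inhomogeneous Poisson spike counts per imaging frame."""
    rate = firing_rate(neuron, protocol, frame_interval_s, n_frames)
    rng = np.random.default_rng(seed)
    return rng.poisson(rate * frame_interval_s)


# --------------------------------------------------------------------------
# Fluorescence rendering
# --------------------------------------------------------------------------

def render_fluorescence(
    spikes: np.ndarray,
    kernel: KernelParams,
    noise_sd: float = 0.0,
    drift_amplitude: float = 0.0,
    drift_timescale_s: float = 60.0,
    frame_interval_s: float = 0.1144,
    seed: int = 0,
) -> np.ndarray:
    """F0 + spikes convolved with the kernel + slow drift + Gaussian noise.

    ``noise_sd`` and ``drift_amplitude`` are expressed in units of F0.
    Drift is Gaussian-filtered white noise rescaled to the requested
    amplitude (s.d.), with correlation time ``drift_timescale_s``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    spikes = np.asarray(spikes, float)
    n = len(spikes)
    g = kernel_samples(kernel, frame_interval_s)
    trace = kernel.f0 + np.convolve(spikes, g)[:n]
    rng = np.random.default_rng(seed)
    if drift_amplitude > 0:
        sigma_frames = drift_timescale_s / frame_interval_s
        w = gaussian_filter1d(rng.normal(0.0, 1.0, n), sigma_frames, mode="reflect")
        sd = w.std()
        if sd > 0:
            trace = trace + drift_amplitude * kernel.f0 * w / sd
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd * kernel.f0, n)
    return trace


# --------------------------------------------------------------------------
# Movement
# --------------------------------------------------------------------------

def simulate_movement(
    n_frames: int,
    frame_interval_s: float,
    event_rate_hz: float,
    coupled: np.ndarray,
    seed: int,
    event_duration_s: float = 1.5,
    coupling_hz: float = 25.0,
    forbidden_mask: np.ndarray | None = None,
    rms_baseline: float = 0.5,
    rms_gain: float = 2.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Movement events, the facial-RMS readout and coupled extra spiking.

    Events are Poisson in time with fixed duration; ``facial_rms`` is a
    baseline with additive elevation plus positive noise during events.
    Neurons with ``coupled[i]`` True fire extra Poisson spikes at
    ``coupling_hz`` during each event.  When ``forbidden_mask`` marks tone
    periods, events overlapping them are redrawn so tone-evoked and
    movement-evoked activity stay separable.
    """
    if event_rate_hz < 0:
        raise ValueError("event_rate_hz must be >= 0")
    rng = np.random.default_rng(seed)
    coupled = np.asarray(coupled, bool)
    total_s = n_frames * frame_interval_s
    n_events = rng.poisson(event_rate_hz * total_s)
    dur_f = max(int(round(event_duration_s / frame_interval_s)), 1)
    event_mask = np.zeros(n_frames, bool)
    for _ in range(n_events):
        for _attempt in range(100):
            start = rng.integers(0, max(n_frames - dur_f, 1))
            span = slice(start, start + dur_f)
            if forbidden_mask is None or not forbidden_mask[span].any():
                event_mask[span] = True
                break
    facial = np.full(n_frames, rms_baseline)
    facial[event_mask] += rms_gain * (1.0 + 0.2 * np.abs(rng.normal(size=event_mask.sum())))
    facial += 0.05 * rms_baseline * np.abs(rng.normal(size=n_frames))
    extra = np.zeros((len(coupled), n_frames), int)
    lam = coupling_hz * frame_interval_s
    for i in np.flatnonzero(coupled):
        extra[i, event_mask] = rng.poisson(lam, event_mask.sum())
    return facial, extra


# --------------------------------------------------------------------------
# Pixel stacks
# --------------------------------------------------------------------------

def render_pixel_stack(
    traces: np.ndarray,
    centers: list[tuple[int, int]],
    radius_px: int,
    shape: tuple[int, int],
    background: np.ndarray | None = None,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint each soma's trace into a disk of pixels and add a global
    background component shared by all pixels.

    Returns (stack of shape (T, H, W), masks of shape (n_rois, H, W)).
    Somata must not overlap; overlapping disks raise.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    n_rois, T = traces.shape
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    masks = np.zeros((n_rois, H, W), bool)
    for i, (cy, cx) in enumerate(centers):
        masks[i] = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
    if masks.sum(axis=0).max() > 1:
        raise ValueError("soma masks overlap; move centers apart")
    stack = np.zeros((T, H, W))
    for i in range(n_rois):
        stack[:, masks[i]] = traces[i][:, None]
    if background is not None:
        stack += np.asarray(background, float)[:, None, None]
    if pixel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack += rng.normal(0.0, pixel_noise_sd, stack.shape)
    return stack, masks


# --------------------------------------------------------------------------
# Whole sessions
# --------------------------------------------------------------------------

def simulate_session(
    config: SceneConfig,
    protocol: StimulusProtocol,
    frame_interval_s: float = 0.1144,
) -> tuple[list[RoiSession], pd.DataFrame]:
    """Generate a complete tone session: population, spikes, fluorescence.

    Returns the per-ROI sessions plus the ground-truth table used for
    scoring (true class, true CF, kernel parameters).
    """
    neurons = generate_population(config)
    onsets = protocol.onset_frames(frame_interval_s)
    n_frames = int(onsets[-1] + round(protocol.period_s / frame_interval_s) + 50)
    sessions = []
    seed_seq = np.random.SeedSequence(config.seed)
    child_seeds = seed_seq.spawn(len(neurons))
    for neuron, child in zip(neurons, child_seeds):
        s_spk, s_flu = (int(c.generate_state(1)[0] % (2 ** 31)) for c in child.spawn(2))
        spikes = simulate_spikes(neuron, protocol, s_spk, frame_interval_s, n_frames)
        trace = render_fluorescence(
            spikes,
            neuron.kernel,
            noise_sd=config.noise_sd,
            drift_amplitude=config.drift_amplitude,
            drift_timescale_s=config.drift_timescale_s,
            frame_interval_s=frame_interval_s,
            seed=s_flu,
        )
        sessions.append(
            RoiSession(
                roi_id=neuron.roi_id,
                trace=trace,
                frame_interval_s=frame_interval_s,
                stim_onset_frames=onsets,
                stim_index=protocol.order,
                x_um=neuron.x_um,
                y_um=neuron.y_um,
                depth_um=neuron.depth_um,
                area_um2=neuron.area_um2,
                genotype=neuron.genotype,
            )
        )
    return sessions, truth_table(neurons)


def truth_table(neurons: list[NeuronSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi_id": n.roi_id,
                "true_class": n.true_class,
                "true_cf_khz": n.true_cf_khz,
                "x_um": n.x_um,
                "y_um": n.y_um,
                "depth_um": n.depth_um,
                "area_um2": n.area_um2,
                "genotype": n.genotype,
                "f0": n.kernel.f0,
                "f_1ap": n.kernel.f_1ap,
                "t_rise_ms": n.kernel.t_rise_ms,
                "tau_decay_ms": n.kernel.tau_decay_ms,
            }
            for n in neurons
        ]
    )
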