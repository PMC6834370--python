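# Methods

## Scope and data model

The pipeline analyses background-subtracted fluorescence traces of single
ROIs recorded at a fixed frame interval Δt (default 114.4 ms ≈ 8.74 Hz)
while a frequency × intensity tone grid is presented in pseudorandom
order. Positions live in a common coordinate frame: origin at the
superior/inferior colliculus contact point at the midline, x in µm
medial→lateral, y in µm posterior→anterior, depth in µm from the pia. The
default protocol has 19 frequencies (1–64 kHz, 3 steps/octave), 6
intensities (30–80 dB SPL, 10 dB steps), 1 s tones and 1.5 s
inter-stimulus intervals, each of the 114 stimuli repeated n = 6–10 times.

## Response detection and classification

**Trial segments and QC.** Each presentation contributes the segment from
−1 s to +2 s re tone onset. Window bounds map to frames by
floor(t/Δt), half-open, so at Δt = 114.4 ms the segment spans frames
−9…+16 (26 frames), a 500 ms analysis window spans 4 frames and the 1 s
tone 8. Per-trial baselines (mean over the 1 s pre-onset window) are
fitted with a Gaussian by sample mean/s.d. (the maximum-likelihood fit; no
other estimator is implied by a two-parameter Gaussian), and trials
outside μ ± 3σ are excluded — this absorbs carry-over from strong
responses to preceding stimuli. Excluded trials remain in the container,
flagged, so runs are auditable. At σ = 0 nothing can be excluded and a
warning is logged.

**Signal autocorrelation.** ρ_auto is the mean Pearson correlation over
all n(n−1)/2 trial pairs. Constant (zero-variance) segments make a pair's
correlation undefined; such pairs enter the average as 0, with a warning —
they carry no evidence of stimulus locking either way. ρ_auto is invariant
to per-trial affine transforms and to repetition order (Pearson
properties; enforced by property tests).

**Bootstrap null and p-values.** The null distribution draws B samples of
n segments starting at independent uniform-random frames of the same
session (overlap allowed) and scores each exactly like an observed
stimulus. Stimulus periods are *not* excluded from the draw: the null then
contains tone-locked structure at random phase, which is the appropriate
reference for "no reliably stimulus-locked waveform". The p-value uses
the finite-sample estimator p = (k+1)/(B+1), where k is the number of
null draws strictly greater than the observation (ties count as not
greater). The plain fraction k/B is downward biased; once B is small
relative to the Holm threshold α/m (e.g. B = 3000 against
0.05/114 ≈ 4.4·10⁻⁴) that bias alone inflates the family-wise error to
≈ 7% regardless of the data. The add-one estimator is valid at any B,
converges to k/B as B grows, and reports an observation exceeding every
null draw as 1/(B+1) < 1/B rather than an exact zero. Default
B = 30 000; the test suite uses B = 3000, which keeps the Holm threshold
resolvable (it sits above 1/(B+1)) at a thirtieth of the cost.

**Multiple comparisons.** Holm–Bonferroni at α = 0.05 over all m = 114
stimuli (delegated to `statsmodels.stats.multitest.multipletests`).
Stimuli that cannot be scored (fewer than two usable trials) enter with
p = 1, keeping m fixed.

**Classification gate and window criteria.** A significant stimulus is
classified only if its maximum ρ_cross against up-to-8 grid neighbours
(diagonals included) exceeds 0.12 — FRAs are continuous in
frequency-intensity space, so an isolated significant island is more
likely carry-over or a fluke. Gate-excluded stimuli still count toward the
CF (significance is a weaker claim than class membership). The per-stimulus
classes follow the window criteria verbatim (excitation: onset or steady
window above baseline by 2 s.d.; inhibition: steady or offset window below
by 2 s.d.; offset: conditional on the other two calls); classes are
non-exclusive. The dispersion "s.d. of baseline" is taken across the
per-trial baseline means of the trials entering that stimulus's average
(config `baseline_sd_mode="trials"`); the frame-wise s.d. within the
averaged baseline window is available as `"frames"`. The trials mode
matches the trial-QC statistic and is robust to frame noise.

**FRA class, CF and kinetics.** A class covering ≥ 25% of the classified
significant responses names the FRA; two or more such classes give
*mixed*; none significant gives *none*. The CF is the frequency
significant at the lowest effective intensity, the geometric mean when
several frequencies tie there. Excitatory FRAs are averaged over
excitatory responses whose neighbouring presentations (in time) were not
significant stimuli (falling back, flagged, to all excitatory trials if
isolation empties the set), then fitted with A(1 − exp(−t/τ)) on 0–1 s re
onset and a single-exponential decay on 0.5–4 s re offset. τ_onset > 1 s
designates *sustained*; such τ values are flagged as unsuitable for
population averaging. Fits use multi-start `scipy.optimize.curve_fit`
with τ bounded in (1 ms, 60 s); a non-convergent onset fit leaves the
class as generic excitation with a flag.

## Tonotopy fit

log₁₀(CF in Hz) is modelled as a 4th-order polynomial in the projected
distance r = x·cosθ + y·sinθ. The log base and Hz scale follow from the
printed coefficient units (decades·µm⁻ⁱ) and from a₀ ≈ 6.95 being
consistent with kHz-range CFs. For fixed θ the problem is linear, so θ is
profiled on a 0.5° grid over [0°, 180°) with an exact least-squares solve
per angle, then polished with a bounded scalar minimizer — deterministic,
with no dependence on optimizer initialization. θ is canonicalized to
[0, π); θ+π describes the same axis with r negated. The Vandermonde solve
runs in units of mm (r/1000) and rescales the coefficients afterwards;
in µm the r⁴ column reaches 10¹² and the plain solve loses the solution to
conditioning. The minimum-CF position is located by a dense scan plus
bounded polish, requires an interior local minimum with positive second
derivative, and names the monotone direction in its error otherwise.
Cross-validation uses a seeded 70/30 split and reports train/test variance
explained. Soma diameters default to the circle-equivalent d = 2√(A/π);
the alternative (4/π)√A scaling is a config option.

## Spike → fluorescence model

The kernel is g(t) = F_1AP·t/t_rise for 0 ≤ t < t_rise and
F_1AP·exp(−(t−t_rise)/τ_decay) for t ≥ t_rise; F(t) = F₀ + (n ∗ g)(t) at
frame resolution, with the kernel sampled at frame offsets g(0), g(Δt), …
so a spike contributes from its own frame onward (zero indicator latency
assumed). Voltage preprocessing: a ±1 ms moving-average DC-removal filter
(truncated windows at the edges), blanking of 2 ms before to 3 ms after
every current-injection edge, then thresholding with one spike per
supra-threshold excursion at its local maximum and a 1 ms refractory
merge. The default threshold is 5× the robust s.d. (1.4826 × MAD) of the
filtered trace; at 25 kHz a laxer default admits thousands of noise
crossings per minute. The 4-parameter fit uses seeded
`scipy.optimize.differential_evolution` (population ≈ 40, final local
polish) within bounds F₀ ∈ [0, max F], F_1AP ∈ (0, range F],
t_rise ∈ [50, 3000] ms, τ_decay ∈ [0.1, 10] s, and reports variance
explained = 1 − RSS/TSS.

## Movement analysis

Facial movement is the per-frame RMS of pixel change in a whisker-pad
rectangle, linearly interpolated from the 3 Hz video clock onto imaging
frames. The spontaneous period is defined as frames ≥ 3 s after any tone
offset and ≥ 1 s before any onset, and must total ≥ 60 s. Transients are
detected with hysteresis — events are spans above median + 1 robust s.d.
that reach median + 4 robust s.d., one peak per span — so noise
re-crossings during a slow decay do not fragment one transient into many.
"About 1 s decay kinetics" is operationalized as a median fitted τ within
[300, 3000] ms (configurable): one-frame image-shift artifacts fit far
below, drift far above. The final call is
flagged = (r > 0.25) ∧ kinetics_ok ∧ FRA without excitatory/offset
component; for plain FRA labels (components unknown) *mixed* is excluded
conservatively. The piezo paw-sensor trace is carried through unchanged
but does not enter the rule.

## The synthetic generator

The generator emulates the recording conditions end to end: neurons are
placed uniformly on a configurable footprint (default
x, y ∈ [200, 1000] µm, where the default tonotopy polynomial keeps CFs
within 0.5–128 kHz), with log₁₀ CF following the published best-fit
polynomial along the 50° axis plus Gaussian jitter (default 0.3 octaves).
Spiking is inhomogeneous Poisson at frame resolution. Class templates are
simulator conventions — the simplest forms producing the four published
fluorescence phenotypes: onset cells fire at an evoked rate decaying with
τ = 150 ms from tone onset; sustained cells hold the evoked rate for the
tone; inhibited cells suppress their spontaneous rate in proportion to
drive; offset cells fire for 300 ms after tone end; *mixed* combines
suppression with a rebound. Drive is a Gaussian in log₂ frequency
(s.d. 0.5 octaves — a realistic V-shaped FRA width; FWHM ≈ 1.2 oct) times
an intensity sigmoid (threshold 40 dB SPL, slope 5 dB). Default rates:
1 Hz spontaneous / 40 Hz evoked (onset, offset), 25 Hz evoked
(sustained), 8 Hz spontaneous for inhibited cells (suppression must be
observable), 2 Hz for untuned cells. Fluorescence is the kernel
convolution (defaults F₀ = 30 a.u., F_1AP = 10 a.u. with log-normal
cell-to-cell scatter, t_rise = 480 ms, τ_decay = 1.04 s — published
GCaMP6s kinetics) plus Gaussian noise (s.d. 0.1·F₀ per frame, making a
3-spike burst an ≈ 10σ event) and slow drift (Gaussian-filtered noise,
s.d. 0.05·F₀, 60 s correlation time). Movement events are Poisson in time
(0.05 Hz, 1.5 s), elevate the facial metric, add Poisson spikes at 25 Hz
to coupled cells, and by default avoid tone periods so the FRA and
movement analyses stay separable.

What the generator does **not** emulate: optical point-spread realism,
motion artifacts beyond one-frame shifts, acoustic self-stimulation by
movement, non-Poisson spike statistics (bursting, refractoriness),
indicator nonlinearity/saturation at high rates, and neuropil
contamination beyond a shared additive background. Passing recovery tests
therefore demonstrates correctness of the statistics under the stated
model, not robustness to every artifact of real recordings.

## Determinism and problem sizes

All stochastic operations take explicit integer seeds; populations,
spikes, noise, bootstrap draws and optimizer states are bit-reproducible
given (config, seed). The validation suite runs at these scales, chosen
so each check has clear statistical resolution: family-wise error on 500
tone-free ROIs at B = 3000; class/CF recovery on one 200-neuron session
with 8 repetitions; tonotopy-angle recovery over 20 seeds at n = 500 and
0.3 oct jitter; kernel round-trips over 10 seeds noiseless (5% tolerance)
and at 0.15·F₀ noise (20%); movement flagging over 20 coupled and 20
uncoupled seeds of 10-minute spontaneous sessions.

## Known limitations

- With 2.5 s stimulus periods and 3 s analysis windows, segments of
  neighbouring presentations overlap; carry-over from strong responses is
  only partially absorbed by the baseline QC and the ρ_cross gate, and
  broadens CF estimates for very wide tuning.
- The bootstrap null shares the session's stimulus density; on sessions
  dominated by evoked transients the null widens and power drops.
- The ρ_cross threshold (0.12) and the 25% class-fraction rule are fixed
  conventions, exposed in the config but not derived from data.
- The onset/sustained boundary (τ = 1 s) is close to the indicator decay
  time; cells near the boundary can flip between the two labels at
  realistic noise.
- Kernel fits assume linear summation; strongly bursting cells with
  indicator saturation will show systematic residuals absorbed into
  F_1AP.
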