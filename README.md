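# icfra

Analysis pipeline for tone-evoked two-photon Ca²⁺ imaging of the mouse
dorsal inferior colliculus (IC): statistical detection and classification
of frequency response areas (FRAs), characteristic-frequency (CF) mapping
with a joint direction + polynomial tonotopy fit, a spike-to-fluorescence
forward model for juxtacellular ground truth, and detection of
movement-correlated neurons — together with a synthetic-session generator
that provides ground truth for every stage.

It is written for auditory-systems and imaging labs who record ROI
fluorescence while presenting a tone grid (by default 19 frequencies,
1–64 kHz at 3 steps/octave, × 6 intensities, 30–80 dB SPL in 10 dB steps;
1 s tones, 1.5 s inter-stimulus interval, 6–10 pseudorandom repetitions)
at a 114.4 ms frame interval.

## The statistics at the core

**Response detection.** For each stimulus repeated *n* times, the per-trial
fluorescence waveforms F_i(t) (−1 s to +2 s re tone onset) are compared by
the *signal autocorrelation*

    ρ_auto = 2 / (n(n−1)) · Σ_{i<j} ρ_{i,j},

the mean Pearson correlation over all trial pairs. Significance comes from
a bootstrap null: B draws of *n* random segments from the same session,
each scored identically; the p-value is (k+1)/(B+1) where k counts null
draws exceeding the observation. Holm–Bonferroni over the 114 stimuli
controls the family-wise error at α = 0.05. The CF is the frequency that
is significant at the lowest effective intensity (geometric mean when
several frequencies tie at that intensity).

**Classification.** Significant stimuli whose responses also resemble a
grid neighbour (signal crosscorrelation ρ_cross = (1/nm)·ΣΣ ρ_{i,j} > 0.12
against any of up to 8 neighbours) are classified from window means of the
trial-averaged response (baseline, onset 0–500 ms, steady 500–1000 ms,
offset and off-late windows after the tone) as excitatory, inhibitory
and/or offset using 2 × s.d.-of-baseline criteria. A class covering ≥ 25%
of a cell's significant responses names its FRA; two such classes make it
*mixed*. Excitatory FRAs split into *onset* vs *sustained* by the time
constant of an A(1 − exp(−t/τ)) fit (τ > 1 s ⇒ sustained).

**Tonotopy.** Positions are projected onto an axis at angle θ from the
medial–lateral axis, r = x·cosθ + y·sinθ, and log₁₀ CF (Hz) is fitted as a
4th-order polynomial in r, jointly over θ and the coefficients — θ is
profiled on a 0.5° grid (the inner problem is linear) and polished.

**Spike → fluorescence model.** F(t) = F₀ + n(t) ∗ g(t), with the
ramp-decay kernel g rising linearly to F_1AP over t_rise and decaying as
exp(−(t−t_rise)/τ_decay); fitted to data by seeded differential evolution.

**Movement cells.** Facial movement (RMS frame-to-frame pixel change in a
whisker-pad rectangle) is correlated with fluorescence during tone-free
periods; cells with r > 0.25 are flagged if their transients show ~1 s
decay kinetics and their FRA has no excitatory/offset component.

## Worked example

```python
import numpy as np
from icfra import AnalysisConfig, analyze_session, build_default_protocol
from icfra.synthetic import SceneConfig, simulate_session
from icfra.report import class_proportions, score_against_truth
from icfra import tonotopy

protocol = build_default_protocol(n_reps=8, order_seed=1)
sessions, truth = simulate_session(SceneConfig(n_neurons=40, seed=12), protocol)

cfg = AnalysisConfig(bootstrap_n=3000)
table, results = analyze_session(sessions, protocol, cfg, seed=7)

props = class_proportions(table)
print(props[props["granularity"] == "full"][["fra_class", "count", "fraction"]]
      .to_string(index=False))
print(f"responsive fraction: {props.attrs['responsive_fraction']:.2f}")

scoring = score_against_truth(table, truth)
print(f"class agreement vs ground truth: {scoring['class_agreement']:.2f}")
print(f"median |CF error|: {scoring['cf_median_abs_error_oct']:.2f} octaves")

tuned = table[np.isfinite(table["cf_khz"])]
fit = tonotopy.fit(tuned["x_um"], tuned["y_um"], tuned["cf_khz"])
print(f"tonotopic axis: {fit.theta_deg:.1f} deg from medial-lateral, "
      f"variance explained {fit.variance_explained:.2f}")
```

prints

```
fra_class  count  fraction
    onset     15  0.500000
sustained      9  0.300000
inhibited      5  0.166667
   offset      1  0.033333
    mixed      0  0.000000
responsive fraction: 0.75
class agreement vs ground truth: 1.00
median |CF error|: 0.09 octaves
tonotopic axis: 42.6 deg from medial-lateral, variance explained 0.54
```

Of the 40 simulated neurons, 30 show a significant FRA (the other 10 are
untuned by construction); every recovered class matches the generator's
ground truth, the median CF error is a tenth of an octave (a third of one
grid step), and refitting the tonotopy model to the *estimated* CFs of
this small field recovers an axis near the generating 50° orientation.

The same stages are available as shell commands:
`icfra simulate`, `icfra fra`, `icfra tonotopy`, `icfra kernel-fit`,
`icfra movement`, `icfra report` (see `icfra --help`).

## Layout

```
src/icfra/core_io.py      protocol, sessions, table schemas, config, logging
src/icfra/synthetic.py    ground-truth session generator
src/icfra/response.py     ρ-auto/ρ-cross, bootstrap test, classification, CF
src/icfra/tonotopy.py     joint θ + polynomial fit, spatial summaries
src/icfra/groundtruth.py  spike detection, ramp-decay kernel model and fit
src/icfra/movement.py     facial-movement metric and movement-cell flagging
src/icfra/report.py       proportions, scoring, report files
docs/methods.md           model assumptions, defaults and numerical choices
```
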