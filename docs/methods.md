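# Methods

This note documents the models and procedures implemented in `statecortex`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Conventions

One session clock in seconds, double precision; LFP sample *k* lies at
`t0 + k/fs`. Channel index 0 is the most superficial recording site and
indices increase with depth; with 50 µm spacing, a unit on channel *c* has
relative depth `(recipient_channel − c) × 50 µm`, positive toward the pia
and 0 at the thalamic recipient layer. All analysis windows are half-open
`[a, b)` so shared edges are never double-counted. Signals are stored as
float32 on disk (session directories of flat binary + TSV/JSON) and
processed as float64 in memory; amplitudes are treated as microvolts
throughout (the absolute scale cancels in every reported statistic).

## Preprocessing and spectra

Raw LFP is zero-phase FIR low-pass filtered below 200 Hz (257 taps by
default) and resampled to 1 kHz; input already at 1 kHz is filtered but not
resampled. PSDs are one-sided densities in µV²/Hz over 0–100 Hz, estimated
either with DPSS multitapers (time–bandwidth NW = 3, 2·NW − 1 tapers,
eigenvalue-weighted — the default) or Welch's method; all state comparisons
integrate over bands (delta 0–4, theta 4–8, alpha 8–12, beta 12–30,
low-gamma 30–50 Hz) and are insensitive to the estimator choice, which both
satisfy a Parseval check to within 5 %. Band power integrates the PSD with
the trapezoid rule including both band edges, so adjacent bands sum exactly
to the power of their union. The low-frequency state index is the sliding
total power at ≤ 7 Hz (2 s windows, 0.5 s step) on a single configurable
deep channel — a visualization/verification aid, not an input to any
statistic.

## CSD and depth alignment

The laminar LFP is smoothed across adjacent channels with the triangular
kernel `[1, 2, 1]/4` after duplicating the uppermost and lowermost channels
(so the output keeps the channel count), then the CSD is the negated
three-point second spatial difference divided by h². Conductivity is set to
1 (arbitrary units): only the *location* of the sink matters. Sinks are
negative; the recipient channel is the channel attaining the global minimum
of the click-triggered average CSD in a 0–50 ms post-click window, ties
breaking toward the superficial channel. Each trial is baseline-corrected
by subtracting the per-channel mean CSD over the 50 ms preceding the click
— standard evoked-potential practice that removes ongoing slow-oscillation
leakage; without it the evoked sink is masked unless very many trials are
averaged. Unit somatic depth is the channel maximizing the per-channel
trough-to-peak amplitude (max − min) of the mean waveform, ties again
toward superficial.

## Cell classification

Cortical units split at a trough-to-peak duration of 0.55 ms (measured on
the depth channel from the global trough to the subsequent maximum); a
width of exactly 0.55 ms counts as broad-spiking. The published depth
ranges for BS1–BS4 share their edges, so the bins are implemented half-open
(BS1 `[0, 200]`, BS2 `[−300, 0)`, BS3 `[−700, −300)`, BS4 `[−1100, −700)`)
to guarantee a partition of [−1100, 200] µm; depths outside it are
`unclassified`. NS cells carry no depth bin and keep their class at any
depth. MGB units are class `MGB` regardless of width. Units with isolation
quality below 20 are excluded before any analysis.

## UP-state detection

MUA is the summed spike count of all cortical units in 1 ms bins smoothed
with a unit-area Gaussian (SD 10 ms, truncated at ±4 SD). The threshold θ
is the geometric mean of the smoothed MUA over spontaneous
(stimulus-free synchronized) bins. Because the geometric mean is undefined
over zero bins, all bins are clipped from below at a floor equal to half a
single spike's peak kernel contribution before taking logarithms. Clipping
(rather than excluding sub-floor bins) is deliberate: exclusion discards
nearly every near-silent DOWN bin and pushes θ to ~70 % of the UP-state
mean, where the 200 ms above-threshold requirement rejects most true
onsets; clipping keeps θ between the DOWN and UP levels, which is the
evident intent of a "low, robust" geometric-mean threshold. An onset is a
bin where the MUA crosses above θ (previous ≤ θ < current) with (i) mean
MUA < 0.2 θ over the preceding 100 ms and (ii) every bin above θ for the
following 200 ms (a config flag relaxes (ii) to the window mean); each
retained UP state is reported as that 200 ms window, which is also the
window for UP-state firing-rate estimates. Detected epochs never overlap
and never leave the spontaneous mask.

Two detection limits are intrinsic to these rules: an UP state whose
preceding DOWN state is shorter than ~100 ms can never satisfy (i), and the
symmetric smoothing kernel leaks the rising edge backward into the
pre-onset window. On standalone log-normal UP/DOWN alternation (UP 20 Hz
per unit, DOWN 0.2 Hz, 30-unit population) the detector recovers 92–96 % of
true UP states ≥ 300 ms with ~7 ms median onset error; inside a full
default session the fraction is 0.86–0.95 across seeds, the misses being
dominated by short preceding DOWN states.

## State epochs and response statistics

Per BF stimulation, the spontaneous synchronized window is the 3 s before
`bf_on` and the desynchronized window the 3 s after `bf_off` (truncated at
the next `bf_on`); only stimulations in sound-free blocks enter spontaneous
analyses, since BF pulses inside evoked blocks are followed by stimuli.
Evoked trials are assigned to states by their block label: `stim` blocks
(each trial preceded by 1 s of BF stimulation) are desynchronized, `no_stim`
blocks synchronized. The induced desynchronized state is assumed to last
10 s after stimulation offset when constructing stimulus-free periods.

The modulation index `(DESYNC − SYNC)/(DESYNC + SYNC)` is undefined when
both inputs are zero, in which case the unit is dropped (never recorded as
0); the UP-state variant is `(UP − DESYNC)/(UP + DESYNC)`. Onset statistics
use trial spike counts in 0–100 ms; only units with at least one
onset-window spike in *each* state are kept. Variance uses the unbiased
n − 1 denominator (unstated in the source analyses; chosen for small trial
counts). Mean spike time (80–200 ms) pools spikes across trials rather than
averaging per-trial means (a per-trial variant is config-exposed).
Normalized PSTHs use 1 ms bins over −50…300 ms, Gaussian smoothing of SD
5 ms (matching the correlation kernel; the source smoothing is unstated)
and division by the peak. Spike-count correlations bin each train at 1 ms,
smooth with a 5 ms-SD Gaussian *within* each 3 s window (no leakage across
concatenation joints) and take Pearson r over the concatenated vectors;
zero-variance vectors yield a missing value.

## Phase locking

Spike phases relative to a click train of frequency *f* are
`2π((t − onset) mod T)/T` with `T = 1/f`; spikes in the first 50 ms after
train onset are excluded, and spikes are pooled over presentations before
computing vector strength (the mean resultant length). The Rayleigh
p-value uses the standard finite-n approximation
`p = e^{−Z}[1 + (2Z − Z²)/(4n)]`, Z = n·VS², clipped to [0, 1] — chosen
over permutation for speed; Monte-Carlo calibration on uniform phases shows
the nominal 1 % level is held within [0.007, 0.013] at n = 100, and the
mean of Z is within 5 % of the Exp(1) limit. Per class and train frequency
the pipeline reports the mean vector-strength MI and the difference in the
fraction of significantly locked units (p < 0.01) between states; units
with fewer than two spikes in a state count as non-significant in the
fraction but are dropped from the MI.

## Synthetic sessions

The generator emulates the study design: a sound-free spontaneous block
with repeated 1 s BF stimulations 30 s apart, single-click blocks without
and with per-trial BF stimulation (25 trials each), and click-train blocks
(4/8/16/32/64 Hz, 1 s trains, 6 presentations per frequency per state) —
about 10 minutes of session. Desynchronization starts at `bf_on` and lasts
10 s beyond `bf_off`.

* **States and firing.** Synchronized intervals alternate UP/DOWN with
  log-normal durations (medians 400/300 ms, σ = 0.5 — chosen so UP states
  ≥ 300 ms are common relative to the detector's 100 + 200 ms windows); the
  UP/DOWN schedule is shared across cortical units, which both matches the
  biology and produces the elevated synchronized-state spike-count
  correlations. Desynchronized firing is tonic. Spontaneous rates per class
  (NS 8, BS1 2, BS2 5, BS3 6, BS4 2, MGB 8 Hz, log-normal per-unit jitter)
  are order-of-magnitude choices — absolute rates are not constrained by
  the source — with the desynchronized state halving BS1/BS4 rates.
* **Evoked templates.** Cortical click responses are an onset Gaussian
  (15 ± 6 ms), a suppression of the baseline, and a rebound Gaussian whose
  center is 150 ms (synchronized) vs 120 ms (desynchronized); thalamic
  responses are onset plus a state-invariant exponentially decaying
  sustained component (τ = 40 ms). Onset size falls to 0.65× in the
  desynchronized state for BS cells and rises to 1.5× for NS cells.
  Trial-to-trial log-normal gain jitter is larger in the synchronized state
  (σ = 0.6 vs 0.15), producing the super-Poisson synchronized Fano factors
  and their reduction upon desynchronization.
* **Phase locking.** During trains each click emits Poisson-count spikes
  with von Mises phases; κ rises from 0.8 to 2.0 in cortex and stays at 1.5
  in thalamus.
* **LFP.** Per channel: 1/f noise, a 0.5–2 Hz narrowband component whose
  amplitude grows with depth (attenuated to 0.25× in the desynchronized
  state), and a 30–50 Hz component strongest superficially (present only
  when desynchronized), cross-faded at state boundaries; clicks add a
  spatiotemporal Gaussian potential trough on the recipient channel (peak
  12 ms, 100 µV), which is what the CSD stage localizes. The narrowband
  components are drawn independently per channel: cross-channel coherence
  of the spontaneous LFP is *not* modelled (no analysis consumes it, and an
  all-channel common slow signal would make the null band-power calibration
  converge impractically slowly).
* **Waveforms.** Biphasic trough-then-peak templates with the true width on
  the sample grid, Gaussian spatial decay (SD 1.5 channels) around the true
  depth channel, and 1 µV additive noise by default.
* **Determinism.** Every random draw derives from one integer seed through
  `SeedSequence(seed, spawn_key=(stream, index))` with one stream per unit,
  so adding a unit never perturbs the others; identical (config, seed)
  reproduce sessions byte-for-byte.

What passing tests on these sessions show — and what they do not: the
pipeline provably recovers laminar alignment, cell classes, UP states,
band-power and firing-rate state modulation, evoked-timing shifts and
phase-locking changes *when the data contain them with the encoded effect
sizes*. The generator does not model spike-sorting artifacts, electrode
drift, conduction delays, biophysical LFP generation, laminar LFP
coherence, or thalamic participation in the slow oscillation, so
performance on real recordings with those features is not demonstrated
here.

## Problem sizes and numerical choices

The default session (~600 s, 80 units) runs through the full pipeline in
about 10 s; the test suite uses shorter sessions (3 stimulations, 8 click
trials, 2 trains per frequency) except where recovery statistics need the
full default. The Rayleigh calibration uses 10,000 draws of n = 100; the
UP-state recovery benchmark uses 200 s of alternation and a 30-unit
population (the population sum is what "MUA" denotes; a single 20 Hz unit
cannot constrain onsets to a few milliseconds). Degenerate inputs raise
errors rather than returning silently: all-zero waveforms, flat evoked CSD
("no sink"), empty spontaneous masks, and windows outside the recording.
Ties (sink channel, depth channel) break toward the superficial channel;
threshold crossings use previous ≤ θ < current.
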