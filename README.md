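# statecortex

Analysis pipeline for **cortical-state-dependent activity in the auditory
thalamocortical circuit**, built for laminar silicon-probe recordings from
auditory cortex (AC) and the medial geniculate body (MGB, auditory thalamus)
in which electrical stimulation of the basal forebrain (BF) switches the
cortex from a synchronized state (slow UP/DOWN alternation) to a transient
desynchronized state.

It is aimed at systems neurophysiologists who want a tested, reproducible
implementation of the standard analysis chain for this kind of experiment:

* **Laminar alignment** — current source density (CSD) from the depth
  profile of the LFP: channel duplication at the probe edges, triangular
  spatial smoothing `φs(r) = [φ(r−h) + 2φ(r) + φ(r+h)]/4`, then the negated
  second spatial difference `CSD(r) = −[φ(r+h) − 2φ(r) + φ(r−h)]/h²`
  (h = 50 µm). The channel with the largest click-evoked sink defines the
  thalamic recipient layer (relative depth 0).
* **Cell classification** — units split at a trough-to-peak width of
  0.55 ms into narrow-spiking (NS) and broad-spiking (BS) cells; BS cells
  subdivided by relative depth into BS1 (0…200 µm), BS2 (−300…0),
  BS3 (−700…−300) and BS4 (−1100…−700), approximating layers 2/3–6.
* **UP-state detection** — from multiunit activity (1 ms bins, 10 ms
  Gaussian smoothing): threshold θ = geometric mean of the smoothed MUA over
  spontaneous periods; onsets are upward θ-crossings preceded by 100 ms with
  mean MUA < 0.2 θ and followed by 200 ms entirely above θ.
* **State comparison statistics** — modulation index
  `MI = (DESYNC − SYNC)/(DESYNC + SYNC)`; onset reliability as mean μ,
  variance σ² and Fano factor σ²/μ of trial spike counts in the 0–100 ms
  window; mean spike time in 80–200 ms; peak-normalized PSTHs; pairwise
  spike-count correlations (1 ms bins, 5 ms Gaussian kernel, Pearson r over
  3 s windows before/after BF stimulation).
* **Phase locking to click trains** — vector strength
  `VS = |Σ exp(iθ_k)|/n` with θ = 2π·((t − onset) mod T)/T, Rayleigh test
  `Z = n·VS²`, `p = e^{−Z}[1 + (2Z − Z²)/(4n)]`, significance at p < 0.01;
  the first 50 ms of each train are excluded.
* **Synthetic sessions** — a generator producing complete sessions (LFP,
  spike trains, waveforms, event table) with known ground truth for every
  quantity above, so the whole pipeline is verifiable end to end.

## Worked example

```python
from statecortex import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1), out_dir="results")
print(report["spont_rate_mi"]["BS1"]["mean"])      # -0.266
print(report["band_power_mi"]["deep_delta"])       # -0.862
print(report["band_power_mi"]["superficial_low_gamma"])  # +0.853
print(report["mean_spike_time_ms"]["AC"]["delta"]) # -24.6 (ms)
print(report["vs_mi_by_class"]["BS3"])             # +0.28
print(report["vs_mi_by_class"]["MGB"])             # +0.007
```

This simulates a ~10 minute default session (60 AC + 20 MGB units), runs
every stage and writes `report.json` plus per-stage tables. The numbers
above mean: superficial (BS1) spontaneous firing drops in the
desynchronized state (negative MI); deep-layer delta power falls while
superficial 30–50 Hz power rises after BF stimulation; auditory-cortical
evoked firing shifts ~25 ms earlier in the 80–200 ms rebound window; and
click-train phase locking improves in cortex (positive vector-strength MI)
but not in thalamus (MI ≈ 0).

The same stages are available from the shell:

```bash
statecortex simulate --seed 1 --out session/   # write a synthetic session
statecortex run --seed 1 --out results/        # simulate + full pipeline
statecortex csd session/ --out results/        # single stage on a session
statecortex print-config                       # all defaults as YAML
```

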