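# owlrel

Interaural-cue reliability from owl head filters, and its match to
midbrain frequency tuning — on fully synthetic data.

## The problem

Barn owls localize sounds in azimuth using the interaural time
difference (ITD), detected in narrow frequency channels where it is
read out as an interaural *phase* difference (IPD).  When a second
sound source is present, the IPDs of the target shift in a
frequency-dependent way that is dictated by the head-related transfer
functions (HRTFs): frequencies in which the target out-gains the
interfering source keep a stable IPD, the others do not.  The
hypothesis this package implements and tests end to end is *weighting
by cue reliability*: a space-specific neuron tuned to some direction
should listen to exactly those frequency channels whose IPD is most
reliable at that direction — which predicts that best frequency (BF)
falls as best ITD grows.

Because measured owl HRTFs and recordings are not publicly deposited,
the package ships first-class synthetic stand-ins: a parametric head
model with the documented qualitative acoustics of the owl
(sine-of-azimuth delay law up to ~250 µs; intensity-gain directionality
that strengthens with frequency and whose maximum migrates from lateral
azimuths at low frequencies to a narrow frontal beam at high
frequencies), and a Poisson spiking neuron simulator driven by the
study's stimulus protocols.

## What it computes

* **Cue statistics.** Flat-spectrum (0.5–9 kHz) noise scenes are
  rendered through the head filters, decomposed by an owl gammatone
  filterbank (1–8 kHz, 200 Hz steps), and the per-channel IPD is the
  phase delay maximising the normalized left/right cross-correlation
  within ±half a period.  For each target direction, 37 scenes with a
  second equal-level source at −90…90° (5° steps) give the circular
  standard deviation σ of IPD (in % of a cycle); reliability is 1/σ²,
  normalized within each location.  Companion maps: monaural/averaged
  intensity gain (two normalizations) and the mean interaural
  correlation at the target's delay.
* **Tuning analysis.** From per-trial spike counts: best ITD
  (half-height center of the main peak), BF and frequency edges
  (interpolated 50 %-of-max crossings), ITD→IPD folding,
  wrapped-Gaussian IPD fits, vector-strength synchronization
  coefficient |Σ r·e^{i2πφ}|/Σ r, Fano factors, and spatial-tuning
  similarity under concurrent sounds.
* **Matching statistics.** Per-neuron Pearson correlations of smoothed
  frequency tuning against reliability/gain profiles, OLS regressions
  (BF vs best ITD, tuning edges vs map band edges), and Wilcoxon
  rank-sum comparisons between predictors.
* **Pipeline.** `owlrel run-all --config study.yaml` chains
  heads → maps → population → analysis → matching with explicit seeds
  and a content-hashed manifest.

## Worked example

```python
import numpy as np
from owlrel.hrtf import HeadModelParams, generate_hrir_set
from owlrel.binaural import design_owl_gammatone_bank
from owlrel.cues import build_reliability_map
from owlrel.neurons import simulate_population
from owlrel.pipeline import analyze_population
from owlrel.matching import population_regression

params = HeadModelParams()
head = generate_hrir_set(params, seed=1)
bank = design_owl_gammatone_bank()
rmap = build_reliability_map(head, bank,
                             target_azimuths=np.arange(-90, 91, 15), seed=1)
for az in (0, 45, 90):
    i = np.argmin(np.abs(rmap.target_azimuths_deg - az))
    best = rmap.channel_fcs_hz[np.argmax(rmap.reliability_norm[i])]
    print(f"target {az:3d} deg: most reliable channel {best:.0f} Hz, "
          f"IPD spread {rmap.circ_std_pct_cycle[i].min():.1f}-"
          f"{rmap.circ_std_pct_cycle[i].max():.1f} % of cycle")

pop = simulate_population(rmap, params, n_neurons=50, trials=20, seed=2)
feats = analyze_population(pop, rmap.channel_fcs_hz)
reg = population_regression(feats["abs_best_itd_us"], feats["bf_hz"])
print(f"BF vs best ITD: slope {reg.slope:.1f} Hz/us, "
      f"r^2 = {reg.r_squared:.2f}, p = {reg.p_value:.1e}")
```

prints

```
target   0 deg: most reliable channel 6200 Hz, IPD spread 8.0-41.8 % of cycle
target  45 deg: most reliable channel 1800 Hz, IPD spread 9.7-23.2 % of cycle
target  90 deg: most reliable channel 2200 Hz, IPD spread 16.1-31.2 % of cycle
BF vs best ITD: slope -17.7 Hz/us, r^2 = 0.73, p = 3.1e-15
```

Read: straight ahead the high-frequency channels carry the most stable
IPD; at eccentric targets the reliable band slides down to 1–2 kHz, and
concurrent sources can swing IPD by tens of percent of a cycle.  A
population of 50 simulated space-map neurons weighted by this map, when
re-analysed blind from its spike counts, reproduces the falling
BF-vs-best-ITD relation.

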