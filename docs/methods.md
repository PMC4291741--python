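# Methods

This note documents the models, estimators and numerical choices behind
`owlrel`, and what the synthetic data do and do not establish.

## Synthetic head filters

The head model (`owlrel.hrtf`) is a phenomenological direction- and
frequency-dependent linear filter with owl-like qualitative acoustics,
not a fit to any measured HRTF set.

**Delay.** The interaural delay follows a sine law,
`ITD(az) = max_itd · sin(az)` with `max_itd = 250 µs` (the order of the
largest interaural delays reported for barn owls), split symmetrically
between the ears and implemented as an exact linear-phase term in the
frequency domain, so fractional-sample delays are band-limited rather
than quantized to the sample grid.  A bulk delay of a quarter of the
256-tap response keeps the filters causal.

**Gain.** Each frequency has a gain maximum on a ring of azimuths
`ring(f) = 60° · (1 kHz / f)` that migrates from lateral directions at
low frequencies to a frontal beam at the top of the hearing range; the
gain falls off the ring with a von-Mises-like profile of half-width
`120° · (1 kHz / f)^0.9` down to a floor of `−D(f)` with
`D(f) = 20 dB · f / 8 kHz`.  The two ears share the azimuthal pattern
and are displaced vertically by ±7°, giving mirrored acoustic axes in
elevation and an analysis elevation (midpoint of the two axes) of 0°.

Two constraints fix the *form* of this model: (i) the
frontal-vs-peripheral gain contrast must grow monotonically with
frequency, with high frequencies strongly boosted straight ahead; and
(ii) eccentric directions must enjoy a genuine gain *advantage* in some
middle-frequency band.  Property (ii) is what a fixed frontally-aimed
lobe — the obvious simpler model — cannot provide: with a frontal-only
lobe no frequency ever favours an eccentric target over frontal
interferers, and the most reliable interaural-phase channel collapses
to the lowest frequency everywhere beyond ~±25° instead of declining
gradually with eccentricity.  The migrating gain maximum mirrors the
frequency dependence of the facial ruff's directivity (broad and
laterally oriented at low frequencies, a narrow frontal beam at high
frequencies) and produces the gradual high-to-low reliability ridge.
The ring/width/depth constants were chosen once against an analytic
power-weighted phase-mixing model of the two-source ensemble and then
frozen; they are package defaults, not measurements.

**Inter-individual variation.** `jitter_fraction` applies independent
multiplicative perturbations (uniform, ±jitter) to the delay and gain
parameters per seed, emulating a population of owls for cross-owl
variability surfaces.

## Stimuli and cochlear front end

Noise tokens are 100 ms at 48 kHz with 5 ms raised-cosine gates and an
exactly flat magnitude spectrum between 0.5 and 9 kHz (unit magnitude,
random phase, with one spectral projection after gating so the flatness
contract holds bin by bin; the gating survives as an attenuated onset).
Cue windows exclude the first 30 ms (gate plus gammatone transients)
and the final 5 ms.

The filterbank is a 4th-order gammatone bank, 1–8 kHz in 200 Hz steps
(36 channels), implemented as a cascade of identical complex one-pole
resonators normalized to unit gain at the center frequency — exact
center-frequency control at negligible cost.  Per-channel time
constants follow `tau = order / (2π · ERB(fc))` with a power-law
bandwidth rule `ERB(fc) = 0.79 · fc^0.75` Hz (≈140 Hz at 1 kHz, ≈670 Hz
at 8 kHz), intermediate between the mammalian ERB rule and constant-Q,
standing in for owl cochlear bandwidths; both the rule's coefficients
and the whole `tau` model are configurable where better estimates
exist.

## Interaural cue statistics

**IPD.** Per channel, the IPD is the delay maximising the normalized
left/right cross-correlation restricted to ±half a period of the
channel center frequency (phase delays are cyclically ambiguous beyond
that), expressed in cycles on (−0.5, 0.5], positive when the right ear
lags.  Sub-sample precision comes from a three-point cosine
interpolation at the carrier frequency — exact for tones, and within
0.01 cycle of the analytic phase in every channel (asserted by the
test suite).  Silent channels raise rather than return a number.

**Ensembles.** For each target, one scene per distractor position
(−90…90° in 5° steps, 37 configurations; all sources independent
equal-RMS tokens) at the analysis elevation.  The circular standard
deviation of the 37 IPDs, `SD = sqrt(−2 ln R)` with `R` the mean
resultant length, is reported in percent of a cycle; reliability is
`1/SD²` with SD floored at 0.1 % of a cycle (finite without reordering
non-degenerate cells) and max-normalized within each location.  An
optional `n_realizations` parameter replaces each configuration's IPD
by the circular mean over fresh token draws before taking the circular
SD: token noise in ~200 Hz channels over 100 ms is large enough to flip
near-tied cells of the map, and the qualitative-structure analyses use
3 realizations as a variance-reduction choice.  Three-source maps use
all unordered pairs from a 15°-spaced grid (78 pairs) to bound cost.

**Interaural correlation.** Per channel, the normalized
cross-correlation evaluated (quadratic interpolation between integer
lags) at the *single-source* best lag of the target, averaged over the
distractor ensemble.  For a lone source it is ≈1 in every channel and
strictly decreases when an equal-level source is added.

**Gain maps.** Mean of the two ears' transfer magnitudes in dB, with
two min-max scalings: over frequency within each location, and over
locations per frequency followed by over frequency per location (the
relative-gain cue).  Note the second scaling can leave a location whose
gain is the across-location maximum at every frequency with a flat
(all-zero after scaling) profile; only the first variant guarantees a
per-location maximum of 1.

## Tuning-curve analysis

Rates are trial means divided by the 0.1 s count window minus the
spontaneous rate, floored at zero (the floor never moves features
defined above 50 % of max).  Threshold crossings (frequency edges, ITD
half-height region) are linearly interpolated between grid points; a
region reaching the end of the sampled grid uses the grid end as its
edge.  Best ITD is the midpoint of the half-height region around the
global maximum; BF is the midpoint of the 50 %-of-max frequency range
(30 %/75 % and center-of-mass variants are reported too, and the
threshold ranges are nested by construction).  Fano factors use raw
counts (no spontaneous subtraction), per-stimulus `var/mean` with the
n−1 variance, averaged across stimuli with zero-mean stimuli skipped;
per-stimulus values are also exposed.  ITD→IPD folding averages rates
at coincident phases; wrapped-Gaussian fits (baseline + amplitude ·
period-1 wrapped Gaussian, `scipy.optimize.curve_fit`, with a periodic
interpolation fallback flagged `converged=False`) resample IPD curves
uniformly before the vector-strength synchronization coefficient.
Tuning-vs-predictor correlations smooth the tuning curve with a
centered 3-point moving average (window configurable).

## Synthetic neurons

The neuron module is a test harness with known ground truth, not a
mechanistic claim.  An ICx cell is a weighted sum of narrowband
cross-correlator inputs, `rate = base + peak · max(0, Σ_k w_k
cos(2π f_k (ITD − best_itd)))`; tones at the best ITD draw the rate
from the channel weight at the stimulating frequency, and tonal ITD
curves are single-channel rectified cosines.  Spike counts are Poisson
over the 0.1 s stimulus window (latency ignored) under the standard
protocols: broadband ITD ±300 µs in 30 µs steps × 5 trials; one tone
per filterbank channel × 20 trials; tonal ITD over three periods of the
tone, 21 ITDs × 20 trials.  Populations sample best ITDs uniformly on
0–250 µs, map them to azimuth through the head model's own delay law
(keeping simulation and maps self-consistent), and set channel weights
to the reliability profile at that azimuth; `shuffle_locations` breaks
the pairing as a null model.  An ICCc cell reads the IPD extracted from
the rendered free-field scene in its single best-frequency channel and
responds with von-Mises IPD tuning (concentration 4 by default) —
which also reproduces genuine spatial phase-aliasing at high best
frequencies.  The free-field speaker array is ±100° in 10° steps (21
speakers); concurrent sources default to ±90° from the preferred
location in 20° steps (10 positions, configurable, since 9 is an
equally defensible reading of the protocol).

## Matching statistics

Per-neuron Pearson r (two-sided p) between the smoothed tone tuning
curve and each predictor profile at the neuron's location; "fraction
significantly correlated" counts p < 0.05 with r > 0 (α configurable;
no multiple-testing correction, matching per-neuron reporting
conventions).  Population regressions are ordinary least squares with
the two-sided slope test; predictor comparisons use the two-sided
Wilcoxon rank-sum (Mann–Whitney) test, exact when the pooled sample is
tie-free and small enough, asymptotic otherwise.

## Problem sizes and determinism

The acceptance-grade analyses run the default head with 19 target
azimuths (−90…90°, 10° steps), the full 37-configuration ensemble, 3
realizations, and 100 simulated neurons × 20 trials — a few minutes on
one core; the paper-scale grids (5° targets, 10 owls) are available
through the pipeline config.  Every stochastic step draws from an
explicit seed; maps, populations and pipeline outputs are bit-
reproducible given the config, and the pipeline manifest records
content hashes and per-stage runtimes.

## Limitations

The head model omits everything a measured HRTF contains beyond its
two gross regularities: spectral notches, ruff reflections and
asymmetries, elevation-dependent ITD, interaural-canal effects, and
room acoustics.  The cochlear stage is linear (no middle-ear shaping,
compression or level dependence), and the neuron models have no
biophysics.  Passing the closed-loop tests therefore shows that the
*analysis chain* correctly recovers reliability weighting wherever the
acoustics have the owl's qualitative structure — it does not, and
cannot, certify the quantitative numbers of any particular animal's
head filters.
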