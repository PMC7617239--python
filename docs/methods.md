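# Methods

This note documents the models behind `flickersync`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical decisions a user should know before trusting a result.

## Phase conventions

All phases follow the cosine convention — phase 0 at the peak of the
carrier's fundamental — wrapped to (−π, π]. A 50 % duty square wave that
switches on at a trial onset has fundamental (2/π)·sin(2πf·τ), so its
analytic phase is 2πf·τ − π/2; the generator, the wavelet extractor and the
spike-triggered spectra all agree on this convention, which the test suite
checks (a spike on a cosine peak gets phase 0, a spike on the rising zero
crossing −π/2).

## Synthetic recordings

The generator produces inputs with exactly the statistical structure the
analyses assume, with one seeded `numpy` generator per object (identical
seeds are bit-identical):

* **Flicker stimulus** — 0/1 square wave at one of the LED (10/20/40/60/80
  Hz) or monitor (16/29/36/49 Hz) frequencies, 2 s trials, inter-stimulus
  intervals uniform in 4–10 s, sampled at 1200 Hz by default.
* **Locked spike trains** — inhomogeneous Poisson processes with rate
  λ(t) = r·max(0, 1 + m·cos(φ(t) − φ₀)) inside trials, realized by
  thinning. The rectified cosine is the simplest non-negative rate family
  with one depth parameter m ∈ [0, 1]; its phase density (1 + m cos θ)/2π
  has mean resultant m/2, so expected PPC ≈ (m/2)². Refractoriness is
  enforced afterwards by deleting spikes closer than 1 ms to their
  predecessor — an approximation that slightly thins high-rate trains but
  keeps the thinning construction exact.
* **Area gradient preset** — three areas × 50 units with modulation depth
  LGN 0.8, V1 0.4, CA1 0, each scaled by the low-pass 1/(1 + (f/40)²) so
  locking falls with flicker frequency as in thalamocortical data; V1
  broad-waveform units get an extra 1/(1 + (f/30)²) roll-off so the
  broad/narrow locking ratio decreases with frequency. Per-unit base rates
  are uniform in 8–20 spikes/s (firing-rate distributions are free
  parameters; these give every unit the ≥ 150 spikes a valid PPC needs
  within 30 trials).
* **Laminar flash LFP** — a negative alpha-function deflection (15 ms rise)
  with a Gaussian depth profile centered on the granular channel, on
  low-passed noise; the second spatial derivative of a Gaussian bump has a
  single dominant central sink flanked by sources, which is the structure
  the CSD analysis expects.
* **CA1 ripple LFP** — 1/f-amplitude (pink) background noise plus
  165 Hz bursts under a Tukey (25 % taper) envelope, calibrated so the peak
  envelope is a stated multiple of the channel's 130–200 Hz background SD.
  The Tukey envelope makes the burst's suprathreshold core match its
  nominal duration, so duration-filter contracts are sharp.
* **Spike waveforms** — biphasic templates (Gaussian trough, slower
  Gaussian after-potential) with trough-to-peak drawn from disjoint class
  ranges (narrow 0.20–0.35 ms, broad 0.60–0.90 ms at 30 kHz) plus white
  noise; polarity inversion produces the positive-peak artifacts the
  classifier must discard.

What the generator does **not** emulate: eye/retina dynamics,
monitor-refresh artifacts, spike-sorting contamination, electrode drift,
non-stationary firing, correlated noise across units, or a biophysical LFP
forward model. Passing tests therefore demonstrate the *analysis chain* is
correct under its stated assumptions, not that it is robust to every
pathology of real recordings.

## LFP preprocessing and stimulus phase

The preprocessing chain is: third-order Butterworth low-pass at 400 Hz,
high-pass at 0.1 Hz, band-stop 49.5–50.5 and 99–101 Hz, all applied
forward-backward (zero phase, because phase analyses follow), then
downsampling to 1200 Hz by non-overlapping block means (trailing samples
truncated with a warning if the factor does not divide the length).
Stimulus phase comes from convolution with a complex Morlet wavelet at the
flicker frequency; the width (default 7 cycles) trades temporal against
spectral resolution and is exposed because nothing in the problem pins it.

## Spike-triggered phases and PPC

Each spike's phase is the angle of the Hann-tapered discrete Fourier
transform of a 250 ms signal window centered on the spike, evaluated at the
flicker frequency, with two corrections that matter in practice:

* the segment is taper-weighted **demeaned** first — otherwise the DC
  content of a 0/1 stimulus leaks a *common* phase into every spike and
  fabricates locking at arbitrary frequencies (phase has no amplitude
  floor);
* the coefficient is rotated by the sub-sample offset between the spike
  time and the window-center sample, so the phase refers to the exact
  spike time rather than the sample grid (at 1200 Hz and 40 Hz the grid
  alone would add ±0.1 rad of quantization).

Spikes whose window crosses the signal edge are dropped. One 250 ms window
is used at every frequency; at 10 Hz that is 2.5 cycles, so very-low
frequency estimates are spectrally broad — a deliberate single-window-length
policy. Windows overlapping trial edges measure a mixture of stimulus and
silence; this attenuates measured PPC by roughly 10–15 % uniformly across
areas (the README example shows 0.133 where the ideal density gives 0.16)
and leaves orderings untouched.

PPC is computed in closed form from the resultant; it is exactly the mean
pairwise cosine (bounded in [−1/(N−1), 1]) and count-unbiased. Estimates
from fewer than 150 spikes are flagged invalid.

Group statistics: two-sided label-permutation tests for group differences,
Benjamini–Hochberg FDR across frequencies, and — for "is this group locked
at all?" — a randomization test that simulates the exact null distribution
of the group-mean PPC from each unit's spike count under uniform phases.
The latter exists because per-unit null PPC is strongly right-skewed, and a
sign-flip test (which assumes symmetry) empirically over-rejects about
twofold on this statistic.

## Layers and CA1

CSD is −∂²φ/∂z² of the event-averaged LFP after cubic ×4 depth
interpolation, with a 200 µm finite-difference step (the step must be
representable on the interpolated grid); the sign makes synaptic sinks
negative, and any depth-linear field is annihilated exactly. The granular
band is the contiguous run of channels around the *earliest* sink reaching
half the window's deepest sink within 100 ms of the flash — early input
arrives in L4, and the earliest-sink rule avoids being captured by larger
late sinks. Maps whose deepest sink stays within 5 pre-event noise SDs are
flagged unassigned.

Ripples: 130–200 Hz band-pass, instantaneous power via the Hilbert
envelope squared (the raw squared trace crosses zero twice per cycle and
has no contiguous suprathreshold extent), 12 ms boxcar smoothing, and a
z-score against the background (iterated with >5 SD samples excluded, so a
single large event in a short recording cannot inflate its own
normalization). Events are ≥ 2 SD excursions containing a ≥ 5 SD peak;
since a boxcar of width w widens any excursion by exactly w, boundaries
are pulled in by w/2 per side before the 20–200 ms duration filter. The
CA1 channel maximizes mean ripple-band power during pooled events, with
near-ties (1 %) broken toward unit density.

## Waveform classification

Mean waveforms (up to the first 10 000 snippets, 84 samples) are upsampled
×3 by cubic spline on the grid j/3 (252 output samples; the last two
extend the spline marginally past the final raw sample), centered on the
median of the first 10 samples, and normalized so the trough is exactly
−1; waveforms whose largest absolute excursion is positive are discarded.
The 80 post-trough samples (upsampled grid) are embedded with t-SNE
(perplexity 80, PCA initialization, fixed seed) and cut at two clusters by
Ward linkage on the 2-D embedding. The cluster with the shorter mean
trough-to-peak is "narrow", so class semantics never depend on embedding
chirality; below 2× perplexity units the embedding is unreliable and a 1-D
two-means split of trough-to-peak times substitutes (flagged in the
result), and identical waveforms collapse to a flagged single class.

## Responsiveness testing

The statistic is max |ECDF − uniform ramp| of pooled event-relative spike
times in the analysis window ((−10, 10) ms around laser onset; (0, 10) ms
after flash onset, used as printed although it is short). The null
circularly jitters each event's spikes by an independent uniform offset
(modulo the window), which preserves within-event spike counts and
patterns; p-values use the add-one rule, so exactness is finite-sample at
the price of simulation (the Gumbel tail approximation of the original
formulation is deliberately not used). Measured type-I at α = 0.05 sits at
≈ 0.03–0.05 across 1–20 spikes/s nulls, conservative at very low rates
where p-values are discrete. Latency is the first crossing of half the
peak of the event-averaged rate (0.5 ms bins, 1 ms Gaussian smoothing);
optotagging requires p < 0.05 AND latency in [1, 10] ms (the 1 ms floor
rejects laser artifacts).

## Phase regression

Counts per 8 ms bin are Poisson with log-rate β₀ sin(φ + β₁) + β₂
(Poisson is the canonical pairing for an exponential link on count data;
multiple counts per bin are allowed). The identity β₀ sin(φ + β₁) =
a sin φ + b cos φ makes the likelihood a convex Poisson GLM; (β₀, β₁) =
(√(a² + b²), atan2(b, a)), with delta-method standard errors. The trial
split (default 90/10) is random with a recorded seed. Evaluation is the
Pearson correlation between held-out binned counts and predicted counts;
note this correlation is ceiling-limited by Poisson noise — at 0.14
expected counts/bin even a perfect model cannot exceed r ≈ 0.26 — so
absolute r values are only comparable between units at similar rates.

## Compartmental models

The two archetypes are ball-and-stick reductions with a passive cable and
a threshold-reset soma (spike at V ≥ V_th, reset, 2 ms refractory):

| | soma | dendrite | N parallel | Cm (µF/cm²) | τ_m (ms) | V_th (mV) |
|---|---|---|---|---|---|---|
| pyramidal-like | 20 µm | 600 µm × 0.8 µm, 20 comps | 3 | 2.5 (dend) | 20 | −50 |
| PV-like | 15 µm | 300 µm × 1.2 µm, 10 comps | 5 | 0.9 (dend) | 5 | −55 |

Axial resistivity is 150 Ω·cm; leak conductance follows from Cm/τ_m. The
`n_parallel` factor lumps N identical dendrites into one chain (membrane
and axial quantities × N); by symmetry and superposition this preserves
somatic transfer impedances exactly. The parameters were chosen so the
reduction realizes the physics the full morphological models exhibit:
the spiny, slow pyramidal dendrite carries the larger capacitance and the
lower corner frequency, the PV cell is leakier, faster and more excitable.
Two of these choices deserve emphasis. First, unless the PV membrane
corner (1/2πτ ≈ 32–53 Hz) lies inside the tested band, both cells are in
the 1/ω regime above ~40 Hz and their filtering *ratio* flattens — the
cell-type contrast then disappears from locking measurements. Second, with
equal thresholds the leaky PV cell needs several times more background
drive to fire at all, and that noise drowns its locking at every
frequency; the lower PV threshold keeps both cells in the same
fluctuation-driven regime. Absolute impedance and locking magnitudes of
the full reconstructed-morphology models are expressly not reproduced —
the claims exercised here are filtering shapes and cell-type orderings.

Integration is backward Euler on the tridiagonal cable system (Thomas
algorithm, numba-compiled), default dt = 0.025 ms with a 200 ms discarded
pre-run; halving dt changes the somatic trace by < 0.5 % RMS, and the
solver aborts with diagnostics if |V| exceeds 200 mV. Synapses are
Exp2Syn double exponentials (rise 1 ms, decay 3 ms, reversal 0 mV)
normalized to peak at the stated weight; all synapses on one compartment
collapse into two exactly-decayed state variables.

Protocols:

* **Sinusoidal transfer impedance** — 100 pA at the compartment nearest
  150 µm, grid 2–10 Hz (step 2) and 10–105 Hz (step 5); |Z(f)| is the
  magnitude of the ratio of single-frequency DFTs of somatic voltage and
  injected current over an integer number of cycles (means subtracted to
  kill DC leakage); mV/nA = MΩ. For the single-compartment RC check,
  dt = 0.005 ms keeps the first-order integrator bias below 1 %.
* **Synaptic bursts** — 9 spikes at 5–100 Hz through one 0.004 µS synapse
  at 150 µm (1 ms delay). The response is a transient, so the Fourier
  ratio integrates the *whole* transient (burst + 0.4 s decay tail,
  baseline-subtracted) rather than an integer-cycle window — truncating
  the slow somatic decay would bias the pyramidal magnitude at high rates.
  The synaptic drive is the actual synaptic current g(t)·(E − V_site). In
  the weak-synapse regime this construction reproduces the sinusoidal
  |Z(f)| to ~0.1 %.
* **Rhythmic drive** — per the reference protocol, each input neuron makes
  70 contacts of 1.2e−5 µS with 4 ms delay; the pyramidal cell receives 6
  modulated + 60 background inputs (modulated ones on the proximal half of
  the dendrite, the basal analog), the PV cell 8 + 43 (whole tree). Input
  rates are free parameters, calibrated once so both archetypes fire ~4–7
  spikes/s (background 4.0 / 3.5 Hz, modulated 10 Hz). Output locking is
  reported two ways: PPC against the surrogate LFP of the modulated input
  population, and PPC against the analytic modulation phase. The two
  diverge where rhythm locking is weak: a neuron always shares
  fluctuations with its own finite (6–8 neuron) input population, so the
  sLFP-referenced PPC has a rhythm-independent common-input floor. The
  cell-type locking-ratio claims are therefore evaluated on the
  stimulus-phase PPC; both numbers are reported. Because the ratio of two
  simulated PPCs at 200 repetitions carries a few percent of Monte-Carlo
  error — comparable to the 40→60 Hz margin — monotonicity is asserted at
  the 2-SE resolution of the estimates, i.e. as a property of the
  expectation.
* **Capacitance sweep** — dendritic Cm scaled and any protocol re-run;
  halving Cm raises |Z(f)| at every tested frequency.
* **Modulation fitting** — bisection on the depth of the inhomogeneous
  input population until its own pooled phase PPC (expectation (m/2)²)
  matches a target within 0.005; a noise-violated bracket doubles the
  averaging, and unreachable targets return the achieved maximum, flagged.

## Problem sizes

Default test and benchmark sizes were chosen to give stable statistics at
desk scale: 50 units per area and 30 trials per frequency for the gradient
(every unit clears the 150-spike validity floor), 100 injected ripples at
10 SD, 400 waveforms, 1000 null simulations for test calibration, ~10⁵
bins for regression recovery, and 200 repetitions × 2.5 s for the
rhythmic-drive protocol (the production protocol of 200 × 10 s is a
configuration change).

## Known limitations

* The surrogate-LFP common-input floor means spike–sLFP PPC from small
  populations cannot be interpreted as rhythm locking when it is below a
  few times 1/√N_spikes; use the stimulus-phase PPC there.
* The window-edge attenuation of spike phases (above) makes absolute PPC
  values conservative near trial boundaries.
* Refractoriness-by-deletion distorts the realized rate at rates
  approaching 1/refractory.
* The reduced neurons have passive dendrites and a caricature soma; active
  dendritic conductances, resonance, and morphological detail are out of
  scope, and absolute MΩ / PPC magnitudes should not be compared against
  morphologically detailed simulations.
* The visual-responsiveness window of (0, 10) ms is used as specified but
  is short; its length is configurable.
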