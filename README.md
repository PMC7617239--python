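# flickersync

Analysis toolkit for **flicker frequency tagging** experiments: how does
synchronization imposed by a rhythmic visual stimulus propagate along the
visual hierarchy (LGN → V1 layers → CA1), which cell types does it recruit,
and why does propagation fail at high frequencies?

The package is aimed at systems-neuroscience users working with
multi-area spike/LFP recordings (e.g. Neuropixels) during periodic visual
stimulation, and at modelers studying dendritic filtering. All analyses run
on synthetic recordings produced by the built-in generator, so the whole
pipeline is testable without access to experimental data.

## What it computes

**Phase locking.** For each unit, spike phases are the phase at the flicker
frequency of a Hann-tapered 250 ms Fourier window centered on each spike,
taken from the stimulus/photodiode trace or from a population *surrogate
LFP* (summed spikes, band-passed 1–100 Hz). Locking strength is the
unbiased **pairwise phase consistency**

    PPC = (C² + S² − N) / (N (N − 1)),   C = Σ cos θᵢ,  S = Σ sin θᵢ,

the average cosine of all pairwise phase differences; its expectation for
independent phases with mean resultant length R is R², and it carries no
spike-count bias (units need ≥ 150 spikes to be marked valid). Group
contrasts use two-sided permutation tests with Benjamini–Hochberg FDR
control; "no locking" is tested by simulating the exact uniform-phase null
of the group-mean PPC.

**Anatomy.** Cortical layers are assigned from the current source density
(−∂²φ/∂z², ×4 spatial interpolation, 200 µm derivative step) of
flash-evoked laminar LFP: the granular band sits at the earliest dominant
sink. The CA1 pyramidal layer is found from ripple events (130–200 Hz
band, normalized squared signal, 5 SD peaks, 20–200 ms duration).

**Cell types.** Mean spike waveforms (×3 spline upsampling, trough
normalized to −1) are embedded with t-SNE (perplexity 80, the 80 samples
after the trough) and cut into broad/narrow classes by Ward clustering;
class semantics come from trough-to-peak time.

**Responsiveness.** A ZETA-style statistic (maximum deviation of the
pooled event-relative spike-time CDF from the uniform ramp) with a
circular-jitter permutation null; optotagged units must be significant
*and* reach half of the peak rate 1–10 ms after laser onset.

**Phase regression.** Binned spike counts (125 Hz) are fit by the Poisson
model `r(t) = exp(β₀ sin(φ(t) + β₁) + β₂)` via the convex `a sin φ + b cos φ`
reparameterization, trained on 90 % of trials and scored by the Pearson
correlation between held-out counts and predictions.

**Dendritic filtering.** Ball-and-stick pyramidal-like and PV-like model
neurons (implicit cable solver, threshold-reset soma) are probed with
sinusoidal currents at 150 µm (`|Z(f)| = |FFT(V_soma)/FFT(I)|`), 9-spike
synaptic bursts, and rhythmic + background Poisson synaptic drive, to show
how the slow, high-capacitance pyramidal dendrite attenuates fast rhythms
that the fast PV membrane still follows.

## Worked example

```python
import numpy as np
from flickersync import synthgen, locking

protocol = synthgen.FlickerProtocol(frequency=40.0, n_trials=30)
stimulus, trials = synthgen.make_flicker(protocol, seed=0)

lgn = synthgen.simulate_locked_train(
    synthgen.LockedTrainSpec(base_rate=15.0, mod_depth=0.7, seed=1),
    trials, 40.0, unit_id="lgn-0",
)
ca1 = synthgen.simulate_locked_train(
    synthgen.LockedTrainSpec(base_rate=15.0, mod_depth=0.0, seed=2),
    trials, 40.0, unit_id="ca1-0",
)
for train in (lgn, ca1):
    spec = locking.locking_spectrum(train, stimulus, [40.0])
    print(f"{train.unit_id}: n_spikes={spec.n_spikes[0]}, "
          f"PPC(40 Hz)={spec.ppc[0]:.4f}, valid={bool(spec.valid[0])}")
```

prints

```
lgn-0: n_spikes=891, PPC(40 Hz)=0.1331, valid=True
ca1-0: n_spikes=894, PPC(40 Hz)=-0.0011, valid=True
```

The LGN-like unit (modulation depth 0.7) locks strongly to the 40 Hz
flicker — a rectified-cosine rate with depth *m* has expected PPC ≈ (m/2)²
= 0.12, slightly attenuated here by window edges — while the unmodulated
CA1-like unit sits at the unbiased zero baseline despite the same spike
count.

The same operations are available from the shell:

```bash
flicker simulate --preset area-gradient --seed 1 --out sim/
flicker ppc --spikes sim/spikes_40hz.tsv --signal sim/stimulus_40hz \
        --freqs 10,20,40,60,80 --out ppc.tsv
flicker run --seed 1 --out report/
```

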