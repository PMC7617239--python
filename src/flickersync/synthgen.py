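"""Synthetic recordings with the statistical structure of flicker experiments.

Everything the analysis pipeline consumes can be generated here: square-wave
flicker stimuli with randomized inter-stimulus intervals, inhomogeneous
Poisson spike trains phase-locked to the flicker fundamental, populations
with an area-dependent locking gradient (LGN > V1 > CA1), flash-evoked
laminar LFPs with a granular current sink, CA1-like LFPs carrying
ripple-band bursts, and biphasic spike waveforms of the broad/narrow
classes.

The generators are first-class, deterministic (seeded) code: identical seeds
produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import ContinuousSignal, LaminarRecording, SpikeTrain, trial_table, wrap_phase

__all__ = [
    "LED_FREQUENCIES",
    "MONITOR_FREQUENCIES",
    "FlickerProtocol",
    "LockedTrainSpec",
    "PopulationSpec",
    "FlickerSession",
    "Recording",
    "WaveformBank",
    "make_flicker",
    "flicker_fundamental_phase",
    "simulate_locked_train",
    "simulate_population",
    "area_gradient_population",
    "simulate_laminar_flash",
    "simulate_ripple_lfp",
    "simulate_waveforms",
]

#: LED flicker frequencies used in the emulated protocol (Hz).
LED_FREQUENCIES = (10.0, 20.0, 40.0, 60.0, 80.0)
#: Monitor flicker frequencies (Hz).
MONITOR_FREQUENCIES = (16.0, 29.0, 36.0, 49.0)


@dataclass(frozen=True)
class FlickerProtocol:
    """Timing parameters of one flicker-frequency block.

    Defaults follow the emulated protocol: 2 s trials with inter-stimulus
    intervals drawn uniformly from 4-10 s.
    """

    frequency: float
    trial_duration: float = 2.0
    n_trials: int = 30
    isi_range: Tuple[float, float] = (4.0, 10.0)
    sampling_rate: float = 1200.0
    waveform_kind: str = "square"
    duty_cycle: float = 0.5

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.isi_range[0] > self.isi_range[1] or self.isi_range[0] < 0:
            raise ValueError("isi_range must satisfy 0 <= low <= high")
        if not 0.0 < self.duty_cycle < 1.0:
            raise ValueError("duty_cycle must lie in (0, 1)")
        if self.waveform_kind not in ("square", "sinusoid"):
            raise ValueError("waveform_kind must be 'square' or 'sinusoid'")


@dataclass(frozen=True)
class LockedTrainSpec:
    """Parameters of one phase-locked inhomogeneous Poisson unit.

    The rate inside trials is ``base_rate * max(0, 1 + mod_depth *
    cos(phi(t) - preferred_phase))`` where phi(t) is the stimulus
    fundamental phase; outside trials the unit is silent.
    """

    base_rate: float
    mod_depth: float
    preferred_phase: float = 0.0
    refractory: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be non-negative")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError("mod_depth must lie in [0, 1]")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")


def make_flicker(
    protocol: FlickerProtocol, seed: int
) -> Tuple[ContinuousSignal, pd.DataFrame]:
    """Generate a flicker stimulus trace and its trial table.

    The stimulus alternates between 0 and 1 at ``protocol.frequency`` inside
    each 2 s trial (starting in the "on" state at trial onset) and is 0
    between trials. Trial onsets are separated by ``trial_duration`` plus an
    ISI drawn uniformly from ``isi_range``.
    """
    if protocol.sampling_rate < 10 * protocol.frequency:
        raise ValueError(
            f"sampling_rate {protocol.sampling_rate} Hz is too low for a "
            f"{protocol.frequency} Hz flicker; need >= 10x the flicker frequency"
        )
    rng = np.random.default_rng(seed)
    isis = rng.uniform(*protocol.isi_range, size=protocol.n_trials)
    onsets = np.empty(protocol.n_trials)
    t = isis[0]
    for k in range(protocol.n_trials):
        onsets[k] = t
        t += protocol.trial_duration + (isis[k + 1] if k + 1 < protocol.n_trials else 1.0)
    trials = trial_table(onsets, protocol.trial_duration, protocol.frequency)

    fs = protocol.sampling_rate
    n = int(np.ceil((trials["offset"].iloc[-1] + 1.0) * fs))
    samples = np.zeros(n)
    times = np.arange(n) / fs
    for onset, offset in zip(trials["onset"], trials["offset"]):
        mask = (times >= onset) & (times < offset)
        tau = times[mask] - onset
        if protocol.waveform_kind == "square":
            frac = np.mod(tau * protocol.frequency, 1.0)
            samples[mask] = (frac < protocol.duty_cycle).astype(float)
        else:
            samples[mask] = 0.5 * (1.0 + np.sin(2 * np.pi * protocol.frequency * tau))
    return ContinuousSignal(samples, fs=fs), trials


def flicker_fundamental_phase(
    trials: pd.DataFrame, frequency: float, times: np.ndarray
) -> np.ndarray:
    """Analytic phase of the flicker fundamental at arbitrary times.

    A 50 % duty square wave that switches on at the trial onset has a
    fundamental proportional to ``sin(2 pi f tau)``; in the cosine
    convention (phase 0 at the fundamental's peak) this is the phase
    ``2 pi f tau - pi/2``. Times outside every trial get NaN.
    """
    times = np.asarray(times, dtype=float)
    phase = np.full(times.shape, np.nan)
    for onset, offset in zip(trials["onset"], trials["offset"]):
        mask = (times >= onset) & (times < offset)
        phase[mask] = wrap_phase(2 * np.pi * frequency * (times[mask] - onset) - np.pi / 2)
    return phase


def simulate_locked_train(
    spec: LockedTrainSpec,
    trials: pd.DataFrame,
    frequency: float,
    unit_id: int | str = 0,
    **labels,
) -> SpikeTrain:
    """Inhomogeneous Poisson spike train locked to the flicker fundamental.

    Realized by thinning: candidate spikes are drawn at the ceiling rate
    ``base_rate * (1 + mod_depth)`` and accepted with probability
    ``lambda(t) / lambda_max``. An absolute refractory period is enforced
    afterwards by deleting spikes that follow their predecessor too closely
    (an approximation to true refractoriness, documented as such).
    """
    rng = np.random.default_rng(spec.seed)
    lam_max = spec.base_rate * (1.0 + spec.mod_depth)
    all_times: List[np.ndarray] = []
    all_trials: List[np.ndarray] = []
    for _, row in trials.iterrows():
        dur = row["offset"] - row["onset"]
        n_cand = rng.poisson(lam_max * dur)
        if n_cand == 0:
            continue
        cand = np.sort(rng.uniform(0.0, dur, size=n_cand))
        phi = 2 * np.pi * frequency * cand - np.pi / 2
        lam = spec.base_rate * np.maximum(
            0.0, 1.0 + spec.mod_depth * np.cos(phi - spec.preferred_phase)
        )
        keep = rng.uniform(size=n_cand) < lam / lam_max
        kept = cand[keep] + row["onset"]
        all_times.append(kept)
        all_trials.append(np.full(kept.size, int(row["trial_id"])))
    if all_times:
        times = np.concatenate(all_times)
        tid = np.concatenate(all_trials)
    else:
        times = np.empty(0)
        tid = np.empty(0, dtype=int)

    if spec.refractory > 0 and times.size > 1:
        keep = np.ones(times.size, dtype=bool)
        last = times[0]
        for i in range(1, times.size):
            if times[i] - last < spec.refractory:
                keep[i] = False
            else:
                last = times[i]
        times, tid = times[keep], tid[keep]
    return SpikeTrain(unit_id=unit_id, spike_times=times, trial_ids=tid, **labels)


@dataclass
class PopulationSpec:
    """Structure of a multi-area population with a locking gradient.

    ``mod_depth`` maps (area, frequency) to the modulation depth of every
    unit in that area at that flicker frequency. When emulating the
    area gradient the table must be monotone non-increasing along the
    processing chain (with CA1 at zero).
    """

    n_units: Dict[str, int]
    mod_depth: Dict[Tuple[str, float], float]
    frequencies: Sequence[float] = LED_FREQUENCIES
    rate_range: Tuple[float, float] = (8.0, 20.0)
    protocol_kwargs: Dict = field(default_factory=dict)
    cell_class_fraction_narrow: Dict[str, float] = field(default_factory=dict)
    broad_depth_factor: Dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.n_units:
            raise ValueError("area list must not be empty")
        for area, n in self.n_units.items():
            if n < 1:
                raise ValueError(f"area {area!r} needs at least one unit")
        for key, m in self.mod_depth.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"mod_depth {m} for {key} outside [0, 1]")


@dataclass
class FlickerSession:
    """One flicker frequency block: stimulus, trial table and spike trains."""

    frequency: float
    stimulus: ContinuousSignal
    trials: pd.DataFrame
    trains: List[SpikeTrain]


@dataclass
class Recording:
    """Multi-frequency synthetic recording with ground-truth labels."""

    sessions: Dict[float, FlickerSession]
    units: pd.DataFrame  # unit_id, area, cell_class, base_rate

    def trains(self, frequency: float) -> List[SpikeTrain]:
        return self.sessions[frequency].trains


def area_gradient_population(
    n_per_area: int = 50,
    frequencies: Sequence[float] = LED_FREQUENCIES,
    lgn_depth: float = 0.8,
    v1_depth: float = 0.4,
    corner_hz: float = 40.0,
) -> PopulationSpec:
    """Preset emulating the LGN > V1 > CA1 locking gradient.

    Modulation depth falls off with flicker frequency as a first-order
    low-pass ``1 / (1 + (f / corner_hz)^2)`` in LGN and V1 and is exactly 0
    in CA1 at every frequency. Within V1, broad-waveform units get an extra
    roll-off relative to narrow-waveform units so the broad/narrow locking
    ratio decreases with frequency.
    """
    depth: Dict[Tuple[str, float], float] = {}
    broad_factor: Dict[float, float] = {}
    for f in frequencies:
        g = 1.0 / (1.0 + (f / corner_hz) ** 2)
        depth[("LGN", f)] = lgn_depth * g
        depth[("V1", f)] = v1_depth * g
        depth[("CA1", f)] = 0.0
        broad_factor[f] = 1.0 / (1.0 + (f / 30.0) ** 2)
    return PopulationSpec(
        n_units={"LGN": n_per_area, "V1": n_per_area, "CA1": n_per_area},
        mod_depth=depth,
        frequencies=tuple(frequencies),
        cell_class_fraction_narrow={"V1": 0.4},
        broad_depth_factor=broad_factor,
    )


def simulate_population(pop: PopulationSpec, seed: int) -> Recording:
    """Simulate every unit of ``pop`` at every flicker frequency.

    One stimulus block per frequency; each unit keeps its identity (id,
    base rate, area, waveform class) across blocks, mirroring a recording
    session where frequencies are presented sequentially.
    """
    rng = np.random.default_rng(seed)
    rows = []
    uid = 0
    for area, n in pop.n_units.items():
        frac_nw = pop.cell_class_fraction_narrow.get(area, 0.0)
        for _ in range(n):
            cls = "narrow" if rng.uniform() < frac_nw else "broad"
            rows.append(
                {
                    "unit_id": uid,
                    "area": area,
                    "cell_class": cls if frac_nw > 0 else None,
                    "base_rate": rng.uniform(*pop.rate_range),
                }
            )
            uid += 1
    units = pd.DataFrame(rows)

    sessions: Dict[float, FlickerSession] = {}
    for f in pop.frequencies:
        protocol = FlickerProtocol(frequency=f, **pop.protocol_kwargs)
        stim, trials = make_flicker(protocol, seed=int(rng.integers(2**31)))
        trains = []
        for _, u in units.iterrows():
            m = pop.mod_depth[(u["area"], f)]
            if u["cell_class"] == "broad" and pop.broad_depth_factor:
                m = m * pop.broad_depth_factor.get(f, 1.0)
            spec = LockedTrainSpec(
                base_rate=u["base_rate"],
                mod_depth=m,
                preferred_phase=0.0,
                seed=int(rng.integers(2**31)),
            )
            trains.append(
                simulate_locked_train(
                    spec,
                    trials,
                    f,
                    unit_id=int(u["unit_id"]),
                    area=u["area"],
                    cell_class=u["cell_class"],
                )
            )
        sessions[f] = FlickerSession(frequency=f, stimulus=stim, trials=trials, trains=trains)
    return Recording(sessions=sessions, units=units)


# ---------------------------------------------------------------------------
# Laminar flash-evoked LFP with a granular sink
# ---------------------------------------------------------------------------

def simulate_laminar_flash(
    n_channels: int,
    spacing_um: float,
    flash_events: np.ndarray,
    seed: int,
    fs: float = 1250.0,
    granular_channel: Optional[int] = None,
    sink_amplitude: float = 200.0,
    sink_sigma_channels: float = 1.5,
    noise_sd: float = 10.0,
    duration: Optional[float] = None,
) -> Tuple[LaminarRecording, Dict]:
    """Flash-evoked laminar LFP whose CSD has one dominant granular sink.

    The evoked component is a negative-going alpha-function deflection
    (peak ~30 ms after the flash) with a Gaussian depth profile centered on
    the granular channel; the second spatial derivative of that profile has
    a single dominant sink at the center, flanked by sources. Returns the
    recording and a ground-truth dict with the granular channel/band.
    """
    if n_channels < 5:
        raise ValueError("CSD needs at least 5 channels")
    flash_events = np.asarray(flash_events, dtype=float)
    rng = np.random.default_rng(seed)
    if granular_channel is None:
        granular_channel = n_channels // 2
    if duration is None:
        duration = float(flash_events.max()) + 0.5 if flash_events.size else 1.0
    n = int(np.ceil(duration * fs))
    data = rng.normal(0.0, noise_sd, size=(n_channels, n))
    # smooth the noise a little so it resembles LFP rather than white noise
    if noise_sd > 0:
        b, a = sps.butter(2, 150.0 / (fs / 2), btype="low")
        data = sps.filtfilt(b, a, data, axis=1)

    t_kernel = np.arange(0, int(0.15 * fs)) / fs
    tau = 0.015
    kernel = (t_kernel / tau) * np.exp(1.0 - t_kernel / tau)  # peak 1 at t = tau*?
    kernel /= kernel.max()
    depth_profile = np.exp(
        -0.5 * ((np.arange(n_channels) - granular_channel) / sink_sigma_channels) ** 2
    )
    for ev in flash_events:
        i0 = int(round(ev * fs))
        i1 = min(n, i0 + kernel.size)
        if i0 >= n:
            continue
        data[:, i0:i1] += -sink_amplitude * np.outer(depth_profile, kernel[: i1 - i0])

    band_lo = max(0, int(np.floor(granular_channel - sink_sigma_channels)))
    band_hi = min(n_channels - 1, int(np.ceil(granular_channel + sink_sigma_channels)))
    truth = {
        "granular_channel": granular_channel,
        "granular_band": (band_lo, band_hi),
        "flash_events": flash_events,
    }
    return LaminarRecording(data, fs=fs, spacing_um=spacing_um), truth


# ---------------------------------------------------------------------------
# CA1-like LFP with ripple-band bursts
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via FFT shaping."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return x / x.std()


def simulate_ripple_lfp(
    duration: float,
    fs: float,
    ripple_times: np.ndarray,
    ripple_channel: int,
    n_channels: int,
    seed: int,
    ripple_duration: float = 0.08,
    amplitude_sd: float = 10.0,
    carrier_hz: float = 165.0,
    neighbor_attenuation: float = 0.35,
    ripple_durations: Optional[np.ndarray] = None,
) -> Tuple[LaminarRecording, Dict]:
    """Pink-noise laminar LFP with amplitude-windowed ripple-band bursts.

    Each burst is a ``carrier_hz`` oscillation (130-200 Hz band) under a
    tapered-cosine (Tukey) envelope, so the burst holds its peak amplitude
    -- ``amplitude_sd`` times the ripple-band background SD of that channel
    -- for most of the requested duration; neighbors see the burst
    attenuated by ``neighbor_attenuation`` per channel step. Overlapping
    requested bursts are rejected.
    """
    ripple_times = np.asarray(ripple_times, dtype=float)
    if ripple_durations is None:
        ripple_durations = np.full(ripple_times.size, ripple_duration)
    ripple_durations = np.asarray(ripple_durations, dtype=float)
    order = np.argsort(ripple_times)
    rt, rd = ripple_times[order], ripple_durations[order]
    if np.any(rt[:-1] + rd[:-1] > rt[1:]):
        raise ValueError("requested ripple bursts overlap")
    if not 0 <= ripple_channel < n_channels:
        raise ValueError("ripple_channel out of range")

    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration * fs))
    data = np.vstack([_pink_noise(rng, n, fs) for _ in range(n_channels)])

    # calibrate burst amplitude against the ripple-band background
    sos = sps.butter(3, [130.0 / (fs / 2), 200.0 / (fs / 2)], btype="band", output="sos")
    band_sd = sps.sosfiltfilt(sos, data[ripple_channel]).std()

    for t_start, dur in zip(rt, rd):
        i0 = int(round(t_start * fs))
        nseg = int(round(dur * fs))
        if i0 < 0 or i0 + nseg > n:
            raise ValueError("ripple burst falls outside the recording")
        tau = np.arange(nseg) / fs
        burst = sps.windows.tukey(nseg, alpha=0.25) * np.sin(2 * np.pi * carrier_hz * tau)
        burst *= amplitude_sd * band_sd
        for ch in range(n_channels):
            att = neighbor_attenuation ** abs(ch - ripple_channel)
            data[ch, i0 : i0 + nseg] += att * burst

    truth = {
        "ripple_channel": ripple_channel,
        "ripple_times": rt,
        "ripple_durations": rd,
    }
    return LaminarRecording(data, fs=fs, spacing_um=50.0), truth


# ---------------------------------------------------------------------------
# Spike waveforms of the broad/narrow classes
# ---------------------------------------------------------------------------

@dataclass
class WaveformBank:
    """Raw mean spike waveforms (n_units x 84 samples) with ground truth."""

    waveforms: np.ndarray
    fs: float
    labels: np.ndarray  # ground-truth class per unit
    unit_ids: np.ndarray

    def __post_init__(self) -> None:
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        if self.waveforms.ndim != 2:
            raise ValueError("waveforms must be units x samples")


#: trough-to-peak ranges per class (ms), separable by construction
_T2P_RANGES_MS = {"narrow": (0.20, 0.35), "broad": (0.60, 0.90)}


def _biphasic_template(
    n_samples: int, fs: float, trough_index: int, t2p_ms: float, rep_amp: float = 0.45
) -> np.ndarray:
    """Negative trough followed by a slower positive after-potential."""
    t = (np.arange(n_samples) - trough_index) / fs * 1e3  # ms relative to trough
    trough = -np.exp(-0.5 * (t / 0.12) ** 2)
    rep_width = 0.25 + 0.45 * t2p_ms  # broad spikes repolarize more slowly
    repol = rep_amp * np.exp(-0.5 * ((t - t2p_ms) / rep_width) ** 2)
    return trough + repol


def simulate_waveforms(
    class_label: str,
    n_units: int,
    seed: int,
    fs: float = 30000.0,
    n_samples: int = 84,
    trough_index: int = 41,
    noise_sd: float = 0.02,
    invert: bool = False,
    width_jitter: float = 1.0,
) -> WaveformBank:
    """Biphasic spike waveforms of one class with per-unit width jitter.

    ``class_label`` is ``"broad"`` or ``"narrow"``; trough-to-peak times are
    drawn uniformly from non-overlapping class ranges so the two classes are
    separable by construction (``width_jitter`` scales the range around the
    class center; 0 gives identical templates). ``invert=True`` flips
    polarity (positive absolute peak), producing waveforms the classifier
    must discard.
    """
    if class_label not in _T2P_RANGES_MS:
        raise ValueError("class_label must be 'broad' or 'narrow'")
    rng = np.random.default_rng(seed)
    lo, hi = _T2P_RANGES_MS[class_label]
    center, half = (lo + hi) / 2, (hi - lo) / 2 * width_jitter
    t2p = rng.uniform(center - half, center + half, size=n_units)
    wf = np.empty((n_units, n_samples))
    for i in range(n_units):
        wf[i] = _biphasic_template(n_samples, fs, trough_index, t2p[i])
        wf[i] += rng.normal(0.0, noise_sd, size=n_samples)
    if invert:
        wf = -wf
    return WaveformBank(
        waveforms=wf,
        fs=fs,
        labels=np.full(n_units, class_label, dtype=object),
        unit_ids=np.arange(n_units),
    )
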