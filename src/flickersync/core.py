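"""Core data containers shared across the analysis pipeline.

Conventions used throughout the package:

* all times are in seconds, all frequencies in Hz;
* phases follow the cosine convention -- phase 0 at the peak of the
  carrier's fundamental -- and are wrapped to the half-open interval
  (-pi, pi];
* laminar channels are 0-indexed and ordered superficial -> deep;
* trial windows are half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ContinuousSignal",
    "PhaseSeries",
    "SpikeTrain",
    "LaminarRecording",
    "wrap_phase",
]


def wrap_phase(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-pi, pi].

    ``numpy``'s modulo maps to [-pi, pi); we flip the closed end so that a
    phase of exactly pi stays pi (the convention used for all phase
    containers in this package).
    """
    wrapped = np.mod(np.asarray(theta, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if np.isscalar(theta):
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class ContinuousSignal:
    """Uniformly sampled 1-D trace (stimulus, photodiode, sLFP, voltage)."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_of(self, t: float | np.ndarray) -> np.ndarray:
        """Nearest sample index of time ``t`` (may fall outside bounds)."""
        return np.rint((np.asarray(t) - self.t0) * self.fs).astype(np.int64)

    def with_samples(self, samples: np.ndarray) -> "ContinuousSignal":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phase of a carrier, wrapped to (-pi, pi]."""

    phase: np.ndarray
    fs: float
    t0: float
    carrier_frequency: float

    def __post_init__(self) -> None:
        ph = np.asarray(self.phase, dtype=float)
        if np.any(ph > np.pi) or np.any(ph <= -np.pi):
            ph = wrap_phase(ph)
        object.__setattr__(self, "phase", ph)
        if self.fs <= 0 or self.carrier_frequency <= 0:
            raise ValueError("fs and carrier_frequency must be positive")

    def __len__(self) -> int:
        return self.phase.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.phase.size) / self.fs

    def at(self, t: np.ndarray) -> np.ndarray:
        """Phase at arbitrary times by nearest-sample lookup."""
        idx = np.rint((np.asarray(t) - self.t0) * self.fs).astype(np.int64)
        if np.any(idx < 0) or np.any(idx >= self.phase.size):
            raise ValueError("requested times fall outside the phase series")
        return self.phase[idx]


@dataclass
class SpikeTrain:
    """Event times of one unit, optionally with trial and anatomy labels."""

    unit_id: int | str
    spike_times: np.ndarray
    trial_ids: Optional[np.ndarray] = None
    area: Optional[str] = None
    layer: Optional[str] = None
    cell_class: Optional[str] = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be sorted")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError("spike_times must be non-negative")
        if self.trial_ids is not None:
            self.trial_ids = np.asarray(self.trial_ids)
            if self.trial_ids.shape != self.spike_times.shape:
                raise ValueError("trial_ids must match spike_times in length")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def restricted(self, t_start: float, t_stop: float) -> "SpikeTrain":
        """Spikes inside the half-open window [t_start, t_stop)."""
        mask = (self.spike_times >= t_start) & (self.spike_times < t_stop)
        return SpikeTrain(
            unit_id=self.unit_id,
            spike_times=self.spike_times[mask],
            trial_ids=None if self.trial_ids is None else self.trial_ids[mask],
            area=self.area,
            layer=self.layer,
            cell_class=self.cell_class,
        )


@dataclass(frozen=True)
class LaminarRecording:
    """Multi-channel LFP on a linear depth axis (superficial -> deep)."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    spacing_um: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0 or self.spacing_um <= 0:
            raise ValueError("fs and spacing_um must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def depths_um(self) -> np.ndarray:
        return np.arange(self.n_channels) * self.spacing_um

    def channel(self, i: int) -> ContinuousSignal:
        return ContinuousSignal(self.data[i], fs=self.fs, t0=self.t0)


def trial_table(onsets: np.ndarray, duration: float, frequency: float) -> pd.DataFrame:
    """Build a trial table with half-open [onset, offset) windows."""
    onsets = np.asarray(onsets, dtype=float)
    return pd.DataFrame(
        {
            "trial_id": np.arange(onsets.size, dtype=int),
            "onset": onsets,
            "offset": onsets + duration,
            "frequency": frequency,
        }
    )
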