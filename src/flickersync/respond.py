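"""Event-responsiveness testing and the optotagging / visual rules.

The responsiveness statistic is ZETA-flavored: the maximum absolute
deviation of the pooled event-relative cumulative spike-time distribution
from the uniform ramp. Significance comes from a per-event circular-jitter
permutation null (spike times shifted by an independent uniform offset,
modulo the window) rather than the Gumbel tail approximation of the
original test -- slower, but an exact finite-sample contract.

Optotagged units must be significantly modulated (p < 0.05) *and* reach
half of their peak rate between 1 and 10 ms after laser onset (responses
earlier than 1 ms are treated as laser artifacts). Visually responsive
units only require significance in the flash window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import SpikeTrain

__all__ = [
    "ResponsivenessResult",
    "zeta_like_test",
    "classify_optotagged",
    "classify_visual",
    "OPTO_WINDOW",
    "VISUAL_WINDOW",
]

#: analysis window around laser onset (s)
OPTO_WINDOW = (-0.010, 0.010)
#: analysis window after flash onset (s)
VISUAL_WINDOW = (0.0, 0.010)


@dataclass
class ResponsivenessResult:
    """Outcome of the responsiveness test for one unit."""

    unit_id: int | str
    testable: bool
    statistic: float = float("nan")
    p: float = float("nan")
    latency_half_height: float = float("nan")
    peak_time: float = float("nan")
    n_events: int = 0
    n_spikes: int = 0


def _deviation_stat(rel_sorted: np.ndarray, length: float) -> float:
    """Max |ECDF - uniform ramp| of event-relative spike times in [0, L)."""
    n = rel_sorted.size
    ranks = np.arange(1, n + 1) / n
    return float(np.max(np.abs(ranks - rel_sorted / length)))


def _null_stats(
    rel: np.ndarray,
    event_idx: np.ndarray,
    n_events: int,
    length: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Circular-jitter null: shift each event's spikes by U(0, L) mod L."""
    deltas = rng.uniform(0.0, length, size=(n_perm, n_events))
    shifted = np.mod(rel[None, :] + deltas[:, event_idx], length)
    shifted.sort(axis=1)
    n = rel.size
    ranks = np.arange(1, n + 1) / n
    return np.max(np.abs(ranks[None, :] - shifted / length), axis=1)


def _half_height_latency(
    rel: np.ndarray,
    window: Tuple[float, float],
    n_events: int,
    bin_s: float = 0.0005,
    smooth_s: float = 0.001,
) -> Tuple[float, float]:
    """(first half-height crossing, peak time) of the event-averaged rate.

    The rate is a 0.5 ms histogram smoothed with a 1 ms Gaussian kernel;
    the latency is the first bin where the rate reaches half the peak.
    Both times are relative to event onset.
    """
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    hist, _ = np.histogram(rel + window[0], bins=edges)
    rate = hist / (n_events * bin_s)
    rate = gaussian_filter1d(rate.astype(float), sigma=smooth_s / bin_s)
    centers = edges[:-1] + bin_s / 2
    peak_i = int(np.argmax(rate))
    peak = rate[peak_i]
    if peak <= 0:
        return float("nan"), float("nan")
    half_i = int(np.argmax(rate >= peak / 2))
    return float(centers[half_i]), float(centers[peak_i])


def zeta_like_test(
    train: SpikeTrain,
    event_times: np.ndarray,
    window: Tuple[float, float] = OPTO_WINDOW,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> ResponsivenessResult:
    """Permutation test for time-locked modulation of spiking by events.

    Spike times are pooled relative to event onsets within the half-open
    ``window``; the statistic is the maximum absolute deviation of their
    cumulative distribution from the uniform ramp, and the null is built by
    circularly jittering each event's spikes within the window. The
    p-value uses the add-one rule, so ``p >= 1 / (n_perm + 1)``. With zero
    spikes in the window the unit is untestable (no p-value).
    """
    event_times = np.asarray(event_times, dtype=float)
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must have positive length")
    length = w1 - w0
    rel_list, idx_list = [], []
    for k, ev in enumerate(event_times):
        s = train.spike_times[
            (train.spike_times >= ev + w0) & (train.spike_times < ev + w1)
        ]
        if s.size:
            rel_list.append(s - (ev + w0))
            idx_list.append(np.full(s.size, k))
    if not rel_list:
        return ResponsivenessResult(
            unit_id=train.unit_id, testable=False, n_events=event_times.size
        )
    rel = np.concatenate(rel_list)
    event_idx = np.concatenate(idx_list)
    order = np.argsort(rel)
    stat = _deviation_stat(rel[order], length)
    rng = np.random.default_rng(seed)
    null = _null_stats(rel, event_idx, event_times.size, length, n_perm, rng)
    p = float((1 + np.sum(null >= stat)) / (n_perm + 1))
    latency, peak_time = _half_height_latency(rel, window, event_times.size)
    return ResponsivenessResult(
        unit_id=train.unit_id,
        testable=True,
        statistic=stat,
        p=p,
        latency_half_height=latency,
        peak_time=peak_time,
        n_events=event_times.size,
        n_spikes=rel.size,
    )


def classify_optotagged(
    result: ResponsivenessResult,
    alpha: float = 0.05,
    min_latency: float = 0.001,
    max_latency: float = 0.010,
) -> bool:
    """Tagged iff significant AND half-height latency in [1, 10] ms.

    The 1 ms floor rejects laser artifacts; the 10 ms ceiling enforces a
    direct (monosynaptic-speed) light response.
    """
    if not result.testable:
        return False
    return (
        result.p < alpha
        and np.isfinite(result.latency_half_height)
        and min_latency <= result.latency_half_height <= max_latency
    )


def classify_visual(result: ResponsivenessResult, alpha: float = 0.05) -> bool:
    """Visually responsive iff significantly modulated in the flash window."""
    if not result.testable:
        return False
    return result.p < alpha
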