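"""Anatomical localization: cortical layers from flash-evoked CSD and the
CA1 pyramidal layer from ripple-band events.

Current source density (CSD) is the negative second spatial derivative of
the event-averaged LFP along the depth axis: synaptic current sinks (which
pull the extracellular potential negative) appear as negative CSD. The
granular (input) layer is taken as the band around the earliest dominant
post-flash sink.

Ripples are transient 130-200 Hz oscillations of the CA1 pyramidal layer.
Detection follows the normalized-squared-signal (NSS) recipe: band-pass,
square, smooth, z-score; events are peaks above 5 SD whose extent (at the
2 SD crossings) lasts 20-200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .core import ContinuousSignal, LaminarRecording

__all__ = [
    "CSDMap",
    "compute_csd",
    "LayerAssignment",
    "assign_layers",
    "layer_of_channel",
    "RippleEvent",
    "detect_ripples",
    "Ca1Localization",
    "locate_ca1",
    "RIPPLE_BAND",
    "PEAK_SD",
    "EDGE_SD",
    "MIN_RIPPLE_S",
    "MAX_RIPPLE_S",
]

RIPPLE_BAND = (130.0, 200.0)
PEAK_SD = 5.0  # NSS peak threshold (SD above the mean)
EDGE_SD = 2.0  # event-extent threshold
MIN_RIPPLE_S = 0.020
MAX_RIPPLE_S = 0.200


# ---------------------------------------------------------------------------
# Current source density
# ---------------------------------------------------------------------------

@dataclass
class CSDMap:
    """CSD (interpolated depth x time), sinks negative."""

    values: np.ndarray
    depths_um: np.ndarray  # depth of each interpolated CSD row
    times: np.ndarray  # event-locked time axis (s)
    step_um: float
    original_spacing_um: float

    def channel_of_depth(self, depth_um: float) -> int:
        """Original-channel index nearest a given depth."""
        return int(round(depth_um / self.original_spacing_um))


def compute_csd(
    rec: LaminarRecording,
    events: np.ndarray,
    window: Tuple[float, float] = (-0.05, 0.15),
    interp_factor: int = 4,
    step_um: float = 200.0,
) -> CSDMap:
    """Event-averaged CSD of a laminar recording.

    The LFP is averaged across events, spatially interpolated by
    ``interp_factor`` (cubic along depth), and differentiated with the
    second-order central difference at a finite step of ``step_um``
    (which must be representable on the interpolated grid); the sign is
    flipped so sinks are negative. Rows without both +/-step neighbors
    are dropped.
    """
    if rec.n_channels < 5:
        raise ValueError("CSD needs at least 5 channels")
    events = np.asarray(events, dtype=float)
    i_lo = int(round(window[0] * rec.fs))
    i_hi = int(round(window[1] * rec.fs))
    n_t = i_hi - i_lo
    avg = np.zeros((rec.n_channels, n_t))
    n_used = 0
    for ev in events:
        c = int(round((ev - rec.t0) * rec.fs))
        if c + i_lo < 0 or c + i_hi > rec.n_samples:
            continue
        avg += rec.data[:, c + i_lo : c + i_hi]
        n_used += 1
    if n_used == 0:
        raise ValueError("no event window fits inside the recording")
    avg /= n_used

    depths = rec.depths_um
    fine_spacing = rec.spacing_um / interp_factor
    n_fine = (rec.n_channels - 1) * interp_factor + 1
    fine_depths = np.arange(n_fine) * fine_spacing
    spline = CubicSpline(depths, avg, axis=0)
    fine = spline(fine_depths)

    k_f = step_um / fine_spacing
    k = int(round(k_f))
    if abs(k_f - k) > 1e-9 or k < 1:
        raise ValueError(
            f"step {step_um} um is not representable on the interpolated grid "
            f"(fine spacing {fine_spacing} um)"
        )
    if n_fine <= 2 * k:
        raise ValueError("too few channels for the requested derivative step")
    # sinks negative: CSD ~ -d2(phi)/dz2
    csd = -(fine[2 * k :] - 2 * fine[k:-k] + fine[: -2 * k]) / (step_um**2)
    times = (np.arange(i_lo, i_hi)) / rec.fs
    return CSDMap(
        values=csd,
        depths_um=fine_depths[k:-k],
        times=times,
        step_um=step_um,
        original_spacing_um=rec.spacing_um,
    )


@dataclass
class LayerAssignment:
    """Granular band (original-channel indices, inclusive) or unassigned."""

    assigned: bool
    granular_band: Optional[Tuple[int, int]] = None
    sink_channel: Optional[int] = None
    sink_time: Optional[float] = None


def assign_layers(
    csd: CSDMap,
    search_window: Tuple[float, float] = (0.0, 0.1),
    noise_sd_threshold: float = 5.0,
    band_fraction: float = 0.5,
) -> LayerAssignment:
    """Locate the granular band around the earliest dominant post-flash sink.

    The noise floor is the SD of the CSD over pre-event times (t < 0); if no
    sink exceeds ``noise_sd_threshold`` noise SDs within the first 100 ms
    the map is flagged unassigned. The sink time is the first time any
    channel reaches ``band_fraction`` of the deepest sink value (earliest
    dominant sink, not the largest late sink); the granular band is the
    contiguous run of channels at that time below ``band_fraction`` of the
    sink amplitude.
    """
    pre = csd.values[:, csd.times < 0]
    noise_sd = pre.std() if pre.size else csd.values.std()
    in_win = (csd.times >= search_window[0]) & (csd.times < search_window[1])
    seg = csd.values[:, in_win]
    seg_times = csd.times[in_win]
    global_min = seg.min()
    if noise_sd == 0 or global_min > -noise_sd_threshold * noise_sd:
        return LayerAssignment(assigned=False)
    thresh = band_fraction * global_min  # negative
    crossing = np.nonzero((seg <= thresh).any(axis=0))[0]
    t_idx = crossing[0]
    profile = seg[:, t_idx]
    center = int(np.argmin(profile))
    # contiguous run of interpolated rows below threshold around the center
    below = profile <= band_fraction * profile[center]
    lo = center
    while lo > 0 and below[lo - 1]:
        lo -= 1
    hi = center
    while hi < below.size - 1 and below[hi + 1]:
        hi += 1
    ch_lo = csd.channel_of_depth(csd.depths_um[lo])
    ch_hi = csd.channel_of_depth(csd.depths_um[hi])
    return LayerAssignment(
        assigned=True,
        granular_band=(ch_lo, ch_hi),
        sink_channel=csd.channel_of_depth(csd.depths_um[center]),
        sink_time=float(seg_times[t_idx]),
    )


def layer_of_channel(assignment: LayerAssignment, channel: int) -> str:
    """Layer label for a unit given its peak-amplitude channel.

    Channels are ordered superficial -> deep, so channels above the granular
    band are "superficial" and channels below it are "deep".
    """
    if not assignment.assigned:
        return "unassigned"
    lo, hi = assignment.granular_band
    if channel < lo:
        return "superficial"
    if channel > hi:
        return "deep"
    return "granular"


# ---------------------------------------------------------------------------
# Ripple detection and CA1 localization
# ---------------------------------------------------------------------------

@dataclass
class RippleEvent:
    """One detected ripple: extent at the edge threshold, peak in SD units."""

    start: float
    stop: float
    peak: float
    peak_nss: float
    channel: Optional[int] = None

    @property
    def duration(self) -> float:
        return self.stop - self.start


def _nss(x: np.ndarray, fs: float, smooth_s: float = 0.012) -> np.ndarray:
    """Normalized squared signal of the ripple band.

    Band-pass 130-200 Hz, square via the Hilbert-envelope power (which
    tracks instantaneous ripple power without the twice-per-cycle zeros of
    the raw squared trace), boxcar-smooth, then z-score against the
    *background*: the mean/SD are iterated with samples above the peak
    threshold excluded, so rare large events do not inflate their own
    normalization (in long recordings the two normalizations coincide).
    """
    band = sps.sosfiltfilt(
        sps.butter(
            3, [RIPPLE_BAND[0] / (fs / 2), RIPPLE_BAND[1] / (fs / 2)],
            btype="band", output="sos",
        ),
        x,
    )
    power = np.abs(sps.hilbert(band)) ** 2
    size = max(1, int(round(smooth_s * fs)))
    power = uniform_filter1d(power, size=size)
    mu, sd = power.mean(), power.std()
    for _ in range(5):
        bg = power[(power - mu) / sd < PEAK_SD]
        mu2, sd2 = bg.mean(), bg.std()
        if abs(mu2 - mu) <= 1e-12 * max(abs(mu), 1.0):
            break
        mu, sd = mu2, sd2
    return (power - mu) / sd


def detect_ripples(
    lfp: ContinuousSignal,
    channel: Optional[int] = None,
    smooth_s: float = 0.012,
) -> List[RippleEvent]:
    """Detect ripple events on one channel via the NSS recipe.

    Candidate events are excursions of the NSS above ``EDGE_SD`` that
    contain a peak above ``PEAK_SD``. Because the boxcar smoother widens
    any excursion by exactly its window, the reported boundaries are pulled
    in by half the smoothing window on each side; events whose corrected
    duration falls outside 20-200 ms are discarded.
    """
    if lfp.fs < 600:
        raise ValueError("sampling rate too low for the 130-200 Hz ripple band")
    nss = _nss(lfp.samples, lfp.fs, smooth_s=smooth_s)
    above_edge = nss > EDGE_SD
    if not above_edge.any():
        return []
    edges = np.diff(above_edge.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    stops = np.nonzero(edges == -1)[0] + 1
    if above_edge[0]:
        starts = np.insert(starts, 0, 0)
    if above_edge[-1]:
        stops = np.append(stops, above_edge.size)
    events: List[RippleEvent] = []
    for i0, i1 in zip(starts, stops):
        seg = nss[i0:i1]
        peak_idx = int(np.argmax(seg))
        peak_val = float(seg[peak_idx])
        if peak_val < PEAK_SD:
            continue
        duration = (i1 - i0) / lfp.fs - smooth_s
        if not MIN_RIPPLE_S <= duration <= MAX_RIPPLE_S:
            continue
        events.append(
            RippleEvent(
                start=lfp.t0 + i0 / lfp.fs + smooth_s / 2,
                stop=lfp.t0 + i1 / lfp.fs - smooth_s / 2,
                peak=lfp.t0 + (i0 + peak_idx) / lfp.fs,
                peak_nss=peak_val,
                channel=channel,
            )
        )
    return events


@dataclass
class Ca1Localization:
    """Channel of the CA1 pyramidal layer, or unavailable if no ripples."""

    available: bool
    channel: Optional[int] = None
    ripple_power: Optional[np.ndarray] = None
    n_events: int = 0


def locate_ca1(
    rec: LaminarRecording,
    unit_peak_channels: Optional[Sequence[int]] = None,
    tie_tolerance: float = 0.01,
) -> Ca1Localization:
    """Channel with the largest mean ripple-band power during ripple events.

    Ripples are detected per channel and pooled; mean 130-200 Hz power
    during the pooled event intervals is compared across channels. Channels
    within ``tie_tolerance`` (relative) of the maximum are tie-broken toward
    the channel with the most units (by peak-amplitude channel) in its
    immediate neighborhood.
    """
    intervals: List[Tuple[float, float]] = []
    for ch in range(rec.n_channels):
        for ev in detect_ripples(rec.channel(ch), channel=ch):
            intervals.append((ev.start, ev.stop))
    if not intervals:
        return Ca1Localization(available=False)
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    sos = sps.butter(
        3, [RIPPLE_BAND[0] / (rec.fs / 2), RIPPLE_BAND[1] / (rec.fs / 2)],
        btype="band", output="sos",
    )
    band = sps.sosfiltfilt(sos, rec.data, axis=1)
    mask = np.zeros(rec.n_samples, dtype=bool)
    for s, e in merged:
        i0 = max(0, int(round((s - rec.t0) * rec.fs)))
        i1 = min(rec.n_samples, int(round((e - rec.t0) * rec.fs)))
        mask[i0:i1] = True
    power = (band[:, mask] ** 2).mean(axis=1)

    best = power.max()
    candidates = np.nonzero(power >= best * (1 - tie_tolerance))[0]
    if candidates.size > 1 and unit_peak_channels is not None:
        counts = np.asarray(
            [sum(abs(u - ch) <= 1 for u in unit_peak_channels) for ch in candidates]
        )
        channel = int(candidates[np.argmax(counts)])
    else:
        channel = int(candidates[np.argmax(power[candidates])])
    return Ca1Localization(
        available=True, channel=channel, ripple_power=power, n_events=len(merged)
    )
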