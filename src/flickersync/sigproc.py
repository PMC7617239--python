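"""LFP preprocessing and stimulus-phase extraction.

The preprocessing chain mirrors a standard Neuropixels LFP pipeline:
third-order Butterworth low-pass at 400 Hz, high-pass at 0.1 Hz, band-stop
notches around 50 and 100 Hz line noise, all applied forward-backward
(zero-phase, because phase analyses follow), then downsampling to 1200 Hz
by averaging consecutive frames.

Stimulus phase is extracted with a complex Morlet wavelet centered at the
flicker frequency; for a square-wave flicker the fundamental dominates, so
the extracted phase advances at the flicker frequency.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .core import ContinuousSignal, PhaseSeries, wrap_phase

__all__ = ["preprocess_lfp", "stimulus_phase", "bandpass", "TARGET_FS"]

#: output sampling rate of the preprocessing chain (Hz)
TARGET_FS = 1200.0


def bandpass(
    x: np.ndarray, fs: float, lo: float, hi: float, order: int = 3, axis: int = -1
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (second-order sections)."""
    sos = sps.butter(order, [lo / (fs / 2), hi / (fs / 2)], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x, axis=axis)


def preprocess_lfp(
    raw: ContinuousSignal,
    target_fs: float = TARGET_FS,
    notches: tuple = ((49.5, 50.5), (99.0, 101.0)),
) -> ContinuousSignal:
    """Filter and decimate a wide-band trace to the LFP band.

    Chain: low-pass 400 Hz -> high-pass 0.1 Hz -> band-stop notches ->
    block-mean downsampling to ``target_fs``. All filters are third-order
    Butterworth applied with ``filtfilt`` (zero phase). If the decimation
    factor is not an integer divisor of the signal length, trailing samples
    are truncated with a warning.
    """
    if raw.fs < 2 * target_fs:
        raise ValueError(
            f"input sampling rate {raw.fs} Hz too low; need >= {2 * target_fs} Hz"
        )
    factor_f = raw.fs / target_fs
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-6:
        raise ValueError(
            f"sampling rate {raw.fs} Hz is not an integer multiple of {target_fs} Hz"
        )
    x = raw.samples
    nyq = raw.fs / 2
    sos_lp = sps.butter(3, 400.0 / nyq, btype="low", output="sos")
    x = sps.sosfiltfilt(sos_lp, x)
    sos_hp = sps.butter(3, 0.1 / nyq, btype="high", output="sos")
    x = sps.sosfiltfilt(sos_hp, x)
    for lo, hi in notches:
        sos_bs = sps.butter(3, [lo / nyq, hi / nyq], btype="bandstop", output="sos")
        x = sps.sosfiltfilt(sos_bs, x)
    n_blocks = x.size // factor
    if n_blocks * factor != x.size:
        warnings.warn(
            f"truncating {x.size - n_blocks * factor} trailing samples before "
            "block-mean downsampling",
            stacklevel=2,
        )
        x = x[: n_blocks * factor]
    x = x.reshape(n_blocks, factor).mean(axis=1)
    # block means represent the center of each block
    t0 = raw.t0 + (factor - 1) / (2 * raw.fs)
    return ContinuousSignal(x, fs=target_fs, t0=t0)


def _morlet_kernel(fs: float, frequency: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, Gaussian envelope of ``n_cycles`` cycles."""
    sigma_t = n_cycles / (2 * np.pi * frequency)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(1j * 2 * np.pi * frequency * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return kernel / np.abs(kernel).sum()


def stimulus_phase(
    photodiode: ContinuousSignal, frequency: float, n_cycles: float = 7.0
) -> PhaseSeries:
    """Instantaneous phase of the flicker fundamental via Morlet convolution.

    Cosine convention: a pure ``cos(2 pi f t)`` input yields phase
    ``2 pi f t`` (mod 2 pi). The wavelet width (default 7 cycles) trades
    temporal against spectral resolution and is exposed as configuration.
    """
    if frequency >= photodiode.fs / 2:
        raise ValueError(
            f"frequency {frequency} Hz is at or above Nyquist ({photodiode.fs / 2} Hz)"
        )
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    kernel = _morlet_kernel(photodiode.fs, frequency, n_cycles)
    analytic = sps.fftconvolve(photodiode.samples, kernel, mode="same")
    return PhaseSeries(
        phase=wrap_phase(np.angle(analytic)),
        fs=photodiode.fs,
        t0=photodiode.t0,
        carrier_frequency=frequency,
    )
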