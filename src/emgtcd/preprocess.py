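"""Denoising filters and overlapping analysis-window segmentation.

The denoising chain is the standard surface-EMG recipe: a 20-200 Hz
Butterworth band-pass (removes ECG bleed-through, motion artifact and
high-frequency noise) followed by a 50 Hz Butterworth notch for powerline
interference.  Both are applied zero-phase (forward-backward), so onset
timing is not skewed and the stated stop-band attenuation applies to the
squared magnitude response.

Downstream analysis operates on overlapping fixed-length windows: 256 ms
(512 samples at 2000 Hz) advanced in 64 ms (128 sample) steps, so 1 s of
signal holds 12 fully-contained windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ParameterError, ValidationError
from .recording import EmgRecording

__all__ = [
    "FilterSpec",
    "WindowSpec",
    "bandpass_denoise",
    "notch_filter",
    "segment_windows",
    "windows_per_second",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass + notch design parameters.

    The band-pass order is the minimum meeting ``passband_ripple_db`` at
    (band_lo, band_hi) and ``stopband_atten_db`` at (stop_lo, stop_hi).
    The notch is a minimum-order band-stop: ``stopband_atten_db`` over
    notch_hz +/- notch_halfwidth_hz, ripple held to the pass edges 5 Hz
    out.
    """

    band_lo: float = 20.0
    band_hi: float = 200.0
    passband_ripple_db: float = 0.1
    stopband_atten_db: float = 50.0
    notch_hz: float = 50.0
    stop_lo: float = 10.0
    stop_hi: float = 400.0
    notch_halfwidth_hz: float = 1.0
    notch_pass_offset_hz: float = 5.0

    def __post_init__(self):
        if not (0 < self.stop_lo < self.band_lo < self.band_hi < self.stop_hi):
            raise ParameterError(
                "edges must satisfy 0 < stop_lo < band_lo < band_hi < stop_hi"
            )
        if self.passband_ripple_db <= 0 or self.stopband_atten_db <= 0:
            raise ParameterError("ripple and attenuation must be positive")

    def bandpass_sos(self, fs: float) -> np.ndarray:
        if fs / 2 <= self.stop_hi:
            raise ParameterError(
                f"sampling rate {fs} too low for stop edge {self.stop_hi} Hz"
            )
        order, wn = signal.buttord(
            [self.band_lo, self.band_hi],
            [self.stop_lo, self.stop_hi],
            self.passband_ripple_db,
            self.stopband_atten_db,
            fs=fs,
        )
        return signal.butter(order, wn, btype="bandpass", output="sos", fs=fs)

    def notch_sos(self, fs: float) -> np.ndarray:
        lo = self.notch_hz - self.notch_halfwidth_hz
        hi = self.notch_hz + self.notch_halfwidth_hz
        off = self.notch_pass_offset_hz
        order, wn = signal.buttord(
            [lo - off, hi + off],
            [lo, hi],
            self.passband_ripple_db,
            self.stopband_atten_db,
            fs=fs,
        )
        return signal.butter(order, wn, btype="bandstop", output="sos", fs=fs)


@dataclass(frozen=True)
class WindowSpec:
    """Overlapping analysis-window geometry (milliseconds)."""

    length_ms: float = 256.0
    step_ms: float = 64.0

    def __post_init__(self):
        if not (0 < self.step_ms <= self.length_ms):
            raise ParameterError("require 0 < step_ms <= length_ms")

    def length_samples(self, fs: float) -> int:
        return int(round(self.length_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_ms * fs / 1000.0))


def _apply_sos(rec: EmgRecording, sos: np.ndarray) -> EmgRecording:
    n = rec.n_samples
    # reflective padding of up to 1 s keeps short unit-test signals usable
    pad = min(int(rec.fs), n - 1)
    order_hint = sos.shape[0] * 2
    if n <= 3 * order_hint:
        raise ValidationError(
            f"recording of {n} samples is too short to filter (order ~{order_hint}); "
            "pad the signal first"
        )
    padded = np.pad(rec.samples, ((0, 0), (pad, pad)), mode="reflect")
    out = signal.sosfiltfilt(sos, padded, axis=1)
    return rec.with_samples(out[:, pad: pad + n])


def bandpass_denoise(rec: EmgRecording, spec: FilterSpec | None = None) -> EmgRecording:
    """Zero-phase minimum-order Butterworth band-pass, per channel."""
    spec = spec or FilterSpec()
    return _apply_sos(rec, spec.bandpass_sos(rec.fs))


def notch_filter(rec: EmgRecording, spec: FilterSpec | None = None) -> EmgRecording:
    """Zero-phase Butterworth band-stop around the powerline frequency."""
    spec = spec or FilterSpec()
    return _apply_sos(rec, spec.notch_sos(rec.fs))


def denoise(rec: EmgRecording, spec: FilterSpec | None = None) -> EmgRecording:
    """Band-pass then notch — the full preprocessing chain."""
    spec = spec or FilterSpec()
    return notch_filter(bandpass_denoise(rec, spec), spec)


def segment_windows(series: np.ndarray, wspec: WindowSpec, fs: float) -> np.ndarray:
    """Slice ``series`` into fully-contained overlapping windows.

    Returns an array of shape (n_windows, length_samples); window ``l``
    starts at sample ``l * step_samples``.  Short inputs yield an empty
    (0, length) array.  Count is ``floor((N - length)/step) + 1`` for
    N >= length.
    """
    series = np.asarray(series)
    length = wspec.length_samples(fs)
    step = wspec.step_samples(fs)
    n = series.shape[-1]
    if n < length:
        return np.empty((0, length), dtype=series.dtype)
    n_windows = (n - length) // step + 1
    view = np.lib.stride_tricks.sliding_window_view(series, length)[::step]
    return view[:n_windows]


def windows_per_second(wspec: WindowSpec, fs: float) -> int:
    """Number of analysis windows fully contained in one second of signal
    (12 at the 2000 Hz / 256 ms / 64 ms defaults); sets the minimum
    active-segment length ``L0 = windows_per_second * sec``."""
    length = wspec.length_samples(fs)
    step = wspec.step_samples(fs)
    n = int(round(fs))
    if n < length:
        raise ParameterError("window longer than one second of signal")
    return (n - length) // step + 1
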