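"""Synthetic trunk sEMG generator.

Surrogate sEMG is modeled as band-limited Gaussian noise whose amplitude is
modulated by a burst envelope: each trial is a rest/burst alternation of
``n_bursts`` task repetitions.  Compensation classes differ only in their
activation topography — which muscles' carriers are amplified during
bursts:

* ``SE`` (shoulder elevation) drives the descending trapezius,
* ``TR`` (trunk rotation) drives the external obliques asymmetrically
  (ipsilateral to the moving arm strongest),
* ``LF`` (lean forward) drives all four bilateral trunk pairs,
* ``NC`` (no compensation) carries only a mild task-related gain on all
  channels, so trials still contain detectable bursts.

Powerline (50 Hz) and a periodic biphasic ECG artifact are added on top,
for the preprocessing filters to remove.  Left-affected trials are exact
mirror images of right-affected ones: the recording is built in the
right-side convention and the two channels of each bilateral pair are
swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import CANONICAL_ORDER, PAIR_INDICES, channels_for_codes
from .errors import ParameterError
from .recording import EmgRecording

__all__ = [
    "SyntheticProtocol",
    "GroundTruth",
    "band_limited_carrier",
    "simulate_recording",
    "simulate_dataset",
]

#: Per-muscle burst gains in the right-affected-side convention,
#: canonical channel order [DT, LRA, RRA, LOEA, ROEA, LTES, RTES, LLES, RLES].
DEFAULT_TOPOGRAPHY: dict[str, tuple[float, ...]] = {
    "NC": (0.15,) * 9,
    "SE": (1.0, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1),
    "TR": (0.1, 0.1, 0.1, 0.3, 1.0, 0.1, 0.1, 0.1, 0.1),
    "LF": (0.1, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7),
}

#: Task most naturally eliciting each compensation class.
CLASS_TASK = {"NC": "T1", "LF": "T1", "TR": "T2", "SE": "T3"}

CARRIER_BAND = (20.0, 450.0)
EDGE_S = 0.1  # raised-cosine burst edge, seconds


@dataclass
class SyntheticProtocol:
    """Study-condition parameters of the simulator.

    Defaults emulate the acquisition protocol the detector targets:
    2000 Hz sampling, five task repetitions per trial, ~2 s movements
    separated by ~2 s rests, microvolt-scale baseline noise with a 10x
    within-burst amplification, 50 Hz interference and ECG bleed-through.
    """

    fs: float = 2000.0
    n_bursts: int = 5
    burst_s: float = 2.0
    rest_s: float = 2.0
    topography: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_TOPOGRAPHY.items()}
    )
    baseline_sigma: float = 2.0
    burst_sigma_scale: float = 10.0
    powerline_amp: float = 5.0
    ecg_amp: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_bursts < 1:
            raise ParameterError("n_bursts must be >= 1")
        if self.burst_s <= 0 or self.rest_s <= 0:
            raise ParameterError("burst_s and rest_s must be positive")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        for cls in ("NC", "LF", "TR", "SE"):
            gains = self.topography.get(cls)
            if gains is None or len(gains) != 9:
                raise ParameterError(f"topography for {cls} must list 9 gains")
            if any(g < 0 for g in gains):
                raise ParameterError(f"topography gains for {cls} must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.n_bursts * (self.burst_s + self.rest_s) + self.rest_s

    def burst_intervals(self) -> list[tuple[float, float]]:
        return [
            (self.rest_s + i * (self.burst_s + self.rest_s),
             self.rest_s + i * (self.burst_s + self.rest_s) + self.burst_s)
            for i in range(self.n_bursts)
        ]


@dataclass(frozen=True)
class GroundTruth:
    """True burst intervals (seconds) and class label of a simulated trial."""

    burst_intervals: tuple[tuple[float, float], ...]
    label: str


def band_limited_carrier(duration_s, fs, band, seed) -> np.ndarray:
    """Zero-mean unit-variance Gaussian noise band-limited to ``band``.

    Synthesized spectrally: white Gaussian noise is transformed, bins
    outside [lo, hi] zeroed, and transformed back, so out-of-band power
    is numerically zero.
    """
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ParameterError(f"band must satisfy 0 < lo < hi < fs/2, got {band}")
    n = int(round(duration_s * fs))
    if n < 2:
        raise ParameterError("duration too short for a carrier")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _burst_envelope(t: np.ndarray, intervals, edge_s: float) -> np.ndarray:
    """0→1 envelope with raised-cosine edges of ``edge_s`` inside each burst."""
    env = np.zeros_like(t)
    for ts, te in intervals:
        edge = min(edge_s, (te - ts) / 2)
        inside = (t >= ts) & (t < te)
        tau = t[inside]
        e = np.ones(tau.shape)
        rise = tau < ts + edge
        e[rise] = 0.5 * (1 - np.cos(np.pi * (tau[rise] - ts) / edge))
        fall = tau >= te - edge
        e[fall] = 0.5 * (1 - np.cos(np.pi * (te - tau[fall]) / edge))
        env[inside] = np.maximum(env[inside], e)
    return env


def _ecg_artifact(
    t: np.ndarray, amp: float, rate_hz: float = 1.2, width_s: float = 0.12
) -> np.ndarray:
    """Periodic biphasic pulse train: one sine cycle of ``width_s`` per beat.

    The 120 ms default mimics a QRS complex, whose energy lies below the
    20 Hz high-pass edge — the preprocessing filters are what remove it.
    """
    period = 1.0 / rate_hz
    phase = np.mod(t, period)
    pulse = phase < width_s
    out = np.zeros_like(t)
    out[pulse] = amp * np.sin(2 * np.pi * phase[pulse] / width_s)
    return out


def simulate_recording(
    protocol: SyntheticProtocol,
    label: str,
    affected_side: str = "right",
    seed: int | None = None,
    task: str | None = None,
    subject_id: str = "sim",
) -> tuple[EmgRecording, GroundTruth]:
    """Simulate one labeled 9-channel trial.

    Channel i's signal is ``A_i(t) * carrier_i(t)`` with
    ``A_i(t) = baseline_sigma * (1 + burst_sigma_scale * g_i * env(t))``,
    where ``g_i`` is the class topography gain, plus 50 Hz powerline on
    all channels and ECG on the abdominal/back channels (not DT).
    """
    if label not in protocol.topography:
        raise ParameterError(f"unknown class label {label!r}")
    if affected_side not in ("left", "right"):
        raise ParameterError("affected_side must be 'left' or 'right'")
    if seed is None:
        seed = protocol.seed
    intervals = protocol.burst_intervals()
    n = int(round(protocol.duration_s * protocol.fs))
    t = np.arange(n) / protocol.fs
    env = _burst_envelope(t, intervals, EDGE_S)
    gains = protocol.topography[label]

    child_seeds = np.random.SeedSequence(seed).generate_state(9) % (2**31)
    samples = np.empty((9, n))
    powerline = protocol.powerline_amp * np.sin(2 * np.pi * 50.0 * t)
    ecg = _ecg_artifact(t, protocol.ecg_amp)
    for i in range(9):
        carrier = band_limited_carrier(
            protocol.duration_s, protocol.fs, CARRIER_BAND, int(child_seeds[i])
        )
        amp = protocol.baseline_sigma * (
            1.0 + protocol.burst_sigma_scale * gains[i] * env
        )
        samples[i] = amp * carrier + powerline
        if i > 0:  # ECG contaminates trunk channels, not the trapezius
            samples[i] += ecg

    if affected_side == "left":  # mirror: swap each bilateral pair
        for li, ri in PAIR_INDICES:
            samples[[li - 1, ri - 1]] = samples[[ri - 1, li - 1]]

    rec = EmgRecording(
        samples=samples,
        fs=protocol.fs,
        channels=channels_for_codes(CANONICAL_ORDER),
        task=task or CLASS_TASK[label],
        label=label,
        subject_id=subject_id,
        affected_side=affected_side,
    )
    truth = GroundTruth(burst_intervals=tuple(intervals), label=label)
    return rec, truth


def simulate_dataset(
    protocol: SyntheticProtocol,
    trials_per_class: int,
    seed: int | None = None,
) -> list[tuple[EmgRecording, GroundTruth]]:
    """Balanced dataset: ``trials_per_class`` trials for each of the four
    classes, with per-trial sub-seeds derived deterministically from
    ``seed``.  Affected side alternates right/left across trials."""
    if trials_per_class < 1:
        raise ParameterError("trials_per_class must be >= 1")
    if seed is None:
        seed = protocol.seed
    classes = ("NC", "LF", "TR", "SE")
    n_trials = 4 * trials_per_class
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_trials) % (2**31)
    out = []
    k = 0
    for cls in classes:
        for j in range(trials_per_class):
            side = "right" if j % 2 == 0 else "left"
            out.append(
                simulate_recording(
                    protocol, cls, affected_side=side,
                    seed=int(sub_seeds[k]), subject_id=f"sim{j:02d}",
                )
            )
            k += 1
    return out
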