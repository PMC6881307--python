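"""In-memory representation of a multichannel trunk sEMG recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .channels import (
    CANONICAL_ORDER,
    CLASSES,
    SIDES,
    TASKS,
    MuscleChannel,
    channels_for_codes,
)
from .errors import ValidationError


@dataclass
class EmgRecording:
    """A channels x time sample matrix in microvolts with trial metadata.

    Parameters
    ----------
    samples
        Array of shape (n_channels, n_samples), microvolts.
    fs
        Sampling rate in Hz (2000 for the supported acquisition protocol).
    channels
        Ordered channel list; a full montage is the 9 canonical trunk
        muscles, partial montages are allowed for unit-level work.
    task
        Rehabilitation task: T1 reach-forward-back, T2 reach-side-to-side,
        T3 reach-up-to-down.
    label
        Trial class: NC (no compensation), LF (lean-forward), TR (trunk
        rotation) or SE (shoulder elevation).
    """

    samples: np.ndarray
    fs: float = 2000.0
    channels: list[MuscleChannel] = field(default_factory=list)
    task: str = "T1"
    label: str = "NC"
    subject_id: str = ""
    affected_side: str = "none"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.channels:
            self.channels = channels_for_codes(
                CANONICAL_ORDER[: self.samples.shape[0]]
            )
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channels):
            raise ValidationError(
                f"samples has {self.samples.shape[0]} rows for "
                f"{len(self.channels)} channels"
            )
        if self.samples.shape[1] < 1:
            raise ValidationError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.task not in TASKS:
            raise ValidationError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.label not in CLASSES:
            raise ValidationError(f"label must be one of {CLASSES}, got {self.label!r}")
        if self.affected_side not in SIDES:
            raise ValidationError(
                f"affected_side must be one of {SIDES}, got {self.affected_side!r}"
            )
        codes = [c.code for c in self.channels]
        if len(set(codes)) != len(codes):
            raise ValidationError("duplicate channel codes")

    @property
    def codes(self) -> list[str]:
        return [c.code for c in self.channels]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def canonicalized(self) -> "EmgRecording":
        """Return a copy with channels sorted into canonical order.

        Idempotent; a no-op for recordings already in canonical order.
        """
        order = sorted(range(len(self.channels)), key=lambda i: self.channels[i].index)
        if order == list(range(len(self.channels))):
            return self
        return replace(
            self,
            samples=self.samples[order],
            channels=[self.channels[i] for i in order],
        )

    def with_samples(self, samples: np.ndarray) -> "EmgRecording":
        """Copy of this recording with a new sample matrix (same montage)."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def subset(self, codes) -> "EmgRecording":
        """Restrict to the given channel codes (canonical order preserved)."""
        have = {c.code: i for i, c in enumerate(self.channels)}
        missing = [c for c in codes if c not in have]
        if missing:
            raise ValidationError(f"recording lacks channels {missing}")
        idx = [have[c] for c in codes]
        return replace(
            self,
            samples=self.samples[idx],
            channels=channels_for_codes(list(codes)),
        ).canonicalized()
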