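"""Trunk-muscle channel montage.

Nine superficial trunk muscles are recorded: the descending part of the
trapezius (DT, placed on the moving arm's side) and four bilateral pairs —
rectus abdominis (LRA/RRA), obliquus externus abdominis (LOEA/ROEA),
thoracic erector spinae (LTES/RTES) and lumbar erector spinae (LLES/RLES).
DT drives shoulder-elevation compensation, the OEA pair trunk rotation, and
the remaining trunk pairs lean-forward.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FormatError, ValidationError

#: Canonical channel order; DT is channel 1, left/right pairs follow.
CANONICAL_ORDER: tuple[str, ...] = (
    "DT", "LRA", "RRA", "LOEA", "ROEA", "LTES", "RTES", "LLES", "RLES",
)

#: 1-based (left, right) index pairs; DT (index 1) is unpaired.
PAIR_INDICES: tuple[tuple[int, int], ...] = ((2, 3), (4, 5), (6, 7), (8, 9))

#: Short name of each bilateral muscle pair, in canonical order.
PAIR_NAMES: tuple[str, ...] = ("RA", "OEA", "TES", "LES")

#: Channel subsets used for the reduced-montage configurations.  Whole
#: pairs are dropped abdominal-first (RA, then OEA, then TES); DT and the
#: lumbar erector spinae pair are kept longest.
CHANNEL_SUBSETS: dict[int, tuple[str, ...]] = {
    9: CANONICAL_ORDER,
    7: ("DT", "LOEA", "ROEA", "LTES", "RTES", "LLES", "RLES"),
    5: ("DT", "LTES", "RTES", "LLES", "RLES"),
    3: ("DT", "LLES", "RLES"),
}

TASKS = ("T1", "T2", "T3")
CLASSES = ("NC", "LF", "TR", "SE")
SIDES = ("left", "right", "none")


@dataclass(frozen=True)
class MuscleChannel:
    """One electrode channel: 1-based canonical index plus muscle code."""

    index: int
    code: str

    def __post_init__(self):
        if self.code not in CANONICAL_ORDER:
            raise FormatError(f"unknown muscle code {self.code!r}")
        expected = CANONICAL_ORDER.index(self.code) + 1
        if self.index != expected:
            raise ValidationError(
                f"channel {self.code} must have canonical index {expected}, "
                f"got {self.index}"
            )


def canonical_channels() -> list[MuscleChannel]:
    """The full 9-channel montage in canonical order."""
    return [MuscleChannel(i + 1, c) for i, c in enumerate(CANONICAL_ORDER)]


def channels_for_codes(codes) -> list[MuscleChannel]:
    """Build MuscleChannel objects for ``codes``, validating each code."""
    out = []
    for c in codes:
        if c not in CANONICAL_ORDER:
            raise FormatError(f"unknown muscle code {c!r}")
        out.append(MuscleChannel(CANONICAL_ORDER.index(c) + 1, c))
    return out


def check_pairs_complete(codes) -> None:
    """Reject montages containing half of a bilateral pair, naming the
    absent partner (reconstruction needs both sides)."""
    codes = set(codes)
    for li, ri in PAIR_INDICES:
        left, right = CANONICAL_ORDER[li - 1], CANONICAL_ORDER[ri - 1]
        if left in codes and right not in codes:
            raise FormatError(f"montage lists {left} but is missing {right}")
        if right in codes and left not in codes:
            raise FormatError(f"montage lists {right} but is missing {left}")


def validate_subset(codes) -> tuple[str, ...]:
    """Check that ``codes`` is DT plus complete pairs, in canonical order."""
    codes = tuple(codes)
    if len(codes) not in (9, 7, 5, 3):
        raise ValidationError(f"channel subset size must be 9/7/5/3, got {len(codes)}")
    if "DT" not in codes:
        raise ValidationError("channel subset must contain DT")
    for name, (li, ri) in zip(PAIR_NAMES, PAIR_INDICES):
        left, right = CANONICAL_ORDER[li - 1], CANONICAL_ORDER[ri - 1]
        if (left in codes) != (right in codes):
            raise ValidationError(f"subset must keep whole pairs; {name} pair is split")
    order = {c: i for i, c in enumerate(CANONICAL_ORDER)}
    if list(codes) != sorted(codes, key=order.__getitem__):
        raise ValidationError("channel subset must be in canonical order")
    return codes
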