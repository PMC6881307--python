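"""Time-domain feature extraction over active-segment windows.

Five features per channel per window — RMS, population variance, mean
absolute value, waveform length, and the 4th coefficient of an order-4
autoregressive model (Burg estimate) — giving a 5 x C feature vector
(45 for the full 9-channel montage).

Because a left-affected and a right-affected patient produce mirrored
activity on the four bilateral muscle pairs, pair features are
*reconstructed* into side-invariant combinations: each (left, right)
value pair becomes (left + right, |left - right|).  The trapezius channel
(placed on the moving arm's side) is left untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.linear_model import burg

from .channels import CANONICAL_ORDER, CHANNEL_SUBSETS, PAIR_NAMES, validate_subset
from .errors import DegenerateWindowError, ParameterError, ValidationError
from .preprocess import WindowSpec, segment_windows
from .recording import EmgRecording
from .segmentation import ActiveSegment

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "rms",
    "var",
    "mav",
    "wl",
    "ar4_coefficient",
    "reconstruct_pairs",
    "extract_features",
]

log = logging.getLogger(__name__)

FEATURE_NAMES = ("RMS", "VAR", "MAV", "WL", "AR4")


@dataclass(frozen=True)
class FeatureSpec:
    """Which features over which channels, and whether pairs are
    reconstructed into side-invariant (sum, |difference|) form."""

    features: tuple[str, ...] = FEATURE_NAMES
    ar_order: int = 4
    channel_subset: tuple[str, ...] = CANONICAL_ORDER
    reconstruct: bool = True

    def __post_init__(self):
        object.__setattr__(self, "channel_subset", validate_subset(self.channel_subset))
        for f in self.features:
            if f not in FEATURE_NAMES:
                raise ParameterError(f"unknown feature {f!r}")
        if self.ar_order < 1:
            raise ParameterError("ar_order must be >= 1")

    @classmethod
    def for_n_channels(cls, n: int, **kw) -> "FeatureSpec":
        """Standard reduced montage of size n in {9, 7, 5, 3}."""
        if n not in CHANNEL_SUBSETS:
            raise ParameterError(f"no standard subset of size {n}")
        return cls(channel_subset=CHANNEL_SUBSETS[n], **kw)

    @property
    def dimension(self) -> int:
        return len(self.features) * len(self.channel_subset)

    def column_names(self) -> list[str]:
        """Feature-major column names; reconstructed pairs are named
        ``<feat>_sum_<pair>`` / ``<feat>_absdiff_<pair>``."""
        pair_of = {}
        for name, codes in zip(PAIR_NAMES, (("LRA", "RRA"), ("LOEA", "ROEA"),
                                            ("LTES", "RTES"), ("LLES", "RLES"))):
            pair_of[codes[0]] = (name, "sum")
            pair_of[codes[1]] = (name, "absdiff")
        cols = []
        for feat in self.features:
            for code in self.channel_subset:
                if self.reconstruct and code in pair_of:
                    name, kind = pair_of[code]
                    cols.append(f"{feat}_{kind}_{name}")
                else:
                    cols.append(f"{feat}_{code}")
        return cols


@dataclass
class FeatureMatrix:
    """Windows x D feature table with per-window class labels."""

    values: pd.DataFrame
    labels: np.ndarray
    window_index: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValidationError("feature matrix contains non-finite values")
        if len(self.labels) != len(self.values):
            raise ValidationError("one label per row required")

    @property
    def dimension(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return len(self.values)

    @staticmethod
    def concat(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        parts = [p for p in parts if len(p)]
        return FeatureMatrix(
            values=pd.concat([p.values for p in parts], ignore_index=True),
            labels=np.concatenate([p.labels for p in parts]),
            window_index=[ix for p in parts for ix in p.window_index],
        )


def rms(window) -> float:
    """Root mean square: sqrt of the window's average power."""
    window = _check(window, 1)
    return float(np.sqrt(np.mean(np.square(window))))


def var(window) -> float:
    """Population variance (divisor M) about the window mean."""
    window = _check(window, 1)
    return float(np.mean(np.square(window - window.mean())))


def mav(window) -> float:
    """Mean absolute value."""
    window = _check(window, 1)
    return float(np.mean(np.abs(window)))


def wl(window) -> float:
    """Waveform length: accumulated absolute successive differences."""
    window = _check(window, 2)
    return float(np.sum(np.abs(np.diff(window))))


def ar4_coefficient(window, q: int = 4) -> float:
    """q-th coefficient of an order-q AR model, Burg estimate.

    Sign convention x(k) = sum_j a_j x(k-j) + e(k).  Raises
    DegenerateWindowError on zero-variance windows (callers map that to a
    feature value of 0).
    """
    window = _check(window, 4 * q + 1)
    if np.ptp(window) == 0:
        raise DegenerateWindowError("constant window has no AR model")
    coeffs, _ = burg(window - window.mean(), order=q, demean=False)
    return float(coeffs[q - 1])


def _check(window, min_len: int) -> np.ndarray:
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size < min_len:
        raise ParameterError(f"window must be 1-D with >= {min_len} samples")
    return window


def reconstruct_pairs(values, subset: tuple[str, ...] = CANONICAL_ORDER) -> np.ndarray:
    """Side-invariant pair reconstruction of one feature's per-channel
    values: each (left, right) pair becomes (left+right, |left-right|);
    unpaired DT passes through.  Dimension is unchanged."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(subset),):
        raise ParameterError(
            f"expected {len(subset)} values for subset {subset}, got {values.shape}"
        )
    out = values.copy()
    pos = {c: i for i, c in enumerate(subset)}
    for left, right in (("LRA", "RRA"), ("LOEA", "ROEA"),
                        ("LTES", "RTES"), ("LLES", "RLES")):
        if left in pos:
            i, j = pos[left], pos[right]
            out[i] = values[i] + values[j]
            out[j] = abs(values[i] - values[j])
    return out


_FEATURE_FUNCS = {"RMS": rms, "VAR": var, "MAV": mav, "WL": wl}


def extract_features(
    rec: EmgRecording,
    segments: list[ActiveSegment],
    wspec: WindowSpec | None = None,
    fspec: FeatureSpec | None = None,
    recording_id: str | None = None,
) -> FeatureMatrix:
    """One feature row per analysis window inside any accepted segment.

    Columns are ordered feature-major then channel; every row carries the
    recording's class label.
    """
    wspec = wspec or WindowSpec()
    fspec = fspec or FeatureSpec()
    rec = rec.subset(fspec.channel_subset)
    rid = recording_id if recording_id is not None else rec.subject_id
    if not segments:
        log.warning("no active segments for %s: empty feature matrix", rid)
    per_channel = [
        segment_windows(rec.samples[i], wspec, rec.fs)
        for i in range(len(fspec.channel_subset))
    ]
    n_windows = per_channel[0].shape[0] if per_channel else 0
    active = sorted(
        {l for s in segments for l in range(s.l1, s.l2) if l < n_windows}
    )
    rows = np.empty((len(active), fspec.dimension))
    for row_i, l in enumerate(active):
        vals = []
        for feat in fspec.features:
            if feat == "AR4":
                chan_vals = []
                for ch in range(len(fspec.channel_subset)):
                    try:
                        chan_vals.append(
                            ar4_coefficient(per_channel[ch][l], fspec.ar_order)
                        )
                    except DegenerateWindowError:
                        chan_vals.append(0.0)
            else:
                fn = _FEATURE_FUNCS[feat]
                chan_vals = [
                    fn(per_channel[ch][l])
                    for ch in range(len(fspec.channel_subset))
                ]
            if fspec.reconstruct:
                chan_vals = reconstruct_pairs(
                    np.asarray(chan_vals), fspec.channel_subset
                )
            vals.extend(chan_vals)
        rows[row_i] = vals
    return FeatureMatrix(
        values=pd.DataFrame(rows, columns=fspec.column_names()),
        labels=np.array([rec.label] * len(active)),
        window_index=[(rid, l) for l in active],
    )
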