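"""Sample-entropy active-segment detection with adaptive threshold search.

Muscle-activity onset/offset is detected on the *sum* of the 9 channel
signals.  Each 512-sample analysis window gets a sample entropy (SampEn)
value; rest windows are near-regular relative to the whole-recording
tolerance ``r = r_coef * sigma`` (low SampEn) while movement windows are
complex (high SampEn).  A window is *active* when its SampEn reaches a
threshold ``Th``; a maximal run of active windows is an accepted segment
when its length ``L`` reaches a minimum ``L0 = windows_per_second * sec``.

Since no fixed ``Th`` generalizes across subjects and motions, the
threshold is chosen adaptively: a two-loop grid search over the minimum
duration ``sec`` (outer, 10 down to 1 s) and ``Th`` (inner, 0 to 2)
retains the settings that recover exactly the known number of repetitions
``n0`` while making the segments as long as possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError, SegmentationFailure
from .preprocess import WindowSpec, segment_windows, windows_per_second
from .recording import EmgRecording

__all__ = [
    "SampEnParams",
    "StateSeries",
    "ActiveSegment",
    "SearchResult",
    "sum_channels",
    "sample_entropy",
    "sampen_series",
    "state_function",
    "detect_segments",
    "optimal_threshold_search",
    "segment_recording",
]


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters.

    ``sigma`` is the standard deviation of the *entire* channel-sum
    sequence (not per window); the tolerance is ``r = r_coef * sigma``.
    The defaults m=2, r_coef=0.25 follow the usual empirical ranges
    (m in {1,2}, r in 0.15-0.25 sigma).
    """

    m: int = 2
    r_coef: float = 0.25
    sigma: float = 1.0

    def __post_init__(self):
        if self.m < 1:
            raise ParameterError("embedding dimension m must be >= 1")
        if self.r_coef <= 0:
            raise ParameterError("r_coef must be positive")
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")

    @property
    def r(self) -> float:
        return self.r_coef * self.sigma

    def with_sigma(self, sigma: float) -> "SampEnParams":
        return SampEnParams(self.m, self.r_coef, float(sigma))


@dataclass
class StateSeries:
    """Per-window SampEn values (NaN = undefined), binary states, threshold."""

    sampen: np.ndarray
    states: np.ndarray
    threshold: float


@dataclass(frozen=True)
class ActiveSegment:
    """Half-open run of active windows [l1, l2)."""

    l1: int
    l2: int

    def __post_init__(self):
        if self.l1 >= self.l2:
            raise ParameterError("require l1 < l2")

    @property
    def L(self) -> int:
        return self.l2 - self.l1

    def to_seconds(self, wspec: WindowSpec, fs: float) -> tuple[float, float]:
        """Time span covered by the run's windows."""
        step = wspec.step_samples(fs)
        length = wspec.length_samples(fs)
        return (self.l1 * step / fs, ((self.l2 - 1) * step + length) / fs)


@dataclass
class SearchResult:
    """Winning settings and segments of the adaptive threshold search."""

    segments: list[ActiveSegment]
    threshold: float
    sec: int
    L0: int

    @property
    def n(self) -> int:
        return len(self.segments)


def sum_channels(rec: EmgRecording) -> np.ndarray:
    """Pointwise sum of all channel signals (signed, no rectification)."""
    return rec.samples.sum(axis=0)


def sample_entropy(window: np.ndarray, params: SampEnParams) -> float:
    """SampEn(m, r, M) = -ln(A/B) of one analysis window.

    B counts ordered template pairs (i != j) of length m whose Chebyshev
    distance is strictly below r; A counts the same for length m+1.  Both
    use the same M-m templates so the counts are directly comparable.
    Returns NaN ("undefined") when either count is zero — e.g. a constant
    window, where sigma=0 forces r=0 and the strict inequality finds no
    matches.
    """
    window = np.asarray(window, dtype=float)
    m = params.m
    M = window.size
    if M <= m + 1:
        raise ParameterError(f"window of {M} samples too short for m={m}")
    r = params.r
    n_templ = M - m  # common template count for both embedding dimensions
    emb_m = np.lib.stride_tricks.sliding_window_view(window, m)[:n_templ]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(window, m + 1)[:n_templ]

    def pair_count(emb):
        d = cdist(emb, emb, "chebyshev")
        np.fill_diagonal(d, np.inf)  # exclude self-matches
        return int((d < r).sum())

    b = pair_count(emb_m)
    if b == 0:
        return math.nan
    a = pair_count(emb_m1)
    if a == 0:
        return math.nan
    return -math.log(a / b)


def sampen_series(
    channel_sum: np.ndarray,
    wspec: WindowSpec | None = None,
    fs: float = 2000.0,
    params: SampEnParams | None = None,
) -> np.ndarray:
    """SampEn of every analysis window of the channel-sum signal.

    The tolerance sigma is computed once from the entire sequence.
    """
    wspec = wspec or WindowSpec()
    params = (params or SampEnParams()).with_sigma(np.std(channel_sum))
    windows = segment_windows(channel_sum, wspec, fs)
    return np.array([sample_entropy(w, params) for w in windows])


def state_function(sampen: np.ndarray, threshold: float) -> StateSeries:
    """Binary activity state per window: 1 iff SampEn defined and >= Th."""
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    sampen = np.asarray(sampen, dtype=float)
    states = (~np.isnan(sampen)) & (sampen >= threshold)
    return StateSeries(sampen=sampen, states=states.astype(int), threshold=threshold)


def _runs(states: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as half-open [start, stop) pairs."""
    padded = np.concatenate([[0], np.asarray(states, dtype=int), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_segments(states, L0: int) -> list[ActiveSegment]:
    """Accepted active segments: runs of active windows with L >= L0.

    Shorter runs are rejected as noise.  ``states`` may be a StateSeries
    or a plain binary array.
    """
    if L0 < 1:
        raise ParameterError("L0 must be >= 1")
    if isinstance(states, StateSeries):
        states = states.states
    return [
        ActiveSegment(l1, l2) for l1, l2 in _runs(states) if l2 - l1 >= L0
    ]


def optimal_threshold_search(
    sampen: np.ndarray,
    n0: int = 5,
    th_grid_step: float = 0.01,
    windows_per_sec: int = 12,
    th_max: float = 2.0,
    sec_max: int = 10,
    objective: str = "stability",
) -> SearchResult:
    """Two-loop grid search for the (sec, Th) recovering exactly ``n0``
    segments.

    Outer loop: the minimum segment duration sec (1..sec_max, so
    ``L0 = windows_per_sec * sec``); inner loop: Th over
    {0, step, ..., th_max}.  Two objectives choose among the admissible
    (sec, Th) grid points:

    ``"stability"`` (default)
        The midpoint of the widest contiguous Th interval yielding
        exactly n0 segments; ties break toward larger sec, then lower
        Th.  The detection is then maximally robust to the threshold
        choice, and segments hug the complexity plateaus of genuine
        movement instead of absorbing rest-level fluctuations.

    ``"longest"``
        Largest sec first (descending), then maximal total active
        length, then smallest Th — the make-segments-as-long-as-possible
        reading.  Thresholds land at the bottom of the admissible range,
        which can pad segments with rest windows when the rest-complexity
        floor fluctuates.
    """
    if n0 < 1:
        raise ParameterError("n0 must be >= 1")
    if not (0 < th_grid_step <= 0.1):
        raise ParameterError("th_grid_step must be in (0, 0.1]")
    if objective not in ("stability", "longest"):
        raise ParameterError(f"unknown objective {objective!r}")
    sampen = np.asarray(sampen, dtype=float)
    thresholds = np.arange(0.0, th_max + th_grid_step / 2, th_grid_step)
    closest = None
    best = None
    for sec in range(sec_max, 0, -1):
        L0 = windows_per_sec * sec
        counts = []
        for th in thresholds:
            n = len(detect_segments(state_function(sampen, th), L0))
            counts.append(n)
            if closest is None or abs(n - n0) < abs(closest - n0):
                closest = n
        if objective == "longest":
            cand = None  # maximize (total_length, -Th)
            for th, n in zip(thresholds, counts):
                if n != n0:
                    continue
                segs = detect_segments(state_function(sampen, th), L0)
                key = (sum(s.L for s in segs), -th)
                if cand is None or key > cand[0]:
                    cand = (key, th, segs)
            if cand is not None:
                _, th, segs = cand
                return SearchResult(segments=segs, threshold=float(th),
                                    sec=sec, L0=L0)
        else:
            # widest contiguous run of admissible thresholds at this sec
            i = 0
            while i < len(counts):
                if counts[i] != n0:
                    i += 1
                    continue
                j = i
                while j + 1 < len(counts) and counts[j + 1] == n0:
                    j += 1
                width = j - i + 1
                mid = i + (width - 1) // 2
                # ties: wider wins; then larger sec (first seen); then lower Th
                if best is None or width > best[0]:
                    best = (width, sec, L0, float(thresholds[mid]))
                i = j + 1
    if best is not None:
        width, sec, L0, th = best
        segs = detect_segments(state_function(sampen, th), L0)
        return SearchResult(segments=segs, threshold=th, sec=sec, L0=L0)
    raise SegmentationFailure(
        f"no (sec, Th) on the grid yields {n0} active segments "
        f"(closest count found: {closest})",
        closest_n=closest,
    )


def segment_recording(
    rec: EmgRecording,
    wspec: WindowSpec | None = None,
    params: SampEnParams | None = None,
    n0: int = 5,
    th_grid_step: float = 0.01,
    objective: str = "stability",
) -> tuple[SearchResult, np.ndarray]:
    """Full detector on a preprocessed recording: channel sum, per-window
    SampEn, adaptive threshold search.  Returns (result, sampen series)."""
    wspec = wspec or WindowSpec()
    s = sum_channels(rec)
    sampen = sampen_series(s, wspec, rec.fs, params)
    wps = windows_per_second(wspec, rec.fs)
    result = optimal_threshold_search(
        sampen, n0=n0, th_grid_step=th_grid_step, windows_per_sec=wps,
        objective=objective,
    )
    return result, sampen
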