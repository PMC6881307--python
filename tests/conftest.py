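"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by the most naive
route available (explicit double loops, exhaustive enumeration, pair
counting) so the implementation is checked against code that shares
nothing with it.
"""

from __future__ import annotations

import numpy as np
import pytest

import emgtcd as E


# --------------------------------------------------------------------------
# independent oracles

def naive_sample_entropy(window, m, r):
    """O(M^2) double-loop SampEn: count ordered template pairs (i != j)
    of lengths m and m+1 within Chebyshev distance < r over the same
    M - m templates; -ln(A/B); NaN when either count is zero."""
    x = np.asarray(window, dtype=float)
    n = x.size - m
    b_count = a_count = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) < r:
                b_count += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a_count += 1
    if b_count == 0 or a_count == 0:
        return float("nan")
    return -np.log(a_count / b_count)


def naive_runs(states):
    """Exhaustive scan for maximal runs of 1s as (start, stop) pairs."""
    runs, start = [], None
    for i, s in enumerate(list(states) + [0]):
        if s and start is None:
            start = i
        elif not s and start is not None:
            runs.append((start, i))
            start = None
    return runs


def mann_whitney_auc(scores, positives):
    """AUC as the exhaustive pair-count P(score+ > score-) with ties = 1/2."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def burg_recursion(x, order):
    """Textbook Burg lattice recursion, returning coefficients in the
    x(k) = sum_j a_j x(k-j) + e(k) convention."""
    x = np.asarray(x, dtype=float)
    a = np.array([1.0])
    ef = x.copy()
    eb = x.copy()
    for m in range(1, order + 1):
        f = ef[m:]
        b = eb[m - 1:-1]
        k = -2.0 * np.dot(f, b) / (np.dot(f, f) + np.dot(b, b))
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([a, [0.0]])[::-1]
        ef_new = f + k * b
        eb_new = b + k * f
        ef = np.concatenate([ef[:m], ef_new])
        eb = np.concatenate([eb[:m], eb_new])
    return -a[1:]


# --------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def protocol():
    return E.SyntheticProtocol(seed=1)


@pytest.fixture(scope="session")
def fast_protocol():
    """Short trials (11 s) for tests that run the full pipeline often."""
    return E.SyntheticProtocol(seed=1, burst_s=1.0, rest_s=1.0)


@pytest.fixture(scope="session")
def dataset(protocol):
    """Default study conditions: 10 trials per class, seed 1."""
    return E.simulate_dataset(protocol, 10, seed=1)


@pytest.fixture(scope="session")
def dataset_features(dataset):
    """Denoised + segmented + featurized default dataset, computed once.

    Returns (feature matrix, {recording id: SearchResult}, ground truths
    keyed the same way).
    """
    cfg = E.PipelineConfig(seed=1)
    segments: dict = {}
    from emgtcd.pipeline import extract_dataset_features

    fm, skipped = extract_dataset_features(dataset, cfg, collect_segments=segments)
    truths = {
        f"{rec.subject_id or 'rec'}-{rec.label}-{i:03d}": truth
        for i, (rec, truth) in enumerate(dataset)
    }
    return fm, segments, truths, skipped


@pytest.fixture(scope="session")
def se_recording(protocol):
    rec, truth = E.simulate_recording(protocol, "SE", seed=7)
    return rec, truth


@pytest.fixture(scope="session")
def se_denoised(se_recording):
    rec, truth = se_recording
    return E.denoise(rec), truth
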