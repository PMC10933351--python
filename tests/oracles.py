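"""Brute-force reference implementations, kept deliberately naive.

These re-derive every decision with explicit Python loops, independent of
the package's vectorized code paths, and are the comparison standard for
the oracle-equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np


def brute_pre_cs_flags(trials, factor: float, scope: str = "session"):
    """IQR artifact filter recomputed with explicit loops."""
    pre = []
    for t in trials:
        n_pre = int(math.floor(500.0 * t.sample_rate_hz / 1000.0))
        pre.append(list(t.samples[t.cs_onset_index - n_pre : t.cs_onset_index]))
    if scope == "session":
        pooled = [v for seg in pre for v in seg]
        q1 = np.percentile(pooled, 25)
        q3 = np.percentile(pooled, 75)
        iqrs = [q3 - q1] * len(trials)
    else:
        iqrs = [
            np.percentile(seg, 75) - np.percentile(seg, 25) for seg in pre
        ]
    flags = []
    for seg, iqr in zip(pre, iqrs):
        med = np.median(seg)
        stat = max(abs(v - med) for v in seg)
        if math.isinf(factor):
            flags.append(False)
        else:
            flags.append(stat > factor * iqr)
    return flags


def brute_detect(
    trial,
    amplitude_threshold: float = 0.1,
    onset_window=(50.0, 500.0),
    peak_window=(100.0, 1000.0),
    onset_threshold: float = 0.05,
):
    """CR detection by explicit scan over samples and windows."""
    rate = trial.sample_rate_hz
    cs = trial.cs_onset_index
    lo = cs + int(math.floor(peak_window[0] * rate / 1000.0))
    hi = cs + int(math.floor(peak_window[1] * rate / 1000.0))
    best_i, best_v = lo, trial.samples[lo]
    for i in range(lo, hi + 1):
        if trial.samples[i] > best_v:
            best_i, best_v = i, trial.samples[i]
    peak_ms = (best_i - cs) * 1000.0 / rate
    amp = float(best_v)

    onset_ms = None
    if trial.samples[best_i] > onset_threshold:
        i = best_i
        while i > cs and trial.samples[i - 1] > onset_threshold:
            i -= 1
        onset_ms = (i - cs) * 1000.0 / rate

    is_cr = (
        amp > amplitude_threshold
        and onset_ms is not None
        and onset_window[0] <= onset_ms <= onset_window[1]
        and peak_window[0] <= peak_ms <= peak_window[1]
    )
    return is_cr, onset_ms, peak_ms, amp


def brute_perfect(peak_ms: float, isi: int, windows=None) -> bool:
    w = (windows or {250: 50.0, 500: 100.0})[isi]
    return isi - w <= peak_ms <= isi + w


def brute_holm(pvalues):
    """Step-down Holm adjustment from its textbook definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running_max = 0.0
    for rank, i in enumerate(order):
        val = (m - rank) * pvalues[i]
        running_max = max(running_max, val)
        adj[i] = min(1.0, running_max)
    return adj


def brute_ladder(run, rule: str = "landing") -> float:
    heights = []
    for paw, h in run.steps:
        if paw.value in ("front_left", "front_right"):
            heights.append(h.value)
    if len(heights) < 2:
        return float("nan")
    correct = 0
    total = 0
    for k in range(1, len(heights)):
        total += 1
        if rule == "landing":
            if heights[k] == "high":
                correct += 1
        else:
            if heights[k] == "high" and heights[k - 1] == "high":
                correct += 1
    return 100.0 * correct / total
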