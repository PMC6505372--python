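"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with plain Python loops and the stdlib
``statistics`` module, deliberately avoiding the code paths (and the numpy
idioms) of the package itself.
"""

from __future__ import annotations

import statistics


def bland_altman_brute(pairs: list[tuple[float, float]]) -> tuple[float, float, float, float]:
    """(bias, sd, loa_low, loa_high) from (reference, tracker) pairs."""
    diffs = [ref - trk for ref, trk in pairs]
    bias = statistics.mean(diffs)
    sd = statistics.stdev(diffs)  # n-1 denominator
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def mad_brute(pairs: list[tuple[float, float]]) -> float:
    """Median absolute relative difference in percent."""
    rel = sorted(abs(trk - ref) / ref for ref, trk in pairs)
    n = len(rel)
    if n % 2 == 1:
        med = rel[n // 2]
    else:
        med = (rel[n // 2 - 1] + rel[n // 2]) / 2
    return med * 100.0


def loocv_brute(pairs: list[tuple[float, float]]) -> tuple[float, list[float]]:
    """Corrected MAD%% and per-fold biases via explicit hold-one-out loops."""
    corrected = []
    per_fold = []
    for i, (ref_i, trk_i) in enumerate(pairs):
        train = [(r, t) for j, (r, t) in enumerate(pairs) if j != i]
        b = statistics.mean(r - t for r, t in train)
        per_fold.append(b)
        corrected.append((ref_i, trk_i + b))
    return mad_brute(corrected), per_fold


def zero_runs_brute(steps: list[int], threshold: int) -> list[tuple[int, int]]:
    """[start, end) index ranges of maximal zero runs of length >= threshold."""
    runs = []
    i = 0
    while i < len(steps):
        if steps[i] == 0:
            j = i
            while j < len(steps) and steps[j] == 0:
                j += 1
            if j - i >= threshold:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def overlap_minutes_brute(
    epoch: tuple[int, int], worn: list[tuple[int, int]]
) -> int:
    """Minutes of an [start, start+dur) epoch inside worn [a, b) intervals."""
    start, dur = epoch
    count = 0
    for m in range(start, start + dur):
        if any(a <= m < b for a, b in worn):
            count += 1
    return count
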