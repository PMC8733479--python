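"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: peak detection is a naive
O(n^2) scan and the cutoff rule is re-derived directly from its definition.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np


def naive_local_maxima(values: Sequence[float]) -> List[int]:
    """Interior local maxima; leftmost sample of a flat plateau."""
    v = list(values)
    n = len(v)
    out = []
    for i in range(1, n - 1):
        if v[i] <= v[i - 1]:
            continue
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j + 1 < n and v[j + 1] < v[i]:
            out.append(i)
    return out


def naive_prominence(values: Sequence[float], peak: int) -> float:
    """Topographic prominence: walk out from the peak on each side until a
    strictly higher sample or the signal border; the base on each side is the
    minimum over that walk, and prominence is peak minus the higher base."""
    v = list(values)
    left_min = v[peak]
    i = peak - 1
    while i >= 0 and v[i] <= v[peak]:
        left_min = min(left_min, v[i])
        i -= 1
    right_min = v[peak]
    i = peak + 1
    while i < len(v) and v[i] <= v[peak]:
        right_min = min(right_min, v[i])
        i += 1
    return v[peak] - max(left_min, right_min)


def brute_force_peaks(
    values: Sequence[float], threshold: float, mode: str = "prominence"
) -> List[int]:
    """Exhaustive local-maximum scan followed by the amplitude correction."""
    kept = []
    for p in naive_local_maxima(values):
        crit = naive_prominence(values, p) if mode == "prominence" else values[p]
        if crit >= threshold:
            kept.append(p)
    return kept


def one_fourth_rule(freqs: Sequence[float], mags: Sequence[float]) -> float:
    """Highest frequency among peaks with magnitude >= max(magnitude) / 4."""
    freqs = np.asarray(freqs, float)
    mags = np.asarray(mags, float)
    reference = mags.max()
    return float(freqs[mags >= reference / 4.0].max())
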