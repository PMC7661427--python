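"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from advlfd import LengthFrequency


def make_lfd(counts, start=1, origin=0, width=1, label=""):
    """Dense LFD from a plain count list, classes start..start+len-1."""
    counts = list(counts)
    classes = np.arange(start, start + len(counts) * width, width, dtype=np.int64)
    return LengthFrequency(classes, np.array(counts, dtype=np.int64), origin, width, label)


@pytest.fixture
def toy_alternating():
    """The worked 5-class sample with alternating peaks: [5,1,5,1,5] on 1..5."""
    return make_lfd([5, 1, 5, 1, 5])


# ---------------------------------------------------------------------------
# Independent oracle: a literal, per-class enumeration of the robust
# critical-point definition, deliberately written without the package's
# plateau-run machinery so the two routes can disagree.
# ---------------------------------------------------------------------------

def oracle_extrema(counts):
    """Indices of modes / interior antimodes by scanning each class."""
    n = len(counts)
    modes, antis = [], []
    for j in range(n):
        v = counts[j]
        if j > 0 and counts[j - 1] == v:
            continue  # not the first class of a run of equal values
        k = j - 1
        while k >= 0 and counts[k] == v:
            k -= 1
        left = counts[k] if k >= 0 else None
        k = j + 1
        while k < n and counts[k] == v:
            k += 1
        right = counts[k] if k < n else None
        lpad = 0 if left is None else left
        rpad = 0 if right is None else right
        if v > lpad and v > rpad and v > 0:
            modes.append(j)
        if left is not None and right is not None and v < left and v < right:
            antis.append(j)
    return modes, antis


def oracle_robust(classes, counts, delta, origin=0):
    """Literal enumeration of bandwidth-robust modes and antimodes.

    Returns (mode_labels, antimode_labels) as sorted lists.
    """
    classes = [int(c) for c in classes]
    counts = [int(c) for c in counts]
    modes, antis = oracle_extrema(counts)

    smooth: dict[int, int] = {}
    for c, n in zip(classes, counts):
        b = origin + ((c - origin) // delta) * delta
        smooth[b] = smooth.get(b, 0) + n
    bins = sorted(smooth)
    sm_modes, sm_antis = oracle_extrema([smooth[b] for b in bins])
    mode_bins = {bins[i] for i in sm_modes}
    anti_bins = {bins[i] for i in sm_antis}

    def bin_of(label):
        return origin + ((label - origin) // delta) * delta

    robust_modes = []
    for j in modes:
        b = bin_of(classes[j])
        if b not in mode_bins:
            continue
        in_bin = [k for k in modes if bin_of(classes[k]) == b]
        best = max(counts[k] for k in in_bin)
        chosen = min(k for k in in_bin if counts[k] == best)
        if j == chosen:
            robust_modes.append(j)
    fmax = max((counts[k] for k in modes), default=0)
    robust_modes = [j for j in robust_modes if counts[j] > 0.01 * fmax]

    robust_antis = []
    for j in antis:
        b = bin_of(classes[j])
        if b not in anti_bins:
            continue
        in_bin = [k for k in antis if bin_of(classes[k]) == b]
        best = min(counts[k] for k in in_bin)
        chosen = min(k for k in in_bin if counts[k] == best)
        if j == chosen:
            robust_antis.append(j)

    return sorted(classes[j] for j in robust_modes), sorted(
        classes[j] for j in robust_antis
    )
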