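"""Modes, antimodes, and bandwidth-robust critical points of an LFD.

A length class is a *mode* when its adjacent classes carry strictly lower
counts, and an *antimode* when they carry strictly higher counts.  In a
well-sampled LFD the modes mark year classes (cohorts) and the antimodes
the boundaries between them, but at 1-cm resolution many extrema are
sampling artefacts.  A critical point is *robust* when it survives
smoothing: its 1-cm class must fall inside a bandwidth-``delta`` bin that
is itself an extremum of the smoothed histogram, and it must dominate any
other 1-cm extremum of the same kind inside that bin.  Modes with
negligible frequency (at most 1% of the highest 1-cm mode) are additionally
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lfd import ImportantRange, LengthFrequency, rebin, restrict

__all__ = ["CriticalPoints", "local_extrema", "robust_critical_points"]

MODE_FREQUENCY_FRACTION = 0.01


@dataclass(frozen=True)
class CriticalPoints:
    """Robust modes/antimodes of an LFD and their sorted merge.

    ``merged`` interleaves both sets in ascending class order, tagging each
    entry ``"mode"`` or ``"antimode"``; ``amplitudes_at`` maps each critical
    class to its raised count in the (range-restricted) 1-cm histogram.
    """

    modes: tuple[int, ...]
    antimodes: tuple[int, ...]
    merged: tuple[tuple[int, str], ...]
    amplitudes_at: dict[int, int]

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(lab for lab, _ in self.merged)

    @staticmethod
    def build(modes, antimodes, amplitudes_at) -> "CriticalPoints":
        modes = tuple(sorted(int(m) for m in modes))
        antimodes = tuple(sorted(int(a) for a in antimodes))
        if set(modes) & set(antimodes):
            raise ValueError("modes and antimodes must be disjoint")
        merged = tuple(
            sorted(
                [(m, "mode") for m in modes] + [(a, "antimode") for a in antimodes]
            )
        )
        return CriticalPoints(modes, antimodes, merged, dict(amplitudes_at))


def _plateau_extrema(counts: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of local maxima / interior local minima, plateau-aware.

    The grid is conceptually padded with zero outside, so a boundary class
    can be a mode; antimodes are interior-only (zero padding would make
    every boundary a spurious minimum).  For a run of equal values the
    first (lowest) index represents the run.
    """
    n = len(counts)
    modes: list[int] = []
    antis: list[int] = []
    i = 0
    while i < n:
        j = i
        v = counts[i]
        while j + 1 < n and counts[j + 1] == v:
            j += 1
        left = counts[i - 1] if i > 0 else None
        right = counts[j + 1] if j + 1 < n else None
        lpad = 0 if left is None else left
        rpad = 0 if right is None else right
        if v > lpad and v > rpad and v > 0:
            modes.append(i)
        if left is not None and right is not None and v < left and v < right:
            antis.append(i)
        i = j + 1
    return modes, antis


def local_extrema(lfd: LengthFrequency) -> tuple[list[int], list[int]]:
    """1-cm (or native-width) modes and antimodes of an LFD, as class labels."""
    if lfd.is_empty:
        return [], []
    m_idx, a_idx = _plateau_extrema(lfd.counts)
    return [int(lfd.classes[i]) for i in m_idx], [int(lfd.classes[i]) for i in a_idx]


def robust_critical_points(
    lfd: LengthFrequency,
    delta: int,
    rng: ImportantRange | None = None,
) -> CriticalPoints:
    """Critical points that persist under bandwidth-``delta`` smoothing.

    Procedure on the range-restricted histogram:

    1. find 1-cm modes/antimodes;
    2. rebin with bandwidth ``delta`` and find the smoothed extrema;
    3. a 1-cm mode is robust iff its ``delta``-bin is a smoothed mode and it
       carries the maximal frequency among the 1-cm modes in that bin (ties
       broken toward the smallest class); antimodes symmetrically with the
       minimal frequency;
    4. drop modes whose frequency is <= 1% of the highest 1-cm mode
       frequency (no analogous filter for antimodes).

    A smoothed extremum bin containing no 1-cm extremum of the matching
    kind contributes nothing — points are never synthesized.
    """
    r = restrict(lfd, rng)
    if r.is_empty:
        return CriticalPoints.build((), (), {})
    modes1, antis1 = _plateau_extrema(r.counts)
    labels = r.classes
    counts = r.counts

    smoothed = rebin(r, delta)
    sm_idx, sa_idx = _plateau_extrema(smoothed.counts)
    smode_bins = {int(smoothed.classes[i]) for i in sm_idx}
    santi_bins = {int(smoothed.classes[i]) for i in sa_idx}

    origin = r.origin
    bin_of = origin + ((labels - origin) // delta) * delta

    def _select(idx_list: list[int], target_bins: set[int], maximal: bool) -> list[int]:
        by_bin: dict[int, list[int]] = {}
        for i in idx_list:
            b = int(bin_of[i])
            if b in target_bins:
                by_bin.setdefault(b, []).append(i)
        chosen: list[int] = []
        for b, cands in by_bin.items():
            key = (max if maximal else min)(counts[i] for i in cands)
            # ties -> smallest class: candidate lists are in ascending order
            best = next(i for i in cands if counts[i] == key)
            chosen.append(best)
        return sorted(chosen)

    rob_modes = _select(modes1, smode_bins, maximal=True)
    rob_antis = _select(antis1, santi_bins, maximal=False)

    if modes1:
        fmax = max(counts[i] for i in modes1)
        rob_modes = [i for i in rob_modes if counts[i] > MODE_FREQUENCY_FRACTION * fmax]

    amplitudes = {int(labels[i]): int(counts[i]) for i in rob_modes + rob_antis}
    return CriticalPoints.build(
        [int(labels[i]) for i in rob_modes],
        [int(labels[i]) for i in rob_antis],
        amplitudes,
    )
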