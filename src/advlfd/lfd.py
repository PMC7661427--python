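"""Length-frequency distributions (LFDs) on an integer class grid.

A length-frequency distribution is a histogram of fish counts per length
class.  Commercial catch-sampling databases record length rounded to 1 cm,
so the natural carrier is a dense grid of integer class lower bounds with
nonnegative integer counts.  The grid is *dense*: interior classes with zero
fish are stored explicitly, because a gap between two year-class peaks is an
antimode and must be visible to the mode-detection machinery.

Bins are half-open ``[origin + k*w, origin + (k+1)*w)`` and labelled by
their lower bound.  The bin origin is fixed at zero by default so that the
histogram shape is fully determined by the bandwidth alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmptyRangeError",
    "ImportantRange",
    "LengthFrequency",
    "EmpiricalCDF",
    "build_lfd",
    "rebin",
    "restrict",
    "cdf",
]


class EmptyRangeError(ValueError):
    """Raised when an operation needs mass inside the important range and finds none."""


@dataclass(frozen=True)
class ImportantRange:
    """Closed interval ``[low, high]`` of 1-cm class labels the analysis focuses on.

    Everything downstream — CDFs, critical points, the dissimilarity D — is
    evaluated only on classes inside this interval, so that uninformative
    tails (very small or very large fish) can be excluded.
    """

    low: int
    high: int

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"invalid range: low {self.low} > high {self.high}")

    def contains(self, label: int) -> bool:
        return self.low <= label <= self.high


@dataclass
class LengthFrequency:
    """Dense histogram of raised fish counts per length class.

    Parameters
    ----------
    classes
        Ascending, contiguous class lower bounds (step ``class_width``),
        each congruent to ``origin`` modulo ``class_width``.
    counts
        Nonnegative integer counts, one per class.  Leading/trailing
        zero-count classes are trimmed at construction; interior zeros are
        kept.
    origin
        Lower bound of the global bin grid (default 0 cm).
    class_width
        Bin width in cm (integer >= 1).
    """

    classes: np.ndarray
    counts: np.ndarray
    origin: int = 0
    class_width: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.classes.shape != self.counts.shape or self.classes.ndim != 1:
            raise ValueError("classes and counts must be 1-d arrays of equal length")
        if self.class_width < 1:
            raise ValueError("class_width must be a positive integer")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        # canonical form: trim outer zero classes so the grid runs from the
        # first to the last nonzero class
        nz = np.flatnonzero(self.counts)
        if nz.size == 0:
            self.classes = self.classes[:0]
            self.counts = self.counts[:0]
            return
        self.classes = self.classes[nz[0] : nz[-1] + 1]
        self.counts = self.counts[nz[0] : nz[-1] + 1]
        w = self.class_width
        if np.any(np.diff(self.classes) != w):
            raise ValueError("class grid must be contiguous with step class_width")
        if (int(self.classes[0]) - self.origin) % w != 0:
            raise ValueError("classes must align with the bin origin")

    # -- basic queries -------------------------------------------------
    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.classes.size == 0

    def to_dict(self) -> dict[int, int]:
        return {int(c): int(n) for c, n in zip(self.classes, self.counts)}

    def count_at(self, label: int) -> int:
        if self.is_empty or not (self.classes[0] <= label <= self.classes[-1]):
            return 0
        idx = (label - int(self.classes[0])) // self.class_width
        return int(self.counts[idx])

    def __eq__(self, other: object) -> bool:  # dataclass default breaks on arrays
        if not isinstance(other, LengthFrequency):
            return NotImplemented
        return (
            self.origin == other.origin
            and self.class_width == other.class_width
            and np.array_equal(self.classes, other.classes)
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class EmpiricalCDF:
    """Empirical CDF of an LFD over the important length classes.

    ``values[j]`` is the cumulative share of fish at classes ``<= classes[j]``
    inside the range; the final value is exactly 1 whenever ``total > 0``.
    """

    classes: np.ndarray
    values: np.ndarray
    total: int

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.classes.shape != self.values.shape:
            raise ValueError("classes and values must have equal length")
        if self.values.size:
            if np.any(np.diff(self.values) < -1e-12):
                raise ValueError("CDF values must be nondecreasing")
            if self.total > 0 and not math.isclose(self.values[-1], 1.0, abs_tol=1e-9):
                raise ValueError("final CDF value must be 1 for nonempty input")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (RDB convention)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def build_lfd(
    lengths,
    class_width: int = 1,
    origin: int = 0,
    label: str = "",
) -> LengthFrequency:
    """Tally raw length measurements (cm) into a dense LFD.

    Non-integer lengths are rounded to the nearest cm (ties away from zero)
    before binning.  An empty input yields an empty LFD with total 0.
    """
    arr = np.asarray(lengths, dtype=np.float64)
    if arr.size == 0:
        return LengthFrequency(np.empty(0, np.int64), np.empty(0, np.int64), origin, class_width, label)
    if np.any(arr < 0):
        bad = float(arr[arr < 0][0])
        raise ValueError(f"negative length {bad} cm is not a valid measurement")
    rounded = _round_half_away(arr).astype(np.int64)
    if np.any(rounded < origin):
        raise ValueError("length below the bin origin")
    bins = origin + ((rounded - origin) // class_width) * class_width
    lo, hi = int(bins.min()), int(bins.max())
    grid = np.arange(lo, hi + class_width, class_width, dtype=np.int64)
    counts = np.bincount((bins - lo) // class_width, minlength=grid.size)
    return LengthFrequency(grid, counts, origin, class_width, label)


def rebin(lfd: LengthFrequency, delta: int) -> LengthFrequency:
    """Smooth an LFD by re-binning into bandwidth-``delta`` classes.

    The coarse bins ``[origin + k*delta, origin + (k+1)*delta)`` are anchored
    at the same origin, so widening the bandwidth acts as a smoothing
    parameter while conserving the total count.
    """
    if delta < lfd.class_width or delta % lfd.class_width != 0:
        raise ValueError(
            f"delta {delta} must be a multiple of class_width {lfd.class_width}"
        )
    if delta == lfd.class_width:
        return LengthFrequency(
            lfd.classes.copy(), lfd.counts.copy(), lfd.origin, lfd.class_width, lfd.label
        )
    if lfd.is_empty:
        return LengthFrequency(np.empty(0, np.int64), np.empty(0, np.int64), lfd.origin, delta, lfd.label)
    bins = lfd.origin + ((lfd.classes - lfd.origin) // delta) * delta
    lo, hi = int(bins[0]), int(bins[-1])
    grid = np.arange(lo, hi + delta, delta, dtype=np.int64)
    counts = np.zeros(grid.size, dtype=np.int64)
    np.add.at(counts, (bins - lo) // delta, lfd.counts)
    return LengthFrequency(grid, counts, lfd.origin, delta, lfd.label)


def restrict(lfd: LengthFrequency, rng: ImportantRange | None) -> LengthFrequency:
    """Drop classes outside the important range (interior grid preserved)."""
    if rng is None or lfd.is_empty:
        return lfd
    keep = (lfd.classes >= rng.low) & (lfd.classes <= rng.high)
    return LengthFrequency(
        lfd.classes[keep], lfd.counts[keep], lfd.origin, lfd.class_width, lfd.label
    )


def cdf(lfd: LengthFrequency, rng: ImportantRange | None = None) -> EmpiricalCDF:
    """Empirical CDF of ``lfd`` on the important range.

    ``F(l_j) = sum_{k<=j} f(l_k) / f_bar`` with the normalizer ``f_bar``
    summed over the range only.
    """
    r = restrict(lfd, rng)
    total = r.total
    if total == 0:
        raise EmptyRangeError("no mass in important range")
    values = np.cumsum(r.counts) / total
    values[-1] = 1.0  # exact despite float division
    return EmpiricalCDF(r.classes.copy(), values, total)
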