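"""Penalized L1 dissimilarity between an original sample and a subsample.

The core measure is

    D(S0, Sn) = L1(F, G)
              + c1 * 1{critical-point counts differ}
              + c2 * sum_i max(0, |shift_i| - epsilon)     (counts equal)
              + c3 * sum_i max(0, theta - amplitude_ratio_i)  (counts equal)

where ``F`` and ``G`` are the empirical CDFs of the original sample and the
subsample over the important length classes, and the three penalty terms
punish violations of the similarity conditions:

1. the subsample must show the same number of robust modes and of robust
   antimodes as the original;
2. each corresponding critical point may shift by at most ``epsilon`` cm;
3. the amplitude difference between consecutive critical points must be
   preserved at a fraction of at least ``theta`` of the original one.

``c1 > c2 > c3`` impose a hierarchy of violations (defaults 10, 2, 1: a
changed modal structure is worst).  When all three conditions hold, D
reduces to the plain L1 distance — the area between the two CDFs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .critical import CriticalPoints, robust_critical_points
from .lfd import EmpiricalCDF, ImportantRange, LengthFrequency, cdf, restrict

__all__ = [
    "GammaSpec",
    "AlgorithmParams",
    "DissimilarityResult",
    "ConditionReport",
    "lp_distance",
    "aligned_cdfs",
    "check_conditions",
    "dissimilarity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GammaSpec:
    """Per-class floor on counts the iterative subsampler may not cross.

    gamma reflects managerial sampling requirements (e.g. a minimum number
    of fish per length class for ageing).  Modes:

    - ``"zero"`` — no floor, classes may be emptied;
    - ``"absolute"`` — ``min(value, n_j)`` fish per class;
    - ``"fraction"`` — smallest integer >= ``value * n_j``;
    - ``"survey_default"`` — 20% of the class count, but classes with fewer
      than 5 fish are frozen entirely.
    """

    mode: str = "zero"
    value: float = 0.0

    _MODES = ("zero", "absolute", "fraction", "survey_default")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown gamma mode {self.mode!r}")
        if self.mode == "absolute" and (self.value < 0 or self.value != int(self.value)):
            raise ValueError("absolute gamma must be a nonnegative integer")
        if self.mode == "fraction" and not (0 <= self.value < 1):
            raise ValueError("fractional gamma must lie in [0, 1)")

    @staticmethod
    def zero() -> "GammaSpec":
        return GammaSpec("zero", 0.0)

    @staticmethod
    def absolute(n: int) -> "GammaSpec":
        return GammaSpec("absolute", float(n))

    @staticmethod
    def fraction(q: float) -> "GammaSpec":
        return GammaSpec("fraction", q)

    @staticmethod
    def survey_default() -> "GammaSpec":
        return GammaSpec("survey_default", 0.2)

    def floor_for(self, n_j: int) -> int:
        if self.mode == "zero":
            return 0
        if self.mode == "absolute":
            return min(int(self.value), n_j)
        if self.mode == "fraction":
            return math.ceil(self.value * n_j)
        # survey_default: freeze sparse classes, else 20% floor
        return n_j if n_j < 5 else math.ceil(0.2 * n_j)


@dataclass(frozen=True)
class AlgorithmParams:
    """Tunable parameters of the similarity framework.

    ``delta`` (cm) is the smoothing bandwidth deciding robustness of
    critical points; ``theta`` in (0, 1] the minimum preserved amplitude
    ratio; ``epsilon`` (cm) the allowed shift of a critical point;
    ``gamma`` the per-class subsampling floor; ``length_range`` the
    important classes (``None`` = every class of the original sample).
    ``amplitude_mode`` selects how amplitudes at critical points are read:
    ``"pointwise"`` uses the raised count at the critical class,
    ``"cdf_mass"`` the total mass between consecutive critical points.
    """

    delta: int = 5
    theta: float = 0.9
    epsilon: int = 0
    gamma: GammaSpec = field(default_factory=GammaSpec.zero)
    length_range: ImportantRange | None = None
    c1: float = 10.0
    c2: float = 2.0
    c3: float = 1.0
    amplitude_mode: str = "pointwise"
    p: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.theta <= 1):
            raise ValueError("theta must lie in (0, 1]")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.p < 1:
            raise ValueError("Minkowski order p must be >= 1")
        if min(self.c1, self.c2, self.c3) < 0:
            raise ValueError("penalty constants must be nonnegative")
        if self.amplitude_mode not in ("pointwise", "cdf_mass"):
            raise ValueError(f"unknown amplitude_mode {self.amplitude_mode!r}")


@dataclass
class ConditionReport:
    """Outcome of the three similarity conditions plus diagnostics."""

    counts_equal: bool
    shifts_ok: bool
    amplitudes_ok: bool
    orig_points: CriticalPoints
    sub_points: CriticalPoints
    shifts: list[int]
    amplitude_ratios: list[float]
    skipped_pairs: list[int]

    @property
    def flags(self) -> tuple[bool, bool, bool]:
        return (self.counts_equal, self.shifts_ok, self.amplitudes_ok)

    @property
    def all_ok(self) -> bool:
        return all(self.flags)


@dataclass
class DissimilarityResult:
    """Decomposition of the penalized distance D."""

    l1: float
    penalty_dim: float
    penalty_shift: float
    penalty_amplitude: float
    total_D: float
    condition_flags: tuple[bool, bool, bool]
    paired_points: list[tuple[int | None, int | None]]

    @property
    def conditions_hold(self) -> bool:
        return all(self.condition_flags)


def lp_distance(F: EmpiricalCDF, G: EmpiricalCDF, p: float = 1.0) -> float:
    """Minkowski distance of order ``p`` between two CDFs on one grid.

    With ``p = 1`` this is the Manhattan / 1-Wasserstein distance — the
    area between the two step CDFs measured class by class.
    """
    if not np.array_equal(F.classes, G.classes):
        raise ValueError("CDFs are defined on different class grids; align them first")
    diffs = np.abs(F.values - G.values)
    if p == 1.0:
        return float(diffs.sum())
    return float((diffs**p).sum() ** (1.0 / p))


def aligned_cdfs(
    orig: LengthFrequency,
    sub: LengthFrequency,
    rng: ImportantRange | None = None,
) -> tuple[EmpiricalCDF, EmpiricalCDF]:
    """Empirical CDFs of two samples on their dense union grid within ``rng``.

    Classes where one sample has no mass carry its cumulative value
    forward, so both CDFs share one grid and are directly comparable.
    """
    ro, rs = restrict(orig, rng), restrict(sub, rng)
    Fo, Fs = cdf(ro), cdf(rs)
    lo = int(min(Fo.classes[0], Fs.classes[0]))
    hi = int(max(Fo.classes[-1], Fs.classes[-1]))
    w = orig.class_width
    grid = np.arange(lo, hi + w, w, dtype=np.int64)

    def _on_grid(F: EmpiricalCDF) -> np.ndarray:
        idx = np.searchsorted(F.classes, grid, side="right") - 1
        vals = np.where(idx >= 0, F.values[np.clip(idx, 0, None)], 0.0)
        return vals

    return (
        EmpiricalCDF(grid, _on_grid(Fo), Fo.total),
        EmpiricalCDF(grid.copy(), _on_grid(Fs), Fs.total),
    )


def _amplitude_vector(
    points: CriticalPoints, lfd_restricted: LengthFrequency, mode: str
) -> np.ndarray:
    """Amplitudes at the merged critical points, per the chosen convention."""
    labels = points.labels
    if mode == "pointwise":
        return np.array([points.amplitudes_at[lab] for lab in labels], dtype=np.float64)
    # cdf_mass: mass accumulated since the previous critical point
    cum = np.cumsum(lfd_restricted.counts)
    pos = np.searchsorted(lfd_restricted.classes, labels, side="right") - 1
    masses = []
    prev = 0.0
    for k in pos:
        c = float(cum[k]) if k >= 0 else 0.0
        masses.append(c - prev)
        prev = c
    return np.array(masses, dtype=np.float64)


def check_conditions(
    orig: LengthFrequency,
    sub: LengthFrequency,
    params: AlgorithmParams,
    orig_points: CriticalPoints | None = None,
) -> ConditionReport:
    """Evaluate the three similarity conditions of ``sub`` against ``orig``.

    Condition (1) compares the number of robust modes and of robust
    antimodes.  Condition (2) pairs critical points index-wise within type
    (modes with modes, antimodes with antimodes, in ascending order) and
    requires every shift to stay within ``epsilon``.  Condition (3) walks
    the merged (sorted) sequences and requires the amplitude difference of
    every consecutive pair in the subsample to reach at least ``theta``
    times the original difference.  Conditions (2)-(3) are evaluated only
    when (1) holds.  Pairs whose original amplitude difference is zero have
    an undefined ratio and are skipped with a warning.
    """
    rng = params.length_range
    ro, rs = restrict(orig, rng), restrict(sub, rng)
    V = orig_points if orig_points is not None else robust_critical_points(ro, params.delta)
    v = robust_critical_points(rs, params.delta)

    counts_equal = len(V.modes) == len(v.modes) and len(V.antimodes) == len(v.antimodes)
    shifts: list[int] = []
    ratios: list[float] = []
    skipped: list[int] = []
    shifts_ok = amplitudes_ok = True

    if counts_equal:
        shifts = [abs(a - b) for a, b in zip(v.modes, V.modes)]
        shifts += [abs(a - b) for a, b in zip(v.antimodes, V.antimodes)]
        shifts_ok = all(s <= params.epsilon for s in shifts)

        amp_V = _amplitude_vector(V, ro, params.amplitude_mode)
        amp_v = _amplitude_vector(v, rs, params.amplitude_mode)
        for i in range(1, len(amp_V)):
            den = abs(amp_V[i] - amp_V[i - 1])
            if den == 0:
                skipped.append(i)
                logger.warning(
                    "amplitude ratio undefined for pair %d (zero original difference); skipped",
                    i,
                )
                continue
            ratios.append(abs(amp_v[i] - amp_v[i - 1]) / den)
        amplitudes_ok = all(r >= params.theta for r in ratios)

    return ConditionReport(
        counts_equal, shifts_ok, amplitudes_ok, V, v, shifts, ratios, skipped
    )


def dissimilarity(
    orig: LengthFrequency,
    sub: LengthFrequency,
    params: AlgorithmParams,
    orig_points: CriticalPoints | None = None,
) -> DissimilarityResult:
    """Penalized distance D between a sample and a candidate subsample.

    ``D = 0`` iff the subsample equals the original on the important range;
    ``D`` equals the plain L1 CDF distance iff all three similarity
    conditions hold.
    """
    report = check_conditions(orig, sub, params, orig_points=orig_points)
    F, G = aligned_cdfs(orig, sub, params.length_range)
    l1 = lp_distance(F, G, params.p)

    if not report.counts_equal:
        pen_dim, pen_shift, pen_amp = params.c1, 0.0, 0.0
        paired: list[tuple[int | None, int | None]] = []
    else:
        pen_dim = 0.0
        pen_shift = params.c2 * sum(max(0, s - params.epsilon) for s in report.shifts)
        pen_amp = params.c3 * sum(max(0.0, params.theta - r) for r in report.amplitude_ratios)
        paired = list(zip(report.orig_points.labels, report.sub_points.labels))

    total = l1 + pen_dim + pen_shift + pen_amp
    return DissimilarityResult(
        l1=l1,
        penalty_dim=pen_dim,
        penalty_shift=pen_shift,
        penalty_amplitude=pen_amp,
        total_D=total,
        condition_flags=report.flags,
        paired_points=paired,
    )
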