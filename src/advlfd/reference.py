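"""Reference subsample, ADV, and the deterministic iterative subsampler.

The *reference subsample* is the theoretical minimal subsample that still
satisfies the similarity conditions against the original sample: one fish
is removed from every important length class per iteration (never below a
per-class floor gamma), and the loop stops at the first candidate that
breaks a condition, reverting to the previous state.  The L1 CDF distance
between the original sample and the reference subsample is the *admissible
dissimilarity value* (ADV): any candidate subsample with ``D <= ADV`` is
considered representative of the original.

The procedure is fully deterministic — a random elimination could produce
a subsample that already violates the conditions while still being far
from minimal, which would make a poor benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .critical import CriticalPoints, robust_critical_points
from .dissimilarity import (
    AlgorithmParams,
    DissimilarityResult,
    aligned_cdfs,
    check_conditions,
    dissimilarity,
    lp_distance,
)
from .lfd import EmptyRangeError, ImportantRange, LengthFrequency, restrict

__all__ = [
    "IterationRecord",
    "ReferenceResult",
    "class_floors",
    "reference_subsample",
    "adv",
    "is_admissible",
]

STOP_REASONS = (
    "mode_count_changed",
    "shift_exceeded",
    "amplitude_ratio",
    "all_classes_at_floor",
)


@dataclass(frozen=True)
class IterationRecord:
    """One accepted or rejected step of the iterative subsampler."""

    iteration: int
    subsample_total: int
    n_decremented: int
    counts_equal: bool
    shifts_ok: bool
    amplitudes_ok: bool
    accepted: bool
    frozen_classes: tuple[int, ...] = ()


@dataclass
class ReferenceResult:
    """Reference subsample of an original sample together with its ADV."""

    reference: LengthFrequency
    adv: float
    iterations_accepted: int
    removed_total: int
    stopping_reason: str
    trace: list[IterationRecord] = field(default_factory=list)
    original_points: CriticalPoints | None = None


def class_floors(
    orig: LengthFrequency,
    spec,
    rng: ImportantRange | None = None,
) -> dict[int, int]:
    """Minimum permitted count per important class under a gamma spec."""
    r = restrict(orig, rng)
    return {int(c): spec.floor_for(int(n)) for c, n in zip(r.classes, r.counts)}


def reference_subsample(
    orig: LengthFrequency, params: AlgorithmParams
) -> ReferenceResult:
    """Run the deterministic iterative subsampler and compute the ADV.

    Every iteration simultaneously decrements each important class whose
    current count exceeds its gamma floor, then re-derives the candidate's
    robust critical points and checks the three similarity conditions
    against the (fixed) critical points of the original.  On the first
    violation the previous subsample becomes the reference; if nothing can
    be decremented the loop stops with ``"all_classes_at_floor"``.

    Under gamma = 0, while no class has been emptied, the subsample size
    after ``i`` accepted iterations is exactly ``n - i * I`` with ``I`` the
    number of important classes.
    """
    rng = params.length_range
    r0 = restrict(orig, rng)
    if r0.is_empty:
        raise EmptyRangeError("original sample has no mass in the important range")
    orig_points = robust_critical_points(r0, params.delta)
    floors = np.array(
        [params.gamma.floor_for(int(n)) for n in r0.counts], dtype=np.int64
    )

    classes = r0.classes
    cur = r0.counts.copy()
    trace: list[IterationRecord] = []
    iterations = 0
    reason = "all_classes_at_floor"

    while True:
        mask = cur > floors
        if not mask.any():
            reason = "all_classes_at_floor"
            break
        cand_counts = cur - mask
        if cand_counts.sum() == 0:
            # a candidate with no fish left cannot carry a CDF; the current
            # state is already minimal
            reason = "all_classes_at_floor"
            break
        cand = LengthFrequency(classes, cand_counts, r0.origin, r0.class_width)
        report = check_conditions(r0, cand, params, orig_points=orig_points)
        frozen = tuple(int(c) for c in classes[~mask])
        rec = IterationRecord(
            iteration=iterations + 1,
            subsample_total=int(cand_counts.sum()),
            n_decremented=int(mask.sum()),
            counts_equal=report.counts_equal,
            shifts_ok=report.shifts_ok,
            amplitudes_ok=report.amplitudes_ok,
            accepted=report.all_ok,
            frozen_classes=frozen,
        )
        trace.append(rec)
        if report.all_ok:
            cur = cand_counts
            iterations += 1
            continue
        if not report.counts_equal:
            reason = "mode_count_changed"
        elif not report.shifts_ok:
            reason = "shift_exceeded"
        else:
            reason = "amplitude_ratio"
        break

    reference = LengthFrequency(classes, cur, r0.origin, r0.class_width, orig.label)
    F, G = aligned_cdfs(r0, reference, None)
    adv_value = lp_distance(F, G, params.p)
    return ReferenceResult(
        reference=reference,
        adv=adv_value,
        iterations_accepted=iterations,
        removed_total=r0.total - reference.total,
        stopping_reason=reason,
        trace=trace,
        original_points=orig_points,
    )


def adv(orig: LengthFrequency, params: AlgorithmParams) -> float:
    """Admissible dissimilarity value of a sample (L1 to its reference subsample)."""
    return reference_subsample(orig, params).adv


def is_admissible(
    orig: LengthFrequency,
    sub: LengthFrequency,
    params: AlgorithmParams,
    reference: ReferenceResult | None = None,
) -> tuple[bool, DissimilarityResult, float]:
    """Decide whether ``sub`` is representative of ``orig``.

    A subsample is admissible when its penalized distance D to the
    original does not exceed the ADV.  Returns the verdict together with
    the full distance decomposition and the ADV used.
    """
    ref = reference if reference is not None else reference_subsample(orig, params)
    result = dissimilarity(orig, sub, params, orig_points=ref.original_points)
    return result.total_D <= ref.adv, result, ref.adv
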