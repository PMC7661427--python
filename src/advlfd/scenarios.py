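"""Sampling-effort reduction scenarios on hierarchical trip/haul/fish records.

Commercial catch sampling is hierarchical: observers join trips, sample
hauls (fishing operations) within trips, and measure individual fish
within hauls.  Measured counts are *raised* to the whole catch by the
ratio of haul catch weight to measured-sample weight.  This module
evaluates what happens to the length-frequency distribution when whole
trips, low-catch hauls, night-time hauls, or fractions of individuals are
dropped: the reduced record set is aggregated, its penalized distance D to
the original LFD computed, and admissibility decided against the ADV.

Mean length and its standard error are tracked alongside via a nested
random-effects model ``s_ihr = mu + e_trip + e_haul + e_within`` with
``Var[s] = sigma_t^2 + sigma_h^2 + sigma_r^2``, fitted by method-of-moments
nested ANOVA on the unraised measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, time

import numpy as np
import pandas as pd

from .dissimilarity import AlgorithmParams, dissimilarity
from .lfd import EmptyRangeError, ImportantRange, LengthFrequency, restrict
from .reference import ReferenceResult, reference_subsample

__all__ = [
    "MeasurementRecord",
    "ScenarioResult",
    "VarianceComponents",
    "aggregate_lfd",
    "apply_scenario",
    "mean_length_varcomp",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeasurementRecord:
    """One length-measurement row of an observer-sampling export.

    ``n_measured`` fish of length ``length_cm`` were measured in haul
    ``haul_id`` of trip ``trip_id``; ``raising_factor`` expands them to the
    whole catch of the haul (catch weight / measured-sample weight >= 1).
    """

    trip_id: str
    haul_id: str
    haul_time: datetime
    haul_catch_kg: float
    length_cm: int
    n_measured: int
    raising_factor: float

    def __post_init__(self) -> None:
        if self.n_measured < 1:
            raise ValueError("n_measured must be a positive integer")
        if self.raising_factor < 1:
            raise ValueError("raising_factor must be >= 1")


@dataclass
class ScenarioResult:
    """Outcome of one effort-reduction scenario against the baseline LFD.

    ``D`` is the penalized distance of the reduced, re-aggregated LFD to
    the original (the median over replicates for stochastic thinning
    scenarios).  Sample sizes are reported both raised and unraised, over
    all classes and within the important range.
    """

    description: str
    D: float
    adv: float
    admissible: bool
    n_raised_all: float
    n_raised_range: float
    n_unraised_all: float
    n_unraised_range: float
    mean_length: float
    se_mean_length: float
    replicates: int = 1
    condition_flags: tuple[bool, bool, bool] = (True, True, True)


@dataclass
class VarianceComponents:
    """Nested (trip / haul / within-haul) variance decomposition of length."""

    mu: float
    var_trip: float
    var_haul: float
    var_within: float
    se_mean: float
    n: int


def aggregate_lfd(
    records: list[MeasurementRecord],
    rng: ImportantRange | None = None,
    origin: int = 0,
) -> LengthFrequency:
    """Raise and aggregate records into a dense LFD.

    Per length class the raised contribution ``n_measured * raising_factor``
    is summed over all records and rounded to the nearest integer (ties
    away from zero) once, after aggregation — the iterative subsampler
    removes whole fish, so integer counts are required, and per-record
    rounding would inflate the error.
    """
    if not records:
        raise ValueError("cannot aggregate an empty record set")
    raised: dict[int, float] = {}
    for rec in records:
        raised[rec.length_cm] = raised.get(rec.length_cm, 0.0) + rec.n_measured * rec.raising_factor
    lo, hi = min(raised), max(raised)
    classes = np.arange(lo, hi + 1, dtype=np.int64)
    counts = np.array(
        [math.floor(abs(raised.get(int(c), 0.0)) + 0.5) for c in classes], dtype=np.int64
    )
    lfd = LengthFrequency(classes, counts, origin=origin, class_width=1)
    return restrict(lfd, rng)


def _in_window(t: datetime, window: tuple[int, int]) -> bool:
    """True when the haul time falls inside a (possibly wrap-around) hour window."""
    start, end = window
    h = t.hour + t.minute / 60 + t.second / 3600
    if start <= end:
        return start <= h < end
    return h >= start or h < end  # wraps past midnight, e.g. 21:00-03:00


def _filter_records(
    records: list[MeasurementRecord],
    drop_trips,
    min_haul_catch_kg,
    exclude_hours,
) -> list[MeasurementRecord]:
    drop = set(drop_trips or ())
    out = []
    for rec in records:
        if rec.trip_id in drop:
            continue
        if min_haul_catch_kg is not None and rec.haul_catch_kg < min_haul_catch_kg:
            continue
        if exclude_hours is not None and _in_window(rec.haul_time, exclude_hours):
            continue
        out.append(rec)
    return out


def _thin_per_haul(
    records: list[MeasurementRecord],
    keep_fraction: float,
    rng: np.random.Generator,
) -> list[MeasurementRecord]:
    """Draw a fraction of measured individuals per haul, without replacement.

    Thinning acts on unraised fish; raising factors are reapplied to the
    retained fish afterwards.
    """
    by_haul: dict[tuple[str, str], list[MeasurementRecord]] = {}
    for rec in records:
        by_haul.setdefault((rec.trip_id, rec.haul_id), []).append(rec)
    thinned: list[MeasurementRecord] = []
    for recs in by_haul.values():
        lengths = np.repeat(
            [r.length_cm for r in recs], [r.n_measured for r in recs]
        )
        n = lengths.size
        k = int(round(keep_fraction * n))
        if k == 0:
            continue
        kept = rng.choice(lengths, size=k, replace=False)
        template = recs[0]
        vals, cnts = np.unique(kept, return_counts=True)
        for v, c in zip(vals, cnts):
            thinned.append(
                MeasurementRecord(
                    trip_id=template.trip_id,
                    haul_id=template.haul_id,
                    haul_time=template.haul_time,
                    haul_catch_kg=template.haul_catch_kg,
                    length_cm=int(v),
                    n_measured=int(c),
                    raising_factor=template.raising_factor,
                )
            )
    return thinned


def apply_scenario(
    records: list[MeasurementRecord],
    params: AlgorithmParams,
    *,
    drop_trips=(),
    min_haul_catch_kg: float | None = None,
    exclude_hours: tuple[int, int] | None = None,
    keep_fraction_per_haul: float | None = None,
    replicates: int = 1,
    seed: int | None = None,
    baseline: ReferenceResult | None = None,
    description: str = "",
) -> ScenarioResult:
    """Evaluate one hierarchical effort-reduction scenario.

    Filters are applied in order: whole trips (``drop_trips``), hauls below
    a catch-weight threshold (``min_haul_catch_kg``), hauls inside a daily
    hour window (``exclude_hours``, wrap-around, e.g. ``(21, 3)`` for night
    hauls), and finally random per-haul thinning of individuals
    (``keep_fraction_per_haul``; repeated ``replicates`` times, reporting
    the median D, which is less affected by extreme replicate values than
    the mean).
    """
    if not records:
        raise ValueError("scenario evaluation needs a nonempty baseline record set")
    orig = aggregate_lfd(records)
    ref = baseline if baseline is not None else reference_subsample(orig, params)

    filtered = _filter_records(records, drop_trips, min_haul_catch_kg, exclude_hours)
    if not filtered:
        raise ValueError("scenario removed every record")

    def _evaluate(recs: list[MeasurementRecord]):
        sub = aggregate_lfd(recs)
        if restrict(sub, params.length_range).is_empty:
            raise EmptyRangeError("scenario left no mass in the important range")
        result = dissimilarity(orig, sub, params, orig_points=ref.original_points)
        vc = mean_length_varcomp(recs, params.length_range)
        sub_r = restrict(sub, params.length_range)
        unraised = sum(r.n_measured for r in recs)
        unraised_range = sum(
            r.n_measured
            for r in recs
            if params.length_range is None or params.length_range.contains(r.length_cm)
        )
        return result, sub.total, sub_r.total, unraised, unraised_range, vc

    if keep_fraction_per_haul is None:
        result, nr_all, nr_rng, nu_all, nu_rng, vc = _evaluate(filtered)
        D = result.total_D
        flags = result.condition_flags
        reps = 1
    else:
        if replicates < 1:
            raise ValueError("replicates must be >= 1")
        root = np.random.default_rng(seed)
        Ds, sizes = [], []
        means, ses, flags_list = [], [], []
        for _ in range(replicates):
            thinned = _thin_per_haul(filtered, keep_fraction_per_haul, root)
            if not thinned:
                raise ValueError("thinning removed every record")
            result, nr_all, nr_rng, nu_all, nu_rng, vc = _evaluate(thinned)
            Ds.append(result.total_D)
            sizes.append((nr_all, nr_rng, nu_all, nu_rng))
            means.append(vc.mu)
            ses.append(vc.se_mean)
            flags_list.append(result.condition_flags)
        D = float(np.median(Ds))
        nr_all, nr_rng, nu_all, nu_rng = (float(np.mean(x)) for x in zip(*sizes))
        vc = VarianceComponents(
            mu=float(np.mean(means)),
            var_trip=np.nan,
            var_haul=np.nan,
            var_within=np.nan,
            se_mean=float(np.mean(ses)),
            n=int(nu_rng),
        )
        # flags of the median-D replicate, for reporting
        flags = flags_list[int(np.argsort(Ds)[len(Ds) // 2])]
        reps = replicates

    return ScenarioResult(
        description=description,
        D=D,
        adv=ref.adv,
        admissible=bool(D <= ref.adv),
        n_raised_all=float(nr_all),
        n_raised_range=float(nr_rng),
        n_unraised_all=float(nu_all),
        n_unraised_range=float(nu_rng),
        mean_length=vc.mu,
        se_mean_length=vc.se_mean,
        replicates=reps,
        condition_flags=flags,
    )


def mean_length_varcomp(
    records: list[MeasurementRecord],
    rng: ImportantRange | None = None,
) -> VarianceComponents:
    """Method-of-moments nested ANOVA of unraised length measurements.

    Fits ``s = mu + e_trip + e_haul + e_within`` on the individual (not
    raised) measurements inside the important range.  The unbalanced-design
    expected-mean-square coefficients follow the classical two-fold nested
    formulas; negative moment estimates are truncated to zero and logged.
    The standard error of the grand mean combines the fitted components
    with the realized design counts.
    """
    rows = []
    for rec in records:
        if rng is not None and not rng.contains(rec.length_cm):
            continue
        rows.append((rec.trip_id, rec.haul_id, rec.length_cm, rec.n_measured))
    if not rows:
        raise EmptyRangeError("no measurements in the important range")
    df = pd.DataFrame(rows, columns=["trip", "haul", "length", "n"])
    y = np.repeat(df["length"].to_numpy(float), df["n"].to_numpy(int))
    trip = np.repeat(df["trip"].to_numpy(), df["n"].to_numpy(int))
    haul_key = (df["trip"] + "\x00" + df["haul"]).to_numpy()
    haul = np.repeat(haul_key, df["n"].to_numpy(int))

    N = y.size
    mu = float(y.mean())
    if N == 1:
        logger.warning("single observation: standard error of mean set to 0")
        return VarianceComponents(mu, 0.0, 0.0, 0.0, 0.0, 1)

    d = pd.DataFrame({"y": y, "trip": trip, "haul": haul})
    per_haul = d.groupby(["trip", "haul"], sort=False)["y"].agg(["sum", "count"])
    per_trip = per_haul.groupby(level="trip", sort=False).agg(
        sum=("sum", "sum"), count=("count", "sum")
    )
    a = len(per_trip)  # trips
    H = len(per_haul)  # hauls
    T = y.sum()

    ss_total_raw = float((y**2).sum())
    ss_haul_means = float((per_haul["sum"] ** 2 / per_haul["count"]).sum())
    ss_trip_means = float((per_trip["sum"] ** 2 / per_trip["count"]).sum())
    sse = ss_total_raw - ss_haul_means
    ssh = ss_haul_means - ss_trip_means
    sst = ss_trip_means - T**2 / N

    n_th = per_haul["count"].to_numpy(float)
    n_t = per_trip["count"].to_numpy(float)
    sum_nth2_over_nt = float(
        (per_haul["count"] ** 2).groupby(level="trip", sort=False).sum().to_numpy()
        @ (1.0 / n_t)
    )
    sum_nth2 = float((n_th**2).sum())
    sum_nt2 = float((n_t**2).sum())

    var_within = sse / (N - H) if N > H else 0.0
    if N == H:
        logger.warning("one fish per haul: within-haul variance is inestimable, set to 0")

    def _truncate(name: str, v: float) -> float:
        if v < 0:
            # routine for moment estimators when a component is near zero
            logger.info("negative %s variance estimate truncated to 0", name)
            return 0.0
        return v

    var_within = _truncate("within", var_within)

    var_haul = 0.0
    if H > a:
        k1 = (N - sum_nth2_over_nt) / (H - a)
        var_haul = _truncate("haul", (ssh / (H - a) - var_within) / k1)

    var_trip = 0.0
    if a > 1:
        k2 = (sum_nth2_over_nt - sum_nth2 / N) / (a - 1)
        k3 = (N - sum_nt2 / N) / (a - 1)
        var_trip = _truncate("trip", (sst / (a - 1) - var_within - k2 * var_haul) / k3)

    se2 = (
        var_trip * sum_nt2 / N**2
        + var_haul * sum_nth2 / N**2
        + var_within / N
    )
    return VarianceComponents(mu, var_trip, var_haul, var_within, math.sqrt(se2), N)
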