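"""Synthetic data generators and the Monte Carlo validation study.

The validation study draws original samples from a three-component normal
mixture ``y ~ 1/4 N(40, sd) + 1/2 N(70, sd) + 1/4 N(100, sd)`` of size
2000, rounded to 1-cm length classes — three year-class peaks whose
separation degrades as ``sd`` grows from 5 (well-isolated cohorts) through
7 to 10 (nearly platykurtic).  On a grid of the shift tolerance ``epsilon``
and the amplitude tolerance ``theta`` it tracks the mean reference
subsample size and mean ADV, contrasts the deterministic reference
construction with plain bootstrap subsampling (which scores far larger
distances than the ADV at matched subsample sizes), and measures how often
the reference CDF stays inside a 95% pointwise bootstrap band.

A hierarchical generator emulating observer trip/haul/fish records (with
trip- and haul-level mean shifts inducing intra-haul correlation) feeds
the scenario machinery; real observer exports are structurally identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .dissimilarity import AlgorithmParams, GammaSpec, dissimilarity
from .lfd import LengthFrequency, build_lfd, restrict
from .reference import reference_subsample
from .scenarios import MeasurementRecord

__all__ = [
    "MixtureConfig",
    "GridResult",
    "BootstrapComparison",
    "simulate_mixture",
    "grid_study",
    "bootstrap_comparison",
    "contrast_datasets",
    "synthetic_hierarchical_data",
    "DEFAULT_THETAS",
    "DEFAULT_EPSILONS",
]

# theta in {0.30, 0.35, ..., 0.95}; epsilon in {0, 1, 2, 3}
DEFAULT_THETAS: tuple[float, ...] = tuple(round(0.30 + 0.05 * k, 2) for k in range(14))
DEFAULT_EPSILONS: tuple[int, ...] = (0, 1, 2, 3)


@dataclass(frozen=True)
class MixtureConfig:
    """A normal-mixture population of fish lengths plus a sample size and seed."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    n: int = 2000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("weights, means and sds must have equal length")
        if min(self.weights) < 0 or not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ValueError("weights must be nonnegative and sum to 1")
        if min(self.sds) <= 0:
            raise ValueError("standard deviations must be positive")
        if self.n < 1:
            raise ValueError("sample size must be >= 1")

    @staticmethod
    def three_cohorts(sd: float, n: int = 2000, seed: int | None = None) -> "MixtureConfig":
        """The study population: cohort peaks at 40, 70, 100 cm with weights 1/4, 1/2, 1/4."""
        return MixtureConfig((0.25, 0.5, 0.25), (40.0, 70.0, 100.0), (sd, sd, sd), n, seed)

    @staticmethod
    def two_cohorts(sd: float = 5.0, n: int = 1000, seed: int | None = None) -> "MixtureConfig":
        """The contrast population: overlapping peaks at 50 and 60 cm."""
        return MixtureConfig((0.5, 0.5), (50.0, 60.0), (sd, sd), n, seed)


def _draw_lengths(config: MixtureConfig, rng: np.random.Generator) -> np.ndarray:
    """Integer-cm lengths from the mixture; draws rounding below 1 cm are redrawn."""
    comp = rng.choice(len(config.weights), size=config.n, p=config.weights)
    means = np.asarray(config.means)[comp]
    sds = np.asarray(config.sds)[comp]
    x = rng.normal(means, sds)
    lengths = np.floor(np.abs(x) + 0.5) * np.sign(x)
    bad = lengths < 1
    while bad.any():
        x = rng.normal(means[bad], sds[bad])
        lengths[bad] = np.floor(np.abs(x) + 0.5) * np.sign(x)
        bad = lengths < 1
    return lengths.astype(np.int64)


def simulate_mixture(config: MixtureConfig) -> LengthFrequency:
    """Draw one sample from the mixture and bin it into a 1-cm LFD."""
    rng = np.random.default_rng(config.seed)
    return build_lfd(_draw_lengths(config, rng))


def _study_params(theta: float, epsilon: int, gamma: GammaSpec, delta: int) -> AlgorithmParams:
    return AlgorithmParams(delta=delta, theta=theta, epsilon=epsilon, gamma=gamma)


@dataclass
class GridResult:
    """Mean reference size and mean ADV per (sd, theta, epsilon) cell."""

    table: pd.DataFrame  # columns: sd, theta, epsilon, mean_ref_size, mean_adv, replicates

    def cell(self, sd: float, theta: float, epsilon: int) -> pd.Series:
        t = self.table
        m = (t["sd"] == sd) & (np.isclose(t["theta"], theta)) & (t["epsilon"] == epsilon)
        return t[m].iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def grid_study(
    sds,
    thetas=DEFAULT_THETAS,
    epsilons=DEFAULT_EPSILONS,
    *,
    n: int = 2000,
    gamma: GammaSpec | None = None,
    delta: int = 5,
    replicates: int = 100,
    seed: int | None = None,
) -> GridResult:
    """Reference-subsample size and ADV across the (sd, theta, epsilon) grid.

    For each ``sd`` a set of ``replicates`` mixture samples is drawn; the
    same replicate samples are reused across the (theta, epsilon) cells so
    that cell-to-cell contrasts are not confounded by sampling noise.  All
    length classes of each sample count as important; gamma defaults to an
    absolute floor of 5 fish per class.
    """
    gamma = gamma if gamma is not None else GammaSpec.absolute(5)
    ss = np.random.SeedSequence(seed)
    rows = []
    for sd in sds:
        rng = np.random.default_rng(ss.spawn(1)[0])
        sizes = {(th, ep): [] for th in thetas for ep in epsilons}
        advs = {(th, ep): [] for th in thetas for ep in epsilons}
        for _ in range(replicates):
            lfd = build_lfd(_draw_lengths(MixtureConfig.three_cohorts(sd, n), rng))
            for th in thetas:
                for ep in epsilons:
                    ref = reference_subsample(lfd, _study_params(th, ep, gamma, delta))
                    sizes[(th, ep)].append(ref.reference.total)
                    advs[(th, ep)].append(ref.adv)
        for th in thetas:
            for ep in epsilons:
                rows.append(
                    {
                        "sd": sd,
                        "theta": th,
                        "epsilon": ep,
                        "mean_ref_size": float(np.mean(sizes[(th, ep)])),
                        "mean_adv": float(np.mean(advs[(th, ep)])),
                        "replicates": replicates,
                    }
                )
    return GridResult(pd.DataFrame(rows))


@dataclass
class BootstrapComparison:
    """Bootstrap subsampling vs the deterministic reference construction.

    ``table`` has one row per (theta, epsilon) cell with the mean reference
    size, mean ADV, mean bootstrap distance D and the coverage — the
    proportion of replicates whose reference CDF lies entirely inside the
    95% pointwise band of the bootstrap CDFs.  ``grand_mean_D`` averages
    the per-replicate mean distances over all cells.
    """

    grand_mean_D: float
    table: pd.DataFrame
    replicates: int
    n_boot: int


def _cdf_on_grid(counts: np.ndarray) -> np.ndarray:
    c = np.cumsum(counts, dtype=np.float64)
    return c / c[-1]


def bootstrap_comparison(
    config: MixtureConfig,
    thetas=DEFAULT_THETAS,
    epsilons=DEFAULT_EPSILONS,
    *,
    replicates: int = 100,
    n_boot: int = 100,
    gamma: GammaSpec | None = None,
    delta: int = 5,
    seed: int | None = None,
    with_replacement: bool = False,
) -> BootstrapComparison:
    """Score random bootstrap subsamples against the ADV benchmark.

    Per replicate sample and per (theta, epsilon) cell, ``n_boot``
    subsamples of the cell's mean reference size are drawn from the
    realized sample (without replacement by default — subsampling), their
    penalized distances D to that sample averaged, and the averages
    combined into a grand mean.  The coverage statistic records how often
    the reference CDF stays inside the 2.5-97.5 percentile band of the
    bootstrap CDFs at every length class.
    """
    gamma = gamma if gamma is not None else GammaSpec.absolute(5)
    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    rng = np.random.default_rng(ss)

    cells = [(th, ep) for th in thetas for ep in epsilons]
    originals: list[LengthFrequency] = []
    orig_points = []
    ref_sizes = {c: [] for c in cells}
    ref_counts: dict[tuple[float, int], list[np.ndarray]] = {c: [] for c in cells}
    advs = {c: [] for c in cells}

    for _ in range(replicates):
        lfd = build_lfd(_draw_lengths(config, rng))
        originals.append(lfd)
        pts = None
        for th, ep in cells:
            ref = reference_subsample(lfd, _study_params(th, ep, gamma, delta))
            pts = ref.original_points
            ref_sizes[(th, ep)].append(ref.reference.total)
            counts = np.zeros(lfd.classes.size, dtype=np.int64)
            off = int(ref.reference.classes[0] - lfd.classes[0])
            counts[off : off + ref.reference.counts.size] = ref.reference.counts
            ref_counts[(th, ep)].append(counts)
            advs[(th, ep)].append(ref.adv)
        orig_points.append(pts)

    mean_sizes = {c: int(round(np.mean(ref_sizes[c]))) for c in cells}

    rows = []
    cell_mean_D = []
    for th, ep in cells:
        params = _study_params(th, ep, gamma, delta)
        m = mean_sizes[(th, ep)]
        rep_means = []
        covered = 0
        for r, lfd in enumerate(originals):
            total = lfd.total
            size = min(m, total)
            boot_cdfs = np.empty((n_boot, lfd.classes.size))
            Ds = np.empty(n_boot)
            for b in range(n_boot):
                if with_replacement:
                    counts = rng.multinomial(size, lfd.counts / total)
                else:
                    counts = rng.multivariate_hypergeometric(lfd.counts, size)
                sub = LengthFrequency(lfd.classes, counts, lfd.origin, lfd.class_width)
                Ds[b] = dissimilarity(lfd, sub, params, orig_points=orig_points[r]).total_D
                boot_cdfs[b] = _cdf_on_grid(counts)
            rep_means.append(float(Ds.mean()))
            lo_band = np.quantile(boot_cdfs, 0.025, axis=0)
            hi_band = np.quantile(boot_cdfs, 0.975, axis=0)
            ref_cdf = _cdf_on_grid(ref_counts[(th, ep)][r])
            if np.all((ref_cdf >= lo_band - 1e-12) & (ref_cdf <= hi_band + 1e-12)):
                covered += 1
        mean_D = float(np.mean(rep_means))
        cell_mean_D.append(mean_D)
        rows.append(
            {
                "theta": th,
                "epsilon": ep,
                "mean_ref_size": float(np.mean(ref_sizes[(th, ep)])),
                "mean_adv": float(np.mean(advs[(th, ep)])),
                "mean_D": mean_D,
                "coverage": covered / replicates,
            }
        )

    return BootstrapComparison(
        grand_mean_D=float(np.mean(cell_mean_D)),
        table=pd.DataFrame(rows),
        replicates=replicates,
        n_boot=n_boot,
    )


def contrast_datasets(
    config1: MixtureConfig,
    config2: MixtureConfig,
    thetas=DEFAULT_THETAS,
    epsilons=DEFAULT_EPSILONS,
    *,
    gamma: GammaSpec | None = None,
    delta: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """ADV of one dataset vs its penalized distance to a different dataset.

    Draws one sample from each configuration and, per (theta, epsilon)
    cell, reports the ADV of the first sample and D(sample1, sample2),
    flagging cells where the distance exceeds the ADV (i.e. where the
    second dataset would be rejected as a stand-in for the first).
    """
    gamma = gamma if gamma is not None else GammaSpec.absolute(5)
    if seed is not None:
        s1, s2 = (int(s) for s in np.random.SeedSequence(seed).generate_state(2) % (2**31))
        config1 = MixtureConfig(config1.weights, config1.means, config1.sds, config1.n, s1)
        config2 = MixtureConfig(config2.weights, config2.means, config2.sds, config2.n, s2)
    d1 = simulate_mixture(config1)
    d2 = simulate_mixture(config2)
    rows = []
    for th in thetas:
        for ep in epsilons:
            params = _study_params(th, ep, gamma, delta)
            ref = reference_subsample(d1, params)
            D = dissimilarity(d1, d2, params, orig_points=ref.original_points).total_D
            rows.append(
                {
                    "theta": th,
                    "epsilon": ep,
                    "adv": ref.adv,
                    "D": D,
                    "exceeds_adv": D > ref.adv,
                }
            )
    return pd.DataFrame(rows)


def _weight_kg(length_cm: np.ndarray) -> np.ndarray:
    # cubic length-weight relation with condition factor ~1 (cod-like):
    # a 50 cm fish weighs about 1.25 kg
    return 1e-5 * np.asarray(length_cm, dtype=float) ** 3


def synthetic_hierarchical_data(
    n_trips: int,
    hauls_per_trip: int,
    fish_per_haul: int,
    mixture: MixtureConfig,
    *,
    trip_sd: float = 2.0,
    haul_sd: float = 1.0,
    catch_kg_range: tuple[float, float] = (500.0, 20000.0),
    start: datetime = datetime(2018, 7, 1),
    days: int = 92,
    seed: int | None = None,
) -> list[MeasurementRecord]:
    """Generate observer-style trip/haul/fish records (one record per fish).

    Lengths are mixture draws shifted by a normal trip effect and a normal
    haul effect (emulating intra-haul correlation), rounded to 1 cm with a
    1-cm lower bound.  Haul metadata: times uniform over the period's 24-h
    days, catch weights uniform over ``catch_kg_range``; the raising factor
    is the haul catch weight over the summed length-weight of the measured
    fish (at least 1).
    """
    if min(n_trips, hauls_per_trip, fish_per_haul) < 1:
        raise ValueError("design dimensions must be positive")
    rng = np.random.default_rng(seed)
    records: list[MeasurementRecord] = []
    for t in range(n_trips):
        trip_id = f"T{t + 1:03d}"
        trip_eff = rng.normal(0.0, trip_sd) if trip_sd > 0 else 0.0
        for h in range(hauls_per_trip):
            haul_id = f"H{h + 1:03d}"
            haul_eff = rng.normal(0.0, haul_sd) if haul_sd > 0 else 0.0
            minutes = rng.uniform(0, days * 24 * 60)
            haul_time = start + timedelta(minutes=float(minutes))
            catch_kg = float(rng.uniform(*catch_kg_range))
            base = _draw_lengths(
                MixtureConfig(mixture.weights, mixture.means, mixture.sds, fish_per_haul),
                rng,
            )
            lengths = np.maximum(
                1, np.floor(np.abs(base + trip_eff + haul_eff) + 0.5).astype(np.int64)
            )
            sample_kg = float(_weight_kg(lengths).sum())
            factor = max(1.0, catch_kg / sample_kg)
            for L in lengths:
                records.append(
                    MeasurementRecord(
                        trip_id=trip_id,
                        haul_id=haul_id,
                        haul_time=haul_time,
                        haul_catch_kg=catch_kg,
                        length_cm=int(L),
                        n_measured=1,
                        raising_factor=factor,
                    )
                )
    return records
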