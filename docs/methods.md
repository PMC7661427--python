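# Methods

## Model and procedure

The package decides whether a reduced length-frequency sample is still
representative of an original sample. Representativeness is defined
structurally, not by a hypothesis test: the subsample must preserve the
*robust* modal/antimodal skeleton of the original LFD, and the residual
discrepancy is measured by an L1 distance between empirical CDFs with
additive penalties for structural violations.

### Length-frequency carrier

An LFD is a dense histogram on an integer class grid: half-open bins
`[origin + k·w, origin + (k+1)·w)` labelled by their lower bound, with
nonnegative integer (raised) counts. The bin origin is fixed at 0 cm by
default so that the histogram shape depends only on the bandwidth; the
grid runs contiguously from the first to the last nonzero class, with
interior zero classes materialized so empty classes can carry antimodes.
Non-integer lengths are rounded to the nearest cm, ties away from zero,
the convention of regional sampling databases. Species measured in ½-cm
classes are handled by pre-scaling to an integer grid; there is no native
fractional grid.

### Critical points and robustness

At native resolution, a class is a mode (antimode) when its neighbours
carry strictly lower (higher) counts; for a run of equal counts the first
class represents the run. The grid is conceptually padded with zeros for
mode detection, so a boundary class can be a mode; antimodes are
interior-only, because a zero pad would make every boundary a spurious
minimum.

A 1-cm critical point is *robust* under bandwidth Δ when (i) its Δ-bin is
an extremum of the Δ-rebinned histogram, and (ii) it dominates all other
1-cm extrema of the same kind in that bin (maximal count for modes,
minimal for antimodes; ties resolved toward the smallest class). Modes
with counts at or below 1% of the maximal 1-cm mode count are discarded;
antimodes have no frequency filter. A smoothed extremum bin containing no
native extremum of the matching kind contributes nothing — robust points
are never synthesized. Robust modes and antimodes are kept as computed;
mode/antimode alternation is not enforced.

### Similarity conditions and the distance D

Given the important class range `l^I`, the original S₀ and a candidate Sₙ
are similar when (1) they have equal numbers of robust modes and equal
numbers of robust antimodes; (2) pairing modes with modes and antimodes
with antimodes in ascending order, every shift is at most ε cm; (3) along
the merged (sorted) sequences of critical points, the amplitude
difference of each consecutive pair in Sₙ is at least θ times the
corresponding difference in S₀. Conditions (2)–(3) are evaluated only
when (1) holds.

The distance adds one penalty per condition to the L1 CDF distance:
`c1` once for a count mismatch, `c2·max(0, shift − ε)` per critical-point
pair, and `c3·max(0, θ − ratio)` per consecutive amplitude pair
(defaults 10, 2, 1 — a vanished mode is graver than a shifted one, which
is graver than a flattened one). D is zero exactly for identical inputs
and collapses to the plain L1 distance exactly when all three conditions
hold. CDFs are aligned on the dense union grid of both samples within
`l^I`, cumulative values carried forward through classes without mass.

Two conventions exist for "amplitude at a critical point": the raised
count at the critical class (`pointwise`, the default) and the total mass
between consecutive critical points (`cdf_mass`). The definitions in the
source framework are not mutually consistent on this point; both are
implemented. The pointwise reading is the default because the
mass-between reading makes consecutive-pair differences track segment
*lengths* rather than peak heights — under uniform per-class removal it
collapses the iterative algorithm after at most one iteration, which is
clearly not the intended behaviour.

Amplitude pairs whose original difference is zero have an undefined ratio
and are skipped (logged); they contribute no penalty.

### Reference subsample and ADV

The reference subsample is produced deterministically: each iteration
simultaneously decrements every important class whose count still exceeds
its floor γ, the candidate's robust critical points are recomputed, and
the three conditions are checked against the *fixed* critical points of
the original. The first violation reverts to the previous state and
stops; if nothing is decrementable the loop stops with
`all_classes_at_floor`. Randomized elimination is deliberately excluded:
a random subsample can violate the conditions long before reaching a
minimal size, making it useless as a benchmark. The ADV is the L1
distance between the original and the reference (the penalties vanish by
construction), and a candidate subsample is admissible iff D ≤ ADV.

γ encodes managerial floors: `zero` (none), `absolute` n (at most n fish
per class, capped by the class count), `fraction` q (smallest integer
≥ q·n_j), and `survey_default` (20% of the class count, classes under 5
fish frozen entirely). A "γ < θ" side condition appearing in the source
material compares a count to a ratio and is dimensionally inconsistent;
no such constraint is imposed.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| Δ (`delta`) | cm | 5 | smoothing bandwidth deciding robustness; 5 cm suits species with ~120–150 cm maximum length |
| θ (`theta`) | — | 0.9 | minimum preserved amplitude ratio, in (0, 1] |
| ε (`epsilon`) | cm | 0 | tolerated shift per critical point |
| γ (`gamma`) | fish | zero | per-class subsampling floor |
| `l^I` (`length_range`) | cm | all classes | important classes; CDFs, critical points and D live here |
| c₁, c₂, c₃ | — | 10, 2, 1 | violation hierarchy |
| p | — | 1 | Minkowski order of the CDF distance |

## Hierarchical scenarios and the mean-length model

Observer records form a trip → haul → fish hierarchy; measured counts are
raised by catch-weight/sample-weight factors. Raised contributions are
summed per class over all records and rounded to integers once, after
aggregation (the subsampler removes whole fish; per-record rounding would
inflate error). Scenario filters: trip elimination, haul catch-weight
thresholds, a wrap-around daily hour window (night hauls, e.g. 21:00–03:00
as [21,24)∪[0,3)), and per-haul random thinning of unraised individuals
without replacement, with raising factors reapplied afterwards; thinning
scenarios are replicated and summarized by the median D, which is less
sensitive to extreme replicates than the mean.

Mean length and its standard error come from the nested random-effects
model s = μ + ε_trip + ε_haul + ε_within, fitted by method-of-moments
nested ANOVA with the classical unbalanced-design expected-mean-square
coefficients; negative moment estimates are truncated at zero (logged),
and the standard error of the grand mean combines the fitted components
with the realized design counts. The estimator slot is deliberately
simple and reproducible; a REML fit could be substituted without touching
the interface.

## Synthetic data

The study population is a three-cohort normal mixture
¼ N(40, sd) + ½ N(70, sd) + ¼ N(100, sd), n = 2000, examined at
sd ∈ {5, 7, 10}: cleanly separated cohorts at 5, weak near-platykurtic
structure at 10. Continuous draws are rounded to the nearest cm; draws
rounding below 1 cm are redrawn. The contrast population is
½ N(50, 5) + ½ N(60, 5), n = 1000.

The hierarchical generator emulates observer data by shifting mixture
draws with normal trip- and haul-level effects (intra-haul correlation),
uniform haul times over the period and uniform catch weights; the raising
factor is the haul catch weight over the summed cubic length-weight of
the measured fish (a 50-cm fish ≈ 1.25 kg), floored at 1. It reproduces
the *structure* of real observer exports, not their artefacts: no
selectivity at length, no missing metadata, no measurement error beyond
cm rounding, and haul sizes are balanced. Passing tests therefore
demonstrate correctness of the machinery on clean hierarchical data, not
robustness to the messiness of real regional-database extracts.

## Monte Carlo study and numerical choices

The grid study fixes γ = 5, Δ = 5 and all classes important, and sweeps
θ ∈ {0.30, 0.35, …, 0.95}, ε ∈ {0, 1, 2, 3}; replicate samples are shared
across grid cells so cell contrasts are not confounded by sampling noise.
Reported per cell: mean reference size and mean ADV. Default replicate
counts in this package are 100 (the tests and the acceptance script use
25–100), chosen so a full grid runs in minutes on one core; the counts
are parameters and can be raised.

The bootstrap comparison draws subsamples **without replacement**
(subsampling) by default — a with-replacement switch exists — of the
per-cell mean reference size, scores their D against the originating
sample, and additionally records coverage: the share of replicates whose
reference CDF lies inside the pointwise 2.5–97.5% band of the bootstrap
CDFs at every class. Without replacement the band width carries the
finite-population factor (N−m)/(N−1), so coverage tightens as θ → 1 and
the subsample size approaches n.

Numerical conventions worth noting: admissibility uses a plain D ≤ ADV
comparison (the reference's own D is computed by the identical code path
as the ADV, so equality is exact); CDF final values are set to exactly 1
to avoid accumulation error; empty critical-point sets are legal
throughout; a candidate that would empty the important range entirely is
never accepted (the current state is already minimal).

## Known limitations

- The iterative algorithm's stopping point is sensitive to small-count
  critical points near the tails: once such a class freezes at its γ
  floor, amplitude ratios and critical-point positions can degrade within
  a few iterations, so reference sizes for weakly separated cohorts
  (sd ≥ 7) stay closer to n than the well-separated case. Range
  restriction (`l^I`) excluding volatile tails is the practical remedy.
- With equal tolerances for every critical point, one fragile pair
  controls the stop; vector-valued θ, ε are not implemented.
- Amplitude *ranks* are not penalized: for small θ a flattening trend of
  amplitudes can pass condition (3).
- The mean-length model assumes independent, homoscedastic random
  effects; raising factors enter the LFD but not the variance model.
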