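"""Hierarchical effort-reduction scenarios and the nested variance model."""

from datetime import datetime

import numpy as np
import pytest

from advlfd import (
    AlgorithmParams,
    GammaSpec,
    ImportantRange,
    MeasurementRecord,
    aggregate_lfd,
    apply_scenario,
    mean_length_varcomp,
)


def rec(trip, haul, length, n=1, factor=1.0, catch=5000.0, hour=12):
    return MeasurementRecord(
        trip_id=trip,
        haul_id=haul,
        haul_time=datetime(2018, 7, 15, hour, 0),
        haul_catch_kg=catch,
        length_cm=length,
        n_measured=n,
        raising_factor=factor,
    )


@pytest.fixture
def three_cluster_records():
    """Two trips: trip A carries two low clusters, trip B the upper cluster."""
    records = []
    for length, count in [(29, 5), (30, 10), (31, 5), (49, 5), (50, 12), (51, 5)]:
        records.append(rec("A", "h1", length, n=count))
    for length, count in [(69, 5), (70, 10), (71, 5)]:
        records.append(rec("B", "h1", length, n=count))
    return records


class TestAggregateLfd:
    def test_single_record_product(self):
        assert aggregate_lfd([rec("t", "h", 50, n=2, factor=3.0)]).to_dict() == {50: 6}

    def test_unit_factors_reproduce_unraised_counts(self):
        records = [rec("t", "h", 40, n=3), rec("t", "h", 42, n=1)]
        assert aggregate_lfd(records).to_dict() == {40: 3, 41: 0, 42: 1}

    def test_rounding_after_aggregation(self):
        records = [rec("t", "h", 50, factor=1.3), rec("t", "h2", 50, factor=1.3)]
        assert aggregate_lfd(records).to_dict() == {50: 3}  # 2.6 rounds to 3

    def test_additive_over_disjoint_subsets_up_to_rounding(self):
        rng = np.random.default_rng(11)
        records = [
            rec(f"t{i%3}", f"h{i%5}", int(rng.integers(30, 60)), factor=float(rng.uniform(1, 4)))
            for i in range(100)
        ]
        whole = aggregate_lfd(records)
        part1 = aggregate_lfd(records[:50])
        part2 = aggregate_lfd(records[50:])
        for c in whole.classes:
            s = part1.count_at(int(c)) + part2.count_at(int(c))
            assert abs(s - whole.count_at(int(c))) <= 1  # 0.5 per subset


class TestApplyScenario:
    def test_no_filters_is_identity(self, three_cluster_records):
        p = AlgorithmParams(delta=1, theta=0.8)
        res = apply_scenario(three_cluster_records, p, description="baseline")
        assert res.D == 0.0
        assert res.admissible

    def test_dropping_out_of_range_trip_changes_nothing(self, three_cluster_records):
        p = AlgorithmParams(delta=1, theta=0.8, length_range=ImportantRange(25, 60))
        res = apply_scenario(three_cluster_records, p, drop_trips={"B"})
        assert res.D == 0.0

    def test_dropping_trip_with_upper_mode_violates_condition_one(
        self, three_cluster_records
    ):
        p = AlgorithmParams(delta=1, theta=0.8)
        res = apply_scenario(three_cluster_records, p, drop_trips={"B"})
        assert res.condition_flags[0] is False
        assert res.D >= p.c1
        assert not res.admissible

    def test_haul_catch_threshold_filter(self):
        records = [rec("A", "h1", 40, n=10, catch=1000.0), rec("A", "h2", 45, n=10, catch=9000.0)]
        p = AlgorithmParams(delta=1, theta=0.8)
        res = apply_scenario(records, p, min_haul_catch_kg=3000.0)
        assert res.n_unraised_all == 10

    def test_night_window_wraps_midnight(self):
        records = [
            rec("A", "h1", 40, n=10, hour=22),
            rec("A", "h2", 41, n=10, hour=2),
            rec("A", "h3", 42, n=10, hour=12),
        ]
        p = AlgorithmParams(delta=1, theta=0.8)
        res = apply_scenario(records, p, exclude_hours=(21, 3))
        assert res.n_unraised_all == 10  # only the midday haul survives

    def test_scenario_removing_everything_rejected(self, three_cluster_records):
        p = AlgorithmParams(delta=1, theta=0.8)
        with pytest.raises(ValueError, match="every record"):
            apply_scenario(three_cluster_records, p, drop_trips={"A", "B"})

    def test_thinning_reports_median_over_replicates(self, three_cluster_records):
        p = AlgorithmParams(delta=1, theta=0.5, epsilon=1)
        res = apply_scenario(
            three_cluster_records,
            p,
            keep_fraction_per_haul=0.9,
            replicates=11,
            seed=5,
        )
        assert res.replicates == 11
        assert res.D >= 0.0
        # 90% of the 62 measured fish kept on average
        assert res.n_unraised_all == pytest.approx(0.9 * 62, abs=2)

    def test_thinning_median_stable_across_seed_batches(self):
        # two independent seed batches agree within the replicate spread
        rng = np.random.default_rng(3)
        records = []
        for t in range(3):
            for h in range(4):
                for L in rng.normal(55, 8, size=40):
                    records.append(rec(f"t{t}", f"h{h}", int(max(1, round(L)))))
        p = AlgorithmParams(delta=5, theta=0.7, epsilon=1)

        def batch(seed):
            Ds = []
            for k in range(50):
                r = apply_scenario(
                    records, p, keep_fraction_per_haul=0.5, replicates=1, seed=seed + k
                )
                Ds.append(r.D)
            return np.array(Ds)

        b1, b2 = batch(100), batch(900)
        pooled = np.concatenate([b1, b2])
        iqr = np.subtract(*np.percentile(pooled, [75, 25]))
        assert abs(np.median(b1) - np.median(b2)) < max(iqr, 1e-6)


class TestVarianceComponents:
    def test_identical_lengths(self):
        records = [rec("t1", "h1", 50, n=5), rec("t1", "h2", 50, n=5)]
        vc = mean_length_varcomp(records)
        assert vc.mu == 50.0
        assert vc.var_trip == vc.var_haul == vc.var_within == 0.0
        assert vc.se_mean == 0.0

    def test_single_trip_single_haul_degenerates_to_sample_variance(self):
        lengths = [48, 50, 52, 54]
        records = [rec("t1", "h1", L) for L in lengths]
        vc = mean_length_varcomp(records)
        assert vc.var_trip == 0.0 and vc.var_haul == 0.0
        assert vc.var_within == pytest.approx(np.var(lengths, ddof=1))

    def test_single_observation_has_zero_se(self, caplog):
        with caplog.at_level("WARNING"):
            vc = mean_length_varcomp([rec("t1", "h1", 50)])
        assert vc.se_mean == 0.0

    def test_balanced_recovery_of_known_components(self):
        # sigma^2 = (4, 1, 9) at a 20 trips x 5 hauls x 30 fish design;
        # averaged over replicate designs (the trip-level moment estimator
        # alone has ~30% sampling sd with 20 trips)
        rng = np.random.default_rng(77)
        estimates = []
        for _ in range(4):
            records = []
            for t in range(20):
                et = rng.normal(0, 2.0)
                for h in range(5):
                    eh = rng.normal(0, 1.0)
                    for L in 55 + et + eh + rng.normal(0, 3.0, size=30):
                        records.append(rec(f"t{t}", f"h{h}", int(round(L))))
            vc = mean_length_varcomp(records)
            assert vc.mu == pytest.approx(55, abs=1.5)
            assert vc.se_mean > 0
            estimates.append((vc.var_trip, vc.var_haul, vc.var_within))
        mean_trip, mean_haul, mean_within = np.mean(estimates, axis=0)
        assert mean_trip == pytest.approx(4.0, rel=0.3)
        assert mean_haul == pytest.approx(1.0, rel=0.3)
        assert mean_within == pytest.approx(9.0, rel=0.3)
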