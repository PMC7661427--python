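"""Mixture generators, the parameter-grid study, and the bootstrap contrast."""

import numpy as np
import pytest

from advlfd import (
    AlgorithmParams,
    GammaSpec,
    MixtureConfig,
    bootstrap_comparison,
    contrast_datasets,
    grid_study,
    reference_subsample,
    simulate_mixture,
    synthetic_hierarchical_data,
)
from advlfd.simulation import _draw_lengths


class TestSimulateMixture:
    def test_same_seed_reproduces_sample(self):
        cfg = MixtureConfig.three_cohorts(7.0, 500, seed=9)
        assert simulate_mixture(cfg) == simulate_mixture(cfg)

    def test_sample_mean_near_mixture_mean(self):
        cfg = MixtureConfig.three_cohorts(5.0, 2000, seed=1)
        lfd = simulate_mixture(cfg)
        mean = float(np.average(lfd.classes, weights=lfd.counts))
        pooled_sd = np.sqrt(5**2 + 0.25 * 40**2 + 0.5 * 0 + 0.25 * 40**2 - 0)
        assert abs(mean - 70.0) < 3 * pooled_sd / np.sqrt(2000)

    def test_component_proportions_within_binomial_bounds(self):
        rng = np.random.default_rng(4)
        lengths = _draw_lengths(MixtureConfig.three_cohorts(5.0, 2000), rng)
        # sd=5 cohorts at 40/70/100 barely overlap at the 55/85 midpoints
        n1 = int((lengths < 55).sum())
        n3 = int((lengths > 85).sum())
        sigma = np.sqrt(2000 * 0.25 * 0.75)
        assert abs(n1 - 500) < 3 * sigma
        assert abs(n3 - 500) < 3 * sigma
        assert abs((2000 - n1 - n3) - 1000) < 3 * np.sqrt(2000 * 0.5 * 0.5)

    def test_no_lengths_below_one_cm(self):
        rng = np.random.default_rng(0)
        cfg = MixtureConfig((1.0,), (2.0,), (3.0,), 500)
        assert _draw_lengths(cfg, rng).min() >= 1

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MixtureConfig((0.5, 0.4), (40, 70), (5, 5))
        with pytest.raises(ValueError):
            MixtureConfig((0.5, 0.5), (40, 70), (5, -1))


class TestGridStudy:
    def test_single_cell_single_replicate_matches_direct_call(self):
        gr = grid_study([5.0], thetas=(0.8,), epsilons=(1,), n=400, replicates=1, seed=21)
        cell = gr.cell(5.0, 0.8, 1)
        # replay the generator's stream to rebuild the identical sample
        rng = np.random.default_rng(np.random.SeedSequence(21).spawn(1)[0])
        from advlfd import build_lfd

        lfd = build_lfd(_draw_lengths(MixtureConfig.three_cohorts(5.0, 400), rng))
        ref = reference_subsample(
            lfd, AlgorithmParams(delta=5, theta=0.8, epsilon=1, gamma=GammaSpec.absolute(5))
        )
        assert cell["mean_ref_size"] == ref.reference.total
        assert cell["mean_adv"] == pytest.approx(ref.adv)

    def test_cell_means_stabilize_with_replicates(self):
        # doubling the replicate count moves a cell mean by less than 3 SE
        sizes = []
        p = AlgorithmParams(delta=5, theta=0.8, epsilon=0, gamma=GammaSpec.absolute(5))
        rng = np.random.default_rng(31)
        from advlfd import build_lfd

        for _ in range(36):
            lfd = build_lfd(_draw_lengths(MixtureConfig.three_cohorts(5.0, 800), rng))
            sizes.append(reference_subsample(lfd, p).reference.total)
        first, both = np.mean(sizes[:12]), np.mean(sizes)
        se = np.std(sizes, ddof=1) / np.sqrt(12)
        assert abs(first - both) < 3 * se

    def test_gamma_floor_flattens_reference_tails_at_large_sd(self):
        # weak-mode regime: a large share of classes ends pinned at the floor
        fracs = []
        p = AlgorithmParams(delta=5, theta=0.95, epsilon=0, gamma=GammaSpec.absolute(5))
        for s in range(4):
            lfd = simulate_mixture(MixtureConfig.three_cohorts(10.0, 2000, seed=s))
            res = reference_subsample(lfd, p)
            floors = np.array([p.gamma.floor_for(int(n)) for n in lfd.counts])
            ref = np.zeros(lfd.classes.size, dtype=int)
            off = int(res.reference.classes[0] - lfd.classes[0])
            ref[off : off + res.reference.counts.size] = res.reference.counts
            fracs.append(float((ref == floors).mean()))
        assert np.mean(fracs) > 0.2


class TestBootstrapComparison:
    def test_coverage_is_a_proportion_and_distances_exceed_adv(self):
        bc = bootstrap_comparison(
            MixtureConfig.three_cohorts(7.0, 1000),
            thetas=(0.7, 0.9),
            epsilons=(0, 3),
            replicates=5,
            n_boot=10,
            seed=6,
        )
        t = bc.table
        assert ((t["coverage"] >= 0) & (t["coverage"] <= 1)).all()
        # random subsampling scores far above the admissible threshold
        assert bc.grand_mean_D > t["mean_adv"].mean()

    def test_reproducible_given_seed(self):
        kw = dict(thetas=(0.9,), epsilons=(0,), replicates=3, n_boot=5, seed=8)
        a = bootstrap_comparison(MixtureConfig.three_cohorts(7.0, 500), **kw)
        b = bootstrap_comparison(MixtureConfig.three_cohorts(7.0, 500), **kw)
        assert a.grand_mean_D == b.grand_mean_D
        assert a.table.equals(b.table)


class TestContrastDatasets:
    def test_identical_configs_same_seed_give_zero_distance(self):
        cfg = MixtureConfig.three_cohorts(5.0, 800, seed=12)
        table = contrast_datasets(cfg, cfg, thetas=(0.8,), epsilons=(0,))
        assert table["D"].iloc[0] == 0.0
        assert not table["exceeds_adv"].iloc[0]

    def test_same_population_different_seed_much_closer_than_different_population(self):
        cfg = MixtureConfig.three_cohorts(5.0, 2000)
        same = []
        for s in range(10):
            c1 = MixtureConfig.three_cohorts(5.0, 2000, seed=2 * s)
            c2 = MixtureConfig.three_cohorts(5.0, 2000, seed=2 * s + 1)
            same.append(
                contrast_datasets(c1, c2, thetas=(0.7,), epsilons=(0,))["D"].iloc[0]
            )
        diff = contrast_datasets(
            MixtureConfig.three_cohorts(5.0, 2000, seed=3),
            MixtureConfig.two_cohorts(5.0, 1000, seed=4),
            thetas=(0.7,),
            epsilons=(0,),
        )["D"].iloc[0]
        assert np.median(same) < diff


class TestHierarchicalGenerator:
    def test_record_count_and_determinism(self):
        cfg = MixtureConfig.three_cohorts(7.0)
        a = synthetic_hierarchical_data(3, 4, 10, cfg, seed=5)
        b = synthetic_hierarchical_data(3, 4, 10, cfg, seed=5)
        assert len(a) == 3 * 4 * 10
        assert a == b

    def test_marginal_matches_mixture_without_cluster_effects(self):
        from scipy import stats

        cfg = MixtureConfig.three_cohorts(7.0)
        records = synthetic_hierarchical_data(
            5, 5, 200, cfg, trip_sd=0.0, haul_sd=0.0, seed=13
        )
        lengths = np.array([r.length_cm for r in records], dtype=float)
        grid = np.arange(1, 141)
        theo = (
            0.25 * stats.norm.cdf(grid + 0.5, 40, 7)
            + 0.5 * stats.norm.cdf(grid + 0.5, 70, 7)
            + 0.25 * stats.norm.cdf(grid + 0.5, 100, 7)
        )
        emp = np.searchsorted(np.sort(lengths), grid, side="right") / lengths.size
        assert np.max(np.abs(emp - theo)) < 0.03

    def test_raising_factor_and_metadata_bounds(self):
        records = synthetic_hierarchical_data(
            2, 3, 20, MixtureConfig.three_cohorts(5.0), catch_kg_range=(100.0, 200.0), seed=2
        )
        for r in records:
            assert r.raising_factor >= 1.0
            assert 100.0 <= r.haul_catch_kg <= 200.0
            assert r.length_cm >= 1
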