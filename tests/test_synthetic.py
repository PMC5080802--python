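"""Generator contracts: determinism, geometry, conservation, planted effects."""

import numpy as np
import pandas as pd
import pytest

from equimir import discovery, synthetic
from equimir.types import BackgroundSpec, CountSimConfig, StackProfile


class TestToyGenome:
    def test_shape_and_determinism(self):
        g = synthetic.make_toy_genome(1, [1000], seed=7)
        assert g.chrom_names == ["chr1"] and len(g.sequences[0]) == 1000
        g2 = synthetic.make_toy_genome(1, [1000], seed=7)
        assert g.sequences == g2.sequences

    def test_base_composition_within_binomial_bounds(self):
        # binomial oracle: each base count ~ Bin(n, 0.25)
        g = synthetic.make_toy_genome(2, [500, 300], seed=1)
        for seq in g.sequences:
            n = len(seq)
            sd = np.sqrt(n * 0.25 * 0.75)
            for base in "ACGT":
                assert abs(seq.count(base) - 0.25 * n) <= 3 * sd

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            synthetic.make_toy_genome(1, [0], seed=0)
        with pytest.raises(ValueError):
            synthetic.make_toy_genome(2, [100], seed=0)


class TestPlantedLoci:
    def test_no_loci_is_empty(self):
        g = synthetic.make_toy_genome(1, [5000], seed=0)
        assert synthetic.plant_mirna_loci(g, 0, seed=0) == []

    def test_full_clustering_puts_every_locus_near_a_neighbour(self):
        g = synthetic.make_toy_genome(1, [100_000], seed=3)
        loci = synthetic.plant_mirna_loci(g, 4, cluster_fraction=1.0, seed=4)
        starts = sorted(l.hairpin[0] for l in loci)
        for i, s in enumerate(starts):
            gaps = [abs(s - t) for j, t in enumerate(starts) if j != i]
            assert min(gaps) <= 3000

    def test_planted_hairpin_refolds_with_mature_arm_paired(self):
        g = synthetic.make_toy_genome(1, [50_000], seed=5)
        loci = synthetic.plant_mirna_loci(g, 5, seed=6)
        for locus in loci:
            rna = g.fetch(locus.chrom, *locus.hairpin, strand=locus.strand)
            structure, mfe = discovery.fold_hairpin(rna)
            m_len = locus.mature[1] - locus.mature[0]
            paired = sum(1 for c in structure[:m_len] if c in "()")
            assert paired / m_len >= 0.6
            assert mfe < -15

    def test_capacity_error_on_tiny_genome(self):
        g = synthetic.make_toy_genome(1, [300], seed=0)
        with pytest.raises(ValueError):
            synthetic.plant_mirna_loci(g, 10, min_gap=500, seed=0)

    def test_determinism(self):
        g1 = synthetic.make_toy_genome(1, [50_000], seed=9)
        g2 = synthetic.make_toy_genome(1, [50_000], seed=9)
        l1 = synthetic.plant_mirna_loci(g1, 6, seed=10)
        l2 = synthetic.plant_mirna_loci(g2, 6, seed=10)
        assert [(l.chrom, l.strand, l.hairpin) for l in l1] == \
               [(l.chrom, l.strand, l.hairpin) for l in l2]
        assert g1.sequences == g2.sequences


@pytest.fixture(scope="module")
def world():
    g = synthetic.make_toy_genome(1, [50_000], seed=11)
    loci = synthetic.plant_mirna_loci(g, 5, seed=12)
    return g, loci


class TestReadStacks:
    def test_read_count_conservation(self, world):
        g, loci = world
        profile = StackProfile(depth=40)
        tags = synthetic.simulate_read_stacks(loci, profile, g,
                                              n_background=1000, seed=13)
        assert sum(t.count for t in tags) == 5 * 40 + 1000

    def test_empty_input_gives_empty_output(self, world):
        g, _ = world
        assert synthetic.simulate_read_stacks([], StackProfile(), g,
                                              n_background=0, seed=0) == []

    def test_zero_jitter_means_single_modal_five_prime(self, world):
        g, loci = world
        profile = StackProfile(five_prime_jitter_sd=0.0, tail_au_fraction=0.0, depth=30)
        tags = synthetic.simulate_read_stacks(loci, profile, g, n_background=0, seed=14)
        for locus in loci:
            arm = [t for t in tags
                   if t.chrom == locus.chrom and t.strand == locus.strand
                   and locus.mature[0] - 1 <= t.start and t.end <= locus.mature[1] + 1]
            five = {t.five_prime() for t in arm}
            assert len(five) == 1

    def test_zero_loop_fraction_leaves_loops_empty(self, world):
        g, loci = world
        profile = StackProfile(loop_fraction=0.0, star_fraction=0.0,
                               mature_fraction=1.0, depth=30)
        tags = synthetic.simulate_read_stacks(loci, profile, g, n_background=0, seed=15)
        for locus in loci:
            inside_loop = [t for t in tags
                           if t.chrom == locus.chrom
                           and locus.loop[0] <= t.start and t.end <= locus.loop[1]]
            assert inside_loop == []

    def test_background_length_mixture_fraction(self):
        # binomial oracle on the 30-32 nt peak weight
        g = synthetic.make_toy_genome(1, [100_000], seed=16)
        tags = synthetic.simulate_read_stacks([], StackProfile(), g,
                                              background=BackgroundSpec(),
                                              n_background=10_000, seed=17)
        total = sum(t.count for t in tags)
        in_peak = sum(t.count for t in tags if 30 <= t.length <= 32)
        sd = np.sqrt(10_000 * 0.78 * 0.22)
        assert abs(in_peak - 0.78 * total) <= 3 * sd

    def test_tailed_reads_extend_past_the_arm(self, world):
        g, loci = world
        profile = StackProfile(tail_au_fraction=1.0, star_fraction=0.0,
                               loop_fraction=0.0, mature_fraction=1.0, depth=30)
        tags = synthetic.simulate_read_stacks(loci, profile, g, n_background=0, seed=18)
        tailed = [t for t in tags if t.length > 25]
        assert tailed
        for t in tailed:
            assert t.sequence[-1] in "AT"

    def test_multihit_background_fraction(self):
        g = synthetic.make_toy_genome(1, [100_000], seed=19)
        spec = BackgroundSpec(multihit_fraction=0.5)
        tags = synthetic.simulate_read_stacks([], StackProfile(), g, background=spec,
                                              n_background=5000, seed=20)
        frac = sum(t.count for t in tags if t.n_hits > 5) / sum(t.count for t in tags)
        assert abs(frac - 0.5) < 0.05


class TestCountSimulation:
    def test_dispersion_zero_is_poisson_like(self):
        # Poisson-limit oracle: with equal library sizes and no planted
        # effects every sample of a row shares one mean, so the across-sample
        # variance of a row should match its mean
        cfg = CountSimConfig(n_mirnas=40, group_sizes={"A": 500, "B": 500},
                             dispersion=0.0, lib_size_range=(50_000, 50_000),
                             seed=1000)
        cm = synthetic.simulate_counts([f"m{i}" for i in range(40)], cfg)
        row_mean = cm.counts.mean(axis=1)
        row_var = cm.counts.var(axis=1, ddof=1)
        big = row_mean > 20
        ratio = (row_var[big] / row_mean[big]).to_numpy()
        assert abs(np.median(ratio) - 1.0) < 0.2

    def test_positive_dispersion_is_overdispersed(self):
        cfg = CountSimConfig(n_mirnas=40, group_sizes={"A": 500, "B": 500},
                             dispersion=0.5, lib_size_range=(50_000, 50_000),
                             seed=1001)
        cm = synthetic.simulate_counts([f"m{i}" for i in range(40)], cfg)
        row_mean = cm.counts.mean(axis=1)
        row_var = cm.counts.var(axis=1, ddof=1)
        big = row_mean > 20
        assert np.median((row_var[big] / row_mean[big]).to_numpy()) > 2.0

    def test_null_simulation_has_equal_group_means(self):
        ids = [f"m{i}" for i in range(100)]
        cfg = CountSimConfig(n_mirnas=100, group_sizes={"A": 20, "B": 20},
                             dispersion=0.05, lib_size_range=(10 ** 6, 10 ** 6), seed=21)
        cm = synthetic.simulate_counts(ids, cfg)
        a = cm.counts.loc[:, cm.metadata["breed"] == "A"].mean(axis=1)
        b = cm.counts.loc[:, cm.metadata["breed"] == "B"].mean(axis=1)
        lfc = np.log2((a + 0.5) / (b + 0.5))
        assert abs(lfc.mean()) < 0.1

    def test_planted_effect_is_recovered_at_stated_magnitude(self):
        # Monte-Carlo oracle at the largest planted breed effect (7.05)
        ids = [f"m{i}" for i in range(200)]
        cfg = CountSimConfig(n_mirnas=200, group_sizes={"Warmblood": 10, "pony": 10},
                             dispersion=0.05, lib_size_range=(10 ** 6, 10 ** 6),
                             planted_lfc={("m7", "pony"): 7.05}, seed=22)
        cm = synthetic.simulate_counts(ids, cfg)
        pony = cm.counts.loc["m7", cm.metadata["breed"] == "pony"].mean()
        wb = cm.counts.loc["m7", cm.metadata["breed"] == "Warmblood"].mean()
        assert np.log2((pony + 0.5) / (wb + 0.5)) == pytest.approx(7.05, abs=0.5)

    def test_metadata_covers_all_samples(self):
        cfg = CountSimConfig(n_mirnas=10, group_sizes={"A": 2, "B": 3}, seed=0)
        cm = synthetic.simulate_counts([f"m{i}" for i in range(10)], cfg)
        assert list(cm.counts.columns) == list(cm.metadata.index)
        for col in ("breed", "tissue", "sex", "age", "absorbance414"):
            assert col in cm.metadata.columns

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            CountSimConfig(dispersion=-1)
        with pytest.raises(ValueError):
            CountSimConfig(group_sizes={"A": 1, "B": 5})
        cfg = CountSimConfig(n_mirnas=5, group_sizes={"A": 2, "B": 2},
                             planted_lfc={("nope", "A"): 2.0})
        with pytest.raises(ValueError):
            synthetic.simulate_counts([f"m{i}" for i in range(5)], cfg)

    def test_determinism(self):
        cfg = CountSimConfig(n_mirnas=20, group_sizes={"A": 3, "B": 3}, seed=5)
        ids = [f"m{i}" for i in range(20)]
        cm1 = synthetic.simulate_counts(ids, cfg)
        cm2 = synthetic.simulate_counts(ids, cfg)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
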