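"""Candidate excision, the ten stringent criteria, scoring, permutation SNR."""

import numpy as np
import pytest

from equimir import discovery, synthetic
from equimir.types import AlignedTag, BackgroundSpec, StackProfile, revcomp

from conftest import call_matches_locus


def make_tag(genome, chrom, start, end, strand="+", count=1, n_hits=1, tail=""):
    seq = genome.fetch(chrom, start, end, strand) + tail
    if tail:
        if strand == "+":
            end += len(tail)
        else:
            start -= len(tail)
    return AlignedTag(chrom=chrom, start=start, end=end, strand=strand,
                      sequence=seq, count=count, n_hits=n_hits)


class TestExcision:
    def test_planted_loci_recovered_exactly(self, planted_world):
        genome, loci = planted_world["genome"], planted_world["loci"]
        profile = StackProfile(five_prime_jitter_sd=0.0, depth=50)
        tags = synthetic.simulate_read_stacks(loci, profile, genome,
                                              n_background=0, seed=99)
        cands = discovery.excise_candidates(tags, genome)
        assert len(cands) == len(loci)
        found = {c.mature_genomic for c in cands}
        assert found == {l.mature for l in loci}

    def test_low_depth_random_tags_give_no_candidates(self, planted_world):
        genome = planted_world["genome"]
        rng = np.random.default_rng(7)
        tags = [make_tag(genome, "chr1", int(s), int(s) + 22)
                for s in rng.integers(0, 50_000, size=400)]
        assert discovery.excise_candidates(tags, genome, min_stack_count=5) == []

    def test_two_locus_toy_fixture_yields_two_candidates(self):
        genome = synthetic.make_toy_genome(1, [20_000], seed=70)
        loci = synthetic.plant_mirna_loci(genome, 2, min_gap=2000, seed=71)
        tags = synthetic.simulate_read_stacks(loci, StackProfile(depth=30), genome,
                                              n_background=0, seed=72)
        assert len(discovery.excise_candidates(tags, genome)) == 2

    def test_contig_edge_window_is_flagged(self):
        genome = synthetic.make_toy_genome(1, [400], seed=73)
        tags = [make_tag(genome, "chr1", 5, 27, count=10)]
        cands = discovery.excise_candidates(tags, genome)
        assert cands and cands[0].truncated


@pytest.fixture(scope="module")
def clean_candidate():
    """One clean planted locus: no positional scatter, 30 % tailed reads."""
    genome = synthetic.make_toy_genome(1, [30_000], seed=80)
    loci = synthetic.plant_mirna_loci(genome, 1, seed=81)
    profile = StackProfile(mature_fraction=0.88, star_fraction=0.10,
                           loop_fraction=0.02, depth=60, tail_au_fraction=0.3)
    tags = synthetic.simulate_read_stacks(loci, profile, genome,
                                          n_background=0, seed=82)
    cands = discovery.excise_candidates(tags, genome)
    assert len(cands) == 1
    return genome, loci[0], cands[0]


class TestEvaluation:
    def test_clean_duplex_has_two_nt_overhangs(self, clean_candidate):
        genome, _, cand = clean_candidate
        ev = discovery.evaluate_candidate(cand, cand.support, genome=genome)
        assert ev.overhang_ok

    def test_zero_jitter_means_zero_heterogeneity(self, clean_candidate):
        genome, _, cand = clean_candidate
        ev = discovery.evaluate_candidate(cand, cand.support, genome=genome)
        assert ev.five_prime_heterogeneity == 0.0
        assert ev.three_prime_heterogeneity == 0.0

    def test_tailing_detected(self, clean_candidate):
        genome, _, cand = clean_candidate
        ev = discovery.evaluate_candidate(cand, cand.support, genome=genome)
        assert 0.1 <= ev.tailing_fraction <= 0.6

    def test_excess_multimapping_fails_the_candidate(self, clean_candidate):
        genome, locus, cand = clean_candidate
        bumped = [AlignedTag(t.chrom, t.start, t.end, t.strand, t.sequence,
                             count=t.count, n_hits=5) for t in cand.support]
        ev = discovery.evaluate_candidate(cand, bumped, genome=genome)
        assert ev.multimap_factor == 5
        assert not ev.passed

    def test_pass_implies_multimap_bound(self, planted_world):
        genome, tags = planted_world["genome"], planted_world["tags"]
        for cand in discovery.excise_candidates(tags, genome):
            ev = discovery.evaluate_candidate(cand, cand.support, genome=genome)
            if ev.passed:
                assert ev.multimap_factor <= 4

    def test_empty_support_is_an_error(self, clean_candidate):
        genome, _, cand = clean_candidate
        with pytest.raises(ValueError):
            discovery.evaluate_candidate(cand, [], genome=genome)


class TestScoring:
    def test_score_is_sum_of_its_four_terms(self, planted_world):
        genome, tags = planted_world["genome"], planted_world["tags"]
        bg = planted_world["background_model"]
        cand = discovery.excise_candidates(tags, genome)[0]
        support = cand.support[:5]
        terms = discovery.score_terms(cand, support, bg)
        assert set(terms) == {"structure", "duplex", "reads", "star"}
        assert discovery.score_candidate(cand, support, bg) == pytest.approx(sum(terms.values()))

    def test_clean_planted_stack_scores_above_cutoff(self, planted_world):
        genome, tags = planted_world["genome"], planted_world["tags"]
        bg = planted_world["background_model"]
        scores = [discovery.score_candidate(c, c.support, bg)
                  for c in discovery.excise_candidates(tags, genome)]
        assert np.median(scores) >= 1.0

    def test_scattered_reads_score_strictly_lower(self):
        genome = synthetic.make_toy_genome(1, [30_000], seed=85)
        loci = synthetic.plant_mirna_loci(genome, 1, seed=86)
        tags = synthetic.simulate_read_stacks(loci, StackProfile(depth=50), genome,
                                              n_background=0, seed=87)
        bg = discovery.fit_background_model(genome, seed=88)
        cand = discovery.excise_candidates(tags, genome)[0]
        clean = discovery.score_candidate(cand, cand.support, bg)
        # scatter the same read mass uniformly over the hairpin window
        rng = np.random.default_rng(89)
        w0, w1 = cand.interval
        scattered = []
        for t in cand.support:
            s = int(rng.integers(w0, w1 - 22))
            scattered.append(make_tag(genome, t.chrom, s, s + 22, t.strand, count=t.count))
        assert discovery.score_candidate(cand, scattered, bg) < clean

    def test_adding_modal_mature_reads_never_decreases_score(self, planted_world):
        genome, tags = planted_world["genome"], planted_world["tags"]
        bg = planted_world["background_model"]
        cand = discovery.excise_candidates(tags, genome)[0]
        m0, m1 = cand.mature_genomic
        extra = make_tag(genome, cand.chrom, m0, m1, cand.strand, count=25)
        s1 = discovery.score_candidate(cand, cand.support, bg)
        s2 = discovery.score_candidate(cand, cand.support + [extra], bg)
        assert s2 >= s1


class TestCalling:
    def test_deep_mode_recalls_planted_loci(self, planted_world):
        genome, loci, tags = (planted_world["genome"], planted_world["loci"],
                              planted_world["tags"])
        calls = discovery.call_mirnas(tags, genome, mode="deep", score_cutoff=1.0,
                                      background=planted_world["background_model"])
        recall = sum(any(call_matches_locus(c, l) for c in calls) for l in loci) / len(loci)
        assert recall == 1.0

    def test_dentify_calls_are_fewer_and_respect_multimap(self, planted_world):
        genome, tags = planted_world["genome"], planted_world["tags"]
        bg = planted_world["background_model"]
        deep = discovery.call_mirnas(tags, genome, mode="deep", score_cutoff=1.0,
                                     background=bg)
        dentify = discovery.call_mirnas(tags, genome, mode="dentify", background=bg)
        assert len(dentify) <= len(deep)
        assert {c.tool for c in dentify} <= {"dentify"}

    def test_infinite_cutoff_returns_nothing(self, planted_world):
        genome, tags = planted_world["genome"], planted_world["tags"]
        calls = discovery.call_mirnas(tags, genome, mode="deep",
                                      score_cutoff=float("inf"),
                                      background=planted_world["background_model"])
        assert calls == []

    def test_unknown_mode_rejected(self, planted_world):
        with pytest.raises(ValueError):
            discovery.call_mirnas([], planted_world["genome"], mode="strict")


class TestSignalToNoise:
    def test_single_permutation_is_reproducible(self, background_world):
        genome, tags = background_world["genome"], background_world["tags"]
        bg = discovery.fit_background_model(genome, seed=90)
        p1 = discovery.signal_to_noise(tags, genome, n_perm=1, seed=91, background=bg)
        p2 = discovery.signal_to_noise(tags, genome, n_perm=1, seed=91, background=bg)
        assert np.array_equal(p1.perm_counts, p2.perm_counts)
        assert len(p1.cutoffs) == 21

    def test_planted_signal_beats_low_cutoff_noise(self, planted_world):
        genome, tags = planted_world["genome"], planted_world["tags"]
        profile = discovery.signal_to_noise(
            tags, genome, n_perm=10, seed=92,
            background=planted_world["background_model"])
        at = {c: i for i, c in enumerate(profile.cutoffs)}
        snr1 = profile.snr[at[1]]
        snr_lo = profile.snr[at[-10]]
        assert profile.real_counts[at[1]] >= 19
        assert np.isnan(snr_lo) or snr1 > snr_lo or np.isinf(snr1)

    def test_permutation_preserves_tag_metadata(self, background_world):
        genome, tags = background_world["genome"], background_world["tags"]
        rng = np.random.default_rng(93)
        perm = discovery.permute_tags(tags, genome, rng)
        assert sorted((t.length, t.count, t.n_hits, t.strand) for t in perm) == \
               sorted((t.length, t.count, t.n_hits, t.strand) for t in tags)
        for t in perm[:20]:
            assert t.sequence == genome.fetch(t.chrom, t.start, t.end, t.strand)
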