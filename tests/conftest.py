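"""Shared fixtures: a toy genome with planted loci and simulated samples."""

import numpy as np
import pytest

from equimir import discovery, read_processing, synthetic
from equimir.types import BackgroundSpec, StackProfile


@pytest.fixture(scope="session")
def planted_world():
    """Two-chromosome toy genome, 20 clean planted loci, one 50x sample."""
    genome = synthetic.make_toy_genome(2, [60_000, 40_000], seed=1)
    loci = synthetic.plant_mirna_loci(genome, 20, cluster_fraction=0.2,
                                      min_gap=500, seed=2)
    profile = StackProfile(depth=50)
    tags = synthetic.simulate_read_stacks(loci, profile, genome,
                                          background=BackgroundSpec(),
                                          n_background=3000, seed=3)
    tags = read_processing.filter_tags(tags)
    background_model = discovery.fit_background_model(genome, seed=4)
    return {"genome": genome, "loci": loci, "tags": tags,
            "profile": profile, "background_model": background_model}


@pytest.fixture(scope="session")
def background_world():
    """A genome with no planted loci and a dense pure-background sample."""
    genome = synthetic.make_toy_genome(1, [20_000], seed=50)
    tags = synthetic.simulate_read_stacks([], StackProfile(depth=50), genome,
                                          background=BackgroundSpec(),
                                          n_background=4000, seed=51)
    tags = read_processing.filter_tags(tags)
    return {"genome": genome, "tags": tags}


def call_matches_locus(call, locus, tol=3):
    return (call.chrom == locus.chrom and call.strand == locus.strand
            and abs(call.mature[0] - locus.mature[0]) <= tol
            and abs(call.mature[1] - locus.mature[1]) <= tol)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
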