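"""Synthetic genomes, planted hairpin loci, read stacks and count matrices.

Every downstream stage is testable offline against these generators: the
planted loci obey the Dicer duplex geometry the discovery module looks for
(mature/star arms reverse-complementary with 2-nt 3' overhangs at both
duplex ends), read stacks reproduce the mature-arm-dominant coverage of
authentic miRNA loci over a two-peak fragment-length background, and the
count simulator produces negative-binomial matrices with library-size and
composition bias plus planted tissue/breed effects.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .read_processing import collapse_reads
from .types import (ALPHABET, AlignedTag, BackgroundSpec, CountMatrix, CountSimConfig,
                    GenomeRef, PlantedLocus, StackProfile, revcomp)


def make_toy_genome(n_chroms: int, lengths: Sequence[int], seed: int = 0,
                    base_probs=(0.25, 0.25, 0.25, 0.25),
                    names: Optional[Sequence[str]] = None) -> GenomeRef:
    """Random genome with ``n_chroms`` chromosomes of the given lengths.

    Base composition is i.i.d. with ``base_probs`` over (A, C, G, T);
    the default is GC ~= 0.5. Reproducible given ``seed``.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if len(lengths) != n_chroms:
        raise ValueError("need one length per chromosome")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_chroms)]
    bases = np.array(list(ALPHABET))
    seqs = ["".join(rng.choice(bases, size=l, p=np.asarray(base_probs))) for l in lengths]
    return GenomeRef(chrom_names=list(names), sequences=seqs)


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=n))


def _build_hairpin(rng, mature_len: int, loop_len: int, identity_fraction: float):
    """Mature + loop + star with 2-nt 3' overhangs built into the geometry.

    The star pairs mature[0 : L-2] (leaving the mature 3' overhang
    unpaired) and carries two extra 3' nucleotides of its own; a fraction
    (1 - identity_fraction) of the paired star positions is mutated.
    """
    mature = _random_seq(rng, mature_len)
    loop = _random_seq(rng, loop_len)
    # keep the Dicer 2-nt 3' overhang geometry intact: the loop bases facing
    # the mature overhang must not extend the helix (no WC or GU pair)
    pairable = {"A": "T", "T": "AG", "G": "CT", "C": "G"}
    loop_chars = list(loop)
    for k, m_base in ((1, mature[-2]), (2, mature[-1])):
        if loop_chars[-k] in pairable[m_base]:
            loop_chars[-k] = rng.choice([b for b in ALPHABET if b not in pairable[m_base]])
    loop = "".join(loop_chars)
    paired = revcomp(mature[: mature_len - 2])
    if identity_fraction < 1.0:
        n_mut = int(round((1.0 - identity_fraction) * len(paired)))
        pos = rng.choice(len(paired), size=n_mut, replace=False)
        chars = list(paired)
        for p in pos:
            chars[p] = rng.choice([b for b in ALPHABET if b != chars[p]])
        paired = "".join(chars)
    star = paired + _random_seq(rng, 2)
    return mature, loop, star


def plant_mirna_loci(genome: GenomeRef, n_loci: int, cluster_fraction: float = 0.0,
                     min_gap: int = 500, seed: int = 0,
                     mature_len_range=(20, 23), loop_len_range=(12, 18),
                     identity_fraction: float = 1.0) -> list:
    """Write ``n_loci`` hairpin loci into the genome (in place).

    ``cluster_fraction`` of the loci are placed < 3000 nt from a
    neighbouring locus (genomic miRNA clusters); the rest are at least
    ``min_gap`` apart. Strands are assigned ~50/50. Raises a capacity
    error when the genome cannot host the requested loci.
    """
    if n_loci == 0:
        return []
    rng = np.random.default_rng(seed)
    max_hairpin = 2 * mature_len_range[1] + loop_len_range[1]
    chrom_lens = [len(s) for s in genome.sequences]
    if sum(max(l - 2 * max_hairpin, 0) for l in chrom_lens) < n_loci * (min_gap + max_hairpin):
        raise ValueError("genome too small for the requested loci and min_gap")

    n_clustered = int(round(cluster_fraction * n_loci))
    if n_clustered == 1:
        n_clustered = 2 if n_loci >= 2 else 0
    placements = []      # (chrom_idx, start, hairpin_len)

    def fits(ci, start, hlen, gap):
        if start < 0 or start + hlen > chrom_lens[ci]:
            return False
        return all(c != ci or (start + hlen + gap <= s or s + h + gap <= start)
                   for c, s, h in placements)

    lens = []
    for _ in range(n_loci):
        ml = int(rng.integers(mature_len_range[0], mature_len_range[1] + 1))
        ll = int(rng.integers(loop_len_range[0], loop_len_range[1] + 1))
        lens.append((ml, ll, 2 * ml + ll))

    weights = np.asarray(chrom_lens, dtype=float) / sum(chrom_lens)
    i = 0
    while i < n_loci:
        ml, ll, hlen = lens[i]
        placed = False
        for _ in range(2000):
            if i > 0 and i < n_clustered:       # anchor to the previous locus
                ci, s_prev, h_prev = placements[-1]
                offset = int(rng.integers(h_prev + 20, 2800))
                start = s_prev + offset
                gap = 20
            else:
                ci = int(rng.choice(len(chrom_lens), p=weights))
                start = int(rng.integers(0, max(chrom_lens[ci] - hlen, 1)))
                gap = min_gap
            if fits(ci, start, hlen, gap):
                placements.append((ci, start, hlen))
                placed = True
                break
        if not placed:
            raise ValueError("could not place all loci; genome capacity exhausted")
        i += 1

    loci = []
    for idx, ((ci, start, hlen), (ml, ll, _)) in enumerate(zip(placements, lens)):
        strand = "+" if rng.random() < 0.5 else "-"
        mature, loop, star = _build_hairpin(rng, ml, ll, identity_fraction)
        hairpin_rna = mature + loop + star
        chrom = genome.chrom_names[ci]
        written = hairpin_rna if strand == "+" else revcomp(hairpin_rna)
        seq = genome.sequences[ci]
        genome.sequences[ci] = seq[:start] + written + seq[start + hlen:]
        h = (start, start + hlen)
        if strand == "+":
            m = (start, start + ml)
            lp = (start + ml, start + ml + ll)
            st = (start + ml + ll, start + hlen)
        else:
            m = (start + hlen - ml, start + hlen)
            lp = (start + ml, start + hlen - ml)
            st = (start, start + ml)
        loci.append(PlantedLocus(
            chrom=chrom, strand=strand, hairpin=h, mature=m, star=st, loop=lp,
            identity_fraction=identity_fraction, name=f"planted-mir-{idx + 1}",
        ))
    return loci


def _jittered(rng, interval, strand, sd, chrom_len):
    """Shift the 5' end of an arm interval by a rounded normal deviate."""
    s, e = interval
    if sd > 0:
        j = int(round(rng.normal(0.0, sd)))
        if strand == "+":
            s = min(max(s + j, 0), e - 15)
        else:
            e = max(min(e + j, chrom_len), s + 15)
    return s, e


def simulate_read_stacks(loci: Sequence[PlantedLocus], profile: StackProfile,
                         genome: GenomeRef,
                         background: Optional[BackgroundSpec] = None,
                         n_background: int = 0, seed: int = 0) -> list:
    """Simulate one sample's collapsed tags over planted loci plus background.

    Per locus, ``profile.depth`` reads are split multinomially between the
    mature arm, star arm, loop and hairpin-wide scatter; mature/star reads
    get 5'-end jitter and, for ``tail_au_fraction`` of them, 1-3 untemplated
    A/U 3' additions (the tag interval is extended over the mismatching
    genomic bases, as an aligner tolerating terminal mismatches would
    report). Background fragments follow the two-peak length mixture at
    uniform positions; a configurable fraction of them carries > 5 genomic
    hits. The summed tag count equals depth x loci + ``n_background``.
    """
    rng = np.random.default_rng(seed)
    background = background or BackgroundSpec()
    reads = []

    for locus in loci:
        clen = genome.length(locus.chrom)
        rest = 1.0 - profile.mature_fraction - profile.star_fraction - profile.loop_fraction
        n_m, n_s, n_l, n_r = rng.multinomial(
            profile.depth,
            [profile.mature_fraction, profile.star_fraction, profile.loop_fraction, max(rest, 0.0)],
        )
        for arm, n_arm in ((locus.mature, n_m), (locus.star, n_s)):
            for _ in range(n_arm):
                s, e = _jittered(rng, arm, locus.strand, profile.five_prime_jitter_sd, clen)
                seq = genome.fetch(locus.chrom, s, e, locus.strand)
                if profile.tail_au_fraction > 0 and rng.random() < profile.tail_au_fraction:
                    k = int(rng.integers(1, 4))
                    # untemplated additions must mismatch the genome, or an
                    # aligner would simply have extended the alignment
                    if locus.strand == "+" and e + k <= clen:
                        ext = genome.fetch(locus.chrom, e, e + k, "+")
                        tail = "".join(("T" if b == "A" else "A") if b in "AT"
                                       else rng.choice(["A", "T"]) for b in ext)
                        e, seq = e + k, seq + tail
                    elif locus.strand == "-" and s - k >= 0:
                        ext = genome.fetch(locus.chrom, s - k, s, "-")
                        tail = "".join(("T" if b == "A" else "A") if b in "AT"
                                       else rng.choice(["A", "T"]) for b in ext)
                        s, seq = s - k, seq + tail
                reads.append(AlignedTag(locus.chrom, s, e, locus.strand, seq))
        l0, l1 = locus.loop
        for _ in range(n_l):
            reads.append(AlignedTag(locus.chrom, l0, l1, locus.strand,
                                    genome.fetch(locus.chrom, l0, l1, locus.strand)))
        h0, h1 = locus.hairpin
        for _ in range(n_r):
            L = min(int(rng.integers(18, 25)), h1 - h0)
            s = int(rng.integers(h0, h1 - L + 1))
            reads.append(AlignedTag(locus.chrom, s, s + L, locus.strand,
                                    genome.fetch(locus.chrom, s, s + L, locus.strand)))

    if n_background > 0:
        probs = background.length_probabilities()
        lens = np.array(sorted(probs))
        p = np.array([probs[l] for l in lens])
        p = p / p.sum()
        chrom_lens = np.array([len(s) for s in genome.sequences], dtype=float)
        cw = chrom_lens / chrom_lens.sum()
        drawn = rng.choice(lens, size=n_background, p=p)
        cidx = rng.choice(len(chrom_lens), size=n_background, p=cw)
        multi = rng.random(n_background) < background.multihit_fraction
        for L, ci, mh in zip(drawn, cidx, multi):
            chrom = genome.chrom_names[ci]
            clen = int(chrom_lens[ci])
            L = int(min(L, clen))
            s = int(rng.integers(0, clen - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            n_hits = int(rng.integers(6, 51)) if mh else 1
            reads.append(AlignedTag(chrom, s, s + L, strand,
                                    genome.fetch(chrom, s, s + L, strand), n_hits=n_hits))

    return collapse_reads(reads)


def simulate_counts(catalog, config: CountSimConfig) -> CountMatrix:
    """Negative-binomial miRNA x sample counts with planted effects.

    Baseline relative abundances are log-normal; per-sample means are the
    column-renormalised abundances times a random library size, so planted
    fold changes and composition bias displace the counts of unaffected
    miRNAs exactly the way sequencing depth competition does. Counts are
    NB(mean, dispersion) with variance mu + phi mu^2 (Poisson at phi = 0).
    """
    rng = np.random.default_rng(config.seed)
    ids = [getattr(e, "id", e) for e in catalog]
    if len(ids) == 0:
        raise ValueError("empty catalog")
    for (mid, _g) in config.planted_lfc:
        if mid not in ids:
            raise ValueError(f"planted effect refers to unknown miRNA {mid!r}")

    samples, groups = [], []
    for g, n in config.group_sizes.items():
        for k in range(n):
            samples.append(f"{g}_{k + 1}")
            groups.append(g)
    n_s = len(samples)
    for (_m, g) in config.planted_lfc:
        if g not in config.group_sizes:
            raise ValueError(f"planted effect refers to unknown group {g!r}")

    meta = pd.DataFrame(index=pd.Index(samples, name="sample"))
    meta[config.group_col] = groups
    other = "tissue" if config.group_col == "breed" else "breed"
    meta[other] = "serum" if other == "tissue" else "mixed"
    meta["sex"] = [("M", "F")[i % 2] for i in range(n_s)]
    meta["age"] = rng.integers(5, 26, size=n_s)
    meta["absorbance414"] = np.round(rng.uniform(0.05, 1.5, size=n_s), 3)

    base = rng.lognormal(mean=2.0, sigma=1.5, size=len(ids))
    mu = np.tile(base[:, None], (1, n_s)).astype(float)
    for (mid, g), lfc in config.planted_lfc.items():
        i = ids.index(mid)
        cols = [j for j, gg in enumerate(groups) if gg == g]
        mu[i, cols] *= 2.0 ** lfc
    for mid, slope in config.absorbance_effect.items():
        i = ids.index(mid)
        a = meta["absorbance414"].to_numpy()
        mu[i, :] *= (a / a.mean()) ** slope
    if config.composition_bias_fraction > 0 and len(config.bias_samples) > 0:
        n_bias = int(round(config.composition_bias_fraction * len(ids)))
        bias_rows = rng.choice(len(ids), size=n_bias, replace=False)
        for s in config.bias_samples:
            j = samples.index(s) if isinstance(s, str) else int(s)
            mu[bias_rows, j] *= config.bias_factor

    lib = rng.integers(config.lib_size_range[0], config.lib_size_range[1] + 1, size=n_s)
    mu = mu / mu.sum(axis=0, keepdims=True) * lib[None, :]

    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    frame = pd.DataFrame(counts, index=pd.Index(ids, name="mirna"), columns=samples)
    return CountMatrix(counts=frame, metadata=meta)
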