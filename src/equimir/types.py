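"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open; conversion to the 1-based,
closed GFF3 convention happens only inside :mod:`equimir.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

ALPHABET = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returns DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRef:
    """A reference genome held in memory.

    Chromosome names must be unique and sequences non-empty over {A,C,G,T}.
    """

    chrom_names: list
    sequences: list

    def __post_init__(self):
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if len(self.chrom_names) != len(self.sequences):
            raise ValueError("names/sequences length mismatch")
        for name, seq in zip(self.chrom_names, self.sequences):
            if len(seq) == 0:
                raise ValueError(f"empty sequence for {name}")
            if set(seq) - set(ALPHABET):
                raise ValueError(f"non-ACGT characters in {name}")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[self.chrom_names.index(chrom)]

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of an interval; '-' strand returns the reverse complement."""
        seq = self[chrom][max(start, 0):end]
        return revcomp(seq) if strand == "-" else seq


@dataclass
class PlantedLocus:
    """A miRNA hairpin written into a toy genome.

    Intervals are genomic. The mature arm is the 5' arm of the hairpin RNA;
    on the '-' strand that corresponds to the right-hand genomic side.
    """

    chrom: str
    strand: str
    hairpin: tuple          # (start, end)
    mature: tuple
    star: tuple
    loop: tuple
    identity_fraction: float = 1.0
    name: str = ""

    def __post_init__(self):
        h0, h1 = self.hairpin
        for iv in (self.mature, self.star, self.loop):
            if not (h0 <= iv[0] < iv[1] <= h1):
                raise ValueError("sub-interval outside hairpin")
        m0, m1 = self.mature
        if not (19 <= m1 - m0 <= 25):
            raise ValueError("mature length outside 19-25 nt")


@dataclass
class StackProfile:
    """How reads pile up over a planted hairpin.

    Fractions are of the per-locus depth; whatever is left over is scattered
    uniformly across the hairpin. The mature arm is expected to dominate.
    """

    mature_fraction: float = 0.80
    star_fraction: float = 0.12
    loop_fraction: float = 0.02
    five_prime_jitter_sd: float = 0.0
    tail_au_fraction: float = 0.0
    depth: int = 50

    def __post_init__(self):
        fr = (self.mature_fraction, self.star_fraction, self.loop_fraction)
        if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1 + 1e-9:
            raise ValueError("fractions must be in [0,1] and sum to <= 1")
        if not (self.mature_fraction >= self.star_fraction >= self.loop_fraction):
            raise ValueError("expected mature >= star >= loop fractions")


@dataclass
class BackgroundSpec:
    """Two-peak fragment length mixture for non-miRNA background.

    Defaults follow serum small-RNA libraries: a dominant piRNA-sized peak
    (30-32 nt, 78 %) and a small mature-miRNA-sized peak (22-23 nt, 4 %);
    the remainder is uniform over the other lengths in ``length_range``.
    """

    peaks: dict = field(default_factory=lambda: {(30, 32): 0.78, (22, 23): 0.04})
    length_range: tuple = (18, 35)
    multihit_fraction: float = 0.0

    def length_probabilities(self) -> dict:
        lo, hi = self.length_range
        probs = {}
        peak_lengths = set()
        for (a, b), w in self.peaks.items():
            ls = list(range(a, b + 1))
            peak_lengths.update(ls)
            for l in ls:
                probs[l] = probs.get(l, 0.0) + w / len(ls)
        rest = [l for l in range(lo, hi + 1) if l not in peak_lengths]
        w_rest = 1.0 - sum(self.peaks.values())
        if w_rest < -1e-9:
            raise ValueError("peak weights exceed 1")
        for l in rest:
            probs[l] = probs.get(l, 0.0) + max(w_rest, 0.0) / len(rest)
        return probs


@dataclass
class CountSimConfig:
    """Negative-binomial count matrix simulation settings.

    ``group_sizes`` maps group label -> number of samples for the grouping
    column named by ``group_col`` (tissue or breed). ``planted_lfc`` maps
    (miRNA id, group label) -> log2 fold change applied multiplicatively.
    """

    n_mirnas: int = 200
    group_sizes: dict = field(default_factory=lambda: {"Warmblood": 44, "pony": 5})
    group_col: str = "breed"
    dispersion: float = 0.1
    lib_size_range: tuple = (500_000, 1_500_000)
    planted_lfc: dict = field(default_factory=dict)
    composition_bias_fraction: float = 0.0
    bias_factor: float = 8.0
    bias_samples: tuple = ()
    absorbance_effect: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples")


@dataclass
class AlignedTag:
    """One collapsed, uniquely-identified aligned read.

    ``count`` is the number of identical raw reads collapsed into the tag;
    ``n_hits`` the number of genomic placements the aligner reported.
    """

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    count: int = 1
    n_hits: int = 1

    def __post_init__(self):
        if self.end - self.start != len(self.sequence):
            raise ValueError("interval length != sequence length")
        if self.count < 1 or self.n_hits < 1:
            raise ValueError("count and n_hits must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (position of the first base)."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class HairpinCandidate:
    """A putative precursor excised around a read stack.

    ``sequence``/``structure`` are in RNA orientation (5'->3'); ``mature``,
    ``star`` and ``loop`` are local intervals into that sequence. ``interval``
    is the genomic span of the excised window.
    """

    chrom: str
    strand: str
    interval: tuple
    sequence: str
    structure: str
    mfe: float
    mature: tuple
    star: Optional[tuple]
    loop: Optional[tuple]
    truncated: bool = False
    support: list = field(default_factory=list, repr=False)

    def local_to_genomic(self, local: tuple) -> tuple:
        s, e = self.interval
        a, b = local
        if self.strand == "+":
            return (s + a, s + b)
        return (e - b, e - a)

    @property
    def mature_genomic(self) -> tuple:
        return self.local_to_genomic(self.mature)

    @property
    def star_genomic(self) -> Optional[tuple]:
        return None if self.star is None else self.local_to_genomic(self.star)


@dataclass
class CandidateEvaluation:
    """The ten biogenesis criteria evaluated for one candidate."""

    five_prime_heterogeneity: float
    three_prime_heterogeneity: float
    overhang_ok: bool
    duplex_mfe: float
    flanking_mfe: float
    nucleotide_entropy: float
    structural_entropy: float
    tailing_fraction: float
    multimap_factor: int
    passed: bool


@dataclass
class CandidateCall:
    """One per-sample discovery call."""

    sample: str
    tool: str                      # "deep" | "dentify"
    chrom: str
    strand: str
    mature: tuple                  # genomic interval
    hairpin: tuple                 # genomic interval
    mature_sequence: str
    score: float

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")
        if not (self.hairpin[0] <= self.mature[0] < self.mature[1] <= self.hairpin[1]):
            raise ValueError("mature interval must lie within the hairpin")


@dataclass
class SNRProfile:
    """Signal-to-noise over integer score cutoffs -10..10."""

    cutoffs: np.ndarray
    real_counts: np.ndarray
    perm_mean: np.ndarray
    perm_counts: np.ndarray        # (n_perm, n_cutoffs)
    snr: np.ndarray                # real / mean permuted; NaN where 0/0

    def band(self, lo: float = 2.5, hi: float = 97.5):
        return (np.percentile(self.perm_counts, lo, axis=0),
                np.percentile(self.perm_counts, hi, axis=0))


@dataclass
class CatalogEntry:
    """A consolidated mature+hairpin pair in the non-redundant catalog."""

    id: str
    chrom: str
    strand: str
    mature: tuple
    hairpin: tuple
    mature_sequence: str
    support_samples: int
    best_score: float
    tools: frozenset
    novel: bool
    known_overlap: str = "none"    # none | same-strand | opposite-strand | near-identical
    known_partner: Optional[str] = None
    cluster_id: Optional[int] = None


@dataclass
class MiRNACluster:
    """>= 2 catalog entries whose hairpins start within ``max_gap`` of a neighbour."""

    chrom: str
    members: list
    span: tuple

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a cluster needs >= 2 members")


@dataclass
class CountMatrix:
    """miRNA x sample raw counts plus per-sample metadata.

    ``counts`` rows are mature-hairpin combinations; ``metadata`` is indexed
    by sample and covers every column of ``counts``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class DEResult:
    """Per-miRNA differential expression result."""

    mirna: str
    log2fc: float
    pvalue: float
    fdr: float
    direction: str                 # "up" | "down" | "ns"
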