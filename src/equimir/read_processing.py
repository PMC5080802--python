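"""Post-alignment tag hygiene and read-context statistics.

Implements the standard small-RNA post-alignment filters (length cap,
multimapper cap, collapsing of identical placed reads) and the
gene-centric genomic-context breakdown of where tags fall relative to
protein-coding annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .types import AlignedTag

#: priority order used to resolve tags overlapping several categories;
#: nested upstream/downstream windows are reported as disjoint rings
CONTEXT_PRIORITY = (
    "CDS", "five_utr", "three_utr", "intron",
    "upstream1k", "downstream1k", "upstream5k", "downstream5k",
    "upstream10k", "downstream10k", "intergenic",
)


def filter_tags(tags: Sequence[AlignedTag], max_len: int = 30, max_hits: int = 5) -> list:
    """Keep tags with length <= ``max_len`` and n_hits <= ``max_hits``.

    Order is preserved. The two sub-filters commute.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    return [t for t in tags if t.length <= max_len and t.n_hits <= max_hits]


def collapse_reads(reads: Sequence[AlignedTag]) -> list:
    """Collapse identically placed, identical-sequence reads into tags.

    One tag per (chrom, start, end, strand, sequence); counts add up, so
    the total count is conserved. Idempotent. Output is sorted by
    placement for determinism.
    """
    merged = {}
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand, r.sequence)
        if key in merged:
            prev = merged[key]
            merged[key] = AlignedTag(r.chrom, r.start, r.end, r.strand, r.sequence,
                                     count=prev.count + r.count,
                                     n_hits=max(prev.n_hits, r.n_hits))
        else:
            merged[key] = AlignedTag(r.chrom, r.start, r.end, r.strand, r.sequence,
                                     count=r.count, n_hits=r.n_hits)
    return [merged[k] for k in sorted(merged)]


def length_histogram(tags: Sequence[AlignedTag],
                     mirna_bin=(22, 23), pirna_bin=(30, 32)):
    """Count-weighted read-length histogram plus the two diagnostic bins.

    Returns ``(histogram, fractions)`` where ``histogram`` is a Series
    indexed by length and ``fractions`` reports the share of read counts in
    the mature-miRNA-sized (22-23 nt) and piRNA-sized (30-32 nt) bins.
    """
    lengths = {}
    for t in tags:
        lengths[t.length] = lengths.get(t.length, 0) + t.count
    hist = pd.Series(lengths, dtype=float).sort_index()
    total = hist.sum()
    def _frac(bin_):
        if total == 0:
            return 0.0
        return float(hist.loc[(hist.index >= bin_[0]) & (hist.index <= bin_[1])].sum() / total)
    return hist, {"mirna_22_23": _frac(mirna_bin), "pirna_30_32": _frac(pirna_bin)}


@dataclass
class ContextAnnotation:
    """Count-weighted read fractions over the genomic-context partition."""

    fractions: dict
    excluded_mirna_fraction: float
    total_count: int

    def __post_init__(self):
        for k, v in self.fractions.items():
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"fraction out of range for {k}")


def _gene_table(features: pd.DataFrame) -> list:
    """Assemble per-gene annotation from a GFF3-style feature frame."""
    genes = []
    feature_types = set(features["type"])
    gene_rows = features[features["type"] == "gene"]
    for _, g in gene_rows.iterrows():
        gid = g["attributes"].get("ID", f"{g['chrom']}:{g['start']}")
        sub = features[[a.get("Parent", a.get("gene_id")) == gid or a.get("ID", "").startswith(gid)
                        for a in features["attributes"]]]
        genes.append({
            "chrom": g["chrom"], "start": int(g["start"]), "end": int(g["end"]),
            "strand": g["strand"],
            "cds": [(int(r["start"]), int(r["end"])) for _, r in sub.iterrows() if r["type"] == "CDS"],
            "five_utr": [(int(r["start"]), int(r["end"])) for _, r in sub.iterrows()
                         if r["type"] == "five_prime_UTR"],
            "three_utr": [(int(r["start"]), int(r["end"])) for _, r in sub.iterrows()
                          if r["type"] == "three_prime_UTR"],
        })
    if not gene_rows.shape[0] and feature_types:
        raise ValueError("gene model contains no 'gene' features")
    return genes


def _overlaps_any(start, end, intervals):
    return any(s < end and start < e for s, e in intervals)


def annotate_genomic_context(tags: Sequence[AlignedTag], gene_model: pd.DataFrame,
                             known_mirna: pd.DataFrame = None) -> ContextAnnotation:
    """Assign every tag one gene-centric category and report count fractions.

    Tags overlapping a known miRNA gene are excluded first. The remaining
    tags take the first matching category in :data:`CONTEXT_PRIORITY`;
    upstream/downstream windows are measured from the TSS/TES of the
    nearest qualifying gene and the nested 1/5/10 kb windows are reported
    as disjoint rings. Overlap means >= 1 shared base, strand-agnostic.
    Tags on chromosomes absent from the annotation raise a warning and
    count as intergenic.
    """
    genes = _gene_table(gene_model)
    known = [] if known_mirna is None else [
        (r["chrom"], int(r["start"]), int(r["end"])) for _, r in known_mirna.iterrows()
    ]
    gene_chroms = {g["chrom"] for g in genes} | {c for c, _, _ in known}

    counts = {c: 0 for c in CONTEXT_PRIORITY}
    excluded = 0
    total = 0
    warned = set()
    for t in tags:
        total += t.count
        if any(c == t.chrom and s < t.end and t.start < e for c, s, e in known):
            excluded += t.count
            continue
        if t.chrom not in gene_chroms and t.chrom not in warned:
            warnings.warn(f"tag chromosome {t.chrom!r} absent from annotation; counted intergenic")
            warned.add(t.chrom)
        category = "intergenic"
        for cat in CONTEXT_PRIORITY[:-1]:
            if any(_tag_in_category(t, g, cat) for g in genes if g["chrom"] == t.chrom):
                category = cat
                break
        counts[category] += t.count
    kept = total - excluded
    fractions = {c: (counts[c] / kept if kept else 0.0) for c in CONTEXT_PRIORITY}
    return ContextAnnotation(fractions=fractions,
                             excluded_mirna_fraction=(excluded / total if total else 0.0),
                             total_count=total)


def _tag_in_category(tag: AlignedTag, gene: dict, category: str) -> bool:
    s, e = tag.start, tag.end
    if category == "CDS":
        return _overlaps_any(s, e, gene["cds"])
    if category == "five_utr":
        return _overlaps_any(s, e, gene["five_utr"])
    if category == "three_utr":
        return _overlaps_any(s, e, gene["three_utr"])
    if category == "intron":
        return s < gene["end"] and gene["start"] < e
    tss, tes = (gene["start"], gene["end"]) if gene["strand"] == "+" else (gene["end"], gene["start"])
    rings = {"1k": (0, 1000), "5k": (1000, 5000), "10k": (5000, 10000)}
    for label, (inner, outer) in rings.items():
        if category == f"upstream{label}":
            if gene["strand"] == "+":
                win = (gene["start"] - outer, gene["start"] - inner)
            else:
                win = (gene["end"] + inner, gene["end"] + outer)
            return s < win[1] and win[0] < e
        if category == f"downstream{label}":
            if gene["strand"] == "+":
                win = (gene["end"] + inner, gene["end"] + outer)
            else:
                win = (gene["start"] - outer, gene["start"] - inner)
            return s < win[1] and win[0] < e
    return False
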