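"""Readers and writers for the pipeline's on-disk formats.

Genomes travel as FASTA (Biopython), loci/calls/catalogs as GFF3 in the
miRBase dialect (``pre_miRNA`` features with ``miRNA`` children), tags as a
7-column TSV, counts and metadata as TSV matrices. Internal coordinates
are 0-based half-open; GFF3 is written and read as 1-based closed, and the
conversion happens only here.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import AlignedTag, CatalogEntry, CandidateCall, GenomeRef, PlantedLocus

TAG_COLUMNS = ["chrom", "start", "end", "sequence", "count", "strand", "n_hits"]


def write_fasta(genome: GenomeRef, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in zip(genome.chrom_names, genome.sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> GenomeRef:
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return GenomeRef(chrom_names=names, sequences=seqs)


def _fmt_attrs(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attrs(text: str) -> dict:
    out = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _gff3_row(chrom, source, ftype, start0, end, score, strand, attrs):
    return "\t".join([
        chrom, source, ftype, str(start0 + 1), str(end),
        "." if score is None else f"{score:.3f}", strand, ".", _fmt_attrs(attrs),
    ])


def write_loci_gff3(loci: Sequence[PlantedLocus], path) -> None:
    """Planted loci as pre_miRNA features with miRNA (mature/star) children."""
    lines = ["##gff-version 3"]
    for locus in loci:
        pre_id = locus.name or f"{locus.chrom}:{locus.hairpin[0]}"
        lines.append(_gff3_row(locus.chrom, "equimir", "pre_miRNA",
                               locus.hairpin[0], locus.hairpin[1], None, locus.strand,
                               {"ID": pre_id, "Name": pre_id}))
        lines.append(_gff3_row(locus.chrom, "equimir", "miRNA",
                               locus.mature[0], locus.mature[1], None, locus.strand,
                               {"ID": f"{pre_id}-mature", "Derives_from": pre_id}))
        lines.append(_gff3_row(locus.chrom, "equimir", "miRNA_star",
                               locus.star[0], locus.star[1], None, locus.strand,
                               {"ID": f"{pre_id}-star", "Derives_from": pre_id}))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_calls_gff3(calls: Sequence[CandidateCall], path) -> None:
    lines = ["##gff-version 3"]
    for i, c in enumerate(calls, start=1):
        cid = f"{c.tool}-call-{i}"
        lines.append(_gff3_row(c.chrom, "equimir", "pre_miRNA",
                               c.hairpin[0], c.hairpin[1], c.score, c.strand,
                               {"ID": cid, "sample": c.sample, "tool": c.tool}))
        lines.append(_gff3_row(c.chrom, "equimir", "miRNA",
                               c.mature[0], c.mature[1], c.score, c.strand,
                               {"ID": f"{cid}-mature", "Derives_from": cid,
                                "sequence": c.mature_sequence}))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_catalog_gff3(catalog: Sequence[CatalogEntry], path) -> None:
    lines = ["##gff-version 3"]
    for e in catalog:
        attrs = {"ID": e.id, "Name": e.id, "novel": str(e.novel).lower(),
                 "support": e.support_samples, "tools": ",".join(sorted(e.tools)),
                 "known_overlap": e.known_overlap}
        if e.cluster_id is not None:
            attrs["cluster"] = e.cluster_id
        lines.append(_gff3_row(e.chrom, "equimir", "pre_miRNA",
                               e.hairpin[0], e.hairpin[1], e.best_score, e.strand, attrs))
        lines.append(_gff3_row(e.chrom, "equimir", "miRNA",
                               e.mature[0], e.mature[1], e.best_score, e.strand,
                               {"ID": f"{e.id}-mature", "Derives_from": e.id,
                                "sequence": e.mature_sequence}))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path, types: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """GFF3 as a frame with 0-based half-open coordinates and parsed attributes."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 at line {lineno}")
            chrom, source, ftype, start, end, score, strand, _, attrs = fields
            if types is not None and ftype not in types:
                continue
            try:
                start0, end1 = int(start) - 1, int(end)
            except ValueError:
                raise ValueError(f"{path}: bad coordinates at line {lineno}") from None
            rows.append({
                "chrom": chrom, "source": source, "type": ftype,
                "start": start0, "end": end1,
                "score": None if score == "." else float(score),
                "strand": strand, "attributes": _parse_attrs(attrs),
            })
    return pd.DataFrame(rows, columns=["chrom", "source", "type", "start", "end",
                                       "score", "strand", "attributes"])


def write_tags_tsv(tags: Sequence[AlignedTag], path) -> None:
    frame = pd.DataFrame([{
        "chrom": t.chrom, "start": t.start, "end": t.end, "sequence": t.sequence,
        "count": t.count, "strand": t.strand, "n_hits": t.n_hits,
    } for t in tags], columns=TAG_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_tags_tsv(path) -> list:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sequence": str})
    return [AlignedTag(chrom=r.chrom, start=int(r.start), end=int(r.end),
                       strand=r.strand, sequence=r.sequence,
                       count=int(r.count), n_hits=int(r.n_hits))
            for r in frame.itertuples()]


def read_tags_sam(path) -> list:
    """Collapsed tags from a SAM file; NH carries the hit count, XC the multiplicity."""
    import pysam

    tags = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            seq = rec.get_forward_sequence() or rec.query_sequence
            tags.append(AlignedTag(
                chrom=rec.reference_name, start=rec.reference_start,
                end=rec.reference_end, strand="-" if rec.is_reverse else "+",
                sequence=seq.upper(),
                count=int(rec.get_tag("XC")) if rec.has_tag("XC") else 1,
                n_hits=int(rec.get_tag("NH")) if rec.has_tag("NH") else 1,
            ))
    return tags


def write_counts(counts, metadata, counts_path, metadata_path) -> None:
    counts.to_csv(counts_path, sep="\t")
    metadata.to_csv(metadata_path, sep="\t")


def read_counts(counts_path, metadata_path):
    from .types import CountMatrix

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, metadata=metadata)
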