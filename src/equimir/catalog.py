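"""Consolidation of per-sample discovery calls into a non-redundant catalog.

Calls from many libraries are merged under a 2-nt end tolerance, reduced to
one representative per merge group, filtered for single-library artifacts,
annotated against known miRNA annotation, clustered along chromosomes and
summarised per chromosome.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

import pandas as pd

from .types import CandidateCall, CatalogEntry, MiRNACluster

_PLACED = re.compile(r"^(chr)?([0-9]+|[XYZW]|MT?)$", re.IGNORECASE)


def merge_calls(calls: Sequence[CandidateCall], tol: int = 2) -> list:
    """Group calls whose mature intervals agree within ``tol`` nt at each end.

    Two calls merge iff same chromosome and strand, |start difference| <=
    tol and |end difference| <= tol; merging is the transitive closure of
    that relation. Deterministic for any input order (calls are sorted
    internally), idempotent, and permutation-invariant. Returns a list of
    groups (lists of calls).
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.strand, c.mature[0], c.mature[1],
                                           c.sample, c.tool))
    parent = list(range(len(ordered)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i, a in enumerate(ordered):
        for j in range(i + 1, len(ordered)):
            b = ordered[j]
            if (b.chrom, b.strand) != (a.chrom, a.strand) or b.mature[0] - a.mature[0] > tol:
                break
            if abs(b.mature[0] - a.mature[0]) <= tol and abs(b.mature[1] - a.mature[1]) <= tol:
                union(i, j)
    groups = {}
    for i in range(len(ordered)):
        groups.setdefault(find(i), []).append(ordered[i])
    return [groups[k] for k in sorted(groups)]


def pick_representative(group: Sequence[CandidateCall]) -> CandidateCall:
    """Representative = variant seen in most samples; ties by score, then position.

    A variant is an exact mature interval; its support is the number of
    distinct samples it was called in. Remaining ties break on the best
    score within the variant, then lexicographically smallest
    (chrom, start, end).
    """
    if not group:
        raise ValueError("empty merge group")
    variants = {}
    for c in group:
        variants.setdefault((c.chrom, c.strand, c.mature[0], c.mature[1]), []).append(c)
    def key(item):
        (chrom, _strand, start, end), calls = item
        n_samples = len({c.sample for c in calls})
        best = max(c.score for c in calls)
        return (-n_samples, -best, chrom, start, end)
    _, best_calls = min(variants.items(), key=key)
    return max(best_calls, key=lambda c: (c.score, c.sample))


def support_samples(group: Sequence[CandidateCall]) -> int:
    return len({c.sample for c in group})


def filter_singletons(groups: Sequence[Sequence[CandidateCall]]) -> list:
    """Drop merge groups supported by a single library.

    Support counts distinct sample ids, not calls: a group with two calls
    from one sample is still a singleton.
    """
    return [g for g in groups if support_samples(g) >= 2]


def _classify_against_known(rep: CandidateCall, known: pd.DataFrame, tol: int):
    """(novel, known_overlap, partner) for one representative call.

    Same-strand agreement within ``tol`` at both ends marks the entry as a
    known miRNA; a same-strand overlap differing only by <= 2 nt at one end
    is flagged near-identical but stays novel (it earns its own identifier,
    like the documented 2-nt-shorter case); an antisense overlap stays
    novel with the opposite-strand flag.
    """
    m0, m1 = rep.mature
    best = (True, "none", None)
    for _, k in known.iterrows():
        if k["chrom"] != rep.chrom:
            continue
        ks, ke = int(k["start"]), int(k["end"])
        if not (ks < m1 and m0 < ke):
            continue
        name = k["attributes"].get("Name", k["attributes"].get("ID", "known"))
        if k["strand"] == rep.strand:
            d0, d1 = abs(m0 - ks), abs(m1 - ke)
            if d0 <= tol and d1 <= tol:
                if (d0 == 0) != (d1 == 0):   # offset confined to one end
                    return (True, "near-identical", name)
                return (False, "same-strand", name)
            if (d0 == 0 and d1 <= 2) or (d1 == 0 and d0 <= 2):
                return (True, "near-identical", name)
            best = (True, "same-strand", name)
        else:
            if best[1] == "none":
                best = (True, "opposite-strand", name)
    return best


def combine_and_annotate(deep_groups: Sequence[Sequence[CandidateCall]],
                         dentify_groups: Sequence[Sequence[CandidateCall]],
                         known: Optional[pd.DataFrame] = None, tol: int = 2) -> list:
    """Union the two tools' merge groups into annotated catalog entries.

    Groups from the two tools that agree within ``tol`` are fused with a
    combined provenance set. Each entry is classified against the known
    mature annotation (a GFF3-derived frame with chrom/start/end/strand/
    attributes); an entry is never both known and novel.
    """
    pooled = []
    for groups, tool in ((deep_groups, "deep"), (dentify_groups, "dentify")):
        for g in groups:
            rep = pick_representative(g)
            pooled.append({"rep": rep, "group": list(g), "tools": {tool}})

    pooled.sort(key=lambda e: (e["rep"].chrom, e["rep"].strand,
                               e["rep"].mature[0], e["rep"].mature[1]))
    fused = []
    for entry in pooled:
        r = entry["rep"]
        target = None
        for other in fused:
            o = other["rep"]
            if (o.chrom, o.strand) == (r.chrom, r.strand) \
                    and abs(o.mature[0] - r.mature[0]) <= tol \
                    and abs(o.mature[1] - r.mature[1]) <= tol:
                target = other
                break
        if target is None:
            fused.append(entry)
        else:
            target["group"].extend(entry["group"])
            target["tools"] |= entry["tools"]
            target["rep"] = pick_representative(target["group"])

    entries = []
    novel_counter = 0
    for e in fused:
        rep, group = e["rep"], e["group"]
        if known is not None and len(known):
            novel, overlap, partner = _classify_against_known(rep, known, tol)
        else:
            novel, overlap, partner = True, "none", None
        if novel:
            novel_counter += 1
            eid = f"novel-mir-{novel_counter}"
        else:
            eid = partner or f"known-mir-{len(entries) + 1}"
        entries.append(CatalogEntry(
            id=eid, chrom=rep.chrom, strand=rep.strand, mature=rep.mature,
            hairpin=rep.hairpin, mature_sequence=rep.mature_sequence,
            support_samples=support_samples(group),
            best_score=max(c.score for c in group),
            tools=frozenset(e["tools"]), novel=novel,
            known_overlap=overlap, known_partner=partner,
        ))
    return entries


def find_clusters(catalog: Sequence[CatalogEntry], max_gap: int = 3000) -> list:
    """Single-linkage chains of entries with hairpin starts <= ``max_gap`` apart.

    Strand-agnostic; clusters need >= 2 members. Assigns ``cluster_id`` on
    the member entries as a side effect and returns the cluster list.
    """
    clusters = []
    by_chrom = {}
    for entry in catalog:
        by_chrom.setdefault(entry.chrom, []).append(entry)
    cid = 0
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda e: e.hairpin[0])
        chain = [members[0]]
        for entry in members[1:]:
            if entry.hairpin[0] - chain[-1].hairpin[0] <= max_gap:
                chain.append(entry)
            else:
                if len(chain) >= 2:
                    cid += 1
                    for m in chain:
                        m.cluster_id = cid
                    clusters.append(MiRNACluster(chrom=chrom, members=[m.id for m in chain],
                                                 span=(chain[0].hairpin[0], chain[-1].hairpin[1])))
                chain = [entry]
        if len(chain) >= 2:
            cid += 1
            for m in chain:
                m.cluster_id = cid
            clusters.append(MiRNACluster(chrom=chrom, members=[m.id for m in chain],
                                         span=(chain[0].hairpin[0], chain[-1].hairpin[1])))
    return clusters


def chromosome_summary(catalog: Sequence[CatalogEntry]) -> pd.DataFrame:
    """Entry counts per chromosome; unplaced scaffolds pooled as 'Unplaced'.

    Includes a sense-strand tally per chromosome. Counts sum to the catalog
    size.
    """
    rows = {}
    for e in catalog:
        name = e.chrom if _PLACED.match(e.chrom) else "Unplaced"
        rec = rows.setdefault(name, {"n": 0, "sense": 0})
        rec["n"] += 1
        rec["sense"] += int(e.strand == "+")
    frame = pd.DataFrame.from_dict(rows, orient="index").rename_axis("chrom")
    if frame.empty:
        frame = pd.DataFrame(columns=["n", "sense"]).rename_axis("chrom")
    return frame.sort_index()
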