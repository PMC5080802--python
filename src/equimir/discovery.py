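"""Hairpin candidate discovery from aligned small-RNA read stacks.

The discovery stage mirrors the two-tool strategy used for miRNA gene
finding in non-model genomes: a permissive, score-based caller ("deep"
mode: excise a window around every read stack, fold it, and compute a
log-odds score for the miRNA biogenesis model against a uniform
fragmentation null) and a stringent rule-based caller ("dentify" mode:
ten explicit biogenesis criteria, all of which must hold).

Folding uses a self-contained Nussinov-style base-pair maximisation with
per-pair weights (GC=3, AU=2, GU=1), a minimum loop of 3 nt and one
opening penalty per helix so only stacked runs of pairs form. The
absolute value of the score is a free-energy-like quantity, not kcal/mol;
all downstream thresholds are expressed on this internal scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import AlignedTag, CandidateCall, CandidateEvaluation, GenomeRef, HairpinCandidate, SNRProfile

PAIR_WEIGHTS = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}
MIN_LOOP = 3
#: opening a new helix costs this much, so only stacked runs of pairs pay
#: off; isolated pairs are never worth forming under this model
HELIX_OPEN_PENALTY = 4.0

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_WEIGHT_MATRIX = np.zeros((4, 4))
for (x, y), w in PAIR_WEIGHTS.items():
    _WEIGHT_MATRIX[_BASE_INDEX[x], _BASE_INDEX[y]] = w


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper().replace("U", "T")
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from None


def structure_energy(sequence: str, pair_list, open_penalty: float = HELIX_OPEN_PENALTY) -> float:
    """Score a complete structure: sum of pair weights minus one opening
    penalty per helix (maximal run of consecutively stacked pairs)."""
    enc = _encode(sequence)
    pairs = sorted(pair_list)
    pair_set = set(pairs)
    total = 0.0
    helices = 0
    for i, j in pairs:
        total += _WEIGHT_MATRIX[enc[i], enc[j]]
        if (i - 1, j + 1) not in pair_set:
            helices += 1
    return total - open_penalty * helices


def fold_hairpin(sequence: str, min_loop: int = MIN_LOOP,
                 open_penalty: float = HELIX_OPEN_PENALTY):
    """Fold a sequence by weighted base-pair maximisation with stacking.

    Returns ``(dot_bracket, mfe)`` where ``mfe`` is minus the best
    achievable :func:`structure_energy` (always <= 0: the empty structure
    scores 0). Pairs are non-crossing; Watson-Crick and GU wobble pairs are
    allowed; hairpin loops span at least ``min_loop`` nt; every maximal
    helix pays one opening penalty, so isolated pairs never form.
    Deterministic: ties break in a fixed traceback order (unpaired before
    paired, stacked continuation before a fresh interior, smaller
    bifurcation point first).
    """
    enc = _encode(sequence)
    n = len(enc)
    if n < 1:
        raise ValueError("empty sequence")
    pairw = _WEIGHT_MATRIX[enc[:, None], enc[None, :]]
    NEG = -1e9
    # V[i, j]: best energy of [i..j] given (i, j) paired, before charging
    # the helix-opening penalty of the helix (i, j) starts
    V = np.full((n, n), NEG)
    # W[i, j]: best energy over half-open [i, j), all helices charged
    W = np.zeros((n + 1, n + 1))
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            last = j - 1
            if pairw[i, last] > 0:
                # continue the same helix (uncharged) or close over a fresh
                # interior whose helices are all already charged
                V[i, last] = pairw[i, last] + max(V[i + 1, last - 1], W[i + 1, last])
            best = W[i + 1, j]
            ks = np.arange(i + min_loop + 1, j)
            if ks.size:
                cand = V[i, ks] - open_penalty + W[ks + 1, j]
                m = cand.max()
                if m > best:
                    best = m
            W[i, j] = best

    structure = ["."] * n
    EPS = 1e-9

    def trace_w(i, j):
        while j - i >= min_loop + 2:
            if W[i, j] <= W[i + 1, j] + EPS:
                i += 1
                continue
            for k in range(i + min_loop + 1, j):
                if V[i, k] > NEG / 2 and abs(W[i, j] - (V[i, k] - open_penalty + W[k + 1, j])) < EPS:
                    trace_v(i, k)
                    i, j = k + 1, j
                    break
            else:
                i += 1
            continue

    def trace_v(i, last):
        while True:
            structure[i], structure[last] = "(", ")"
            if V[i + 1, last - 1] > NEG / 2 and \
                    abs(V[i, last] - (pairw[i, last] + V[i + 1, last - 1])) < EPS:
                i, last = i + 1, last - 1
                continue
            trace_w(i + 1, last)
            return

    trace_w(0, n)
    return "".join(structure), -float(max(W[0, n], 0.0))


def pairs_from_structure(structure: str) -> dict:
    """Map each paired position to its partner (both directions)."""
    pairs = {}
    opens = []
    for i, c in enumerate(structure):
        if c == "(":
            opens.append(i)
        elif c == ")":
            j = opens.pop()
            pairs[i] = j
            pairs[j] = i
    if opens:
        raise ValueError("unbalanced structure")
    return pairs


@dataclass
class DiscoveryConfig:
    """Tunable discovery parameters.

    The stringent-mode thresholds (``h_max`` .. ``max_multimap``) bound the
    ten biogenesis criteria; they are on the package's internal energy
    scale where noted. ``require_tailing`` is off by default because
    untemplated tailing is informative but not universal.
    """

    window: int = 50
    min_stack_count: int = 5
    stack_merge_dist: int = 3
    min_mature_paired: float = 0.6
    h_max: float = 0.33
    mfe_max: float = -15.0
    e_min: float = 1.5
    s_max: float = 2.5
    t_min: float = 0.1
    require_tailing: bool = False
    max_multimap: int = 4


@dataclass
class BackgroundModel:
    """Null model of folding scores for random genomic windows.

    Fit once per genome; used by the scorer to turn a candidate's folding
    score into a z-score against length- and GC-matched random windows.
    """

    coef: np.ndarray            # mfe ~ 1 + length + gc*length
    resid_sd: float

    def expected_mfe(self, length: int, gc: float) -> float:
        return float(self.coef[0] + self.coef[1] * length + self.coef[2] * gc * length)

    def z(self, mfe: float, length: int, gc: float) -> float:
        return (mfe - self.expected_mfe(length, gc)) / max(self.resid_sd, 1e-6)


def fit_background_model(genome: GenomeRef, n_windows: int = 60, seed: int = 0,
                         length_range=(60, 140)) -> BackgroundModel:
    """Fold random genomic windows and regress MFE on length and GC."""
    rng = np.random.default_rng(seed)
    lengths, gcs, mfes = [], [], []
    chrom_lens = np.array([len(s) for s in genome.sequences], dtype=float)
    probs = chrom_lens / chrom_lens.sum()
    for _ in range(n_windows):
        ci = rng.choice(len(genome.chrom_names), p=probs)
        seq = genome.sequences[ci]
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        if len(seq) <= L:
            continue
        start = int(rng.integers(0, len(seq) - L))
        window = seq[start:start + L]
        _, mfe = fold_hairpin(window)
        lengths.append(L)
        gcs.append((window.count("G") + window.count("C")) / L)
        mfes.append(mfe)
    lengths = np.asarray(lengths, dtype=float)
    gcs = np.asarray(gcs, dtype=float)
    mfes = np.asarray(mfes, dtype=float)
    X = np.column_stack([np.ones_like(lengths), lengths, gcs * lengths])
    coef, *_ = np.linalg.lstsq(X, mfes, rcond=None)
    resid = mfes - X @ coef
    sd = float(resid.std(ddof=min(3, len(mfes) - 1))) if len(mfes) > 3 else 1.0
    return BackgroundModel(coef=coef, resid_sd=max(sd, 1e-3))


def _genomic_to_local(interval, candidate_interval, strand):
    s, e = candidate_interval
    g0, g1 = interval
    if strand == "+":
        return (g0 - s, g1 - s)
    return (e - g1, e - g0)


def _locate_star(structure: str, mature_local, min_paired: float):
    """Locate the star arm from the Dicer duplex geometry.

    The star is the pairing partner of the mature arm shifted so that both
    duplex ends carry 2-nt 3' overhangs. Returns ``(star, loop, paired_frac)``
    with ``star``/``loop`` None when the mature arm is not convincingly
    paired into one contiguous partner helix.
    """
    pairs = pairs_from_structure(structure)
    a, b = mature_local
    partnered = [(i, pairs[i]) for i in range(a, b) if i in pairs]
    paired_frac = len(partnered) / (b - a)
    if paired_frac < min_paired:
        return None, None, paired_frac
    partners = [p for _, p in partnered]
    p_lo, p_hi = min(partners), max(partners)
    # partner region must be one near-contiguous helix outside the mature arm
    if p_hi - p_lo + 1 > 1.5 * len(partners) + 4:
        return None, None, paired_frac
    if not (p_lo >= b or p_hi < a):
        return None, None, paired_frac
    i_min = min(i for i, _ in partnered)
    i_max = max(i for i, _ in partnered)
    n = len(structure)
    s0 = pairs[i_max]
    s1 = min(pairs[i_min] + 3, n)
    if pairs[i_min] < a:            # mature on the 3' arm; star upstream
        s0 = max(pairs[i_max], 0)
        s1 = min(pairs[i_min] + 3, a)
    star = (s0, s1)
    if star[1] <= star[0]:
        return None, None, paired_frac
    if star[0] >= b:
        loop = (b, star[0]) if star[0] > b else None
    else:
        loop = (star[1], a) if a > star[1] else None
    return star, loop, paired_frac


def excise_candidates(tags: Sequence[AlignedTag], genome: GenomeRef,
                      window: int = 50, min_stack_count: int = 5,
                      config: Optional[DiscoveryConfig] = None):
    """Excise and fold a precursor window around every read stack.

    A stack is a cluster of tags sharing a modal 5' end (within
    ``stack_merge_dist``) whose summed count reaches ``min_stack_count``.
    Stacks are processed by descending count; a stack falling inside an
    already-excised hairpin (typically the star arm of a stronger stack)
    is absorbed into it rather than spawning a duplicate candidate.
    Windows truncated at a contig edge are flagged.
    """
    cfg = config or DiscoveryConfig(window=window, min_stack_count=min_stack_count)
    by_key = {}
    for t in tags:
        by_key.setdefault((t.chrom, t.strand), []).append(t)

    candidates = []
    for (chrom, strand), group in sorted(by_key.items()):
        counts_at = {}
        for t in group:
            counts_at[t.five_prime()] = counts_at.get(t.five_prime(), 0) + t.count
        positions = sorted(counts_at)
        # cluster 5' positions within stack_merge_dist
        clusters, current = [], [positions[0]] if positions else []
        for p in positions[1:]:
            if p - current[-1] <= cfg.stack_merge_dist:
                current.append(p)
            else:
                clusters.append(current)
                current = [p]
        if current:
            clusters.append(current)

        stacks = []
        for cl in clusters:
            total = sum(counts_at[p] for p in cl)
            if total < cfg.min_stack_count:
                continue
            modal = max(cl, key=lambda p: (counts_at[p], -p))
            modal_tags = [t for t in group if t.five_prime() == modal]
            mature_tag = max(modal_tags, key=lambda t: (t.count, -t.start))
            stacks.append((total, mature_tag))
        stacks.sort(key=lambda s: (-s[0], s[1].start))

        taken = []
        for total, mtag in stacks:
            # slack tolerates star stacks poking a few nt past a taken window
            if any(iv[0] - 5 <= mtag.start and mtag.end <= iv[1] + 5 for iv in taken):
                continue
            clen = genome.length(chrom)
            w0 = mtag.start - cfg.window
            w1 = mtag.end + cfg.window
            truncated = w0 < 0 or w1 > clen
            w0, w1 = max(w0, 0), min(w1, clen)
            seq = genome.fetch(chrom, w0, w1, strand)
            if len(seq) < 40:
                continue
            structure, mfe = fold_hairpin(seq)
            mature_local = _genomic_to_local((mtag.start, mtag.end), (w0, w1), strand)
            star, loop, _ = _locate_star(structure, mature_local, cfg.min_mature_paired)
            support = [t for t in group if t.start < w1 and t.end > w0]
            cand = HairpinCandidate(
                chrom=chrom, strand=strand, interval=(w0, w1), sequence=seq,
                structure=structure, mfe=mfe, mature=mature_local,
                star=star, loop=loop, truncated=truncated,
            )
            cand.support = support
            candidates.append(cand)
            taken.append((w0, w1))
    return candidates


def _overlaps(iv, jv, slack=0):
    return iv[0] < jv[1] + slack and jv[0] < iv[1] + slack


def _read_region(tag: AlignedTag, cand: HairpinCandidate, slack: int = 3) -> str:
    local = _genomic_to_local((tag.start, tag.end), cand.interval, cand.strand)
    a, b = cand.mature
    if local[0] >= a - slack and local[1] <= b + slack:
        return "mature"
    if cand.star is not None and local[0] >= cand.star[0] - slack and local[1] <= cand.star[1] + slack:
        return "star"
    if cand.loop is not None and local[0] >= cand.loop[0] and local[1] <= cand.loop[1]:
        return "loop"
    return "other"


def _untemplated_tail(tag: AlignedTag, genome: GenomeRef, max_tail: int = 3) -> int:
    """Number of trailing read bases (<=3) that are A/U and mismatch the genome."""
    g = genome.fetch(tag.chrom, max(tag.start, 0), min(tag.end, genome.length(tag.chrom)), tag.strand)
    if len(g) != len(tag.sequence):
        return 0
    k = 0
    for read_base, gen_base in zip(tag.sequence[::-1], g[::-1]):
        if k >= max_tail or read_base not in ("A", "T", "U") or read_base == gen_base:
            break
        k += 1
    return k


def nucleotide_entropy(sequence: str) -> float:
    """Shannon entropy (bits) of mononucleotide composition."""
    seq = sequence.upper().replace("U", "T")
    counts = np.array([seq.count(b) for b in "ACGT"], dtype=float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def structural_entropy(structure: str) -> float:
    """Pairing-complexity score: entropy (bits) of the run-length multiset.

    A clean hairpin (one long helix, one loop) has few distinct runs and a
    low score; interrupted, bulgy structures have many short runs and a
    high score. Runs are maximal stretches of identical dot-bracket state.
    """
    if not structure:
        return 0.0
    runs = []
    cur, length = structure[0], 1
    for c in structure[1:]:
        if c == cur:
            length += 1
        else:
            runs.append(length)
            cur, length = c, 1
    runs.append(length)
    vals, counts = np.unique(runs, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def evaluate_candidate(candidate: HairpinCandidate, tags: Sequence[AlignedTag],
                       genome: Optional[GenomeRef] = None,
                       config: Optional[DiscoveryConfig] = None) -> CandidateEvaluation:
    """Evaluate the ten stringent biogenesis criteria for one candidate.

    Requires at least one supporting tag on the mature arm. ``genome`` is
    needed to detect untemplated A/U tailing and to trim tails before the
    3'-heterogeneity computation; without it tailing is reported as 0.
    """
    cfg = config or DiscoveryConfig()
    mature_tags = [t for t in tags if _read_region(t, candidate) == "mature"]
    if not mature_tags:
        raise ValueError("no supporting tags on the mature arm")

    total = sum(t.count for t in mature_tags)
    five = {}
    three = {}
    tail_count = 0
    for t in mature_tags:
        five[t.five_prime()] = five.get(t.five_prime(), 0) + t.count
        k = _untemplated_tail(t, genome) if genome is not None else 0
        if k > 0:
            tail_count += t.count
        tp = t.three_prime()
        tp = tp - k if t.strand == "+" else tp + k
        three[tp] = three.get(tp, 0) + t.count
    het5 = 1.0 - max(five.values()) / total
    het3 = 1.0 - max(three.values()) / total

    pairs = pairs_from_structure(candidate.structure)
    a, b = candidate.mature
    duplex_pairs = []
    if candidate.star is not None:
        s0, s1 = candidate.star
        duplex_pairs = [(i, pairs[i]) for i in range(a, b)
                        if i in pairs and s0 <= pairs[i] < s1]
    duplex_mfe = -sum(PAIR_WEIGHTS[(candidate.sequence[i], candidate.sequence[j])]
                      for i, j in duplex_pairs)

    overhang_ok = False
    if duplex_pairs and candidate.star is not None:
        i_min = min(i for i, _ in duplex_pairs)
        i_max = max(i for i, _ in duplex_pairs)
        s0, s1 = candidate.star
        if s0 >= b:    # star downstream: mature 3' overhang at b, star 3' overhang at s1
            overhang_ok = ((b - 1) - i_max == 2) and ((s1 - 1) - pairs[i_min] == 2)
        else:          # star upstream
            overhang_ok = ((b - 1) - i_max == 2) and ((s1 - 1) - pairs[i_min] == 2)

    n = len(candidate.sequence)
    if candidate.star is not None:
        d_lo = min(a, candidate.star[0])
        d_hi = max(b, candidate.star[1])
    else:
        d_lo, d_hi = a, b
    flank_mfe = 0.0
    if d_lo >= 10:
        flank_mfe += fold_hairpin(candidate.sequence[:d_lo])[1]
    if n - d_hi >= 10:
        flank_mfe += fold_hairpin(candidate.sequence[d_hi:])[1]

    nt_ent = nucleotide_entropy(candidate.sequence)
    # pairing complexity of the hairpin proper (duplex + loop), not the
    # flanking window, which is arbitrary genomic context
    st_ent = structural_entropy(candidate.structure[d_lo:d_hi])
    tail_frac = tail_count / total
    multimap = max(t.n_hits for t in mature_tags)

    passed = (
        het5 <= cfg.h_max
        and het3 <= cfg.h_max
        and overhang_ok
        and duplex_mfe <= cfg.mfe_max
        and duplex_mfe < flank_mfe
        and nt_ent >= cfg.e_min
        and st_ent <= cfg.s_max
        and (tail_frac >= cfg.t_min if cfg.require_tailing else True)
        and multimap <= cfg.max_multimap
    )
    return CandidateEvaluation(
        five_prime_heterogeneity=het5, three_prime_heterogeneity=het3,
        overhang_ok=overhang_ok, duplex_mfe=duplex_mfe, flanking_mfe=flank_mfe,
        nucleotide_entropy=nt_ent, structural_entropy=st_ent,
        tailing_fraction=tail_frac, multimap_factor=multimap, passed=passed,
    )


def score_terms(candidate: HairpinCandidate, tags: Sequence[AlignedTag],
                background: BackgroundModel) -> dict:
    """The four additive log-odds terms of the candidate score.

    structure: folding-score z against random genomic windows (lower
    energy than expected scores positively). duplex: how completely the
    mature arm pairs into one partner helix. reads: concentration of
    supporting reads onto the mature/star arms relative to a uniform
    fragmentation null, scaled by log2 read support. star: bonus for
    observed star-arm reads (Dicer duplex evidence), penalty without.
    """
    seq = candidate.sequence
    n = len(seq)
    gc = (seq.count("G") + seq.count("C")) / n
    z = background.z(candidate.mfe, n, gc)
    t_struct = float(np.clip(-z, -8.0, 8.0))

    pairs = pairs_from_structure(candidate.structure)
    a, b = candidate.mature
    q = sum(1 for i in range(a, b) if i in pairs) / (b - a)
    t_duplex = float(np.clip(12.0 * (q - 0.65), -8.0, 4.0))

    regions = [(_read_region(t, candidate), t.count) for t in tags]
    total = sum(c for _, c in regions)
    if candidate.star is None or total == 0:
        t_reads = 0.0
        t_star = -2.0
    else:
        arm_count = sum(c for r, c in regions if r in ("mature", "star"))
        frac_arm = arm_count / total
        null_frac = min(((b - a) + (candidate.star[1] - candidate.star[0]) + 12) / n, 1.0)
        t_reads = (frac_arm - null_frac) * 2.0 * math.log2(1 + total)
        star_count = sum(c for r, c in regions if r == "star")
        t_star = 2.0 if star_count > 0 else -1.0
    return {"structure": t_struct, "duplex": t_duplex, "reads": t_reads, "star": t_star}


def score_candidate(candidate: HairpinCandidate, tags: Sequence[AlignedTag],
                    background: BackgroundModel) -> float:
    """Log-odds score for the biogenesis model vs uniform fragmentation."""
    return float(sum(score_terms(candidate, tags, background).values()))


def call_mirnas(tags: Sequence[AlignedTag], genome: GenomeRef, mode: str = "deep",
                score_cutoff: float = 1.0, sample: str = "sample",
                config: Optional[DiscoveryConfig] = None,
                background: Optional[BackgroundModel] = None):
    """Run excision + evaluation and return per-sample candidate calls.

    ``deep`` mode keeps candidates with score >= ``score_cutoff``;
    ``dentify`` mode keeps candidates passing all ten stringent criteria.
    """
    if mode not in ("deep", "dentify"):
        raise ValueError("mode must be 'deep' or 'dentify'")
    cfg = config or DiscoveryConfig()
    bg = background or fit_background_model(genome)
    calls = []
    for cand in excise_candidates(tags, genome, config=cfg):
        support = cand.support
        if mode == "deep":
            score = score_candidate(cand, support, bg)
            if score < score_cutoff:
                continue
        else:
            try:
                ev = evaluate_candidate(cand, support, genome=genome, config=cfg)
            except ValueError:
                continue
            if not ev.passed:
                continue
            score = score_candidate(cand, support, bg)
        m0, m1 = cand.mature_genomic
        calls.append(CandidateCall(
            sample=sample, tool=mode, chrom=cand.chrom, strand=cand.strand,
            mature=(m0, m1), hairpin=cand.interval,
            mature_sequence=genome.fetch(cand.chrom, m0, m1, cand.strand),
            score=score,
        ))
    return calls


def _candidate_scores(tags, genome, cfg, bg):
    return np.array([
        score_candidate(c, c.support, bg)
        for c in excise_candidates(tags, genome, config=cfg)
    ])


def permute_tags(tags: Sequence[AlignedTag], genome: GenomeRef, rng) -> list:
    """Shuffle tag positions uniformly over their chromosome.

    Lengths, counts, strands, chromosomes and hit counts are preserved;
    sequences are re-read from the genome at the new position.
    """
    out = []
    for t in tags:
        clen = genome.length(t.chrom)
        L = min(t.length, clen)
        start = int(rng.integers(0, clen - L + 1))
        out.append(AlignedTag(
            chrom=t.chrom, start=start, end=start + L, strand=t.strand,
            sequence=genome.fetch(t.chrom, start, start + L, t.strand),
            count=t.count, n_hits=t.n_hits,
        ))
    return out


def signal_to_noise(tags: Sequence[AlignedTag], genome: GenomeRef,
                    n_perm: int = 100, cutoffs=None, seed: int = 0,
                    config: Optional[DiscoveryConfig] = None,
                    background: Optional[BackgroundModel] = None) -> SNRProfile:
    """Permutation signal-to-noise over integer score cutoffs.

    For each permutation round, tag positions are shuffled uniformly over
    the genome and the excise+score pipeline re-run; SNR per cutoff is the
    real call count divided by the mean permuted call count (NaN at 0/0).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cfg = config or DiscoveryConfig()
    bg = background or fit_background_model(genome)
    cutoffs = np.arange(-10, 11) if cutoffs is None else np.asarray(cutoffs)
    rng = np.random.default_rng(seed)

    real_scores = _candidate_scores(tags, genome, cfg, bg)
    real_counts = np.array([(real_scores >= c).sum() for c in cutoffs], dtype=float)
    perm_counts = np.zeros((n_perm, len(cutoffs)))
    for r in range(n_perm):
        p_scores = _candidate_scores(permute_tags(tags, genome, rng), genome, cfg, bg)
        perm_counts[r] = [(p_scores >= c).sum() for c in cutoffs]
    perm_mean = perm_counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = real_counts / perm_mean
    snr[(real_counts == 0) & (perm_mean == 0)] = np.nan
    return SNRProfile(cutoffs=cutoffs, real_counts=real_counts,
                      perm_mean=perm_mean, perm_counts=perm_counts, snr=snr)
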