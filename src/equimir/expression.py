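"""Quantification, TMM normalization, expression filters and MDS.

Counts are summarised per mature-hairpin combination; normalization is
counts-per-million over TMM-corrected effective library sizes (trimmed
mean of M-values computed against a reference sample); group expression
calls follow the moderate/high-expression rule (>= 10 cpm in 90 % of the
group's libraries) with derived group-specific and universal sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CatalogEntry, CountMatrix

LOG_PSEUDOCOUNT = 0.5


def quantify(tags_by_sample: dict, catalog: Sequence[CatalogEntry],
             metadata: Optional[pd.DataFrame] = None, slack: int = 2) -> CountMatrix:
    """Count tags per mature-hairpin combination and sample.

    A tag counts toward an entry iff it shares the strand and its interval
    lies within the entry's mature interval extended by ``slack`` nt on
    each side. A tag matching several entries contributes its full count to
    each of them (one mature may derive from more than one hairpin).
    """
    samples = list(tags_by_sample)
    ids = [e.id for e in catalog]
    counts = pd.DataFrame(0, index=pd.Index(ids, name="mirna"), columns=samples, dtype=int)
    for sample, tags in tags_by_sample.items():
        for t in tags:
            for e in catalog:
                if t.chrom == e.chrom and t.strand == e.strand \
                        and t.start >= e.mature[0] - slack and t.end <= e.mature[1] + slack:
                    counts.loc[e.id, sample] += t.count
    if metadata is None:
        metadata = pd.DataFrame(index=pd.Index(samples, name="sample"))
    return CountMatrix(counts=counts, metadata=metadata)


def _as_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def tmm_factors(counts, trim_m: float = 0.3, trim_a: float = 0.05,
                ref_column: Optional[str] = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the column whose upper quartile of non-zero
    scaled counts is closest to the mean upper quartile. Per sample, M
    (log2 expression ratio vs reference) and A (mean log2 abundance) are
    computed over rows positive in both; rows in the top/bottom ``trim_m``
    of M and ``trim_a`` of A are trimmed; the factor is 2 to the
    precision-weighted mean of the remaining M values. Factors are rescaled
    to geometric mean 1, so they are invariant to pure depth changes.
    """
    y = _as_frame(counts)
    if y.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = y.sum(axis=0).astype(float)
    zero_cols = lib[lib == 0]
    if len(zero_cols):
        raise ValueError(f"all-zero library: {list(zero_cols.index)}")
    p = y.divide(lib, axis=1)
    if ref_column is None:
        uq = p.apply(lambda col: np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0)
        ref_column = (uq - uq.mean()).abs().idxmin()
    ref = p[ref_column].to_numpy()
    nref = lib[ref_column]

    factors = {}
    for col in y.columns:
        obs = p[col].to_numpy()
        keep = (obs > 0) & (ref > 0)
        if keep.sum() == 0:
            raise ValueError(f"no rows positive in both {col!r} and reference")
        o, r = obs[keep], ref[keep]
        m = np.log2(o / r)
        a = 0.5 * (np.log2(o) + np.log2(r))
        # delta-method precision weights at a nominal depth, so factors are
        # a function of the count proportions only (exact scale invariance)
        nominal = 1e6
        yk = o * nominal
        yr = r * nominal
        w = (nominal - yk) / (nominal * yk) + (nominal - yr) / (nominal * yr)
        n = len(m)
        lo_m, hi_m = np.floor(n * trim_m), np.ceil(n * (1 - trim_m))
        lo_a, hi_a = np.floor(n * trim_a), np.ceil(n * (1 - trim_a))
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        sel = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
        if sel.sum() == 0:
            factors[col] = 1.0
            continue
        mean_m = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
        factors[col] = float(2.0 ** mean_m)
    f = pd.Series(factors)
    f /= np.exp(np.log(f).mean())
    return f


def cpm_matrix(counts, factors: Optional[pd.Series] = None) -> pd.DataFrame:
    """Counts per million over effective library sizes (library x factor)."""
    y = _as_frame(counts)
    lib = y.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=y.columns)
    if (factors <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = lib * factors.reindex(y.columns)
    if (eff == 0).any():
        raise ValueError("zero effective library size")
    return y.divide(eff, axis=1) * 1e6


def filter_low_expression(cpm: pd.DataFrame, min_cpm: float = 1.0,
                          frac: float = 0.9) -> pd.Index:
    """Rows kept after the low-expression filter.

    A row is removed iff its cpm is below ``min_cpm`` in at least ``frac``
    of all samples.
    """
    below = (cpm < min_cpm).mean(axis=1)
    return cpm.index[below < frac]


@dataclass
class GroupExpressionTable:
    """Group-level expression calls and the derived specificity sets."""

    expressed: pd.DataFrame        # miRNA x group, boolean
    specific: pd.DataFrame         # miRNA x group, boolean (expressed in that group only)
    universal: pd.Series           # miRNA -> bool (expressed in every group)
    high: pd.DataFrame             # rows (group, miRNA, mean_cpm) with mean cpm > high_cpm

    def venn_counts(self) -> pd.Series:
        """Number of expressed miRNAs per exact group-membership pattern."""
        patterns = self.expressed.apply(
            lambda row: "&".join(sorted(self.expressed.columns[row])) or "(none)", axis=1)
        return patterns.value_counts()


def group_expression_calls(cpm: pd.DataFrame, groups: pd.Series,
                           min_cpm: float = 10.0, frac: float = 0.9,
                           high_cpm: float = 100.0) -> GroupExpressionTable:
    """Call each miRNA expressed per group and derive specific/universal sets.

    A miRNA is expressed in a group iff its cpm reaches ``min_cpm`` in at
    least ``frac`` of the group's samples; group-specific means expressed in
    exactly that one group; universal means expressed in every group. The
    ``high`` table lists group-specific miRNAs whose within-group mean cpm
    exceeds ``high_cpm``.
    """
    groups = groups.reindex(cpm.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group")
    import warnings
    labels = sorted(groups.unique())
    expressed = {}
    for g in labels:
        cols = groups.index[groups == g]
        if len(cols) < 2:
            warnings.warn(f"group {g!r} has < 2 samples")
        expressed[g] = (cpm[cols] >= min_cpm).mean(axis=1) >= frac
    expressed = pd.DataFrame(expressed)
    n_groups = expressed.sum(axis=1)
    specific = pd.DataFrame(expressed.to_numpy() & (n_groups.to_numpy()[:, None] == 1),
                            index=expressed.index, columns=expressed.columns)
    universal = n_groups == len(labels)
    high_rows = []
    for g in labels:
        cols = groups.index[groups == g]
        means = cpm.loc[specific[g], cols].mean(axis=1)
        for mirna, mean in means[means > high_cpm].items():
            high_rows.append({"group": g, "mirna": mirna, "mean_cpm": float(mean)})
    high = pd.DataFrame(high_rows, columns=["group", "mirna", "mean_cpm"])
    return GroupExpressionTable(expressed=expressed, specific=specific,
                                universal=universal, high=high)


def mds_coordinates(cpm: pd.DataFrame, top_n: int = 500,
                    pseudocount: float = LOG_PSEUDOCOUNT) -> pd.DataFrame:
    """Classical 2-D scaling on leading log-fold-change distances.

    The distance between two samples is the root-mean-square of the
    ``top_n`` largest absolute log2 fold changes between them (on cpm plus
    a pseudocount); coordinates come from Torgerson double-centering, so
    sign and rotation are arbitrary.
    """
    if cpm.shape[1] < 3:
        raise ValueError("MDS needs >= 3 samples")
    logx = np.log2(cpm.to_numpy(dtype=float) + pseudocount)
    n = logx.shape[1]
    k = min(top_n, logx.shape[0])
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(logx[:, i] - logx[:, j])
            top = np.partition(diff, len(diff) - k)[len(diff) - k:]
            D[i, j] = D[j, i] = np.sqrt(np.mean(top ** 2))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pd.DataFrame(coords, index=cpm.columns, columns=["dim1", "dim2"])
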