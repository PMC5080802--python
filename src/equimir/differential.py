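"""Negative-binomial exact-test differential expression.

The two-group path mirrors the classic small-sample RNA-seq workflow:
moderate/high-expression prefilter, TMM normalization, quantile adjustment
of all libraries to one common effective size, common-dispersion
estimation by conditional maximum likelihood, a two-sided conditional
exact test per miRNA, and Benjamini-Hochberg FDR control. A per-miRNA
covariate screen (exact test for binary covariates, rank correlation for
numeric ones) covers nuisance factors such as sex, age and haemolysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .expression import LOG_PSEUDOCOUNT, cpm_matrix, tmm_factors
from .types import CountMatrix, DEResult


@dataclass
class DispersionEstimate:
    """Common negative-binomial dispersion (variance = mu + phi mu^2)."""

    common: float

    def __post_init__(self):
        if self.common < 0:
            raise ValueError("dispersion must be >= 0")


def quantile_adjust(counts: pd.DataFrame, factors: Optional[pd.Series] = None) -> pd.DataFrame:
    """Scale every library to the geometric-mean effective size.

    Columns are scaled so all samples share one effective library size
    (the geometric mean of the observed effective sizes); entries are
    rounded with the largest-remainder rule so column sums are preserved
    up to integer resolution. This is the summarised form of the
    quantile-to-common-size adjustment the conditional likelihood assumes.
    """
    lib = counts.sum(axis=0).astype(float)
    eff = lib if factors is None else lib * factors.reindex(counts.columns)
    target = float(np.exp(np.log(eff).mean()))
    out = {}
    for col in counts.columns:
        scaled = counts[col].to_numpy(dtype=float) * (target / eff[col])
        floor = np.floor(scaled)
        remainder = scaled - floor
        deficit = int(round(scaled.sum() - floor.sum()))
        add = np.zeros_like(floor)
        if deficit > 0:
            top = np.argsort(-remainder, kind="stable")[:deficit]
            add[top] = 1
        out[col] = (floor + add).astype(int)
    return pd.DataFrame(out, index=counts.index)


def _cond_loglik(y: np.ndarray, r: float) -> float:
    """Conditional NB log-likelihood of one group given its total."""
    n = y.shape[0]
    z = y.sum()
    return float(gammaln(y + r).sum() + gammaln(n * r)
                 - gammaln(z + n * r) - n * gammaln(r))


def estimate_dispersion(counts: pd.DataFrame, groups: pd.Series,
                        grid=(1e-4, 5.0), tol: float = 1e-4) -> DispersionEstimate:
    """Common dispersion maximizing the conditional likelihood.

    Counts should be quantile-adjusted to a common library size. The
    conditional likelihood (given per-group totals) is summed over genes
    and groups and maximized over phi by golden-section search on
    log10(phi), after a coarse grid pass. Deterministic; invariant to
    sample order.
    """
    groups = groups.reindex(counts.columns)
    for g, n in groups.value_counts().items():
        if n < 2:
            raise ValueError(f"group {g!r} has a single sample; no within-group information")
    blocks = [counts.loc[:, groups == g].to_numpy(dtype=float) for g in sorted(groups.unique())]

    def total_ll(log_phi):
        r = 1.0 / (10.0 ** log_phi)
        return sum(
            _cond_loglik(block[i], r)
            for block in blocks for i in range(block.shape[0])
        )

    lo, hi = np.log10(grid[0]), np.log10(grid[1])
    xs = np.linspace(lo, hi, 25)
    lls = [total_ll(x) for x in xs]
    k = int(np.argmax(lls))
    a = xs[max(k - 1, 0)]
    b = xs[min(k + 1, len(xs) - 1)]
    gr = (np.sqrt(5) - 1) / 2
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = total_ll(c), total_ll(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = total_ll(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = total_ll(d)
    phi = 10.0 ** ((a + b) / 2)
    if k == 0 and lls[0] >= max(lls):
        phi = grid[0]
    return DispersionEstimate(common=float(phi))


def _conditional_logpmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(A = k | A + B = t) for k = 0..t under the common-mean NB model.

    Group sums are NB with sizes n_a/phi and n_b/phi and a shared success
    probability, which cancels in the conditional: the result is a
    beta-binomial-type distribution depending only on the sizes and phi.
    At phi = 0 it reduces to Binomial(t, n_a / (n_a + n_b)).
    """
    k = np.arange(t + 1)
    if phi <= 0:
        return stats.binom.logpmf(k, t, n_a / (n_a + n_b))
    ra, rb = n_a / phi, n_b / phi
    lg = (gammaln(k + ra) - gammaln(k + 1) - gammaln(ra)
          + gammaln(t - k + rb) - gammaln(t - k + 1) - gammaln(rb))
    norm = gammaln(t + ra + rb) - gammaln(t + 1) - gammaln(ra + rb)
    return lg - norm


def exact_test(counts_a, counts_b, phi: float):
    """Two-sided conditional exact test for equal means between two groups.

    ``counts_a``/``counts_b`` are per-sample counts for one miRNA (1-D) or
    a genes x samples block (2-D); library sizes must have been equalised
    first. Conditioning on the total t, the p-value sums the probabilities
    of all splits no more likely than the observed one (minimum-likelihood
    two-sided convention, ties included). Returns a float or an array.
    """
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative counts")
    if a.ndim == 1:
        return _exact_one(a, b, phi)
    return np.array([_exact_one(a[i], b[i], phi) for i in range(a.shape[0])])


def _exact_one(a: np.ndarray, b: np.ndarray, phi: float) -> float:
    sa, t = int(a.sum()), int(a.sum() + b.sum())
    if t == 0:
        return 1.0
    logp = _conditional_logpmf(t, len(a), len(b), phi)
    obs = logp[sa]
    p = np.exp(logp[logp <= obs + 1e-12]).sum()
    return float(min(p, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def run_de(counts: CountMatrix, group_col: str = "breed",
           groups: Optional[Sequence[str]] = None, fdr_threshold: float = 0.001,
           min_cpm: float = 10.0, frac: float = 0.9):
    """Full two-group DE pipeline; returns (results, de_set).

    Steps: keep miRNAs at >= ``min_cpm`` cpm in >= ``frac`` of all samples,
    TMM-normalize, quantile-adjust to a common library size, estimate the
    common dispersion, exact-test each miRNA, BH-adjust, and call DE below
    ``fdr_threshold``. log2FC is group2 over group1 on normalized mean cpm
    with a pseudocount, so it is always finite.
    """
    labels = counts.metadata[group_col].reindex(counts.counts.columns)
    if groups is None:
        groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = groups
    cols1 = labels.index[labels == g1]
    cols2 = labels.index[labels == g2]
    if len(cols1) == 0 or len(cols2) == 0:
        raise ValueError("a group is empty")

    y = counts.counts[list(cols1) + list(cols2)]
    raw_cpm = cpm_matrix(y)
    keep = raw_cpm.index[((raw_cpm >= min_cpm).mean(axis=1) >= frac)]
    y = y.loc[keep]
    if y.shape[0] == 0:
        return [], set()

    factors = tmm_factors(y)
    adj = quantile_adjust(y, factors)
    sub_groups = pd.Series([g1] * len(cols1) + [g2] * len(cols2), index=y.columns)
    disp = estimate_dispersion(adj, sub_groups)
    a = adj[cols1].to_numpy()
    b = adj[cols2].to_numpy()
    pvals = exact_test(a, b, disp.common)

    norm_cpm = cpm_matrix(y, factors)
    mean1 = norm_cpm[cols1].mean(axis=1) + LOG_PSEUDOCOUNT
    mean2 = norm_cpm[cols2].mean(axis=1) + LOG_PSEUDOCOUNT
    lfc = np.log2(mean2 / mean1)
    fdr = bh_fdr(pvals)

    results = []
    for i, mirna in enumerate(y.index):
        de = fdr[i] < fdr_threshold
        direction = "ns" if not de else ("up" if lfc.iloc[i] > 0 else "down")
        results.append(DEResult(mirna=mirna, log2fc=float(lfc.iloc[i]),
                                pvalue=float(pvals[i]), fdr=float(fdr[i]),
                                direction=direction))
    results.sort(key=lambda r: (r.fdr, r.pvalue, r.mirna))
    de_set = {r.mirna for r in results if r.fdr < fdr_threshold}
    return results, de_set


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mirna": r.mirna, "log2fc": r.log2fc, "pvalue": r.pvalue,
        "fdr": r.fdr, "direction": r.direction,
    } for r in results])


def covariate_screen(counts: CountMatrix, covariate: str,
                     min_cpm: float = 10.0, frac: float = 0.9) -> pd.DataFrame:
    """Per-miRNA association screen against one sample covariate.

    Binary covariates (two distinct values, e.g. sex) go through the same
    two-group exact-test path as the DE pipeline; numeric covariates (age,
    haemolysis absorbance) are tested by Spearman rank correlation of
    log2(cpm + pseudocount) against the covariate. Returns a frame with
    per-miRNA p and BH FDR.
    """
    cov = counts.metadata[covariate].reindex(counts.counts.columns)
    if cov.isna().any():
        raise ValueError("covariate must be defined for all samples")
    if cov.nunique() < 2:
        raise ValueError("constant covariate")

    if cov.nunique() == 2:
        results, _ = run_de(counts, group_col=covariate,
                            groups=sorted(cov.unique()), min_cpm=min_cpm, frac=frac)
        frame = results_to_frame(results).set_index("mirna")[["pvalue", "fdr"]]
        return frame.sort_values("fdr")

    y = counts.counts
    raw_cpm = cpm_matrix(y)
    keep = raw_cpm.index[((raw_cpm >= min_cpm).mean(axis=1) >= frac)]
    y = y.loc[keep]
    factors = tmm_factors(y)
    logx = np.log2(cpm_matrix(y, factors) + LOG_PSEUDOCOUNT)
    x = cov.astype(float).to_numpy()
    pvals = []
    for mirna in logx.index:
        rho, p = stats.spearmanr(logx.loc[mirna].to_numpy(), x)
        pvals.append(1.0 if np.isnan(p) else float(p))
    frame = pd.DataFrame({"pvalue": pvals, "fdr": bh_fdr(pvals)}, index=logx.index)
    return frame.sort_values("fdr")
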