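"""Quantitative Significance Analysis of Microarrays (SAM).

Given a log2 gene-expression matrix and a continuous per-sample response
(here: the log2 ratio of an isoform pair), each gene gets a moderated
regression statistic

    d_i = r_i / (s_i + s0)

where r_i is the least-squares slope of the gene's expression on the centered
response, s_i its standard error, and s0 a "fudge factor" that stabilizes the
ranking of low-variance genes. s0 is chosen by the standard automatic rule:
among candidate percentiles of the s_i distribution, pick the one minimizing
the coefficient of variation of the median absolute deviation of d_i across
s_i-quantile bins. The false discovery rate at a cut |d| >= c is estimated by
permuting the response: FDR(c) = median over permutations of the number of
null |d| beyond c, divided by the observed count beyond c. Selection at an
FDR threshold of exactly 0 requires that *no* permutation produces any
statistic beyond the cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IsoswitchError


@dataclass
class SamResult:
    """Per-gene SAM table plus run-level quantities."""

    table: pd.DataFrame  # gene_id, r, s, d, q_value, selected
    s0: float
    s0_percentile: float
    n_permutations: int
    excluded_genes: list[str]  # zero-variance genes, not testable


def _slopes(Gc: np.ndarray, rc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-gene OLS slope and its standard error.

    Gc: genes x samples, row-centered. rc: centered response (samples,).
    """
    n = Gc.shape[1]
    ss = float(rc @ rc)
    r = Gc @ rc / ss
    rss = (Gc * Gc).sum(axis=1) - r * r * ss
    rss = np.clip(rss, 0.0, None)
    s = np.sqrt(rss / (n - 2) / ss)
    return r, s


def _auto_s0(r: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """SAM's automatic fudge factor: the s-percentile minimizing the CV of
    bin-wise MADs of d. Returns (s0, percentile)."""
    from scipy.stats import median_abs_deviation

    alphas = np.arange(0.0, 1.01, 0.05)
    n_bins = int(min(100, max(2, len(s) // 10)))
    # bin genes by s quantiles
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    best = (np.inf, 0.0, 0.0)
    for alpha in alphas:
        s0 = float(np.quantile(s, alpha))
        d = r / (s + s0)
        mads = []
        for b in range(n_bins):
            mask = bins == b
            if mask.sum() >= 2:
                mads.append(median_abs_deviation(d[mask], scale="normal"))
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best[0]:
            best = (cv, s0, alpha)
    if not np.isfinite(best[0]):
        return float(np.median(s)), 0.5
    return best[1], best[2]


def sam_quantitative(
    gene_matrix: pd.DataFrame,
    response: pd.Series,
    n_permutations: int = 200,
    seed: int = 0,
    fdr_threshold: float = 0.05,
    s0_percentile: float | None = None,
) -> SamResult:
    """Quantitative SAM of every gene against a continuous response.

    Parameters
    ----------
    gene_matrix : genes x samples log2 expression.
    response : per-sample quantitative response (must share sample ids).
    n_permutations : response permutations for the null (>= 10).
    s0_percentile : fix s0 at this percentile of s instead of the automatic
        CV-minimizing rule.
    """
    samples = gene_matrix.columns
    if not set(samples) <= set(response.index):
        missing = sorted(set(samples) - set(response.index))[:3]
        raise IsoswitchError(f"response missing samples, e.g. {missing}")
    resp = response.loc[samples].to_numpy(dtype=float)
    n = len(samples)
    if n < 8:
        raise IsoswitchError(f"SAM needs >=8 samples, got {n}")
    if np.std(resp) == 0:
        raise IsoswitchError("constant response; SAM is undefined")
    if n_permutations < 10:
        raise IsoswitchError("need at least 10 permutations")

    G = gene_matrix.to_numpy(dtype=float)
    variances = G.var(axis=1)
    testable = variances > 0
    excluded = list(gene_matrix.index[~testable])
    Gt = G[testable]
    genes = gene_matrix.index[testable]

    rc = resp - resp.mean()
    Gc = Gt - Gt.mean(axis=1, keepdims=True)
    r, s = _slopes(Gc, rc)
    if s0_percentile is None:
        s0, used_pct = _auto_s0(r, s)
    else:
        s0 = float(np.quantile(s, s0_percentile))
        used_pct = float(s0_percentile)
    d = r / (s + s0)

    rng = np.random.default_rng(seed)
    ss = float(rc @ rc)
    row_ss = (Gc * Gc).sum(axis=1)
    null_counts = np.empty((n_permutations, len(d)))
    abs_d_sorted_desc = np.sort(np.abs(d))[::-1]
    max_null = -np.inf
    for pi in range(n_permutations):
        perm = rng.permutation(rc)
        rp = Gc @ perm / ss
        rssp = np.clip(row_ss - rp * rp * ss, 0.0, None)
        sp = np.sqrt(rssp / (n - 2) / ss)
        dp = np.abs(rp / (sp + s0))
        max_null = max(max_null, float(dp.max()))
        # null genes at least as extreme as each observed cut
        dp_sorted = np.sort(dp)
        null_counts[pi] = len(dp) - np.searchsorted(dp_sorted, abs_d_sorted_desc, side="left")

    obs_counts = np.arange(1, len(d) + 1)
    median_null = np.median(null_counts, axis=0)
    q_raw = np.minimum(median_null / obs_counts, 1.0)
    # monotone: a gene's q is the best FDR over all cuts that include it
    q_sorted = np.minimum.accumulate(q_raw[::-1])[::-1]

    order = np.argsort(-np.abs(d), kind="stable")
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    if fdr_threshold <= 0:
        selected = np.abs(d) > max_null
    else:
        selected = q <= fdr_threshold

    table = pd.DataFrame(
        {"r": r, "s": s, "d": d, "q_value": q, "selected": selected}, index=genes
    )
    table.index.name = "gene_id"
    return SamResult(
        table=table,
        s0=s0,
        s0_percentile=used_pct,
        n_permutations=n_permutations,
        excluded_genes=excluded,
    )


def signature_response(matrix, pair: tuple[str, str], offset: float = 1.0) -> pd.Series:
    """The pair's log2 alternative/predominant ratio as SAM's response."""
    from .subtype import ratio_profile

    return ratio_profile(matrix, pair, offset=offset)


def signature_clusters(gene_matrix: pd.DataFrame, k: int = 4) -> pd.Series:
    """Agglomerative clustering of genes (1 - Pearson distance, average
    linkage) cut at ``k``; labels 1..k ordered by cluster size descending."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    if len(gene_matrix) < k:
        raise IsoswitchError(f"need at least k={k} genes, got {len(gene_matrix)}")
    if k == 1:
        return pd.Series(1, index=gene_matrix.index)
    X = gene_matrix.to_numpy(dtype=float)
    # guard zero-variance rows: correlation distance undefined; nudge to 0 distance
    dist = pdist(X, metric="correlation")
    dist = np.nan_to_num(dist, nan=0.0)
    Z = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    sizes = pd.Series(labels).value_counts()
    rank = {old: new for new, old in enumerate(sizes.index, start=1)}
    return pd.Series([rank[x] for x in labels], index=gene_matrix.index)
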