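"""Predominant-isoform selection and isoform-switch detection.

Stages, in pipeline order:

1. For each gene, the *predominant* isoform is the detected transcript with
   the greatest upper-quartile (75th percentile) abundance across samples;
   every other detected isoform forms a (predominant, alternative) pair.
2. First-pass screen: OLS of the alternative on the predominant isoform
   (log2 scale); a pair passes when the slope is significantly negative.
3. RIN-artifact screen: hierarchical clustering of samples on the passing
   pairs' isoforms; if the 2-cut separates low-RIN samples, isoforms that are
   differentially expressed between the clusters in opposite directions mark
   a pair as a degradation artifact. Degradation preferentially inflates the
   shorter transcript of a pair, which the screen tallies.
4. RIN-adjusted switch model: per pair, OLS of the alternative isoform on RIN
   and the predominant isoform. A switch requires a negative predominant
   coefficient with p < 0.05 while the RIN coefficient stays non-significant
   (p > 0.2, strict) — switching explained by degradation is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats as sps

from .io import IsoformCatalog, IsoformMatrix, IsoswitchError, SampleAnnotation
from .normalize import DetectionResult
from .stats import bh_adjust, ols, quantile75, welch_t

CANDIDATE_COLUMNS = [
    "gene_id",
    "predominant_id",
    "alternative_id",
    "first_pass_slope",
    "first_pass_p",
    "passed_first_pass",
    "untestable",
]

FIT_COLUMNS = [
    "gene_id",
    "predominant_id",
    "alternative_id",
    "beta_rin",
    "beta_pred",
    "p_rin",
    "p_pred",
    "n_samples_used",
    "is_switch",
    "untestable",
]


def predominant_isoform(
    matrix: IsoformMatrix, det: DetectionResult, catalog: IsoformCatalog, gene_id: str
) -> str:
    """Detected isoform of ``gene_id`` with maximal 75th-percentile abundance.

    Ties break by greater total abundance, then lexicographically smaller id.
    Operates on the uq_normalized scale over all samples.
    """
    if matrix.scale != "uq_normalized":
        raise IsoswitchError("predominant isoform is defined on the uq_normalized scale")
    isos = det.detected_of(gene_id, catalog)
    if not isos:
        raise IsoswitchError(f"gene {gene_id!r} has no detected isoform")
    best = None
    for iso in sorted(isos):
        row = matrix.values.loc[iso].to_numpy()
        key = (quantile75(row), float(row.sum()))
        if best is None or key > best[0]:
            best = (key, iso)
    return best[1]


def predominant_map(
    matrix: IsoformMatrix, det: DetectionResult, catalog: IsoformCatalog
) -> dict[str, str]:
    """Predominant isoform per gene, for genes with >=1 detected isoform."""
    genes = det.per_gene_isoform_count.index[det.per_gene_isoform_count > 0]
    return {g: predominant_isoform(matrix, det, catalog, g) for g in genes}


def enumerate_pairs(
    det: DetectionResult, predominant: dict[str, str], catalog: IsoformCatalog
) -> list[tuple[str, str, str]]:
    """(gene_id, predominant_id, alternative_id) for every non-predominant
    detected isoform; single-isoform genes emit nothing."""
    pairs = []
    for gene in sorted(predominant):
        pred = predominant[gene]
        for iso in sorted(det.detected_of(gene, catalog)):
            if iso != pred:
                pairs.append((gene, pred, iso))
    return pairs


def first_pass_screen(
    matrix: IsoformMatrix, pairs: list[tuple[str, str, str]], alpha: float = 0.05
) -> pd.DataFrame:
    """Simple regression of alternative on predominant isoform (log2 scale).

    A pair passes when slope < 0 and its two-sided p-value < ``alpha``.
    Zero-variance predictors are flagged untestable and never pass.
    """
    if matrix.scale != "log2":
        raise IsoswitchError("first-pass screen operates on the log2 scale")
    if matrix.n_samples < 3:
        raise IsoswitchError("first-pass screen needs at least 3 samples")
    rows = []
    values = matrix.values
    for gene, pred, alt in pairs:
        x = values.loc[pred].to_numpy()
        y = values.loc[alt].to_numpy()
        if np.std(x) == 0:
            rows.append((gene, pred, alt, np.nan, np.nan, False, True))
            continue
        fit = ols(x, y)
        slope, p = float(fit.beta[1]), float(fit.p[1])
        rows.append((gene, pred, alt, slope, p, bool(slope < 0 and p < alpha), False))
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


@dataclass
class RinScreenResult:
    """Outcome of the degradation-artifact screen."""

    sample_cluster: pd.Series  # sample_id -> {1, 2}
    low_rin_cluster: int
    rin_cluster_p: float
    per_isoform_direction: pd.Series  # isoform_id -> high_in_low_rin/low_in_low_rin/ns
    artifact_pairs: set[tuple[str, str]]  # (predominant_id, alternative_id)
    shorter_isoform_high_count: int
    aborted: bool = False
    abort_reason: str = ""
    tested_isoforms: list[str] = field(default_factory=list)


def _empty_screen(reason: str) -> RinScreenResult:
    return RinScreenResult(
        sample_cluster=pd.Series(dtype=int),
        low_rin_cluster=0,
        rin_cluster_p=float("nan"),
        per_isoform_direction=pd.Series(dtype=object),
        artifact_pairs=set(),
        shorter_isoform_high_count=0,
        aborted=True,
        abort_reason=reason,
    )


def rin_artifact_screen(
    matrix: IsoformMatrix,
    candidates: pd.DataFrame,
    annot: SampleAnnotation,
    catalog: IsoformCatalog,
    linkage: str = "average",
    alpha_iso: float = 0.05,
    correct: bool = True,
    center: str = "mean",
) -> RinScreenResult:
    """Flag first-pass pairs whose inverse correlation tracks RNA degradation.

    Samples are clustered (row-centered log2 values, 1 - Pearson distance
    between sample profiles, agglomerative with the given linkage, cut at 2).
    Rows are centered by their mean by default: when a minority of degraded
    samples deviates strongly, mean-centering leaves the intact majority
    coherently offset in the opposite direction, which lets the correlation
    distance separate the degradation stratum; ``center="median"`` gives the
    classic median-polish dialect.
    A Welch t-test on RIN labels the low-RIN cluster; per-isoform Welch tests
    between the clusters (BH-corrected at ``alpha_iso`` unless
    ``correct=False``) assign each isoform a direction, and a pair whose two
    members move in opposite directions is an artifact.
    """
    if matrix.scale != "log2":
        raise IsoswitchError("RIN screen operates on the log2 scale")
    passing = candidates[candidates["passed_first_pass"]]
    if len(passing) < 2:
        return _empty_screen("fewer than 2 first-pass pairs")
    if matrix.n_samples < 4:
        return _empty_screen("fewer than 4 samples")

    isoforms = sorted(set(passing["predominant_id"]) | set(passing["alternative_id"]))
    data = matrix.values.loc[isoforms]
    if center == "mean":
        centered = data.sub(data.mean(axis=1), axis=0)
    elif center == "median":
        centered = data.sub(data.median(axis=1), axis=0)
    else:
        raise IsoswitchError(f"unknown row centering {center!r}")
    # distance between sample profiles = 1 - Pearson correlation
    dist = pdist(centered.to_numpy().T, metric="correlation")
    if not np.all(np.isfinite(dist)):
        return _empty_screen("degenerate sample profiles (zero variance)")
    Z = hierarchy.linkage(dist, method=linkage)
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    cluster = pd.Series(labels, index=data.columns)
    n1, n2 = int((labels == 1).sum()), int((labels == 2).sum())
    if min(n1, n2) < 2:
        return _empty_screen(f"cluster sizes {n1}/{n2}; need >=2 each")

    rin = annot.frame.loc[data.columns, "rin"].to_numpy()
    in1 = labels == 1
    _, rin_p = welch_t(rin[in1], rin[~in1])
    low_rin_cluster = 1 if rin[in1].mean() <= rin[~in1].mean() else 2
    low = labels == low_rin_cluster

    arr = data.to_numpy()
    tstat, pvals = sps.ttest_ind(arr[:, low], arr[:, ~low], axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    padj = bh_adjust(pvals) if correct else pvals
    direction = np.where(
        padj < alpha_iso,
        np.where(tstat > 0, "high_in_low_rin", "low_in_low_rin"),
        "ns",
    )
    per_iso = pd.Series(direction, index=data.index)

    artifacts: set[tuple[str, str]] = set()
    shorter_high = 0
    for _, row in passing.iterrows():
        pred, alt = row["predominant_id"], row["alternative_id"]
        dp, da = per_iso[pred], per_iso[alt]
        if {dp, da} == {"high_in_low_rin", "low_in_low_rin"}:
            artifacts.add((pred, alt))
            high = pred if dp == "high_in_low_rin" else alt
            other = alt if high == pred else pred
            if catalog.length_of(high) < catalog.length_of(other):
                shorter_high += 1
    return RinScreenResult(
        sample_cluster=cluster,
        low_rin_cluster=low_rin_cluster,
        rin_cluster_p=float(rin_p),
        per_isoform_direction=per_iso,
        artifact_pairs=artifacts,
        shorter_isoform_high_count=shorter_high,
        tested_isoforms=isoforms,
    )


def rin_adjusted_switch_test(
    matrix: IsoformMatrix,
    candidates: pd.DataFrame,
    annot: SampleAnnotation,
    alpha_pred: float = 0.05,
    alpha_rin: float = 0.2,
) -> pd.DataFrame:
    """Per-pair model: alternative ~ intercept + RIN + predominant (log2).

    A pair is a switch iff the predominant-isoform coefficient is negative
    with p < ``alpha_pred`` and the RIN coefficient's p exceeds ``alpha_rin``
    (strictly; boundary equality fails). Runs on all samples, tumor and
    normal alike. Near-collinear predictors (|corr| > 0.999) are flagged
    untestable.
    """
    if matrix.scale != "log2":
        raise IsoswitchError("switch model operates on the log2 scale")
    samples = matrix.sample_ids.intersection(annot.sample_ids)
    n = len(samples)
    if n < 4:
        raise IsoswitchError(f"switch model needs >=4 annotated samples, got {n}")
    rin = annot.frame.loc[samples, "rin"].to_numpy()
    values = matrix.values[samples]
    rows = []
    for _, row in candidates.iterrows():
        gene, pred, alt = row["gene_id"], row["predominant_id"], row["alternative_id"]
        x = values.loc[pred].to_numpy()
        y = values.loc[alt].to_numpy()
        if np.std(x) == 0 or abs(np.corrcoef(x, rin)[0, 1]) > 0.999:
            rows.append((gene, pred, alt, np.nan, np.nan, np.nan, np.nan, n, False, True))
            continue
        fit = ols(np.column_stack([rin, x]), y)
        beta_rin, beta_pred = float(fit.beta[1]), float(fit.beta[2])
        p_rin, p_pred = float(fit.p[1]), float(fit.p[2])
        is_switch = bool(beta_pred < 0 and p_rin > alpha_rin and p_pred < alpha_pred)
        rows.append((gene, pred, alt, beta_rin, beta_pred, p_rin, p_pred, n, is_switch, False))
    return pd.DataFrame(rows, columns=FIT_COLUMNS)
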