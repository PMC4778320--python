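"""Upper-quartile normalization, log2 transform, detection filtering and
expression-complexity summaries.

Each sample is scaled so the 75th percentile of its strictly positive values
equals a fixed target; zeros are excluded from the quantile because a large
fraction of annotated transcripts is typically unexpressed and would drag the
upper quartile to zero. Detection then requires a normalized abundance of at
least ``min_count`` in strictly more than ``min_fraction`` of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IsoformCatalog, IsoformMatrix, IsoswitchError
from .stats import quantile75


@dataclass
class DetectionResult:
    """Detected-isoform set with per-isoform fractions and per-gene counts."""

    detected_isoforms: set[str]
    per_isoform_detection_fraction: pd.Series
    per_gene_isoform_count: pd.Series
    min_count: float
    min_fraction: float

    def detected_of(self, gene_id: str, catalog: IsoformCatalog) -> list[str]:
        return [i for i in catalog.isoforms_of(gene_id) if i in self.detected_isoforms]


@dataclass
class ComplexitySummary:
    """Histogram of genes by detected-isoform count and mean isoforms/gene."""

    histogram: dict[int, int]
    mean_isoforms_per_gene: float | None


def upper_quartile_normalize(matrix: IsoformMatrix, target: float = 1000.0) -> IsoformMatrix:
    """Scale each sample so the upper quartile of its positive values is ``target``.

    The quantile uses linear interpolation between order statistics and is
    computed over strictly positive values only. A sample with no positive
    value cannot be normalized and raises.
    """
    if matrix.scale != "raw":
        raise IsoswitchError(f"expected a raw matrix, got scale={matrix.scale!r}")
    if target <= 0:
        raise IsoswitchError("normalization target must be positive")
    v = matrix.values
    scaled = {}
    for sample in v.columns:
        col = v[sample].to_numpy()
        pos = col[col > 0]
        if pos.size == 0:
            raise IsoswitchError(f"sample {sample!r} has no positive values; cannot normalize")
        uq = quantile75(pos)
        scaled[sample] = col * (target / uq)
    out = pd.DataFrame(scaled, index=v.index)
    return IsoformMatrix(values=out, scale="uq_normalized", normalization_target=target)


def log2_transform(matrix: IsoformMatrix, offset: float = 1.0) -> IsoformMatrix:
    """Apply v -> log2(v + offset) cellwise; offset must be positive."""
    if offset <= 0:
        raise IsoswitchError("log2 offset must be positive")
    out = np.log2(matrix.values + offset)
    return IsoformMatrix(
        values=out, scale="log2", normalization_target=matrix.normalization_target
    )


def detect_isoforms(
    matrix: IsoformMatrix,
    catalog: IsoformCatalog,
    min_count: float = 3.0,
    min_fraction: float = 0.60,
) -> DetectionResult:
    """Detected isoforms: abundance >= min_count in strictly >min_fraction of samples.

    The strict inequality means an isoform present in exactly 60% of samples
    is *not* detected under the defaults.
    """
    if matrix.scale != "uq_normalized":
        raise IsoswitchError(f"detection expects a uq_normalized matrix, got {matrix.scale!r}")
    frac = (matrix.values >= min_count).mean(axis=1)
    detected = frac.index[frac > min_fraction]
    gene_ids = catalog.frame["gene_id"]
    counts = gene_ids.loc[gene_ids.index.intersection(detected)].value_counts()
    return DetectionResult(
        detected_isoforms=set(detected),
        per_isoform_detection_fraction=frac,
        per_gene_isoform_count=counts.sort_index(),
        min_count=min_count,
        min_fraction=min_fraction,
    )


def complexity_summary(det: DetectionResult, max_bin: int = 10) -> ComplexitySummary:
    """Histogram {1: n_genes, 2: ..., max_bin: genes with >= max_bin isoforms}."""
    counts = det.per_gene_isoform_count
    counts = counts[counts > 0]
    if counts.empty:
        return ComplexitySummary(histogram={}, mean_isoforms_per_gene=None)
    binned = counts.clip(upper=max_bin)
    hist = {int(k): int(v) for k, v in binned.value_counts().sort_index().items()}
    mean = float(counts.sum()) / float(len(counts))
    return ComplexitySummary(histogram=hist, mean_isoforms_per_gene=mean)


def pairwise_isoform_correlations(
    matrix: IsoformMatrix, det: DetectionResult, catalog: IsoformCatalog
) -> pd.DataFrame:
    """Pearson correlation over all samples for every unordered within-gene
    pair of detected isoforms (log2 scale).

    Returns a frame with columns gene_id, isoform_a, isoform_b, pearson_r,
    n_samples, defined. Zero-variance members yield defined=False and NaN r.
    """
    if matrix.scale != "log2":
        raise IsoswitchError("pair correlations are computed on the log2 scale")
    rows = []
    n = matrix.n_samples
    gene_ids = catalog.frame["gene_id"]
    by_gene: dict[str, list[str]] = {}
    for iso in matrix.isoform_ids:
        if iso in det.detected_isoforms and iso in gene_ids.index:
            by_gene.setdefault(gene_ids[iso], []).append(iso)
    for gene in sorted(by_gene):
        isos = sorted(by_gene[gene])
        if len(isos) < 2:
            continue
        sub = matrix.values.loc[isos].to_numpy()
        sds = sub.std(axis=1)
        for i in range(len(isos)):
            for j in range(i + 1, len(isos)):
                if sds[i] == 0 or sds[j] == 0:
                    rows.append((gene, isos[i], isos[j], np.nan, n, False))
                else:
                    r = float(np.corrcoef(sub[i], sub[j])[0, 1])
                    rows.append((gene, isos[i], isos[j], r, n, True))
    return pd.DataFrame(
        rows, columns=["gene_id", "isoform_a", "isoform_b", "pearson_r", "n_samples", "defined"]
    )


def correlation_summary(pairs: pd.DataFrame) -> dict[str, float]:
    """Median r and fraction of negative correlations over defined pairs."""
    defined = pairs.loc[pairs["defined"], "pearson_r"]
    if defined.empty:
        return {"n_pairs": 0, "median_r": float("nan"), "fraction_negative": float("nan")}
    return {
        "n_pairs": int(len(defined)),
        "median_r": float(defined.median()),
        "fraction_negative": float((defined < 0).mean()),
    }


def select_top_variable(matrix: IsoformMatrix, k: int) -> list[str]:
    """Top-k isoforms by sample variance of log2 abundance.

    Ties break lexicographically by isoform_id; if k exceeds the number of
    rows, all rows are returned with a warning.
    """
    if matrix.scale != "log2":
        raise IsoswitchError("variable-transcript selection operates on the log2 scale")
    var = matrix.values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda iso: (-var[iso], iso))
    if k > len(order):
        warnings.warn(
            f"requested top {k} transcripts but only {len(order)} available; returning all",
            stacklevel=2,
        )
        k = len(order)
    return order[:k]


def gene_abundance(
    matrix: IsoformMatrix, catalog: IsoformCatalog, offset: float = 1.0
) -> pd.DataFrame:
    """Gene-level log2 abundance: log2(sum of the gene's isoforms + offset).

    The sum-of-isoforms convention mirrors how RSEM gene-level expected counts
    decompose into isoform expected counts. Input must be uq_normalized.
    """
    if matrix.scale != "uq_normalized":
        raise IsoswitchError("gene abundance expects a uq_normalized matrix")
    gene_ids = catalog.frame["gene_id"]
    common = matrix.isoform_ids.intersection(gene_ids.index)
    sums = matrix.values.loc[common].groupby(gene_ids.loc[common]).sum()
    sums.index.name = "gene_id"
    return np.log2(sums + offset)
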