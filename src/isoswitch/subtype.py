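"""Subtype association of switching pairs via the alternative/predominant ratio.

The per-sample statistic is the log2 ratio of the alternative to the
predominant isoform (a difference of offset log2 abundances, so it is bounded
and antisymmetric under member swap). Each intrinsic subtype is contrasted
one-vs-rest among tumor samples with a subtype call; an extra contrast
compares Basal against the pooled luminal classes. Alongside each ratio test,
the same Welch t-test on log2 gene abundance records whether total gene
expression differs — switches with constant gene level are the cases where
splicing carries information that gene-level expression misses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import IsoformCatalog, IsoformMatrix, IsoswitchError, SampleAnnotation
from .normalize import gene_abundance

CONTRASTS = ("Basal", "Her2", "LumA", "LumB", "NormalLike", "LuminalVsBasal")
ONE_VS_REST = ("Basal", "Her2", "LumA", "LumB", "NormalLike")

ASSOC_COLUMNS = [
    "gene_id",
    "predominant_id",
    "alternative_id",
    "contrast",
    "t_stat",
    "p_value",
    "associated",
    "gene_level_t",
    "gene_level_p",
    "gene_level_different",
    "untestable",
]


def ratio_profile(
    matrix: IsoformMatrix, pair: tuple[str, str], offset: float = 1.0
) -> pd.Series:
    """Per-sample log2(alternative + offset) - log2(predominant + offset).

    ``pair`` is (predominant_id, alternative_id); the uq_normalized scale is
    required so ratios are comparable across samples.
    """
    if matrix.scale != "uq_normalized":
        raise IsoswitchError("ratio profiles are computed on the uq_normalized scale")
    if offset <= 0:
        raise IsoswitchError("ratio offset must be positive")
    pred, alt = pair
    return np.log2(matrix.values.loc[alt] + offset) - np.log2(matrix.values.loc[pred] + offset)


def contrast_groups(
    annot: SampleAnnotation, contrast: str
) -> tuple[pd.Index, pd.Index]:
    """Sample groups for a contrast, restricted to subtyped tumor samples."""
    f = annot.frame
    tumors = f[(f["tissue"] == "tumor") & (f["subtype"] != "NA")]
    if contrast == "LuminalVsBasal":
        g1 = tumors.index[tumors["subtype"] == "Basal"]
        g2 = tumors.index[tumors["subtype"].isin(["LumA", "LumB"])]
    elif contrast in ONE_VS_REST:
        g1 = tumors.index[tumors["subtype"] == contrast]
        g2 = tumors.index[tumors["subtype"] != contrast]
    else:
        raise IsoswitchError(f"unknown contrast {contrast!r}")
    return g1, g2


def subtype_tests(
    ratio: pd.Series,
    gene_log2: pd.Series,
    annot: SampleAnnotation,
    contrast: str,
    alpha: float = 0.05,
) -> dict:
    """Welch t-test of the pair ratio (and of gene abundance) between the
    contrast's groups; association and gene-level-difference flags at ``alpha``."""
    from .stats import welch_t

    g1, g2 = contrast_groups(annot, contrast)
    g1 = g1.intersection(ratio.index)
    g2 = g2.intersection(ratio.index)
    if len(g1) < 2 or len(g2) < 2:
        return {
            "contrast": contrast,
            "t_stat": np.nan,
            "p_value": np.nan,
            "associated": False,
            "gene_level_t": np.nan,
            "gene_level_p": np.nan,
            "gene_level_different": False,
            "untestable": True,
        }
    t, p = welch_t(ratio[g1].to_numpy(), ratio[g2].to_numpy())
    gt, gp = welch_t(gene_log2[g1].to_numpy(), gene_log2[g2].to_numpy())
    return {
        "contrast": contrast,
        "t_stat": t,
        "p_value": p,
        "associated": bool(p < alpha),
        "gene_level_t": gt,
        "gene_level_p": gp,
        "gene_level_different": bool(gp < alpha),
        "untestable": False,
    }


def subtype_tests_all(
    pairs: pd.DataFrame,
    matrix: IsoformMatrix,
    catalog: IsoformCatalog,
    annot: SampleAnnotation,
    contrasts: tuple[str, ...] = CONTRASTS,
    offset: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run every contrast for every pair (rows need gene_id/predominant_id/
    alternative_id columns, e.g. the switch-test output)."""
    gene_log2 = gene_abundance(matrix, catalog, offset=offset)
    rows = []
    for _, row in pairs.iterrows():
        gene, pred, alt = row["gene_id"], row["predominant_id"], row["alternative_id"]
        ratio = ratio_profile(matrix, (pred, alt), offset=offset)
        gvec = gene_log2.loc[gene]
        for contrast in contrasts:
            res = subtype_tests(ratio, gvec, annot, contrast, alpha=alpha)
            rows.append({"gene_id": gene, "predominant_id": pred, "alternative_id": alt, **res})
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def subtype_summary(associations: pd.DataFrame) -> pd.DataFrame:
    """Per-contrast counts: associated pairs, distinct genes among them, and
    associated pairs without a gene-level difference. A pair may count under
    several contrasts."""
    rows = []
    for contrast in CONTRASTS:
        sub = associations[(associations["contrast"] == contrast) & associations["associated"]]
        rows.append(
            {
                "contrast": contrast,
                "associated_pairs": int(len(sub)),
                "associated_genes": int(sub["gene_id"].nunique()),
                "pairs_no_gene_difference": int((~sub["gene_level_different"]).sum()),
            }
        )
    return pd.DataFrame(rows)
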