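"""Bimodality screen for subtype-independent switching pairs.

A switching pair that is not explained by subtype may still reflect two
genuine sample subpopulations with opposite isoform usage — or merely a rare
event in a handful of samples. K-means with k=2 on the pair's two log2
abundances separates the candidates: a pair passes only when both clusters
hold more than ``min_cluster`` samples, both isoforms are expressed in both
clusters, and the clusters move the two isoforms in opposite directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import IsoformMatrix, IsoswitchError, SampleAnnotation
from .stats import welch_t


@dataclass
class BimodalVerdict:
    """K-means screen outcome for one pair."""

    pair: tuple[str, str]
    cluster_assignment: pd.Series  # sample_id -> {1, 2}
    cluster_sizes: tuple[int, int]
    both_detected_in_both: bool
    inverse_pattern: bool
    passes: bool
    rin_p: float = float("nan")
    untestable: bool = False


def kmeans_bimodal_screen(
    matrix: IsoformMatrix,
    pair: tuple[str, str],
    min_cluster: int = 50,
    seed: int = 0,
    min_count: float = 3.0,
    offset: float = 1.0,
    annot: SampleAnnotation | None = None,
) -> BimodalVerdict:
    """Screen one pair for two-cluster bimodal isoform usage.

    Features are the two members' log2 abundances; K-means (k=2, 10 restarts,
    seeded) provides the split. Cluster 1 is the cluster with the higher mean
    of the first (predominant) member, so labels are stable under sample
    permutation. "Detected in both clusters" means each isoform's
    within-cluster median abundance reaches ``min_count`` on the normalized
    scale (threshold log2(min_count + offset) on the log2 scale). When an
    annotation is given, a Welch t-test on RIN between clusters is reported
    so degradation-driven splits can be recognized.
    """
    if matrix.scale != "log2":
        raise IsoswitchError("bimodal screen operates on the log2 scale")
    pred, alt = pair
    X = matrix.values.loc[[pred, alt]].to_numpy().T  # samples x 2
    n = X.shape[0]
    if n < 2 * min_cluster:
        return BimodalVerdict(
            pair=pair,
            cluster_assignment=pd.Series(dtype=int),
            cluster_sizes=(0, 0),
            both_detected_in_both=False,
            inverse_pattern=False,
            passes=False,
            untestable=True,
        )
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    raw_labels = km.fit_predict(X)
    # order-normalize: cluster 1 = higher mean of the first member
    mean0 = X[raw_labels == 0, 0].mean()
    mean1 = X[raw_labels == 1, 0].mean()
    labels = np.where(raw_labels == (0 if mean0 >= mean1 else 1), 1, 2)
    assignment = pd.Series(labels, index=matrix.sample_ids)
    in1 = labels == 1
    n1, n2 = int(in1.sum()), int((~in1).sum())

    threshold = np.log2(min_count + offset)
    medians = np.array(
        [
            [np.median(X[in1, 0]), np.median(X[in1, 1])],
            [np.median(X[~in1, 0]), np.median(X[~in1, 1])],
        ]
    )
    both_detected = bool((medians >= threshold).all())
    diff_pred = X[in1, 0].mean() - X[~in1, 0].mean()
    diff_alt = X[in1, 1].mean() - X[~in1, 1].mean()
    inverse = bool(diff_pred * diff_alt < 0)
    passes = bool(min(n1, n2) > min_cluster and both_detected and inverse)

    rin_p = float("nan")
    if annot is not None:
        rin = annot.frame.loc[matrix.sample_ids, "rin"].to_numpy()
        _, rin_p = welch_t(rin[in1], rin[~in1])
    return BimodalVerdict(
        pair=pair,
        cluster_assignment=assignment,
        cluster_sizes=(n1, n2),
        both_detected_in_both=both_detected,
        inverse_pattern=inverse,
        passes=passes,
        rin_p=rin_p,
    )


def nonsubtype_set(
    switches: pd.DataFrame, associations: pd.DataFrame
) -> pd.DataFrame:
    """Switch pairs not associated with any one-vs-rest subtype contrast.

    ``switches`` is the RIN-adjusted fit table (rows with is_switch=True are
    used); ``associations`` is the subtype_tests_all output.
    """
    from .subtype import ONE_VS_REST

    sw = switches[switches["is_switch"]]
    assoc = associations[
        associations["contrast"].isin(ONE_VS_REST) & associations["associated"]
    ]
    assoc_keys = set(zip(assoc["predominant_id"], assoc["alternative_id"]))
    keep = [
        (p, a) not in assoc_keys
        for p, a in zip(sw["predominant_id"], sw["alternative_id"])
    ]
    return sw[keep].reset_index(drop=True)


def verdicts_frame(verdicts: list[BimodalVerdict]) -> pd.DataFrame:
    """Tabular summary of a list of verdicts (one row per pair)."""
    rows = []
    for v in verdicts:
        rows.append(
            {
                "predominant_id": v.pair[0],
                "alternative_id": v.pair[1],
                "n_cluster1": v.cluster_sizes[0],
                "n_cluster2": v.cluster_sizes[1],
                "both_detected_in_both": v.both_detected_in_both,
                "inverse_pattern": v.inverse_pattern,
                "rin_p": v.rin_p,
                "passes": v.passes,
                "untestable": v.untestable,
            }
        )
    return pd.DataFrame(rows)
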