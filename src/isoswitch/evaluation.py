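"""Planted-truth evaluation: run the full analysis on a simulated cohort and
score every stage against the generator's registry.

Pair matching is orientation-insensitive (a planted event is recovered even
if degradation or a usage flip swapped which member the pipeline designates
predominant — the screens' verdicts are symmetric in the pair).
"""

from __future__ import annotations

import numpy as np

from . import bimodal as bimodal_mod
from . import normalize as norm
from . import sam as sam_mod
from . import subtype as subtype_mod
from . import switching
from .simulate import SimConfig, simulate_cohort


def _key(pair) -> frozenset:
    return frozenset(pair)


def run_reference_analysis(
    config: SimConfig | None = None,
    kmeans_seed: int = 17,
    sam_seed: int = 17,
    sam_permutations: int = 200,
    n_null_bimodal: int = 200,
) -> dict:
    """Simulate a cohort, run every stage, and measure recovery metrics.

    Returns a flat dict of scalar metrics; fractions are on [0, 1].
    """
    config = config or SimConfig()
    matrix, catalog, annot, truth = simulate_cohort(config)
    normed = norm.upper_quartile_normalize(matrix)
    logged = norm.log2_transform(normed)
    det = norm.detect_isoforms(normed, catalog)
    summary = norm.complexity_summary(det)
    corr = norm.correlation_summary(norm.pairwise_isoform_correlations(logged, det, catalog))

    pred = switching.predominant_map(normed, det, catalog)
    pairs = switching.enumerate_pairs(det, pred, catalog)
    candidates = switching.first_pass_screen(logged, pairs)
    screen = switching.rin_artifact_screen(logged, candidates, annot, catalog)
    fits = switching.rin_adjusted_switch_test(logged, candidates, annot)

    metrics: dict[str, float] = {
        "n_samples": matrix.n_samples,
        "n_isoforms": len(matrix.isoform_ids),
        "mean_isoforms_per_gene": summary.mean_isoforms_per_gene or 0.0,
        "median_pair_correlation": corr["median_r"],
        "fraction_negative_pairs": corr["fraction_negative"],
        "first_pass_pairs": int(candidates["passed_first_pass"].sum()),
    }

    # --- degradation screen ------------------------------------------------
    art_truth = {_key(p) for p in truth.rin_artifact_pairs}
    flagged = {_key(p) for p in screen.artifact_pairs}
    flagged_planted = art_truth & flagged
    metrics["rin_artifact_sensitivity"] = (
        len(flagged_planted) / len(art_truth) if art_truth else float("nan")
    )
    # direction: among flagged planted pairs, is the high-in-low-RIN member
    # the shorter transcript?
    short_high = 0
    per = screen.per_isoform_direction
    for pair in screen.artifact_pairs:
        if _key(pair) not in flagged_planted:
            continue
        a, b = pair
        hi = a if per.get(a) == "high_in_low_rin" else b
        lo = b if hi == a else a
        if catalog.length_of(hi) < catalog.length_of(lo):
            short_high += 1
    metrics["shorter_isoform_high_fraction"] = (
        short_high / len(flagged_planted) if flagged_planted else float("nan")
    )

    # --- RIN-adjusted switch model -----------------------------------------
    switch_set = {
        _key((p, a))
        for p, a in zip(
            fits.loc[fits["is_switch"], "predominant_id"],
            fits.loc[fits["is_switch"], "alternative_id"],
        )
    }
    sub_truth = {_key(p): v for p, v in truth.subtype_switch_pairs.items()}
    bim_truth = {_key(p): v for p, v in truth.bimodal_pairs.items()}
    recovered_sub = set(sub_truth) & switch_set
    metrics["switch_sensitivity"] = (
        len(recovered_sub) / len(sub_truth) if sub_truth else float("nan")
    )
    true_switches = set(sub_truth) | set(bim_truth)
    false_disc = [k for k in switch_set if k not in true_switches]
    metrics["switch_fdp"] = len(false_disc) / len(switch_set) if switch_set else 0.0
    metrics["switch_pairs"] = len(switch_set)

    # --- subtype association on recovered switches --------------------------
    switch_rows = fits[fits["is_switch"]].reset_index(drop=True)
    assoc = subtype_mod.subtype_tests_all(switch_rows, normed, catalog, annot)
    n_correct = n_const = n_rec = 0
    for _, row in switch_rows.iterrows():
        key = _key((row["predominant_id"], row["alternative_id"]))
        if key not in sub_truth:
            continue
        n_rec += 1
        sub = assoc[
            (assoc["predominant_id"] == row["predominant_id"])
            & (assoc["alternative_id"] == row["alternative_id"])
        ]
        target = sub[sub["contrast"] == sub_truth[key]["subtype"]]
        if target["associated"].any():
            n_correct += 1
        if not target["gene_level_different"].any():
            n_const += 1
    metrics["subtype_correct_fraction"] = n_correct / n_rec if n_rec else float("nan")
    metrics["gene_level_constant_fraction"] = n_const / n_rec if n_rec else float("nan")

    # --- bimodal screen: planted pairs and a null panel ----------------------
    n_pass = 0
    for pair in sorted(truth.bimodal_pairs):
        verdict = bimodal_mod.kmeans_bimodal_screen(logged, pair, seed=kmeans_seed)
        n_pass += bool(verdict.passes)
    metrics["bimodal_sensitivity"] = (
        n_pass / len(truth.bimodal_pairs) if truth.bimodal_pairs else float("nan")
    )
    planted_genes = {
        catalog.gene_of(iso)
        for group in (truth.rin_artifact_pairs, truth.subtype_switch_pairs, truth.bimodal_pairs)
        for pair in group
        for iso in pair
    }
    null_pairs = [
        (p, a)
        for g, p, a in pairs
        if g not in planted_genes
    ][:n_null_bimodal]
    null_pass = sum(
        bimodal_mod.kmeans_bimodal_screen(logged, pair, seed=kmeans_seed).passes
        for pair in null_pairs
    )
    metrics["bimodal_null_pass_fraction"] = (
        null_pass / len(null_pairs) if null_pairs else float("nan")
    )
    metrics["n_null_bimodal_pairs"] = len(null_pairs)

    # --- SAM signature -------------------------------------------------------
    driver = truth.driver_pair()
    if driver is not None and truth.signature_genes:
        gene_log2 = norm.gene_abundance(normed, catalog)
        response = sam_mod.signature_response(normed, driver)
        result = sam_mod.sam_quantitative(
            gene_log2,
            response,
            n_permutations=sam_permutations,
            seed=sam_seed,
            fdr_threshold=0.05,
        )
        selected = set(result.table.index[result.table["selected"]])
        signature = set(truth.signature_genes)
        tp = len(selected & signature)
        metrics["sam_selected_genes"] = len(selected)
        metrics["sam_sensitivity"] = tp / len(signature)
        metrics["sam_empirical_fdr"] = (
            (len(selected) - tp) / len(selected) if selected else 0.0
        )
    return metrics


def label_permutation_association_rate(
    config: SimConfig | None = None,
    n_pairs: int = 100,
    n_permutations: int = 50,
    contrast: str = "LumA",
    alpha: float = 0.05,
    seed: int = 23,
) -> float:
    """Fraction of (pair, permutation) tests called subtype-associated after
    shuffling subtype labels — the pipeline's false-association rate, which
    should sit near ``alpha`` on a cohort without planted effects."""
    from scipy import stats as sps

    config = config or SimConfig(
        n_rin_artifacts=0, n_subtype_switches=0, n_bimodal_switches=0, n_signature_genes=0
    )
    matrix, catalog, annot, _ = simulate_cohort(config)
    normed = norm.upper_quartile_normalize(matrix)
    det = norm.detect_isoforms(normed, catalog)
    pred = switching.predominant_map(normed, det, catalog)
    pairs = switching.enumerate_pairs(det, pred, catalog)[:n_pairs]
    ratios = np.vstack(
        [subtype_mod.ratio_profile(normed, (p, a)).to_numpy() for _, p, a in pairs]
    )
    tumors = (annot.frame["tissue"] == "tumor") & (annot.frame["subtype"] != "NA")
    labels = (annot.frame["subtype"] == contrast)[tumors].to_numpy()
    R = ratios[:, tumors.to_numpy()]
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        _, p = sps.ttest_ind(R[:, perm], R[:, ~perm], axis=1, equal_var=False)
        hits += int((p < alpha).sum())
        total += len(p)
    return hits / total
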