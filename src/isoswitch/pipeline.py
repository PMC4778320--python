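"""End-to-end orchestration: normalize -> detect -> predominant -> first-pass
-> RIN screen -> RIN-adjusted model -> subtype -> non-subtype/bimodal -> SAM.

Every stage writes a plain TSV/JSON artifact; the run manifest records the
configuration snapshot, per-stage counts, and a sha256 digest of every
output, so identical configs and seeds yield bit-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import bimodal as bimodal_mod
from . import normalize as norm
from . import sam as sam_mod
from . import subtype as subtype_mod
from . import switching
from .io import (
    IsoswitchError,
    read_annotation,
    read_catalog,
    read_isoform_matrix,
    validate_inputs,
)
from .simulate import config_from_dict, simulate_cohort, write_cohort

log = logging.getLogger("isoswitch")

DEFAULTS = {
    "seed": 17,
    "normalize": {"target": 1000.0, "offset": 1.0},
    "detect": {"min_count": 3.0, "min_fraction": 0.60},
    "first_pass": {"alpha": 0.05},
    "rin_screen": {"linkage": "average", "alpha_iso": 0.05, "correct": True, "center": "mean"},
    "switch": {"alpha_pred": 0.05, "alpha_rin": 0.2},
    "subtype": {"alpha": 0.05},
    "bimodal": {"min_cluster": 50},
    "sam": {"pair": "auto", "fdr_threshold": 0.05, "n_permutations": 200},
}


def _merged(config: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_all(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest (also written as JSON).

    ``config`` is a mapping (or YAML path) with either a ``simulate`` block
    (SimConfig fields) or an ``inputs`` block naming ``matrix``, ``catalog``
    and ``annotation`` paths, plus optional per-stage parameter blocks.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    counts: dict[str, int | float] = {}

    # --- inputs -----------------------------------------------------------
    if "simulate" in cfg:
        sim_cfg = config_from_dict({"seed": cfg["seed"], **cfg["simulate"]})
        log.info("simulating cohort: %d samples, %d genes", sim_cfg.n_samples, sim_cfg.n_genes)
        matrix, catalog, annot, truth = simulate_cohort(sim_cfg)
        outputs.update(write_cohort(matrix, catalog, annot, truth, out / "cohort"))
    elif "inputs" in cfg:
        inputs = cfg["inputs"]
        for fieldname in ("matrix", "catalog", "annotation"):
            if fieldname not in inputs:
                raise IsoswitchError(f"config inputs block is missing {fieldname!r}")
        matrix = read_isoform_matrix(inputs["matrix"], format=inputs.get("matrix_format", "tsv"))
        catalog = read_catalog(inputs["catalog"], format=inputs.get("catalog_format", "tsv"))
        annot = read_annotation(inputs["annotation"])
    else:
        raise IsoswitchError("config needs a 'simulate' or an 'inputs' block")

    report = validate_inputs(matrix, catalog, annot)
    if report.blocking:
        raise IsoswitchError(
            "blocking validation failure: "
            f"isoforms without catalog entry {report.missing_isoforms[:3]}, "
            f"samples without annotation {report.missing_samples[:3]}"
        )
    counts["n_samples"] = matrix.n_samples
    counts["n_isoforms"] = len(matrix.isoform_ids)

    # --- normalization & detection ---------------------------------------
    target = cfg["normalize"]["target"]
    offset = cfg["normalize"]["offset"]
    normed = norm.upper_quartile_normalize(matrix, target=target)
    logged = norm.log2_transform(normed, offset=offset)
    det = norm.detect_isoforms(normed, catalog, **cfg["detect"])
    summary = norm.complexity_summary(det)
    counts["detected_isoforms"] = len(det.detected_isoforms)
    counts["detected_genes"] = int((det.per_gene_isoform_count > 0).sum())
    counts["mean_isoforms_per_gene"] = summary.mean_isoforms_per_gene or 0.0
    log.info(
        "detected %d isoforms in %d genes (%.2f per gene)",
        counts["detected_isoforms"],
        counts["detected_genes"],
        counts["mean_isoforms_per_gene"],
    )
    det_path = out / "detection.tsv"
    pd.DataFrame(
        {
            "detection_fraction": det.per_isoform_detection_fraction,
            "detected": det.per_isoform_detection_fraction.index.isin(
                det.detected_isoforms
            ),
        }
    ).to_csv(det_path, sep="\t", index_label="isoform_id")
    outputs["detection"] = det_path

    # --- switching --------------------------------------------------------
    pred = switching.predominant_map(normed, det, catalog)
    pairs = switching.enumerate_pairs(det, pred, catalog)
    counts["candidate_pairs"] = len(pairs)
    candidates = switching.first_pass_screen(logged, pairs, **cfg["first_pass"])
    counts["first_pass_pairs"] = int(candidates["passed_first_pass"].sum())
    cand_path = out / "candidates.tsv"
    candidates.to_csv(cand_path, sep="\t", index=False)
    outputs["candidates"] = cand_path

    screen = switching.rin_artifact_screen(
        logged, candidates, annot, catalog, **cfg["rin_screen"]
    )
    counts["rin_artifact_pairs"] = len(screen.artifact_pairs)
    counts["shorter_isoform_high"] = screen.shorter_isoform_high_count
    screen_path = out / "rin_screen.tsv"
    pd.DataFrame(
        {
            "direction": screen.per_isoform_direction,
        }
    ).to_csv(screen_path, sep="\t", index_label="isoform_id")
    outputs["rin_screen"] = screen_path
    log.info(
        "RIN screen: %d artifact pairs (%d shorter-isoform-high), cluster p=%.3g",
        counts["rin_artifact_pairs"],
        counts["shorter_isoform_high"],
        screen.rin_cluster_p,
    )

    fits = switching.rin_adjusted_switch_test(logged, candidates, annot, **cfg["switch"])
    counts["switch_pairs"] = int(fits["is_switch"].sum())
    counts["switch_genes"] = int(fits.loc[fits["is_switch"], "gene_id"].nunique())
    fits_path = out / "switches.tsv"
    fits.to_csv(fits_path, sep="\t", index=False)
    outputs["switches"] = fits_path

    # --- subtype association ---------------------------------------------
    switch_rows = fits[fits["is_switch"]].reset_index(drop=True)
    assoc = subtype_mod.subtype_tests_all(
        switch_rows, normed, catalog, annot, offset=offset, **cfg["subtype"]
    )
    assoc_path = out / "subtype_associations.tsv"
    assoc.to_csv(assoc_path, sep="\t", index=False)
    outputs["subtype_associations"] = assoc_path
    summary_tbl = subtype_mod.subtype_summary(assoc)
    summary_path = out / "subtype_summary.tsv"
    summary_tbl.to_csv(summary_path, sep="\t", index=False)
    outputs["subtype_summary"] = summary_path
    one_vs_rest = assoc[assoc["contrast"].isin(subtype_mod.ONE_VS_REST) & assoc["associated"]]
    counts["subtype_associated_pairs"] = int(
        one_vs_rest[["predominant_id", "alternative_id"]].drop_duplicates().shape[0]
    )

    # --- non-subtype bimodal screen --------------------------------------
    nonsub = bimodal_mod.nonsubtype_set(fits, assoc)
    counts["nonsubtype_pairs"] = len(nonsub)
    verdicts = [
        bimodal_mod.kmeans_bimodal_screen(
            logged,
            (row["predominant_id"], row["alternative_id"]),
            seed=cfg["seed"],
            min_count=cfg["detect"]["min_count"],
            offset=offset,
            annot=annot,
            **cfg["bimodal"],
        )
        for _, row in nonsub.iterrows()
    ]
    vtable = bimodal_mod.verdicts_frame(verdicts)
    counts["bimodal_passes"] = int(vtable["passes"].sum()) if len(vtable) else 0
    bim_path = out / "bimodal_verdicts.tsv"
    vtable.to_csv(bim_path, sep="\t", index=False)
    outputs["bimodal_verdicts"] = bim_path
    log.info(
        "%d non-subtype pairs, %d pass the bimodal screen",
        counts["nonsubtype_pairs"],
        counts["bimodal_passes"],
    )

    # --- SAM signature ----------------------------------------------------
    sam_cfg = cfg["sam"]
    sam_pair = None
    if sam_cfg["pair"] == "auto":
        passing = vtable[vtable["passes"]] if len(vtable) else vtable
        if len(passing):
            first = passing.iloc[0]
            sam_pair = (first["predominant_id"], first["alternative_id"])
    elif sam_cfg["pair"]:
        sam_pair = tuple(sam_cfg["pair"].split(":"))
    counts["sam_selected_genes"] = 0
    if sam_pair is not None:
        gene_log2 = norm.gene_abundance(normed, catalog, offset=offset)
        response = sam_mod.signature_response(normed, sam_pair, offset=offset)
        result = sam_mod.sam_quantitative(
            gene_log2,
            response,
            n_permutations=sam_cfg["n_permutations"],
            seed=cfg["seed"],
            fdr_threshold=sam_cfg["fdr_threshold"],
        )
        counts["sam_selected_genes"] = int(result.table["selected"].sum())
        sam_path = out / "sam_results.tsv"
        result.table.to_csv(sam_path, sep="\t")
        outputs["sam_results"] = sam_path
        selected = result.table.index[result.table["selected"]]
        if len(selected) >= 4:
            clusters = sam_mod.signature_clusters(gene_log2.loc[selected], k=4)
            clus_path = out / "signature_clusters.tsv"
            clusters.rename("cluster").to_csv(clus_path, sep="\t", index_label="gene_id")
            outputs["signature_clusters"] = clus_path

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": cfg,
        "seed": cfg["seed"],
        "counts": counts,
        "outputs": {k: {"path": str(p), "sha256": _digest(Path(p))} for k, p in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest
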