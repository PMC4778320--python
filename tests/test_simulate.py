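import json

import numpy as np
import pandas as pd
import pytest

from isoswitch.io import IsoswitchError, read_annotation, read_catalog, read_isoform_matrix
from isoswitch.simulate import (
    SimConfig,
    TruthRegistry,
    config_from_dict,
    simulate_cohort,
    write_cohort,
)

SMALL = dict(
    n_samples=80,
    n_genes=120,
    n_rin_artifacts=5,
    n_subtype_switches=5,
    n_bimodal_switches=2,
    n_signature_genes=20,
)


class TestDeterminism:
    def test_same_seed_identical_output(self):
        a = simulate_cohort(SimConfig(**SMALL, seed=3))
        b = simulate_cohort(SimConfig(**SMALL, seed=3))
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[2].frame, b[2].frame)
        assert a[3].signature_genes == b[3].signature_genes

    def test_different_seed_differs(self):
        a = simulate_cohort(SimConfig(**SMALL, seed=3))
        b = simulate_cohort(SimConfig(**SMALL, seed=4))
        assert not a[0].values.equals(b[0].values)


class TestPlantedStructure:
    def test_degradation_off_breaks_ratio_rin_link(self):
        cfg = SimConfig(
            n_samples=500, n_genes=150, n_rin_artifacts=10, n_subtype_switches=0,
            n_bimodal_switches=0, n_signature_genes=0, degradation_effect=0.0, seed=5,
        )
        matrix, catalog, annot, truth = simulate_cohort(cfg)
        rin = annot.frame["rin"].to_numpy()
        log2 = np.log2(matrix.values + 1)
        rs = []
        for pred, alt in sorted(truth.rin_artifact_pairs):
            ratio = log2.loc[alt] - log2.loc[pred]
            rs.append(np.corrcoef(ratio, rin)[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_degradation_on_inflates_short_member_at_low_rin(self):
        matrix, catalog, annot, truth = simulate_cohort(SimConfig(**SMALL, seed=6))
        rin = annot.frame["rin"].to_numpy()
        log2 = np.log2(matrix.values + 1)
        for pred, alt in sorted(truth.rin_artifact_pairs):
            short = min((pred, alt), key=catalog.length_of)
            lon = alt if short == pred else pred
            ratio = log2.loc[short] - log2.loc[lon]
            assert np.corrcoef(ratio, rin)[0, 1] < -0.5

    def test_switch_delta_recovered_in_group_difference(self):
        diffs = []
        for seed in range(8):
            cfg = SimConfig(
                n_samples=300, n_genes=150, n_rin_artifacts=0, n_subtype_switches=6,
                n_bimodal_switches=0, n_signature_genes=0, switch_effect_delta=3.0,
                normal_fraction=0.0,
                subtype_proportions={"Basal": 0.5, "LumA": 0.5, "Her2": 0, "LumB": 0,
                                     "NormalLike": 0},
                seed=seed,
            )
            matrix, catalog, annot, truth = simulate_cohort(cfg)
            log2 = np.log2(matrix.values + 1)
            sub = annot.frame["subtype"]
            for (pred, alt), info in truth.subtype_switch_pairs.items():
                if info["subtype"] not in ("Basal", "LumA"):
                    continue
                ratio = log2.loc[alt] - log2.loc[pred]
                ingrp = sub == info["subtype"]
                diffs.append(ratio[ingrp].mean() - ratio[~ingrp].mean())
        assert np.mean(diffs) == pytest.approx(3.0, abs=0.2)

    def test_gene_total_conserved_for_switch_genes(self):
        from scipy.stats import ks_2samp

        cfg = SimConfig(
            n_samples=300, n_genes=200, n_rin_artifacts=0, n_subtype_switches=8,
            n_bimodal_switches=0, n_signature_genes=0, seed=7,
        )
        matrix, catalog, annot, truth = simulate_cohort(cfg)
        sub = annot.frame["subtype"]
        for (pred, alt), info in truth.subtype_switch_pairs.items():
            total = matrix.values.loc[pred] + matrix.values.loc[alt]
            total = np.log2(total)
            ingrp = (sub == info["subtype"]).to_numpy()
            if ingrp.sum() < 5:
                continue
            assert ks_2samp(total[ingrp], total[~ingrp]).pvalue > 0.01

    def test_minority_of_null_pairs_negatively_correlated(self, small_pipeline):
        from isoswitch.normalize import correlation_summary, pairwise_isoform_correlations

        normed, logged, det, catalog, annot, truth = small_pipeline
        pairs = pairwise_isoform_correlations(logged, det, catalog)
        planted = {g for p in truth.rin_artifact_pairs for g in p}
        pairs = pairs[~pairs["isoform_a"].isin(planted)]
        assert correlation_summary(pairs)["fraction_negative"] < 0.25

    def test_bimodal_assignment_registered_per_sample(self):
        matrix, catalog, annot, truth = simulate_cohort(SimConfig(**SMALL, seed=8))
        for pair, info in truth.bimodal_pairs.items():
            z = pd.Series(info["assignment"])
            assert set(z.index) == set(matrix.sample_ids)
            assert 0.1 < z.mean() < 0.7


class TestWriteCohort:
    def test_round_trip_and_truth_counts(self, tmp_path):
        out = simulate_cohort(SimConfig(**SMALL, seed=9))
        paths = write_cohort(*out, tmp_path)
        matrix = read_isoform_matrix(paths["matrix"])
        catalog = read_catalog(paths["catalog"])
        annot = read_annotation(paths["annotation"])
        pd.testing.assert_frame_equal(matrix.values, out[0].values)
        pd.testing.assert_frame_equal(catalog.frame, out[1].frame)
        pd.testing.assert_frame_equal(annot.frame, out[2].frame)
        truth = TruthRegistry.from_json(paths["truth"])
        assert len(truth.rin_artifact_pairs) == SMALL["n_rin_artifacts"]
        assert len(truth.subtype_switch_pairs) == SMALL["n_subtype_switches"]
        assert len(truth.signature_genes) == SMALL["n_signature_genes"]

    def test_empty_cohort_has_empty_truth(self, tmp_path):
        cfg = SimConfig(
            n_samples=20, n_genes=30, n_rin_artifacts=0, n_subtype_switches=0,
            n_bimodal_switches=0, n_signature_genes=0, seed=10,
        )
        paths = write_cohort(*simulate_cohort(cfg), tmp_path)
        payload = json.loads(paths["truth"].read_text())
        assert payload["rin_artifact_pairs"] == []
        assert payload["signature_genes"] == {}


class TestConfig:
    def test_unknown_field_rejected_by_name(self):
        with pytest.raises(IsoswitchError, match="not_a_field"):
            config_from_dict({"not_a_field": 1})

    def test_signature_without_bimodal_rejected(self):
        with pytest.raises(IsoswitchError, match="n_signature_genes"):
            SimConfig(n_bimodal_switches=0, n_signature_genes=10).validate()

    def test_event_overflow_rejected(self):
        with pytest.raises(IsoswitchError, match="n_genes"):
            SimConfig(n_genes=50, n_subtype_switches=60).validate()

    def test_bad_proportions_rejected(self):
        with pytest.raises(IsoswitchError, match="subtype_proportions"):
            SimConfig(subtype_proportions={"Basal": 0.5}).validate()
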