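import numpy as np
import pandas as pd
import pytest

from isoswitch.io import IsoformCatalog, IsoformMatrix, IsoswitchError
from isoswitch.normalize import (
    complexity_summary,
    correlation_summary,
    detect_isoforms,
    gene_abundance,
    log2_transform,
    pairwise_isoform_correlations,
    select_top_variable,
    upper_quartile_normalize,
)


def matrix_from(rows: dict, scale="raw", **kw) -> IsoformMatrix:
    frame = pd.DataFrame(rows).T
    frame.columns = [f"s{i + 1}" for i in range(frame.shape[1])]
    return IsoformMatrix(values=frame.astype(float), scale=scale, **kw)


def catalog_for(mapping: dict) -> IsoformCatalog:
    return IsoformCatalog(
        pd.DataFrame(
            {"gene_id": list(mapping.values()), "length": 100}, index=list(mapping.keys())
        )
    )


class TestUpperQuartile:
    def test_sample_already_at_target_unchanged(self):
        # positive values [4, 8, 12]: h = (3-1)*0.75+1 = 2.5 => 8 + 0.5*4 = 10
        m = matrix_from({"a": [0], "b": [0], "c": [4], "d": [8], "e": [12]})
        out = upper_quartile_normalize(m, target=10.0)
        np.testing.assert_allclose(out.values["s1"], [0, 0, 4, 8, 12])

    def test_hand_computed_quantile_scaling(self):
        # positive values [1,2,3,4]: h = 3.25 => UQ = 3 + 0.25*(4-3) = 3.25
        m = matrix_from({"a": [1], "b": [2], "c": [3], "d": [4]})
        out = upper_quartile_normalize(m, target=1000.0)
        np.testing.assert_allclose(out.values.loc["a", "s1"], 1000.0 / 3.25)
        assert out.values.loc["a", "s1"] == pytest.approx(307.6923076923077)

    def test_all_zero_sample_error_names_sample(self):
        m = matrix_from({"a": [0.0, 1.0], "b": [0.0, 2.0]})
        with pytest.raises(IsoswitchError, match="s1"):
            upper_quartile_normalize(m)

    def test_uq_of_positive_values_hits_target(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.gamma(1.0, 50, size=(30, 5))
            vals[rng.random(vals.shape) < 0.3] = 0.0
            m = IsoformMatrix(
                pd.DataFrame(vals, index=[f"i{k}" for k in range(30)],
                             columns=[f"s{k}" for k in range(5)])
            )
            out = upper_quartile_normalize(m, target=1000.0)
            for s in out.sample_ids:
                col = out.values[s].to_numpy()
                uq = np.quantile(col[col > 0], 0.75)
                assert abs(uq - 1000.0) <= 1e-9 * 1000.0

    def test_idempotence_and_scale_equivariance(self):
        rng = np.random.default_rng(1)
        vals = rng.gamma(2.0, 30, size=(40, 6))
        m = IsoformMatrix(
            pd.DataFrame(vals, index=[f"i{k}" for k in range(40)],
                         columns=[f"s{k}" for k in range(6)])
        )
        once = upper_quartile_normalize(m, target=500.0)
        twice = upper_quartile_normalize(
            IsoformMatrix(once.values, scale="raw"), target=500.0
        )
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)
        # multiplying one sample by c > 0 leaves its normalized values unchanged
        scaled = m.values.copy()
        scaled["s2"] *= 37.5
        out = upper_quartile_normalize(IsoformMatrix(scaled), target=500.0)
        np.testing.assert_allclose(out.values["s2"], once.values["s2"], rtol=1e-12)


class TestLog2:
    @pytest.mark.parametrize("value,expected", [(0, 0), (3, 2), (7, 3)])
    def test_known_values_offset_one(self, value, expected):
        m = matrix_from({"a": [value]}, scale="uq_normalized")
        assert log2_transform(m, offset=1.0).values.iloc[0, 0] == expected

    def test_nonpositive_offset_rejected(self):
        m = matrix_from({"a": [1]}, scale="uq_normalized")
        with pytest.raises(IsoswitchError):
            log2_transform(m, offset=0.0)


class TestDetection:
    def _matrix(self, counts_ge3: int, n: int = 10):
        vals = [5.0] * counts_ge3 + [1.0] * (n - counts_ge3)
        return matrix_from({"iA": vals}, scale="uq_normalized")

    def test_exact_boundary_not_detected(self):
        det = detect_isoforms(self._matrix(6), catalog_for({"iA": "g1"}))
        assert "iA" not in det.detected_isoforms  # 60% is not > 60%

    def test_one_sample_above_boundary_detected(self):
        det = detect_isoforms(self._matrix(7), catalog_for({"iA": "g1"}))
        assert "iA" in det.detected_isoforms

    def test_per_gene_counts_tally_detected_only(self):
        m = matrix_from(
            {"iA": [5] * 10, "iB": [5] * 10, "iC": [1] * 10}, scale="uq_normalized"
        )
        det = detect_isoforms(m, catalog_for({"iA": "g1", "iB": "g1", "iC": "g1"}))
        assert det.per_gene_isoform_count["g1"] == 2

    def test_detection_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        m = IsoformMatrix(
            pd.DataFrame(rng.gamma(1.5, 4, size=(50, 20)),
                         index=[f"i{k}" for k in range(50)],
                         columns=[f"s{k}" for k in range(20)]),
            scale="uq_normalized",
        )
        cat = catalog_for({f"i{k}": f"g{k}" for k in range(50)})
        base = detect_isoforms(m, cat, min_count=3, min_fraction=0.6).detected_isoforms
        assert detect_isoforms(m, cat, min_count=4, min_fraction=0.6).detected_isoforms <= base
        assert detect_isoforms(m, cat, min_count=3, min_fraction=0.7).detected_isoforms <= base


class TestComplexity:
    def test_histogram_and_mean(self):
        m = matrix_from(
            {"a1": [9] * 5, "b1": [9] * 5, "c1": [9] * 5, "c2": [9] * 5},
            scale="uq_normalized",
        )
        det = detect_isoforms(m, catalog_for({"a1": "g1", "b1": "g2", "c1": "g3", "c2": "g3"}))
        summary = complexity_summary(det)
        assert summary.histogram == {1: 2, 2: 1}
        assert summary.mean_isoforms_per_gene == pytest.approx(4 / 3)

    def test_empty_detection(self):
        m = matrix_from({"a1": [0.0] * 5}, scale="uq_normalized")
        det = detect_isoforms(m, catalog_for({"a1": "g1"}))
        summary = complexity_summary(det)
        assert summary.histogram == {} and summary.mean_isoforms_per_gene is None

    def test_cohort_matches_generator_proportions(self, small_pipeline):
        _, _, det, catalog, _, truth = small_pipeline
        summary = complexity_summary(det)
        total = sum(summary.histogram.values())
        # planted events force some 1- and 2-isoform genes; allow generous
        # binomial-scale slack around the configured 0.43/0.24/0.33 mix
        assert abs(summary.histogram[1] / total - 0.43) < 0.12
        assert abs(summary.histogram[2] / total - 0.24) < 0.12


class TestPairCorrelations:
    def _run(self, rows, mapping):
        m = matrix_from(rows, scale="log2")
        det = detect_isoforms(
            matrix_from({k: [5.0] * len(v) for k, v in rows.items()}, scale="uq_normalized"),
            catalog_for(mapping),
        )
        return pairwise_isoform_correlations(m, det, catalog_for(mapping))

    def test_perfectly_correlated_and_anticorrelated(self):
        out = self._run(
            {"iA": [1, 2, 3], "iB": [2, 4, 6], "iC": [3, 2, 1]},
            {"iA": "g1", "iB": "g1", "iC": "g1"},
        )
        r = out.set_index(["isoform_a", "isoform_b"])["pearson_r"]
        assert r[("iA", "iB")] == pytest.approx(1.0)
        assert r[("iA", "iC")] == pytest.approx(-1.0)

    def test_zero_variance_flagged_undefined(self):
        out = self._run({"iA": [1, 2, 3], "iB": [5, 5, 5]}, {"iA": "g1", "iB": "g1"})
        row = out.iloc[0]
        assert not row["defined"] and np.isnan(row["pearson_r"])
        assert correlation_summary(out)["n_pairs"] == 0

    def test_agrees_with_brute_force_covariance(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=20), rng.normal(size=20)
        out = self._run({"iA": x, "iB": y}, {"iA": "g1", "iB": "g1"})
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert out.iloc[0]["pearson_r"] == pytest.approx(num / den, abs=1e-12)


class TestTopVariable:
    def test_ranking_ties_and_truncation(self):
        m = matrix_from(
            {"iB": [0, 1, 2], "iA": [0, 2, 4], "iC": [0, 3, 6], "iD": [4, 5, 6]},
            scale="log2",
        )
        assert select_top_variable(m, 2) == ["iC", "iA"]
        # iB and iD have equal variance 1.0: lexicographically smaller first
        assert select_top_variable(m, 4)[2:] == ["iB", "iD"]
        with pytest.warns(UserWarning, match="returning all"):
            assert len(select_top_variable(m, 10)) == 4


class TestGeneAbundance:
    def test_sum_of_isoforms_then_log2(self):
        m = matrix_from({"iA": [3.0], "iB": [4.0]}, scale="uq_normalized")
        out = gene_abundance(m, catalog_for({"iA": "g1", "iB": "g1"}), offset=1.0)
        assert out.loc["g1", "s1"] == pytest.approx(3.0)  # log2(3+4+1)
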