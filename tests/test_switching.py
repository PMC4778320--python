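import numpy as np
import pandas as pd
import pytest

from isoswitch.io import IsoformCatalog, IsoformMatrix, SampleAnnotation
from isoswitch.normalize import detect_isoforms, log2_transform, upper_quartile_normalize
from isoswitch.stats import ols
from isoswitch.switching import (
    enumerate_pairs,
    first_pass_screen,
    predominant_isoform,
    predominant_map,
    rin_adjusted_switch_test,
    rin_artifact_screen,
)


def matrix_from(rows: dict, scale) -> IsoformMatrix:
    frame = pd.DataFrame(rows).T.astype(float)
    frame.columns = [f"s{i + 1}" for i in range(frame.shape[1])]
    return IsoformMatrix(values=frame, scale=scale)


def catalog_for(mapping, lengths=None):
    lengths = lengths or {k: 100 for k in mapping}
    return IsoformCatalog(
        pd.DataFrame(
            {"gene_id": [mapping[k] for k in mapping], "length": [lengths[k] for k in mapping]},
            index=list(mapping),
        )
    )


def annotation_for(n, rin=None, subtype="LumA"):
    rin = rin if rin is not None else np.full(n, 8.0)
    return SampleAnnotation(
        pd.DataFrame(
            {"tissue": ["tumor"] * n, "subtype": [subtype] * n, "rin": rin},
            index=[f"s{i + 1}" for i in range(n)],
        )
    )


class TestPredominant:
    def test_greatest_upper_quartile_wins(self):
        # iA UQ: h = 3.25 over [10,10,10,100] => 10 + 0.25*90 = 32.5 > 20
        m = matrix_from({"iA": [10, 10, 10, 100], "iB": [20, 20, 20, 20]}, "uq_normalized")
        det = detect_isoforms(m, catalog_for({"iA": "g1", "iB": "g1"}))
        assert predominant_isoform(m, det, catalog_for({"iA": "g1", "iB": "g1"}), "g1") == "iA"

    def test_single_detected_isoform(self):
        m = matrix_from({"iA": [5, 5, 5, 5]}, "uq_normalized")
        cat = catalog_for({"iA": "g1"})
        det = detect_isoforms(m, cat)
        assert predominant_isoform(m, det, cat, "g1") == "iA"

    def test_identical_vectors_tie_breaks_lexicographically(self):
        m = matrix_from({"iB": [5, 5, 5, 5], "iA": [5, 5, 5, 5]}, "uq_normalized")
        cat = catalog_for({"iB": "g1", "iA": "g1"})
        det = detect_isoforms(m, cat)
        assert predominant_isoform(m, det, cat, "g1") == "iA"


class TestEnumerate:
    def test_pairs_per_gene(self):
        m = matrix_from(
            {"iA": [9] * 5, "iB": [5] * 5, "iC": [4] * 5, "jA": [9] * 5}, "uq_normalized"
        )
        cat = catalog_for({"iA": "g1", "iB": "g1", "iC": "g1", "jA": "g2"})
        det = detect_isoforms(m, cat)
        pred = predominant_map(m, det, cat)
        pairs = enumerate_pairs(det, pred, cat)
        assert [(p, a) for _, p, a in pairs] == [("iA", "iB"), ("iA", "iC")]


class TestFirstPass:
    def test_perfect_negative_fit_passes(self):
        m = matrix_from({"iA": [1, 2, 3, 4], "iB": [8, 6, 4, 2]}, "log2")
        out = first_pass_screen(m, [("g1", "iA", "iB")])
        row = out.iloc[0]
        assert row["first_pass_slope"] == pytest.approx(-2.0)
        assert row["passed_first_pass"]

    def test_positive_slope_fails(self):
        m = matrix_from({"iA": [1, 2, 3, 4], "iB": [2, 4, 6, 8]}, "log2")
        assert not first_pass_screen(m, [("g1", "iA", "iB")]).iloc[0]["passed_first_pass"]

    def test_constant_predictor_untestable(self):
        m = matrix_from({"iA": [3, 3, 3, 3], "iB": [2, 4, 6, 8]}, "log2")
        row = first_pass_screen(m, [("g1", "iA", "iB")]).iloc[0]
        assert row["untestable"] and not row["passed_first_pass"]


class TestOlsOracle:
    def test_against_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        for _ in range(5):
            X = rng.normal(size=(30, 2))
            y = X @ [1.5, -0.7] + rng.normal(size=30)
            mine = ols(X, y)
            ref = sm.OLS(y, sm.add_constant(X)).fit()
            np.testing.assert_allclose(mine.beta, ref.params, atol=1e-10)
            np.testing.assert_allclose(mine.p, ref.pvalues, atol=1e-10)


class TestRinAdjusted:
    def _fit_one(self, y, x, rin):
        m = matrix_from({"iA": x, "iB": y}, "log2")
        cand = pd.DataFrame(
            [{"gene_id": "g1", "predominant_id": "iA", "alternative_id": "iB"}]
        )
        ann = annotation_for(len(x), rin=rin)
        return rin_adjusted_switch_test(m, cand, ann).iloc[0]

    def test_negative_dependence_with_rin_orthogonal_is_switch(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(5, 1, n)
        rin = rng.uniform(6, 10, n)
        eps = rng.normal(0, 0.1, n)
        # project noise out of span{1, rin, x}: the fitted RIN coefficient is
        # then exactly 0, a deterministic version of "RIN-independent switch"
        D = np.column_stack([np.ones(n), rin, x])
        eps -= D @ np.linalg.lstsq(D, eps, rcond=None)[0]
        y = 10 - x + eps
        row = self._fit_one(y, x, rin)
        assert row["beta_pred"] == pytest.approx(-1.0)
        assert row["p_rin"] == pytest.approx(1.0)
        assert row["p_pred"] < 1e-10 and row["is_switch"]

    def test_rin_driven_expression_fails_criterion(self):
        rng = np.random.default_rng(1)
        n = 60
        x = rng.normal(5, 1, n)
        rin = rng.uniform(6, 10, n)
        y = rin + rng.normal(0, 0.05, n) - 0.2 * x
        row = self._fit_one(y, x, rin)
        assert row["p_rin"] < 0.2 and not row["is_switch"]

    def test_positive_slope_fails_sign_rule(self):
        rng = np.random.default_rng(2)
        n = 40
        x = rng.normal(5, 1, n)
        rin = rng.uniform(6, 10, n)
        y = x + rng.normal(0, 0.1, n)
        row = self._fit_one(y, x, rin)
        assert row["beta_pred"] > 0 and not row["is_switch"]

    def test_collinear_predictors_untestable(self):
        n = 20
        rin = np.linspace(6, 10, n)
        row = self._fit_one(rin * 2 + 1, rin.copy(), rin)
        assert row["untestable"]


class TestRinScreen:
    def test_separable_two_cluster_case(self):
        # 3+3 samples; pair rows flip between the clusters; low-RIN cluster
        # has the short isoform high -> both pairs are artifacts
        rows = {
            "iS1": [8, 8, 8, 2, 2, 2],
            "iL1": [2, 2, 2, 8, 8, 8],
            "iS2": [7, 7, 7, 1, 1, 1],
            "iL2": [1, 1, 1, 7, 7, 7],
        }
        m = matrix_from(rows, "log2")
        cand = pd.DataFrame(
            [
                {"gene_id": "g1", "predominant_id": "iL1", "alternative_id": "iS1",
                 "first_pass_slope": -1.0, "first_pass_p": 0.001, "passed_first_pass": True,
                 "untestable": False},
                {"gene_id": "g2", "predominant_id": "iL2", "alternative_id": "iS2",
                 "first_pass_slope": -1.0, "first_pass_p": 0.001, "passed_first_pass": True,
                 "untestable": False},
            ]
        )
        ann = annotation_for(6, rin=np.array([4.0, 4.2, 4.1, 9.0, 9.2, 9.1]))
        cat = catalog_for(
            {"iS1": "g1", "iL1": "g1", "iS2": "g2", "iL2": "g2"},
            lengths={"iS1": 500, "iL1": 5000, "iS2": 600, "iL2": 4000},
        )
        res = rin_artifact_screen(m, cand, ann, cat)
        assert not res.aborted
        assert res.artifact_pairs == {("iL1", "iS1"), ("iL2", "iS2")}
        assert res.shorter_isoform_high_count == 2
        assert res.rin_cluster_p < 0.01

    def test_too_few_pairs_aborts_cleanly(self):
        m = matrix_from({"iA": [1, 2, 3, 4], "iB": [4, 3, 2, 1]}, "log2")
        cand = pd.DataFrame(
            [{"gene_id": "g1", "predominant_id": "iA", "alternative_id": "iB",
              "first_pass_slope": -1.0, "first_pass_p": 0.001, "passed_first_pass": True,
              "untestable": False}]
        )
        res = rin_artifact_screen(
            m, cand, annotation_for(4), catalog_for({"iA": "g1", "iB": "g1"})
        )
        assert res.aborted and res.artifact_pairs == set()


class TestSampleOrderInvariance:
    def test_verdicts_stable_under_joint_permutation(self, small_pipeline):
        normed, logged, det, catalog, annot, _ = small_pipeline
        pred = predominant_map(normed, det, catalog)
        pairs = enumerate_pairs(det, pred, catalog)[:40]
        fits = rin_adjusted_switch_test(logged, first_pass_screen(logged, pairs), annot)

        rng = np.random.default_rng(4)
        order = rng.permutation(logged.sample_ids)
        logged_p = IsoformMatrix(logged.values[order], scale="log2")
        annot_p = SampleAnnotation(annot.frame.loc[order])
        fits_p = rin_adjusted_switch_test(logged_p, first_pass_screen(logged_p, pairs), annot_p)
        pd.testing.assert_series_equal(fits["is_switch"], fits_p["is_switch"])
        np.testing.assert_allclose(fits["beta_pred"], fits_p["beta_pred"], rtol=1e-9)
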