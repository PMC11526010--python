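"""Rank-based AUROC/AUPRC, ROC curves, and disorder-stratified comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vepmeta import metrics as met
from vepmeta.errors import ConfigurationError, UndefinedMetricError
from vepmeta.synthetic import ResidueAnnotation
from vepmeta.variant_io import GeneDataset


def pairwise_auroc(p, b):
    """Independent oracle: exhaustive pairwise comparison with half-ties."""
    wins = sum((pi > bi) + 0.5 * (pi == bi) for pi in p for bi in b)
    return wins / (len(p) * len(b))


class TestAuroc:
    @pytest.mark.parametrize(
        "p,b,expected",
        [
            ([0.9, 0.8], [0.1, 0.2], 1.0),      # perfect separation
            ([0.1, 0.2], [0.9, 0.8], 0.0),      # classes swapped
            ([0.8, 0.5], [0.5, 0.2], 0.875),    # one tied pair counts half
        ],
    )
    def test_examples(self, p, b, expected):
        assert met.auroc(p, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            p = rng.integers(0, 8, rng.integers(1, 30)).astype(float)
            b = rng.integers(0, 8, rng.integers(1, 30)).astype(float)
            assert abs(met.auroc(p, b) - pairwise_auroc(p, b)) < 1e-12

    def test_empty_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            met.auroc([], [0.1])
        with pytest.raises(UndefinedMetricError):
            met.auroc([0.1], [])

    finite = st.floats(-100, 100, allow_nan=False)

    @given(
        p=st.lists(finite, min_size=1, max_size=20),
        b=st.lists(finite, min_size=1, max_size=20),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_label_swap_complement(self, p, b):
        assert met.auroc(p, b) + met.auroc(b, p) == pytest.approx(1.0, abs=1e-12)

    # integer-valued scores keep the transform exactly monotone in floats
    # while still exercising tie handling
    int_scores = st.lists(st.integers(-50, 50).map(float), min_size=1, max_size=20)

    @given(p=int_scores, b=int_scores)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, p, b):
        base = met.auroc(p, b)
        f = lambda x: np.exp(0.05 * np.asarray(x)) * 3 + 1  # strictly increasing
        assert met.auroc(f(p), f(b)) == pytest.approx(base, abs=1e-12)


class TestAuprc:
    def test_single_pathogenic_on_top(self):
        assert met.auprc([0.9], [0.5, 0.4, 0.1]) == 1.0

    def test_interleaved_example(self):
        # ranking: 0.9 (benign), 0.7 (pathogenic), 0.5 (benign)
        assert met.auprc([0.7], [0.9, 0.5]) == pytest.approx(0.5)

    def test_null_equals_pathogenic_fraction(self):
        rng = np.random.default_rng(1)
        n = 10_000
        frac = 0.2
        p = rng.random(int(n * frac))
        b = rng.random(n - int(n * frac))
        assert met.auprc(p, b) == pytest.approx(frac, abs=0.02)

    def test_tie_block_order_independent(self):
        assert met.auprc([0.5, 0.7], [0.5, 0.2]) == met.auprc([0.7, 0.5], [0.2, 0.5])


class TestThresholdCurves:
    def test_point_count_distinct_scores(self):
        c = met.threshold_curves([0.9, 0.7], [0.5, 0.2])
        assert len(c.thresholds) == 5  # 4 distinct scores + sentinel

    def test_constant_scores_degenerate(self):
        c = met.threshold_curves([1.0, 1.0], [1.0])
        assert len(c.thresholds) == 2
        np.testing.assert_allclose(c.tpr, c.fpr)
        assert c.area() == pytest.approx(0.5)

    def test_area_equals_auroc(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p = rng.integers(0, 6, rng.integers(2, 25)).astype(float)
            b = rng.integers(0, 6, rng.integers(2, 25)).astype(float)
            c = met.threshold_curves(p, b)
            assert abs(c.area() - met.auroc(p, b)) < 1e-12

    def test_rates_monotone_and_tnr_complement(self):
        c = met.threshold_curves([3.0, 2.0, 1.0], [2.5, 0.5])
        assert (np.diff(c.tpr) >= 0).all()  # thresholds descend, rates rise
        assert (np.diff(c.fpr) >= 0).all()
        np.testing.assert_allclose(c.tnr, 1 - c.fpr)


def _toy_dataset(variants, orientation):
    genes = sorted(variants["gene_id"].unique())
    return GeneDataset(variants=variants, genes=genes,
                       veps=sorted(orientation), orientation=orientation)


def _variant(gene, res, alt, label):
    return {
        "gene_id": gene, "residue_index": res, "ref_aa": "A", "alt_aa": alt,
        "consequence": "missense", "class_label": label,
    }


def _ann(gene, plddt):
    plddt = np.asarray(plddt, float)
    L = len(plddt)
    coords = np.column_stack([np.arange(L) * 3.8, np.zeros(L), np.zeros(L)])
    return ResidueAnnotation(gene, "A" * L, plddt, coords, np.full(L, 0.5))


class TestPerGenePerformance:
    def test_full_grid_has_all_rows(self):
        variants = pd.DataFrame(
            [_variant(g, r, "V", "pathogenic") for g in ("G1", "G2") for r in (1, 2)]
            + [_variant(g, r, "V", "benign") for g in ("G1", "G2") for r in (3, 4)]
        )
        scores = pd.concat([
            pd.DataFrame({
                "gene_id": variants["gene_id"], "residue_index": variants["residue_index"],
                "alt_aa": "V", "vep": vep,
                "score": np.where(variants["class_label"] == "pathogenic", 0.9, 0.1),
            })
            for vep in ("V1", "V2")
        ])
        ds = _toy_dataset(variants, {"V1": True, "V2": True})
        ann = {g: _ann(g, [90] * 5) for g in ("G1", "G2")}
        perf = met.per_gene_performance(ds, scores, ann)
        assert len(perf) == 4
        assert (perf["auroc"] == 1.0).all()

    def test_orientation_invariance(self):
        variants = pd.DataFrame(
            [_variant("G1", r, "V", "pathogenic") for r in (1, 2)]
            + [_variant("G1", r, "V", "benign") for r in (3, 4)]
        )
        base = pd.DataFrame({
            "gene_id": "G1", "residue_index": [1, 2, 3, 4], "alt_aa": "V",
            "vep": "Vp", "score": [0.9, 0.6, 0.7, 0.1],
        })
        flipped = base.assign(vep="Vn", score=-base["score"])
        scores = pd.concat([base, flipped])
        ds = _toy_dataset(variants, {"Vp": True, "Vn": False})
        perf = met.per_gene_performance(ds, scores, {"G1": _ann("G1", [90] * 5)})
        by_vep = perf.set_index("vep")["auroc"]
        assert by_vep["Vp"] == by_vep["Vn"]

    def test_disorder_excluded_auroc_fixture(self):
        """Benign variants hiding in disordered residues inflate AUROC: 0.625 -> 0.25."""
        variants = pd.DataFrame(
            [_variant("G1", 1, "V", "pathogenic"), _variant("G1", 2, "V", "pathogenic"),
             _variant("G1", 3, "V", "benign"), _variant("G1", 4, "V", "benign"),
             _variant("G1", 5, "V", "benign"), _variant("G1", 6, "V", "benign")]
        )
        scores = pd.DataFrame({
            "gene_id": "G1", "residue_index": [1, 2, 3, 4, 5, 6], "alt_aa": "V",
            "vep": "V1",
            "score": [0.7, 0.6, 0.65, 0.75, 0.1, 0.2],
        })
        # residues 5, 6 are disordered and carry the low-scoring benign variants
        ann = {"G1": _ann("G1", [90, 90, 90, 90, 30, 30])}
        ds = _toy_dataset(variants, {"V1": True})
        perf = met.per_gene_performance(ds, scores, ann).iloc[0]
        assert perf["auroc"] == pytest.approx(0.625)
        assert perf["auroc_no_disorder"] == pytest.approx(0.25)
        assert perf["n_excluded_disordered"] == 2

    def test_missing_orientation_is_configuration_error(self):
        variants = pd.DataFrame([_variant("G1", 1, "V", "pathogenic"),
                                 _variant("G1", 2, "V", "benign")])
        ds = _toy_dataset(variants, {"V1": True})
        ds.veps = ["V1", "V2"]
        with pytest.raises(ConfigurationError):
            met.per_gene_performance(ds, pd.DataFrame(columns=[
                "gene_id", "residue_index", "alt_aa", "vep", "score"]), {})

    def test_undefined_metric_is_nan_not_zero(self):
        variants = pd.DataFrame([_variant("G1", 1, "V", "pathogenic"),
                                 _variant("G1", 2, "V", "benign")])
        scores = pd.DataFrame({  # only the pathogenic variant is scored
            "gene_id": ["G1"], "residue_index": [1], "alt_aa": ["V"],
            "vep": ["V1"], "score": [0.9],
        })
        ds = _toy_dataset(variants, {"V1": True})
        perf = met.per_gene_performance(ds, scores, {})
        assert np.isnan(perf["auroc"]).all()


class TestDisorderSplit:
    def _perf(self, aurocs):
        return pd.DataFrame({
            "gene_id": list(aurocs), "vep": "V1",
            "auroc": list(aurocs.values()),
        })

    def test_two_genes_split_at_median(self):
        ann = {"G1": _ann("G1", [90] * 9 + [30]), "G2": _ann("G2", [90] * 8 + [30, 30])}
        perf = self._perf({"G1": 0.7, "G2": 0.9})
        comp, split = met.disorder_group_comparison(perf, ann)
        assert split.median_disorder_pct == pytest.approx(15.0)
        assert split.groups["G1"] == "Low" and split.groups["G2"] == "High"
        assert comp.loc["V1", "mean_difference"] == pytest.approx(0.2)

    def test_equal_disorder_all_low(self):
        ann = {g: _ann(g, [90] * 8 + [30, 30]) for g in ("G1", "G2", "G3")}
        perf = self._perf({"G1": 0.7, "G2": 0.8, "G3": 0.9})
        comp, split = met.disorder_group_comparison(perf, ann)
        assert (split.groups == "Low").all()


class TestCorrelationMatrix:
    def _perf_from_vectors(self, vectors):
        rows = []
        for vep, vals in vectors.items():
            for i, v in enumerate(vals):
                rows.append({"gene_id": f"G{i}", "vep": vep, "auroc": v})
        return pd.DataFrame(rows)

    def test_diagonal_and_symmetry(self):
        perf = self._perf_from_vectors({"A": [0.6, 0.7, 0.8], "B": [0.5, 0.9, 0.7]})
        corr = met.auroc_correlation_matrix(perf)
        assert corr.loc["A", "A"] == 1.0
        assert corr.loc["A", "B"] == corr.loc["B", "A"]

    def test_hand_computed_pearson(self):
        perf = self._perf_from_vectors({"A": [0.6, 0.7, 0.8], "B": [0.5, 0.9, 0.7]})
        assert met.auroc_correlation_matrix(perf).loc["A", "B"] == pytest.approx(0.5)

    def test_reversed_linear_ranking(self):
        perf = self._perf_from_vectors({"A": [0.6, 0.7, 0.8], "B": [0.8, 0.7, 0.6]})
        assert met.auroc_correlation_matrix(perf).loc["A", "B"] == pytest.approx(-1.0)

    def test_zero_variance_flagged_as_nan(self):
        perf = self._perf_from_vectors({"A": [0.6, 0.7, 0.8], "B": [0.7, 0.7, 0.7]})
        corr = met.auroc_correlation_matrix(perf)
        assert np.isnan(corr.loc["A", "B"])
        assert corr.loc["B", "B"] == 1.0
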