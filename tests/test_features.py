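"""Gene-level feature kernels, GO over-representation, and table assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from vepmeta import features as feat
from vepmeta.errors import SchemaError


class TestAggregationKernels:
    def test_ddg_fold_mean(self):
        assert feat.ddg_fold([1.0, 2.0, 3.0]) == pytest.approx(2.0)
        assert feat.ddg_fold([0.0]) == 0.0

    def test_ddg_fold_skips_missing_and_empty_is_nan(self):
        assert feat.ddg_fold([1.0, np.nan, 3.0]) == pytest.approx(2.0)
        assert np.isnan(feat.ddg_fold([np.nan]))
        assert np.isnan(feat.ddg_fold([]))

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=50)
        assert feat.ddg_fold(vals) == pytest.approx(sum(vals) / 50)

    def test_vep_gnomad_mean_shares_kernel(self):
        vals = [-5.0, -3.0]
        assert feat.vep_gnomad_mean(vals) == pytest.approx(-4.0)
        assert feat.vep_gnomad_mean(vals) == feat.ddg_fold(vals)


class TestGnomadDistance:
    def _chain(self, n):
        return np.column_stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)])

    def test_every_residue_with_variant_is_zero(self):
        coords = self._chain(5)
        assert feat.gnomad_distance(coords, [1, 2, 3, 4, 5]) == 0.0

    def test_collinear_hand_computation(self):
        # residues at 0, 3.8, 7.6 Å; variant at residue 1 -> mean (0+3.8+7.6)/3
        coords = self._chain(3)
        assert feat.gnomad_distance(coords, [1]) == pytest.approx(3.8)

    def test_adding_variant_never_increases(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            coords = rng.normal(scale=10, size=(n, 3))
            residues = list(rng.choice(n, size=rng.integers(1, n), replace=False) + 1)
            before = feat.gnomad_distance(coords, residues)
            extra = int(rng.integers(1, n + 1))
            after = feat.gnomad_distance(coords, residues + [extra])
            assert after <= before + 1e-12

    def test_no_variants_undefined(self):
        assert np.isnan(feat.gnomad_distance(self._chain(3), []))


class TestEfxRaw:
    def test_hand_ratios(self):
        vep = np.array([[-6.0, -3.0, -1.0]])
        ddg = np.array([[2.0, 1.0, 0.5]])
        assert feat.efx_raw(vep, ddg) == pytest.approx(-3.0)

    def test_guard_excludes_near_zero_ddg(self):
        vep = np.array([[1.0, 2.0]])
        ddg = np.array([[1e-9, 1e-8]])
        assert np.isnan(feat.efx_raw(vep, ddg))

    def test_homogeneity_in_ddg(self):
        rng = np.random.default_rng(2)
        vep = rng.normal(size=(10, 19))
        ddg = rng.gamma(2.0, 1.0, size=(10, 19))
        assert feat.efx_raw(vep, 2 * ddg) == pytest.approx(feat.efx_raw(vep, ddg) / 2)

    def test_shape_mismatch_is_schema_error(self):
        with pytest.raises(SchemaError):
            feat.efx_raw(np.zeros((3, 19)), np.zeros((4, 19)))


class TestLofAndPlddt:
    def test_n_lof_normalised_by_length(self):
        n_lof, oe = feat.lof_features([10, 20, 30, 40, 50], expected_lof=16.0, length=500)
        assert n_lof == pytest.approx(0.01)
        assert oe == pytest.approx(5 / 16)

    def test_observed_over_expected(self):
        _, oe = feat.lof_features(range(8), expected_lof=16.0, length=100)
        assert oe == pytest.approx(0.5)

    def test_duplicate_nonsense_counted_once(self):
        a = feat.lof_features([5, 5, 9], expected_lof=2.0, length=100)
        b = feat.lof_features([5, 9], expected_lof=2.0, length=100)
        assert a == b

    def test_nonpositive_expected_undefined(self):
        _, oe = feat.lof_features([1], expected_lof=0.0, length=10)
        assert np.isnan(oe)

    @pytest.mark.parametrize(
        "plddt,expected",
        [([90.0] * 4, (0.0, 90.0)), ([40.0, 60.0], (50.0, 50.0))],
    )
    def test_plddt_features_examples(self, plddt, expected):
        assert feat.plddt_features(plddt) == pytest.approx(expected)

    def test_plddt_permutation_invariant_and_oracle(self):
        rng = np.random.default_rng(3)
        plddt = rng.uniform(0, 100, 1000)
        pct, mean = feat.plddt_features(plddt)
        assert pct == pytest.approx(100 * sum(1 for x in plddt if x < 50) / 1000)
        assert mean == pytest.approx(sum(plddt) / 1000)
        assert feat.plddt_features(rng.permutation(plddt)) == pytest.approx((pct, mean))


def fisher_two_sided_oracle(a, b, c, d):
    """Hypergeometric enumeration of the two-sided Fisher exact p-value."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = {k: hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    cutoff = pmf[a] * (1 + 1e-7)  # relative guard against float ties
    return sum(p for p in pmf.values() if p <= cutoff)


def bh_step_up_oracle(pvals):
    """Hand Benjamini-Hochberg: p_(i)·m/i with a right-to-left running minimum."""
    m = len(pvals)
    order = np.argsort(pvals)
    raw = [pvals[j] * m / (i + 1) for i, j in enumerate(order)]
    adj = np.minimum.accumulate(raw[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestGoSelection:
    def _run(self, mean_auroc, go):
        return feat.go_feature_selection(mean_auroc, go)

    def test_balanced_term_not_selected(self):
        genes = [f"G{i}" for i in range(20)]
        mean_auroc = pd.Series(np.linspace(0.5, 0.9, 20), index=genes)
        # the term annotates half of each group
        members = genes[:5] + genes[10:15]
        go = pd.DataFrame({"gene_id": members, "go_term": "GO:X"})
        results, binary = self._run(mean_auroc, go)
        assert results[0].p_value == pytest.approx(1.0)
        assert not results[0].selected
        assert binary.empty or "GO_GO:X" not in binary.columns

    def test_three_zero_zero_three_table(self):
        genes = [f"G{i}" for i in range(6)]
        mean_auroc = pd.Series([0.9, 0.9, 0.9, 0.5, 0.5, 0.5], index=genes)
        go = pd.DataFrame({"gene_id": genes[:3], "go_term": "GO:Y"})
        results, _ = self._run(mean_auroc, go)
        r = results[0]
        assert (r.a, r.b, r.c, r.d) == (3, 0, 0, 3)
        assert r.p_value == pytest.approx(0.1)  # 2 * 1/20 by enumeration

    def test_enriched_term_selected_and_binary_emitted(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(60)]
        mean_auroc = pd.Series(np.linspace(0.5, 0.95, 60), index=genes)
        members = genes[35:] + list(rng.choice(genes[:30], 3, replace=False))
        go = pd.DataFrame({"gene_id": members, "go_term": "GO:Z"})
        results, binary = self._run(mean_auroc, go)
        assert results[0].selected
        assert set(binary["GO_GO:Z"].unique()) <= {0, 1}
        assert binary["GO_GO:Z"].sum() == len(set(members))

    def test_ties_at_median_go_to_worse_group(self):
        genes = ["G1", "G2", "G3", "G4"]
        mean_auroc = pd.Series([0.6, 0.7, 0.7, 0.9], index=genes)
        go = pd.DataFrame({"gene_id": ["G4"], "go_term": "GO:T"})
        results, _ = self._run(mean_auroc, go)
        # median 0.7; only G4 is strictly above -> better group of size 1
        assert results[0].a + results[0].b == 1

    def test_fisher_matches_enumeration_on_small_margins(self):
        rng = np.random.default_rng(5)
        from scipy.stats import fisher_exact

        for _ in range(100):
            a, b, c, d = rng.integers(0, 7, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-9)

    def test_bh_adjustment_matches_hand_step_up(self):
        from statsmodels.stats.multitest import multipletests

        for pvals in ([0.01, 0.02, 0.03], [0.005, 0.04, 0.04, 0.2], [0.5, 0.01]):
            _, adj, _, _ = multipletests(pvals, method="fdr_bh")
            np.testing.assert_allclose(adj, bh_step_up_oracle(pvals), rtol=1e-12)
        np.testing.assert_allclose(bh_step_up_oracle([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])


class TestAssembleFeatureTable:
    def test_no_missing_equals_concatenation(self):
        idx = pd.Index(["G1", "G2"], name="gene_id")
        a = pd.Series([1.0, 2.0], index=idx, name="fa")
        b = pd.DataFrame({"fb": [3.0, 4.0]}, index=idx)
        table, mask = feat.assemble_feature_table({"a": a, "b": b})
        assert list(table.columns) == ["fa", "fb"]
        assert not mask.any().any()

    def test_median_imputation_with_mask(self):
        idx = pd.Index(["G1", "G2", "G3", "G4"], name="gene_id")
        col = pd.Series([1.0, 2.0, 3.0, np.nan], index=idx, name="f")
        table, mask = feat.assemble_feature_table({"c": col})
        assert table.loc["G4", "f"] == pytest.approx(2.0)
        assert mask["f"].tolist() == [False, False, False, True]

    def test_binary_columns_never_imputed(self):
        idx = pd.Index(["G1", "G2", "G3"], name="gene_id")
        go = pd.Series([1.0, np.nan, 0.0], index=idx, name="GO_X")
        table, mask = feat.assemble_feature_table({"go": go})
        assert table["GO_X"].tolist() == [1, 0, 0]
        assert not mask["GO_X"].any()

    def test_duplicate_feature_names_rejected(self):
        idx = pd.Index(["G1"], name="gene_id")
        a = pd.Series([1.0], index=idx, name="f")
        with pytest.raises(SchemaError):
            feat.assemble_feature_table({"a": a, "b": a})


def test_all_named_features_present_for_every_gene(small_dataset):
    table = small_dataset.features
    for name in feat.NAMED_FEATURES:
        assert name in table.columns
        assert table[name].notna().all(), name
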