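"""Neighborhood profiles, specificity scaling, correlation maps, aggregation
and pseudotime smoothing."""

import numpy as np
import pandas as pd
import pytest

from nhoodcomp import (
    CrossSpeciesCorrelation,
    NeighborhoodProfileMatrix,
    SmoothingConfig,
    SpecificityMatrix,
    aggregate_by_cell_type,
    bidirectional_mapping,
    cross_correlation,
    gene_specificity,
    max_correlation,
    neighborhood_means,
    smooth_ordered_expression,
)
from nhoodcomp.neighborhoods import NeighborhoodSet


def profile(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    idx = [f"n{i}" for i in range(values.shape[0])]
    return NeighborhoodProfileMatrix(values, idx, genes)


def spec_matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    idx = [f"n{i}" for i in range(values.shape[0])]
    return SpecificityMatrix(values, idx, genes)


class TestNeighborhoodMeans:
    def test_singleton_and_two_cell_arithmetic(self, tiny_dataset):
        nh = NeighborhoodSet(["c0", "c1"], [{"c0"}, {"c1", "c2"}], np.array([0, 1]))
        prof = neighborhood_means(tiny_dataset, nh, ["g1", "g3"])
        layer = np.asarray(tiny_dataset.log_layer.todense())
        np.testing.assert_allclose(prof.values[0], layer[0, [0, 2]], atol=1e-12)
        np.testing.assert_allclose(prof.values[1], layer[1:3, [0, 2]].mean(axis=0), atol=1e-12)

    def test_unknown_cell_id_rejected(self, tiny_dataset):
        nh = NeighborhoodSet(["c0"], [{"c0", "nope"}], np.array([0]))
        with pytest.raises(ValueError, match="unknown cell"):
            neighborhood_means(tiny_dataset, nh, ["g1"])

    def test_matches_loop_oracle(self, sim_small):
        _, (ds_a, _, _, _) = sim_small
        rng = np.random.default_rng(0)
        cells = ds_a.cell_ids
        members = [set(rng.choice(cells, size=12, replace=False)) | {cells[i]} for i in range(8)]
        nh = NeighborhoodSet([cells[i] for i in range(8)], members, np.arange(8))
        feats = ds_a.gene_ids[:30]
        prof = neighborhood_means(ds_a, nh, feats)
        layer = np.asarray(ds_a.log_layer.todense())
        row = {c: i for i, c in enumerate(cells)}
        col = {g: j for j, g in enumerate(ds_a.gene_ids)}
        for i, mem in enumerate(members):
            for j, g in enumerate(feats):
                expected = np.mean([layer[row[c], col[g]] for c in mem])
                assert abs(prof.values[i, j] - expected) < 1e-12


class TestGeneSpecificity:
    def test_constant_gene_gives_unit_specificity(self):
        spec = gene_specificity(profile(np.full((4, 2), 3.0)))
        np.testing.assert_allclose(spec.values, 1.0, atol=1e-12)

    def test_forced_arithmetic(self):
        spec = gene_specificity(profile(np.array([[2.0], [0.0], [0.0], [0.0]])))
        np.testing.assert_allclose(spec.values.ravel(), [4.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_zero_mean_gene_dropped_and_listed(self):
        spec = gene_specificity(profile(np.array([[1.0, 0.0], [3.0, 0.0]]), ["ga", "gz"]))
        assert spec.dropped_genes == ["gz"]
        assert spec.gene_ids == ["ga"]

    def test_row_mean_normalization_invariant(self):
        rng = np.random.default_rng(1)
        spec = gene_specificity(profile(rng.gamma(2.0, 1.0, size=(20, 30))))
        np.testing.assert_allclose(spec.values.mean(axis=0), 1.0, atol=1e-10)

    def test_scale_invariance(self):
        """Multiplying a gene's profile by a positive constant leaves its
        specificity unchanged — the formula's whole purpose."""
        rng = np.random.default_rng(2)
        base = rng.gamma(2.0, 1.0, size=(15, 10))
        scales = rng.uniform(0.1, 50.0, size=10)
        s1 = gene_specificity(profile(base))
        s2 = gene_specificity(profile(base * scales))
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-10)


class TestCrossCorrelation:
    def test_identical_rows_correlate_to_one(self):
        rng = np.random.default_rng(3)
        row = rng.random(10)
        corr = cross_correlation(spec_matrix(row[None, :].repeat(2, 0)), spec_matrix(row[None, :]))
        np.testing.assert_allclose(corr.values, 1.0, atol=1e-12)

    def test_constant_row_masked_nan(self):
        a = spec_matrix(np.vstack([np.ones(5), np.arange(5.0)]))
        b = spec_matrix(np.arange(5.0)[None, :])
        corr = cross_correlation(a, b)
        assert np.isnan(corr.values[0, 0]) and corr.nan_mask[0, 0]
        assert abs(corr.values[1, 0] - 1.0) < 1e-12

    def test_matches_two_pass_pearson_oracle(self):
        rng = np.random.default_rng(4)
        A, B = rng.random((3, 5)), rng.random((2, 5))
        corr = cross_correlation(spec_matrix(A), spec_matrix(B))
        for i in range(3):
            for j in range(2):
                x, y = A[i], B[j]
                xm, ym = x - x.mean(), y - y.mean()
                expected = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
                assert abs(corr.values[i, j] - expected) < 1e-12

    def test_symmetry_under_transpose(self):
        rng = np.random.default_rng(5)
        A, B = rng.random((6, 8)), rng.random((4, 8))
        ab = cross_correlation(spec_matrix(A), spec_matrix(B))
        ba = cross_correlation(spec_matrix(B), spec_matrix(A))
        np.testing.assert_allclose(ab.values, ba.values.T, atol=1e-12)

    def test_gene_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different gene counts"):
            cross_correlation(spec_matrix(np.ones((2, 4))), spec_matrix(np.ones((2, 3))))


class TestMaxCorrelation:
    def make(self, values):
        values = np.asarray(values, dtype=float)
        return CrossSpeciesCorrelation(
            values,
            [f"a{i}" for i in range(values.shape[0])],
            [f"b{j}" for j in range(values.shape[1])],
        )

    def test_tie_breaks_to_first_partner(self):
        mm = max_correlation(self.make([[0.2, 0.9, 0.9]]), "a_to_b")
        rec = mm.table.iloc[0]
        assert rec["max_corr"] == 0.9 and rec["partner"] == "b1"

    def test_all_nan_row_flagged_missing(self):
        mm = max_correlation(self.make([[np.nan, np.nan], [0.1, 0.4]]), "a_to_b")
        assert not mm.table.iloc[0]["defined"] and mm.table.iloc[0]["partner"] is None
        assert mm.table.iloc[1]["partner"] == "b1"

    def test_matches_exhaustive_scan_both_directions(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(-1, 1, size=(20, 30))
        corr = self.make(values)
        for direction, mat in (("a_to_b", values), ("b_to_a", values.T)):
            mm = max_correlation(corr, direction)
            for i, row in enumerate(mat):
                rec = mm.table.iloc[i]
                assert rec["max_corr"] == row.max()
                assert rec["partner"].endswith(str(int(np.argmax(row))))


class TestAggregation:
    def test_single_type_collects_all(self):
        mm = max_correlation(
            CrossSpeciesCorrelation(np.array([[0.5], [0.7]]), ["a0", "a1"], ["b0"]), "a_to_b"
        )
        out = aggregate_by_cell_type(mm, {"a0": "t", "a1": "t"})
        assert len(out) == 1 and out.iloc[0]["n"] == 2

    def test_ordering_by_decreasing_mean(self):
        mm = max_correlation(
            CrossSpeciesCorrelation(np.array([[0.5], [0.9]]), ["a0", "a1"], ["b0"]), "a_to_b"
        )
        out = aggregate_by_cell_type(mm, {"a0": "low", "a1": "high"})
        assert out["cell_type"].tolist() == ["high", "low"]

    def test_unlabeled_index_cell_rejected(self):
        mm = max_correlation(CrossSpeciesCorrelation(np.array([[0.5]]), ["a0"], ["b0"]), "a_to_b")
        with pytest.raises(ValueError, match="unlabeled"):
            aggregate_by_cell_type(mm, {"a0": ""})

    def test_group_memberships_match_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 1, size=(30, 10))
        corr = CrossSpeciesCorrelation(values, [f"a{i}" for i in range(30)], [f"b{j}" for j in range(10)])
        labels = {f"a{i}": f"t{i % 4}" for i in range(30)}
        out = aggregate_by_cell_type(max_correlation(corr, "a_to_b"), labels)
        maxima = values.max(axis=1)
        for rec in out.itertuples(index=False):
            expected = sorted(maxima[i] for i in range(30) if labels[f"a{i}"] == rec.cell_type)
            assert sorted(rec.values) == pytest.approx(expected)
            assert rec.mean_max_corr == pytest.approx(float(np.mean(expected)))


class TestBidirectionalMapping:
    def test_single_entry_appears_in_both_directions(self):
        corr = CrossSpeciesCorrelation(np.array([[0.4]]), ["a0"], ["b0"])
        pairs = bidirectional_mapping(corr)
        assert len(pairs) == 2
        assert set(pairs["direction"]) == {"a_to_b", "b_to_a"}
        assert (pairs["nhood_a"] == "a0").all() and (pairs["nhood_b"] == "b0").all()

    def test_reciprocal_argmax_tagged_twice(self):
        values = np.array([[0.9, 0.1], [0.2, 0.3]])
        pairs = bidirectional_mapping(
            CrossSpeciesCorrelation(values, ["a0", "a1"], ["b0", "b1"])
        )
        both = pairs[(pairs["nhood_a"] == "a0") & (pairs["nhood_b"] == "b0")]
        assert set(both["direction"]) == {"a_to_b", "b_to_a"}

    def test_matches_two_exhaustive_scans(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(-1, 1, size=(10, 10))
        corr = CrossSpeciesCorrelation(values, [f"a{i}" for i in range(10)], [f"b{j}" for j in range(10)])
        pairs = bidirectional_mapping(corr)
        expected = set()
        for i in range(10):
            expected.add((f"a{i}", f"b{int(np.argmax(values[i]))}", "a_to_b"))
        for j in range(10):
            expected.add((f"a{int(np.argmax(values[:, j]))}", f"b{j}", "b_to_a"))
        assert set(zip(pairs["nhood_a"], pairs["nhood_b"], pairs["direction"])) == expected


class TestSmoothing:
    def test_window_one_is_identity_then_minmax(self):
        df = pd.DataFrame({"g": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        out, const = smooth_ordered_expression(df, ["a", "b", "c"], SmoothingConfig(window=1))
        assert const == []
        np.testing.assert_allclose(out["g"].to_numpy(), [0.0, 0.5, 1.0], atol=1e-12)

    def test_constant_series_flagged_all_zero(self):
        df = pd.DataFrame({"g": [2.0] * 5}, index=list("abcde"))
        for scaling in ("minmax", "zscore"):
            out, const = smooth_ordered_expression(df, list("abcde"), SmoothingConfig(window=3, scaling=scaling))
            assert const == ["g"]
            assert (out["g"] == 0).all()

    def test_default_window_is_49(self):
        assert SmoothingConfig().window == 49

    def test_matches_truncated_window_loop_oracle(self):
        rng = np.random.default_rng(9)
        n, w = 100, 49
        df = pd.DataFrame(rng.random((n, 3)), index=[f"c{i}" for i in range(n)], columns=list("xyz"))
        ordering = [f"c{i}" for i in rng.permutation(n)]
        out, _ = smooth_ordered_expression(df, ordering, SmoothingConfig(window=w))
        ordered = df.loc[ordering].to_numpy()
        half = w // 2
        for j in range(3):
            smoothed = np.array([ordered[max(0, i - half) : i + half + 1, j].mean() for i in range(n)])
            expected = (smoothed - smoothed.min()) / (smoothed.max() - smoothed.min())
            np.testing.assert_allclose(out.iloc[:, j].to_numpy(), expected, atol=1e-12)

    def test_zscore_variant(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"g": rng.random(30)}, index=[f"c{i}" for i in range(30)])
        out, _ = smooth_ordered_expression(df, list(df.index), SmoothingConfig(window=5, scaling="zscore"))
        assert abs(out["g"].mean()) < 1e-10
        assert abs(out["g"].std(ddof=0) - 1.0) < 1e-10

    def test_invalid_inputs_rejected(self):
        df = pd.DataFrame({"g": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="permutation"):
            smooth_ordered_expression(df, ["a", "a"], SmoothingConfig(window=1))
        with pytest.raises(ValueError, match="window exceeds"):
            smooth_ordered_expression(df, ["a", "b"], SmoothingConfig(window=3))
        with pytest.raises(ValueError, match="odd"):
            SmoothingConfig(window=4)


def test_permutation_null_degrades_max_correlation(sim_small):
    """Shuffling one species' gene labels destroys the cross-species signal:
    the median max correlation drops strictly below the unshuffled value."""
    rng = np.random.default_rng(11)
    base = rng.gamma(2.0, 1.0, size=(25, 60)) * rng.uniform(0.5, 2.0, size=60)
    noise = base + rng.normal(0, 0.05, size=base.shape).clip(-0.4, 0.4)
    s_a = gene_specificity(profile(np.abs(base)))
    s_b = gene_specificity(profile(np.abs(noise)))
    corr = cross_correlation(s_a, s_b)
    med = np.median(max_correlation(corr, "a_to_b").table["max_corr"])
    shuffled = s_b.values[:, rng.permutation(s_b.values.shape[1])]
    corr_null = cross_correlation(s_a, spec_matrix(shuffled, s_a.gene_ids))
    med_null = np.median(max_correlation(corr_null, "a_to_b").table["max_corr"])
    assert med_null < med
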