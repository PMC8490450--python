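import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepatotype.classify import (
    CentroidSet,
    assign_subtypes,
    cca_centroid,
    classify_blast_like,
    classify_cca_like,
    filter_genes,
    median_center,
    merge_cohorts,
    spearman_to_centroid,
)
from hepatotype.io import ExpressionMatrix


def _expr(values, genes=None, samples=None, centered=False):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), is_centered=centered
    )


class TestFilterGenes:
    def test_constant_gene_ranks_last(self):
        expr = _expr([[5, 5, 5, 5], [2, 9, 3, 8], [4, 6, 2, 9]])
        kept = filter_genes(expr, min_expr=1, min_expr_fraction=0.5, top_n_variable=2)
        assert "g0" not in kept

    def test_zero_fraction_passes_expression_filter(self):
        expr = _expr([[0, 0], [0, 0]])
        kept = filter_genes(expr, min_expr=1, min_expr_fraction=0.0, top_n_variable=2)
        assert set(kept) == {"g0", "g1"}

    def test_top2_by_hand_computed_mad(self):
        # MADs: g0 -> 0.5, g1 -> 2.0, g2 -> 1.0, g3 -> 0.0, g4 -> 3.0
        expr = _expr(
            [
                [5, 5.5, 6, 5.5],
                [2, 6, 8, 4],
                [3, 5, 4, 6],
                [7, 7, 7, 7],
                [1, 9, 4, 12],
            ]
        )
        kept = filter_genes(expr, min_expr=0, min_expr_fraction=0.0, top_n_variable=2)
        assert kept == ["g4", "g1"]

    def test_requesting_too_many_keeps_all(self):
        expr = _expr([[1, 2], [3, 4]])
        kept = filter_genes(expr, min_expr=0, min_expr_fraction=0.0, top_n_variable=99)
        assert len(kept) == 2


class TestMedianCenter:
    def test_simple_row(self):
        out = median_center(_expr([[1, 2, 3]]))
        assert out.values.iloc[0].tolist() == [-1, 0, 1]
        assert out.is_centered

    def test_idempotent(self):
        once = median_center(_expr([[1, 5, 2], [0, 0, 10]]))
        twice = median_center(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_zero_median_row_unchanged(self):
        out = median_center(_expr([[0, 0, 10]]))
        assert out.values.iloc[0].tolist() == [0, 0, 10]


class TestSpearman:
    def test_identical_sample_gives_one(self):
        c = CentroidSet("ref", pd.Series([1.0, 2, 3, 4], index=list("abcd")))
        expr = _expr([[1], [2], [3], [4]], genes=list("abcd"))
        assert spearman_to_centroid(expr, c).iloc[0] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        c = CentroidSet("ref", pd.Series([1.0, 2, 3, 4], index=list("abcd")))
        expr = _expr([[9], [7], [5], [3]], genes=list("abcd"))
        assert spearman_to_centroid(expr, c).iloc[0] == pytest.approx(-1.0)

    def test_closed_form_rho_06(self):
        # ranks (1,2,3,4) vs (2,1,4,3): rho = 1 - 6*4/(4*15) = 0.6
        c = CentroidSet("ref", pd.Series([2.0, 1, 4, 3], index=list("abcd")))
        expr = _expr([[1], [2], [3], [4]], genes=list("abcd"))
        assert spearman_to_centroid(expr, c).iloc[0] == pytest.approx(0.6)

    def test_too_few_shared_genes(self):
        c = CentroidSet("ref", pd.Series([1.0, 2], index=["a", "b"]))
        expr = _expr([[1], [2]], genes=["a", "b"])
        with pytest.raises(ValueError, match="shared"):
            spearman_to_centroid(expr, c)


class TestCcaLikeRule:
    def test_threshold_arithmetic(self):
        rhos = pd.Series(
            {"c1": 0.80, "c2": 0.75, "c3": 0.70, "h1": 0.72, "h2": 0.60}
        )
        labels, threshold = classify_cca_like(rhos, ["c1", "c2", "c3"])
        assert threshold == pytest.approx(0.70)
        assert labels["h1"] == "CCA-Like"
        assert labels["h2"] == "HCC"

    def test_boundary_is_inclusive(self):
        rhos = pd.Series({"c1": 0.8, "c2": 0.75, "c3": 0.7, "h1": 0.70})
        labels, _ = classify_cca_like(rhos, ["c1", "c2", "c3"])
        assert labels["h1"] == "CCA-Like"

    def test_no_cca_like_when_all_below(self):
        rhos = pd.Series({"c1": 0.8, "c2": 0.75, "c3": 0.7, "h1": 0.1, "h2": 0.2})
        labels, _ = classify_cca_like(rhos, ["c1", "c2", "c3"])
        assert (labels[["h1", "h2"]] == "HCC").all()

    def test_brute_force_threshold_matches(self):
        """The threshold equals a one-pass brute-force over the CCA vector."""
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 25)
        rhos = pd.Series(vals, index=[f"c{i}" for i in range(25)])
        _, threshold = classify_cca_like(rhos, list(rhos.index))
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert threshold == pytest.approx(mean - sd, abs=1e-12)


class TestBlastLikeRule:
    def test_top_tertile_of_nine(self):
        rhos = pd.Series({f"t{i}": 0.1 * (i + 1) for i in range(9)})
        labels = pd.Series("HCC", index=rhos.index)
        out, cutoff = classify_blast_like(rhos, labels)
        assert (out == "Blast-Like").sum() == 3
        assert set(out[out == "Blast-Like"].index) == {"t6", "t7", "t8"}
        assert 0.6 < cutoff < 0.7

    def test_all_cca_like_means_no_blast(self):
        rhos = pd.Series({f"t{i}": 0.1 * (i + 1) for i in range(9)})
        labels = pd.Series("CCA-Like", index=rhos.index)
        out, _ = classify_blast_like(rhos, labels)
        assert (out == "Blast-Like").sum() == 0

    def test_tie_at_cutoff_all_included(self):
        rhos = pd.Series([0.1, 0.1, 0.1, 0.9, 0.9, 0.9], index=list("abcdef"))
        labels = pd.Series("HCC", index=rhos.index)
        out, cutoff = classify_blast_like(rhos, labels)
        assert cutoff == pytest.approx(0.9)
        assert (out == "Blast-Like").sum() == 3


class TestMergeCohorts:
    def _cohorts(self):
        a = _expr([[1.0, 3], [4, 6], [2, 2]], samples=["a1", "a2"])
        b = _expr([[5.0, 7], [1, 3], [0, 4]], samples=["b1", "b2"])
        return a, b

    def test_identical_anchors_zero_shift(self):
        a = _expr([[1.0, 3], [4, 6], [2, 2]], samples=["a1", "a2"])
        b = _expr([[1.0, 3], [4, 6], [2, 2]], samples=["b1", "b2"])
        merged = merge_cohorts(a, b, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(merged.values[["a1", "a2"]], a.values)

    def test_shift_arithmetic_and_anchor_median_agreement(self):
        a, b = self._cohorts()
        merged = merge_cohorts(a, b, ["a1", "a2"], ["b1", "b2"])
        # gene g0: anchor medians 2 (a) and 6 (b) -> a shifted by +4
        assert merged.values.loc["g0", "a1"] == pytest.approx(5.0)
        med_a = merged.values[["a1", "a2"]].median(axis=1)
        med_b = merged.values[["b1", "b2"]].median(axis=1)
        assert np.allclose(med_a, med_b, atol=1e-9)

    def test_order_invariance(self):
        a, b = self._cohorts()
        m1 = merge_cohorts(a, b, ["a1", "a2"], ["b1", "b2"])
        a_perm = ExpressionMatrix(a.values[["a2", "a1"]])
        m2 = merge_cohorts(a_perm, b, ["a1", "a2"], ["b1", "b2"])
        pd.testing.assert_frame_equal(
            m1.values.sort_index(axis=1), m2.values.sort_index(axis=1)
        )


class TestAssignSubtypes:
    def test_noise_free_labels_equal_truth(self):
        from hepatotype.simulate import SimulationConfig, simulate_expression

        cfg = SimulationConfig(noise_sd=0.0, seed=5)
        expr, centroids, truth = simulate_expression(cfg, seed=5)
        cca_ids = truth.true_class.index[truth.true_class == "CCA"]
        out = assign_subtypes(
            expr,
            cca_ids,
            {k: centroids[k] for k in ("hepatoblast", "hepatocyte", "cholangiocyte")},
        )
        assert (out["label"] == truth.true_class).all()

    def test_only_cca_samples_all_labeled_cca(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.uniform(2, 8, (50, 6)))
        blast = CentroidSet("hepatoblast", pd.Series(rng.uniform(2, 8, 50), index=expr.gene_ids))
        out = assign_subtypes(expr, expr.sample_ids, {"hepatoblast": blast})
        assert (out["label"] == "CCA").all()

    def test_deterministic(self, default_cohort):
        _, expr, centroids, truth = default_cohort
        cca_ids = truth.true_class.index[truth.true_class == "CCA"]
        refs = {k: centroids[k] for k in ("hepatoblast", "hepatocyte", "cholangiocyte")}
        out1 = assign_subtypes(expr, cca_ids, refs)
        out2 = assign_subtypes(expr, cca_ids, refs)
        pd.testing.assert_frame_equal(out1, out2)

    def test_normals_pass_through(self, default_cohort):
        from hepatotype.simulate import SimulationConfig, simulate_expression

        cfg = SimulationConfig(seed=13)
        cfg.n_per_class = {**cfg.n_per_class, "Normal": 10}
        expr, centroids, truth = simulate_expression(cfg, seed=13)
        cca_ids = truth.true_class.index[truth.true_class == "CCA"]
        normals = truth.true_class.index[truth.true_class == "Normal"]
        out = assign_subtypes(
            expr,
            cca_ids,
            {k: centroids[k] for k in ("hepatoblast", "hepatocyte", "cholangiocyte")},
            normal_sample_ids=normals,
        )
        assert (out.loc[normals, "label"] == "Normal").all()


@settings(max_examples=25, deadline=None)
@given(
    scale=st.floats(min_value=0.1, max_value=10.0),
    shift=st.floats(min_value=-5.0, max_value=5.0),
)
def test_labels_invariant_to_monotone_sample_transform(scale, shift):
    """Spearman-based labels survive strictly monotone per-sample transforms."""
    rng = np.random.default_rng(17)
    values = pd.DataFrame(
        rng.uniform(0, 8, (30, 12)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(12)],
    )
    centroid = CentroidSet("ref", pd.Series(rng.uniform(0, 8, 30), index=values.index))
    base = spearman_to_centroid(
        ExpressionMatrix(values, is_centered=False), centroid
    )
    transformed = spearman_to_centroid(
        ExpressionMatrix(values * scale + shift), centroid
    )
    assert np.allclose(base, transformed, atol=1e-12)
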