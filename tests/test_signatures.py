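import numpy as np
import pandas as pd
import pytest

from hepatotype.io import MOTIF_LABELS, SignatureCatalog, VariantTable
from hepatotype.signatures import (
    MotifMatrix,
    canonical_motif,
    class_motif_profile,
    cosine_similarity,
    count_motifs,
    exposure_by_class,
    extract_signatures,
    match_catalog,
    sample_catalog_similarity,
    variant_group_similarity_test,
)

_COMP = str.maketrans("ACGT", "TGCA")


def brute_force_motif(ref, alt, context):
    """Independent re-derivation of the strand-collapse rule."""
    if ref in "AG":
        context = context.translate(_COMP)[::-1]
        ref = ref.translate(_COMP)
        alt = alt.translate(_COMP)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def _variants(rows):
    return VariantTable.from_frame(
        pd.DataFrame(
            rows,
            columns=["sample_id", "chrom", "pos", "ref", "alt", "gene", "protein_change", "context"],
        )
    )


class TestCanonicalMotif:
    def test_pyrimidine_reference_kept(self):
        assert canonical_motif("C", "T", "ACG") == "A[C>T]G"

    def test_purine_reference_collapsed(self):
        assert canonical_motif("G", "T", "AGC") == "G[C>A]T"

    def test_adenine_reference_collapsed(self):
        assert canonical_motif("A", "T", "TAT") == "A[T>A]A"

    def test_ambiguous_base_raises(self):
        with pytest.raises(ValueError):
            canonical_motif("C", "T", "NCG")

    def test_strand_collapse_involution(self):
        """A record and its reverse-complement representation give one label."""
        rng = np.random.default_rng(0)
        bases = "ACGT"
        for _ in range(200):
            ref = rng.choice(list(bases))
            alt = rng.choice([b for b in bases if b != ref])
            ctx = rng.choice(list(bases)) + ref + rng.choice(list(bases))
            rc_ctx = ctx.translate(_COMP)[::-1]
            assert canonical_motif(ref, alt, ctx) == canonical_motif(
                ref.translate(_COMP), alt.translate(_COMP), rc_ctx
            )

    def test_all_96_labels_reachable_and_canonical(self):
        seen = set()
        for ref in "CT":
            for alt in "ACGT":
                if alt == ref:
                    continue
                for five in "ACGT":
                    for three in "ACGT":
                        seen.add(canonical_motif(ref, alt, five + ref + three))
        assert seen == set(MOTIF_LABELS)


class TestCountMotifs:
    def test_three_identical_records(self):
        var = _variants(
            [["s1", "1", i, "C", "T", None, None, "ACG"] for i in (1, 2, 3)]
        )
        motifs = count_motifs(var)
        assert motifs.counts.loc["s1", "A[C>T]G"] == 3
        assert motifs.counts.loc["s1"].sum() == 3

    def test_zero_snv_sample_retained(self):
        var = _variants(
            [
                ["s1", "1", 1, "C", "T", None, None, "ACG"],
                ["s2", "1", 2, "C", "T", None, None, None],  # no context -> skipped
            ]
        )
        motifs = count_motifs(var)
        assert "s2" in motifs.sample_ids
        assert motifs.counts.loc["s2"].sum() == 0
        assert len(motifs.skipped) == 1

    def test_matches_brute_force_counter_on_random_tables(self):
        rng = np.random.default_rng(21)
        bases = "ACGT"
        for _ in range(100):
            rows = []
            for i in range(rng.integers(1, 60)):
                ref = rng.choice(list(bases))
                alt = rng.choice([b for b in bases if b != ref])
                ctx = rng.choice(list(bases)) + ref + rng.choice(list(bases))
                rows.append(
                    [f"s{rng.integers(3)}", "1", i + 1, ref, alt, None, None, ctx]
                )
            var = _variants(rows)
            motifs = count_motifs(var)
            expected = {}
            for r in rows:
                key = (r[0], brute_force_motif(r[3], r[4], r[7]))
                expected[key] = expected.get(key, 0) + 1
            for (sample, label), n in expected.items():
                assert motifs.counts.loc[sample, label] == n
            assert motifs.counts.to_numpy().sum() == len(rows)


class TestClassProfile:
    def test_single_sample_class_is_its_frequency_vector(self):
        var = _variants([["s1", "1", 1, "C", "T", None, None, "ACG"]])
        motifs = count_motifs(var)
        prof = class_motif_profile(motifs, pd.Series({"s1": "X"}))
        assert prof.loc["X", "A[C>T]G"] == 1.0

    def test_median_of_two_samples(self):
        counts = pd.DataFrame(
            0.0, index=["s1", "s2"], columns=list(MOTIF_LABELS)
        )
        counts.loc["s1", ["A[C>A]A", "A[C>A]C"]] = [20, 80]
        counts.loc["s2", ["A[C>A]A", "A[C>A]C"]] = [40, 60]
        motifs = MotifMatrix(counts=counts)
        prof = class_motif_profile(motifs, pd.Series({"s1": "X", "s2": "X"}))
        assert prof.loc["X", "A[C>A]A"] == pytest.approx(0.3)
        assert prof.loc["X", "A[C>A]C"] == pytest.approx(0.7)


class TestCosine:
    def test_identical_vectors(self):
        v = np.arange(1, 97, dtype=float)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        u = np.r_[np.ones(48), np.zeros(48)]
        v = np.r_[np.zeros(48), np.ones(48)]
        assert cosine_similarity(u, v) == 0.0

    def test_closed_form_example(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(0.7071, abs=1e-4)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


def _rank1_motifs(n_samples=6, total=200, seed=0):
    rng = np.random.default_rng(seed)
    profile = rng.dirichlet(np.ones(96))
    counts = pd.DataFrame(
        np.tile((profile * total), (n_samples, 1)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=list(MOTIF_LABELS),
    )
    return MotifMatrix(counts=counts), profile


class TestExtractSignatures:
    def test_rank_one_recovery(self):
        motifs, profile = _rank1_motifs()
        model = extract_signatures(motifs, k=1, n_restarts=5, seed=1)
        assert cosine_similarity(model.signatures["S1"], profile) >= 0.999

    def test_deterministic_under_seed(self):
        motifs, _ = _rank1_motifs(seed=3)
        m1 = extract_signatures(motifs, k=2, n_restarts=3, seed=9)
        m2 = extract_signatures(motifs, k=2, n_restarts=3, seed=9)
        pd.testing.assert_frame_equal(m1.signatures, m2.signatures)
        pd.testing.assert_frame_equal(m1.exposures, m2.exposures)

    def test_error_trajectory_non_increasing(self):
        motifs, _ = _rank1_motifs(seed=5)
        model = extract_signatures(motifs, k=2, n_restarts=2, seed=2)
        increases = np.diff(model.error_trajectory)
        assert increases.max() <= 1e-10 * model.error_trajectory[0]

    def test_k_exceeding_rank_errors(self):
        motifs, _ = _rank1_motifs(n_samples=4)
        with pytest.raises(ValueError, match="rank"):
            extract_signatures(motifs, k=5, n_restarts=1, seed=0)

    def test_matches_sklearn_reconstruction_quality(self):
        """Independent NMF cross-check: our reconstruction error is no more
        than 10% worse than scikit-learn's on the same matrix and k."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(6)
        W = rng.dirichlet(np.ones(96), size=3).T
        H = rng.gamma(2.0, 1.0, (3, 40))
        V = (W @ H).T
        counts = pd.DataFrame(V, index=[f"s{i}" for i in range(40)], columns=list(MOTIF_LABELS))
        motifs = MotifMatrix(counts=counts)
        model = extract_signatures(motifs, k=3, n_restarts=10, seed=4)
        skl = NMF(n_components=3, init="random", random_state=0, max_iter=2000)
        Wm = skl.fit_transform(motifs.frequencies.to_numpy().T)
        err_skl = np.linalg.norm(motifs.frequencies.to_numpy().T - Wm @ skl.components_)
        assert model.reconstruction_error <= err_skl * 1.1 + 1e-9


class TestCatalogOps:
    def _model_and_catalog(self):
        motifs, _ = _rank1_motifs(seed=7)
        model = extract_signatures(motifs, k=2, n_restarts=3, seed=7)
        return model, SignatureCatalog(weights=model.signatures.copy())

    def test_own_signatures_give_unit_diagonal(self):
        model, catalog = self._model_and_catalog()
        table = match_catalog(model, catalog)
        assert np.allclose(np.diag(table.to_numpy(dtype=float)), 1.0, atol=1e-9)

    def test_label_alignment_not_positional(self):
        model, catalog = self._model_and_catalog()
        permuted = SignatureCatalog(
            weights=catalog.weights.sample(frac=1.0, random_state=0)
        )
        pd.testing.assert_frame_equal(
            match_catalog(model, catalog), match_catalog(model, permuted)
        )


class TestSampleCatalogSimilarity:
    def test_profile_equal_to_catalog_column_scores_one(self):
        catalog = SignatureCatalog(
            weights=pd.DataFrame(
                {"A": np.full(96, 1 / 96)}, index=list(MOTIF_LABELS)
            )
        )
        counts = pd.DataFrame(
            np.full((1, 96), 5.0), index=["s1"], columns=list(MOTIF_LABELS)
        )
        out = sample_catalog_similarity(
            MotifMatrix(counts=counts), catalog, pd.Series({"s1": "X"})
        )
        assert out.loc["X", "A"] == pytest.approx(1.0)

    def test_zero_mutation_sample_excluded(self):
        catalog = SignatureCatalog(
            weights=pd.DataFrame({"A": np.full(96, 1 / 96)}, index=list(MOTIF_LABELS))
        )
        counts = pd.DataFrame(
            [[*np.full(96, 1.0)], [*np.zeros(96)]],
            index=["s1", "s2"],
            columns=list(MOTIF_LABELS),
        )
        out = sample_catalog_similarity(
            MotifMatrix(counts=counts), catalog, pd.Series({"s1": "X", "s2": "X"})
        )
        assert out.loc["X", "A"] == pytest.approx(1.0)  # s2 did not drag the median


class TestExposureByClass:
    def test_normalization_and_brute_force_median(self):
        motifs, _ = _rank1_motifs(n_samples=8, seed=11)
        model = extract_signatures(motifs, k=2, n_restarts=3, seed=11)
        labels = pd.Series(
            ["X"] * 4 + ["Y"] * 4, index=[f"s{i}" for i in range(8)]
        )
        out = exposure_by_class(model, labels)
        expo = model.exposures.T
        norm = expo.div(expo.sum(axis=1), axis=0)
        for cls in ("X", "Y"):
            members = labels.index[labels == cls]
            expected = norm.loc[members].median(axis=0)
            assert np.allclose(out.loc[cls], expected, atol=1e-12)
        assert np.allclose(norm.sum(axis=1), 1.0)


class TestGroupSimilarityTest:
    def test_separated_groups_give_tiny_p(self):
        target = np.zeros(96)
        target[:8] = 1 / 8
        catalog = SignatureCatalog(
            weights=pd.DataFrame({"SBS_target": target}, index=list(MOTIF_LABELS))
        )
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(0.0, index=[f"s{i}" for i in range(20)], columns=list(MOTIF_LABELS))
        for i in range(10):  # group a: concentrated on the target support
            counts.iloc[i, :8] = rng.integers(20, 40, 8)
        for i in range(10, 20):  # group b: orthogonal support
            counts.iloc[i, 50:58] = rng.integers(20, 40, 8)
        motifs = MotifMatrix(counts=counts)
        t, p = variant_group_similarity_test(
            motifs, catalog, "SBS_target",
            [f"s{i}" for i in range(10)], [f"s{i}" for i in range(10, 20)],
        )
        assert p < 1e-6 and t > 0

    def test_single_sample_group_errors(self):
        motifs, _ = _rank1_motifs(n_samples=4)
        catalog = SignatureCatalog(
            weights=pd.DataFrame({"A": np.full(96, 1 / 96)}, index=list(MOTIF_LABELS))
        )
        with pytest.raises(ValueError, match="at least 2"):
            variant_group_similarity_test(motifs, catalog, "A", ["s0"], ["s1", "s2"])
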