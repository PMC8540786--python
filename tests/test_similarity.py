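import numpy as np
import pytest

from ssrpopgen.io import BandMatrix, IndividualMeta, to_band_matrix
from ssrpopgen.similarity import (
    SimilarityMatrix,
    bootstrap_supports,
    group_similarity_summary,
    pcoa,
    similarity_matrix,
    upgma,
)
from ssrpopgen.simulate import SimConfig, simulate

from conftest import make_table


def band_matrix(B, band_locus, typed=None, labels=None):
    B = np.asarray(B, dtype=np.uint8)
    band_locus = np.asarray(band_locus)
    L = band_locus.max() + 1
    return BandMatrix(
        B=B,
        bands=[(f"L{l + 1}", 100 + i) for i, l in enumerate(band_locus)],
        band_locus=band_locus,
        typed=np.ones((B.shape[0], L), bool) if typed is None else np.asarray(typed),
        labels=labels or [f"S{i + 1}" for i in range(B.shape[0])],
        locus_names=[f"L{l + 1}" for l in range(L)],
    )


class TestSimilarityMatrix:
    def test_identical_profiles(self):
        b = band_matrix([[1, 0, 1], [1, 0, 1]], [0, 0, 1])
        for coeff in ("simple_matching", "dice"):
            S = similarity_matrix(b, coeff)
            assert S.S[0, 1] == pytest.approx(1.0)

    def test_hand_counts(self):
        # profiles (1,1,0,0) vs (1,0,1,0): a=1, b=1, c=1, d=1
        b = band_matrix([[1, 1, 0, 0], [1, 0, 1, 0]], [0, 0, 0, 0])
        assert similarity_matrix(b, "simple_matching").S[0, 1] == pytest.approx(0.5)
        assert similarity_matrix(b, "dice").S[0, 1] == pytest.approx(0.5)

    def test_pairwise_deletion_of_missing_locus(self):
        # locus 2 untyped in individual 2: bands of locus 2 must not count
        g = make_table([[[100, 102], [200, 202]], [[100, 102], [0, 0]]])
        S = similarity_matrix(to_band_matrix(g), "simple_matching")
        assert S.S[0, 1] == pytest.approx(1.0)

    def test_no_cotyped_pair_warns_nan(self):
        g = make_table([[[100, 100], [0, 0]], [[0, 0], [200, 200]]])
        with pytest.warns(RuntimeWarning, match="no co-typed"):
            S = similarity_matrix(to_band_matrix(g), "simple_matching")
        assert np.isnan(S.S[0, 1])

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([100, 102, 104], size=(6, 4, 2))
        g = make_table(calls)
        S = similarity_matrix(to_band_matrix(g), "dice").S
        perm = rng.permutation(6)
        g2 = g.subset(perm)
        S2 = similarity_matrix(to_band_matrix(g2), "dice").S
        assert np.allclose(S2, S[np.ix_(perm, perm)])


class TestGroupSummary:
    def test_identical_pair_full_similarity(self):
        b = band_matrix([[1, 0], [1, 0], [0, 1]], [0, 0])
        S = similarity_matrix(b, "simple_matching")
        df = group_similarity_summary(S, {"G": [0, 1], "H": [2]})
        assert df.loc["G", "SM"] == pytest.approx(1.0)
        assert np.isnan(df.loc["H", "SM"])  # singleton group

    def test_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([100, 102, 104], size=(4, 3, 2))
        g = make_table(calls)
        S = similarity_matrix(to_band_matrix(g), "simple_matching")
        grouping = {"A": np.array([0, 1]), "B": np.array([2, 3])}
        df = group_similarity_summary(S, grouping)
        assert df.loc["A", "SM"] == pytest.approx(S.S[0, 1])
        # MGS over all pairs involving an A member
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]
        assert df.loc["A", "MGS"] == pytest.approx(
            np.mean([S.S[i, j] for i, j in pairs])
        )


class TestUPGMA:
    def test_three_point_hand_computation(self):
        # D(AB)=0.1, D(AC)=D(BC)=0.4 -> ((A,B),C) at heights 0.05 and 0.2
        S = SimilarityMatrix(
            ["A", "B", "C"],
            1 - np.array([[0, 0.1, 0.4], [0.1, 0, 0.4], [0.4, 0.4, 0]]),
            "dice",
        )
        d = upgma(S)
        assert d.clades() == {frozenset({"A", "B"})}
        heights = sorted(d.linkage[:, 2] / 2)
        assert heights == pytest.approx([0.05, 0.2])

    def test_identical_individuals_merge_at_zero(self):
        S = SimilarityMatrix(["A", "B"], np.ones((2, 2)), "dice")
        d = upgma(S)
        assert d.linkage[0, 2] == pytest.approx(0.0)

    def test_two_leaves_root_at_half_distance(self):
        S = SimilarityMatrix(["A", "B"], 1 - np.array([[0, 0.3], [0.3, 0]]), "dice")
        d = upgma(S)
        tips = {t.name: t for t in d.root.tips()}
        assert tips["A"].length == pytest.approx(0.15)

    def test_recovers_ultrametric_tree(self):
        # an exactly ultrametric distance is reproduced cophenetically
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        D = np.array(
            [
                [0.0, 0.2, 0.6, 0.6],
                [0.2, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.4],
                [0.6, 0.6, 0.4, 0.0],
            ]
        )
        d = upgma(SimilarityMatrix(list("ABCD"), 1 - D, "dice"))
        assert np.allclose(cophenet(d.linkage), squareform(D))

    def test_missing_entries_rejected(self):
        S = SimilarityMatrix(["A", "B"], np.array([[1, np.nan], [np.nan, 1]]), "dice")
        with pytest.raises(ValueError, match="missing"):
            upgma(S)


class TestBootstrap:
    def test_single_rep_degenerate_supports(self):
        g, _ = simulate(
            SimConfig(n_pops=2, n_per_pop=5, n_loci=10, target_fst=0.3,
                      missing_rate=0.0, alleles_per_locus=(3, 5), seed=0)
        )
        d = bootstrap_supports(g, reps=1, seed=1)
        assert set(d.supports.values()) <= {0.0, 100.0}

    def test_separated_clusters_high_support(self):
        g, truth = simulate(
            SimConfig(n_pops=2, n_per_pop=8, n_loci=50, target_fst=0.5,
                      inbreeding_f=0.0, missing_rate=0.0,
                      alleles_per_locus=(4, 8), seed=4)
        )
        d = bootstrap_supports(g, reps=100, seed=9)
        pop1 = frozenset(
            m.sample_id for m, p in zip(g.individuals, truth.pop_of_individual) if p == 0
        )
        supports = {c: s for c, s in d.supports.items()}
        assert pop1 in supports or frozenset(g.sample_ids) - pop1 in supports
        top = supports.get(pop1, supports.get(frozenset(g.sample_ids) - pop1))
        assert top >= 95.0

    def test_reproducible_and_order_invariant(self):
        g, _ = simulate(
            SimConfig(n_pops=2, n_per_pop=5, n_loci=20, target_fst=0.3,
                      missing_rate=0.0, alleles_per_locus=(3, 6), seed=2)
        )
        d1 = bootstrap_supports(g, reps=30, seed=5)
        d2 = bootstrap_supports(g, reps=30, seed=5)
        assert d1.supports == d2.supports
        perm = np.random.default_rng(0).permutation(g.n_individuals)
        d3 = bootstrap_supports(g.subset(perm), reps=30, seed=5)
        assert d3.supports == d1.supports  # clades are label sets


class TestPCoA:
    def test_round_trip_euclidean_distances(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X))
        S = SimilarityMatrix([f"S{i}" for i in range(6)], 1 - D / D.max() * 0.9, "dice")
        res = pcoa(S, axes=5)
        rec = squareform(pdist(res.coordinates.values))
        assert np.allclose(rec, 1 - S.S, atol=1e-8)

    def test_two_clusters_on_a_line(self):
        # two mirror-image groups: axis 1 separates, axis 2 ~ 0
        coords = np.array([-1.0, -1.0, 1.0, 1.0])
        D = np.abs(coords[:, None] - coords[None, :]) / 4
        S = SimilarityMatrix(list("ABCD"), 1 - D, "dice")
        with pytest.warns(RuntimeWarning, match="truncating"):
            res = pcoa(S, axes=2)
        axis1 = res.coordinates.iloc[:, 0].values
        assert np.sign(axis1[0]) == np.sign(axis1[1]) != np.sign(axis1[2])
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_exchangeable_points_equal_eigenvalues(self):
        S = SimilarityMatrix(list("ABC"), np.full((3, 3), 0.5) + 0.5 * np.eye(3), "dice")
        res = pcoa(S, axes=2)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert np.allclose(pos, pos[0])

    def test_eigenvalues_sorted_and_centered(self, fixture104):
        S = similarity_matrix(to_band_matrix(fixture104), "simple_matching")
        res = pcoa(S, axes=2)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)


class TestOrdinationSeparation:
    def test_first_axis_separates_populations(self):
        """Axis 1 separates two moderately differentiated populations."""
        from sklearn.metrics import silhouette_score

        g, truth = simulate(
            SimConfig(n_pops=2, n_per_pop=15, n_loci=40, target_fst=0.2,
                      inbreeding_f=0.0, missing_rate=0.0,
                      alleles_per_locus=(4, 8), seed=14)
        )
        S = similarity_matrix(to_band_matrix(g), "simple_matching")
        res = pcoa(S, axes=2)
        axis1 = res.coordinates.iloc[:, [0]].values
        assert silhouette_score(axis1, truth.pop_of_individual) > 0
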