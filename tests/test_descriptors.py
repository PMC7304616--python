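"""Descriptor count vectors, distance backends, UPGMA and its oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from odorspec import (DescriptorError, DescriptorTable, DistanceMatrix, OOVError,
                      build_group_count_vectors, correlation_distance_matrix,
                      cosine_distance_matrix, filter_rare_descriptors, load_embeddings,
                      read_descriptor_table, to_newick, upgma_cut,
                      write_descriptor_table)
from odorspec.descriptors import EmbeddingTable


def table_of(entries):
    """entries: oil -> (group, descriptors)"""
    return DescriptorTable({o: frozenset(d) for o, (_, d) in entries.items()},
                           {o: g for o, (g, _) in entries.items()})


@pytest.fixture
def toy_table():
    return table_of({
        "a": ("Citrus", {"orange", "fresh"}),
        "b": ("Citrus", {"orange", "lemon"}),
        "c": ("Floral", {"rose", "fresh"}),
        "d": ("Woody", {"cedar", "fresh", "once"}),
    })


class TestTable:
    def test_round_trip(self, tmp_path, toy_table):
        path = tmp_path / "t.csv"
        write_descriptor_table(toy_table, path)
        back = read_descriptor_table(path)
        assert back.descriptors == toy_table.descriptors
        assert back.groups == toy_table.groups

    def test_unknown_group_rejected(self):
        with pytest.raises(DescriptorError, match="unknown group"):
            table_of({"a": ("Minty", {"mint"})})

    def test_descriptors_lowercased_and_trimmed(self):
        t = table_of({"a": ("Citrus", {" Orange ", "LEMON"})})
        assert t.descriptors["a"] == frozenset({"orange", "lemon"})


class TestFilter:
    def test_singletons_removed(self, toy_table):
        filtered = filter_rare_descriptors(toy_table, 2)
        vocab = filtered.vocabulary()
        assert "once" not in vocab and "rose" not in vocab
        assert set(vocab) == {"orange", "fresh"}

    def test_min_occurrence_one_is_identity(self, toy_table):
        assert filter_rare_descriptors(toy_table, 1).descriptors == toy_table.descriptors

    def test_emptied_oils_retained_with_warning(self):
        t = table_of({"a": ("Citrus", {"solo"}), "b": ("Floral", {"rose", "soft"}),
                      "c": ("Floral", {"rose", "soft"})})
        with pytest.warns(UserWarning, match="no descriptors"):
            filtered = filter_rare_descriptors(t, 2)
        assert filtered.descriptors["a"] == frozenset()
        assert filtered.oil_ids == ["a", "b", "c"]


class TestCountVectors:
    def test_counts_by_group(self, toy_table):
        vectors = build_group_count_vectors(toy_table)
        # orange: 2 Citrus oils -> (0,2,0,0,0,0,0)
        assert vectors.loc["orange"].tolist() == [0, 2, 0, 0, 0, 0, 0]
        # fresh: 1 Citrus + 1 Floral + 1 Woody
        assert vectors.loc["fresh"].tolist() == [0, 1, 1, 0, 0, 0, 1]

    def test_row_sum_equals_occurrence(self, toy_table):
        vectors = build_group_count_vectors(toy_table)
        for d, count in toy_table.occurrence_counts().items():
            assert vectors.loc[d].sum() == count

    def test_identical_membership_identical_vectors(self):
        t = table_of({"a": ("Citrus", {"x", "y"}), "b": ("Resin", {"x", "y"})})
        v = build_group_count_vectors(t)
        assert (v.loc["x"] == v.loc["y"]).all()


class TestCorrelationDistance:
    def test_hand_computed_unit_vectors(self):
        # Pearson of e1 vs e2 in 7 dims is -1/6, so d = 7/6
        v = pd.DataFrame([[1, 0, 0, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0, 0]],
                         index=["u", "v"])
        d = correlation_distance_matrix(v)
        assert d.values[0, 1] == pytest.approx(7 / 6)

    def test_affine_invariance(self, rng):
        base = rng.uniform(0, 5, 7)
        v = pd.DataFrame([base, 3.0 * base + 2.0], index=["u", "v"])
        d = correlation_distance_matrix(v)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_gets_distance_one_with_warning(self):
        v = pd.DataFrame([[2, 2, 2, 2, 2, 2, 2], [1, 0, 1, 0, 1, 0, 1]],
                         index=["flat", "var"])
        with pytest.warns(UserWarning, match="constant"):
            d = correlation_distance_matrix(v)
        assert d.values[0, 1] == 1.0

    def test_matrix_invariants(self, rng):
        v = pd.DataFrame(rng.integers(0, 6, (10, 7)).astype(float))
        d = correlation_distance_matrix(v)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)
        assert (d.values >= 0).all() and (d.values <= 2).all()


def write_vec(path, words, vectors):
    dim = len(vectors[0])
    with open(path, "w") as fh:
        fh.write(f"{len(words)} {dim}\n")
        for w, v in zip(words, vectors):
            fh.write(w + " " + " ".join(str(x) for x in v) + "\n")


class TestEmbeddings:
    def test_round_trip(self, tmp_path, rng):
        path = tmp_path / "toy.vec"
        vecs = [rng.normal(size=4) for _ in range(3)]
        write_vec(path, ["rose", "lemon", "cedar"], vecs)
        emb = load_embeddings(path)
        assert emb.dim == 4
        assert np.allclose(emb.vectors["rose"], vecs[0])

    def test_dimension_mismatch_cites_line(self, tmp_path):
        path = tmp_path / "bad.vec"
        path.write_text("2 3\nrose 1 2 3\nlemon 1 2\n")
        with pytest.raises(DescriptorError, match="line 3"):
            load_embeddings(path)

    def test_missing_word_raises_oov_listing_it(self, tmp_path):
        path = tmp_path / "toy.vec"
        write_vec(path, ["rose"], [[1, 2]])
        with pytest.raises(OOVError, match="cedar"):
            load_embeddings(path, vocabulary=["rose", "cedar"])

    def test_multiword_falls_back_to_token_average(self):
        emb = EmbeddingTable({"sweet": np.array([1.0, 0.0]),
                              "orange": np.array([0.0, 1.0])}, 2)
        assert np.allclose(emb.resolve("sweet orange"), [0.5, 0.5])
        with pytest.raises(OOVError):
            emb.resolve("bitter orange")


class TestCosineDistance:
    def test_identical_orthogonal_antiparallel(self):
        emb = EmbeddingTable({"a": np.array([1.0, 0.0]), "b": np.array([2.0, 0.0]),
                              "c": np.array([0.0, 1.0]), "d": np.array([-3.0, 0.0])}, 2)
        d = cosine_distance_matrix(emb, ["a", "b", "c", "d"]).values
        assert d[0, 1] == pytest.approx(0.0)   # parallel
        assert d[0, 2] == pytest.approx(1.0)   # orthogonal
        assert d[0, 3] == pytest.approx(2.0)   # antiparallel

    def test_zero_norm_vector_rejected(self):
        emb = EmbeddingTable({"a": np.array([0.0, 0.0]), "b": np.array([1.0, 0.0])}, 2)
        with pytest.raises(DescriptorError, match="zero-norm"):
            cosine_distance_matrix(emb, ["a", "b"])


def brute_average_linkage(D, k):
    """Exhaustive average-linkage oracle: recompute all cluster-average
    distances from the leaf matrix at every step."""
    clusters = [frozenset([i]) for i in range(D.shape[0])]
    while len(clusters) > k:
        best, bd = None, np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if d < bd:
                    best, bd = (i, j), d
        i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for p, c in enumerate(clusters) if p not in (i, j)] + [merged]
    return frozenset(clusters)


def as_partition(assignment, n):
    return frozenset(frozenset(i for i in range(n) if assignment[f"x{i}"] == c)
                     for c in set(assignment.values()))


class TestUpgma:
    def test_k_equals_n_gives_singletons(self):
        d = DistanceMatrix(["x0", "x1", "x2"], 1 - np.eye(3))
        cl = upgma_cut(d, 3)
        assert sorted(map(len, cl.clusters().values())) == [1, 1, 1]

    def test_k_one_gives_single_cluster(self):
        d = DistanceMatrix(["x0", "x1", "x2"], 1 - np.eye(3))
        assert len(upgma_cut(d, 1).clusters()) == 1

    def test_two_tight_pairs(self):
        D = np.full((4, 4), 8.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 1.0
        D[2, 3] = D[3, 2] = 2.0
        cl = upgma_cut(DistanceMatrix(["a", "b", "c", "d"], D), 2)
        assert cl.clusters() == {1: ["a", "b"], 2: ["c", "d"]}

    def test_out_of_range_k(self):
        d = DistanceMatrix(["x0", "x1"], 1 - np.eye(2))
        with pytest.raises(DescriptorError):
            upgma_cut(d, 0)
        with pytest.raises(DescriptorError):
            upgma_cut(d, 3)

    def test_merge_heights_non_decreasing(self, rng):
        n = 8
        D = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        D[iu] = rng.uniform(0.1, 2.0, iu[0].size)
        D += D.T
        cl = upgma_cut(DistanceMatrix([f"x{i}" for i in range(n)], D), 1)
        heights = [h for _, _, h in cl.merge_history]
        assert all(h2 >= h1 for h1, h2 in zip(heights, heights[1:]))

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_agrees_with_brute_force_oracle(self, k):
        for seed in range(30):
            r = np.random.default_rng(seed)
            D = np.zeros((6, 6))
            iu = np.triu_indices(6, 1)
            D[iu] = r.uniform(0.1, 2.0, 15)
            D += D.T
            dm = DistanceMatrix([f"x{i}" for i in range(6)], D)
            mine = as_partition(upgma_cut(dm, k).assignment, 6)
            assert mine == brute_average_linkage(D, k)

    def test_agrees_with_scipy_average_linkage(self):
        for seed in range(30):
            r = np.random.default_rng(1000 + seed)
            D = np.zeros((7, 7))
            iu = np.triu_indices(7, 1)
            D[iu] = r.uniform(0.1, 2.0, iu[0].size)
            D += D.T
            dm = DistanceMatrix([f"x{i}" for i in range(7)], D)
            sc = fcluster(linkage(squareform(D), "average"), 3, "maxclust")
            part_scipy = frozenset(frozenset(np.flatnonzero(sc == c).tolist())
                                   for c in set(sc))
            assert as_partition(upgma_cut(dm, 3).assignment, 7) == part_scipy

    def test_tie_break_is_lexicographic_and_deterministic(self):
        # all pairwise distances equal: merges must follow label order
        D = np.full((3, 3), 1.0)
        np.fill_diagonal(D, 0.0)
        cl = upgma_cut(DistanceMatrix(["b", "c", "a"], D), 1)
        assert cl.merge_history[0][:2] == (("a",), ("b",))

    def test_cluster_ids_ordered_by_smallest_member(self):
        D = np.full((4, 4), 8.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 1.0
        D[2, 3] = D[3, 2] = 2.0
        cl = upgma_cut(DistanceMatrix(["zed", "ant", "mid", "bee"], D), 2)
        # cluster containing "ant" must be cluster 1
        assert cl.assignment["ant"] == 1 and cl.assignment["zed"] == 1


class TestNewick:
    def test_export_parses_and_preserves_leaves(self):
        import io
        from Bio import Phylo
        D = np.array([[0, 1, 8, 8], [1, 0, 8, 8], [8, 8, 0, 2], [8, 8, 2, 0.0]])
        cl = upgma_cut(DistanceMatrix(["a", "b", "c", "d"], D), 1)
        tree = Phylo.read(io.StringIO(to_newick(cl)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c", "d"]
        # leaf depths are the root merge height (ultrametric under our export)
        depths = tree.depths()
        leaf_depths = {t.name: d for t, d in depths.items() if t.name}
        assert leaf_depths["a"] == pytest.approx(max(h for _, _, h in cl.merge_history))
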