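"""Tree container, I/O, enumeration, and distance behaviour."""

import dendropy
import numpy as np
import pytest

from treevae.codec import decode
from treevae.trees import (
    TreeCollection,
    TreeError,
    TreeTopology,
    enumerate_topologies,
    num_topologies,
    parse_trees,
    path_difference_distance,
    rf_distance,
    same_topology,
    write_trees,
)

from conftest import labels


def random_topology(n, rng):
    """Uniform-ish random topology via a random valid encoding vector."""
    from treevae.codec import allowed_index_set

    s = [rng.choice(sorted(allowed_index_set(k, n))) for k in range(3, n)]
    return decode(s, labels(n))


class TestParsing:
    def test_identical_trees_collapse_to_one_class(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((t1,t2),(t3,(t4,t5)));\n" * 3)
        coll = parse_trees(str(path))
        assert len(coll) == 1
        assert coll.weights[0] == pytest.approx(1.0)

    def test_frequency_weights(self, tmp_path):
        ta = "((t1,t2),(t3,(t4,t5)));\n"
        tb = "((t1,t3),(t2,(t4,t5)));\n"
        path = tmp_path / "trees.nwk"
        path.write_text(ta * 7 + tb * 3)
        coll = parse_trees(str(path))
        assert sorted(coll.weights) == pytest.approx([0.3, 0.7])

    def test_mismatched_leaf_sets_rejected(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((A,B),(C,(D,E)));\n((A,B),(C,(D,F)));\n")
        with pytest.raises(TreeError, match="tree 1"):
            parse_trees(str(path))

    def test_multifurcation_rejected(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("(A,B,C,D,E);\n")
        with pytest.raises(TreeError):
            parse_trees(str(path))

    def test_rooted_input_is_unrooted(self, tmp_path):
        # a rooted bifurcating tree: root suppressed silently
        path = tmp_path / "trees.nwk"
        path.write_text("((A,B),((C,D),E));\n")
        coll = parse_trees(str(path))
        t = coll.topologies[0]
        assert t.n_leaves == 5
        assert all(len(t.adjacency[u]) in (1, 3) for u in t.adjacency)

    def test_explicit_weights_file(self, tmp_path):
        ta = "((t1,t2),(t3,(t4,t5)));\n"
        tb = "((t1,t3),(t2,(t4,t5)));\n"
        (tmp_path / "trees.nwk").write_text(ta + tb)
        (tmp_path / "w.tsv").write_text("0\t0.9\n1\t0.1\n")
        coll = parse_trees(str(tmp_path / "trees.nwk"), weights=str(tmp_path / "w.tsv"))
        assert sorted(coll.weights) == pytest.approx([0.1, 0.9])

    def test_nexus_with_translate_table(self, tmp_path):
        nexus = (
            "#NEXUS\nBEGIN TAXA; DIMENSIONS NTAX=5; TAXLABELS A B C D E; END;\n"
            "BEGIN TREES;\n TRANSLATE 1 A, 2 B, 3 C, 4 D, 5 E;\n"
            " TREE one = ((1,2),(3,(4,5)));\nEND;\n"
        )
        path = tmp_path / "trees.nex"
        path.write_text(nexus)
        coll = parse_trees(str(path), format="nexus")
        assert set(coll.leaf_order) == {"A", "B", "C", "D", "E"}


class TestRoundTrip:
    def test_write_then_parse_preserves_classes_and_weights(self, tmp_path, five_leaf_space):
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(15))
        coll = TreeCollection(list(zip(five_leaf_space, w)))
        write_trees(coll, str(tmp_path / "out.nwk"), weights_path=str(tmp_path / "w.tsv"))
        back = parse_trees(str(tmp_path / "out.nwk"), weights=str(tmp_path / "w.tsv"))
        assert len(back) == 15
        for (t1, w1), (t2, w2) in zip(coll, back):
            assert same_topology(t1, t2)
            assert w1 == pytest.approx(w2)

    def test_empty_collection_writes_empty_file(self, tmp_path):
        write_trees(TreeCollection([]), str(tmp_path / "empty.nwk"))
        assert (tmp_path / "empty.nwk").read_text() == ""

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_newick_round_trip_every_topology(self, n):
        for t in enumerate_topologies(labels(n)):
            back = TreeTopology.from_newick(t.to_newick(), leaf_order=t.leaf_order)
            assert same_topology(t, back)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 3), (5, 15), (6, 105), (7, 945)])
    def test_counts_match_double_factorial(self, n, count):
        tops = enumerate_topologies(labels(n))
        assert len(tops) == count == num_topologies(n)

    def test_all_distinct_on_five_leaves(self, five_leaf_space):
        keys = {frozenset(t.splits()) for t in five_leaf_space}
        assert len(keys) == 15

    def test_refuses_large_spaces(self):
        with pytest.raises(ValueError, match="refusing"):
            enumerate_topologies(labels(10))


class TestSameTopology:
    def test_diagonal_only_on_five_leaf_space(self, five_leaf_space):
        for i, a in enumerate(five_leaf_space):
            for j, b in enumerate(five_leaf_space):
                assert same_topology(a, b) == (i == j)

    def test_leaf_set_mismatch_is_error(self):
        a = TreeTopology.from_newick("(A,B,(C,D));")
        b = TreeTopology.from_newick("(A,B,(C,E));")
        with pytest.raises(TreeError):
            same_topology(a, b)


class TestDistances:
    def test_rf_zero_on_identity(self, five_leaf_space):
        for t in five_leaf_space:
            assert rf_distance(t, t) == 0
            assert path_difference_distance(t, t) == 0.0

    def test_rf_between_disjoint_caterpillars_is_four(self):
        a = TreeTopology.from_newick("((A,B),(C,(D,E)));")  # splits AB, DE
        b = TreeTopology.from_newick("(((A,C),E),(B,D));")  # splits AC, BD
        assert rf_distance(a, b) == 4

    def test_rf_matches_dendropy(self, rng):
        # independent oracle: dendropy's bipartition-based RF
        for _ in range(25):
            a, b = random_topology(8, rng), random_topology(8, rng)
            tns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(data=a.to_newick(), schema="newick", taxon_namespace=tns)
            db = dendropy.Tree.get(data=b.to_newick(), schema="newick", taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
            assert rf_distance(a, b) == expected

    def test_distance_symmetry(self, rng):
        for _ in range(30):
            a, b = random_topology(8, rng), random_topology(8, rng)
            assert rf_distance(a, b) == rf_distance(b, a)
            assert path_difference_distance(a, b) == pytest.approx(
                path_difference_distance(b, a)
            )

    def test_identity_of_indiscernibles_on_five_leaf_space(self, five_leaf_space):
        for i, a in enumerate(five_leaf_space):
            for j, b in enumerate(five_leaf_space):
                assert (rf_distance(a, b) == 0) == (i == j)
                assert (path_difference_distance(a, b) == 0.0) == (i == j)

    def test_path_difference_matches_bfs_oracle(self):
        a = TreeTopology.from_newick("((A,B),(C,(D,E)));")
        b = TreeTopology.from_newick("((A,D),(C,(B,E)));")

        def bfs_vector(t):
            leaves = t.leaves
            out = []
            for i in range(len(leaves)):
                for j in range(i + 1, len(leaves)):
                    # brute-force BFS between the two leaves
                    frontier, dist = [leaves[i]], {leaves[i]: 0}
                    while frontier:
                        u = frontier.pop(0)
                        for v in t.adjacency[u]:
                            if v not in dist:
                                dist[v] = dist[u] + 1
                                frontier.append(v)
                    out.append(dist[leaves[j]])
            return np.array(out, dtype=float)

        expected = float(np.linalg.norm(bfs_vector(a) - bfs_vector(b)))
        assert path_difference_distance(a, b) == pytest.approx(expected)
        assert expected > 0

    def test_distinct_four_leaf_trees_have_positive_pd(self):
        a = TreeTopology.from_newick("((A,B),(C,D));")
        b = TreeTopology.from_newick("((A,C),(B,D));")
        assert path_difference_distance(a, b) > 0


class TestCollectionInvariants:
    def test_duplicates_merged_with_added_weights(self, five_leaf_space):
        t = five_leaf_space[0]
        coll = TreeCollection([(t, 0.4), (t, 0.6)])
        assert len(coll) == 1
        assert coll.weights[0] == pytest.approx(1.0)

    def test_weights_must_sum_to_one(self, five_leaf_space):
        with pytest.raises(TreeError, match="sum"):
            TreeCollection([(five_leaf_space[0], 0.5)])

    def test_negative_weight_rejected(self, five_leaf_space):
        with pytest.raises(TreeError, match="negative"):
            TreeCollection([(five_leaf_space[0], -0.5), (five_leaf_space[1], 1.5)])
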