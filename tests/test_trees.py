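"""Tree model, Newick I/O, pruning to orthoset ancestors, RF* metrics."""

import dendropy
import numpy as np
import pytest

from aspen import (
    OrthosetMap,
    PrunedTopology,
    Topology,
    TreeError,
    UnprunableError,
    accuracy,
    enumerate_topologies,
    precision,
    prune_to_ancestors,
    read_newick,
    rf_star,
    write_newick,
)
from conftest import as_pruned, labels_for, random_topology


class TestNewickIO:
    def test_fig_example_structure(self, fig_tree):
        assert fig_tree.leaves == set("ABCDEF")
        assert frozenset("AB") in fig_tree.clades()
        assert frozenset("CD") in fig_tree.clades()
        assert frozenset("CDE") in fig_tree.clades()

    def test_two_leaf_tree(self):
        t = read_newick("(A,B);")
        assert t.n_leaves == 2
        assert len(t.clades()) == 1

    def test_internal_node_count(self, rng):
        # n leaves -> exactly n-1 internal nodes, root included
        for n in (2, 5, 9, 14):
            t = random_topology(labels_for(n), rng)
            internal = sum(1 for x in t.iter_nodes() if not x.is_leaf)
            assert internal == n - 1

    def test_trifurcation_resolved_deterministically(self):
        t = read_newick("(A,B,C);")
        assert write_newick(t) == "((A,B),C);"
        t2 = read_newick("(C,A,B);")  # same unrooted input, permuted
        assert write_newick(t2) == "((A,B),C);"

    def test_roundtrip_identity(self, rng):
        for n in (3, 6, 10):
            t = random_topology(labels_for(n), rng)
            assert read_newick(write_newick(t)) == t

    def test_canonical_form_ignores_child_order(self):
        a = read_newick("(((A,B),((C,D),E)),F);")
        b = read_newick("(F,((E,(D,C)),(B,A)));")
        assert a == b
        assert write_newick(a) == write_newick(b) == "(((A,B),((C,D),E)),F);"

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            read_newick("((A,B),(A,C));")

    def test_malformed_rejected(self):
        with pytest.raises(TreeError):
            read_newick("((A,B),C")

    def test_nonbasal_polytomy_rejected(self):
        with pytest.raises(TreeError, match="binary"):
            read_newick("((A,B,C,D),E);")

    def test_branch_lengths_retained_but_nonsemantic(self):
        a = read_newick("((A:0.1,B:0.2):0.3,C:0.4);")
        b = read_newick("((A,B),C);")
        assert a == b
        assert "0.1" in write_newick(a, lengths=True)

    def test_midpoint_rooting_recovers_deep_root(self):
        # unrooted input whose midpoint lies on the long central branch
        t = read_newick("(a1:0.1,a2:0.1,(b1:0.1,b2:0.1):2.0);",
                        rooting="midpoint")
        assert frozenset({"a1", "a2"}) in t.clades()
        assert frozenset({"b1", "b2"}) in t.clades()


class TestPruning:
    OM = OrthosetMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                      "c1": "C", "c2": "C"})

    def test_perfect_monophyly(self):
        t = read_newick("((a1,a2),(b1,b2));")
        om = OrthosetMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        p = prune_to_ancestors(t, om)
        assert p.topology.leaves == {"A", "B"}
        assert all(r.monophyletic for r in p.monophyly.values())
        assert not p.missing

    def test_fully_interleaved_is_unprunable(self):
        t = read_newick("((a1,b1),(a2,b2));")
        om = OrthosetMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        with pytest.raises(UnprunableError):
            prune_to_ancestors(t, om)

    def test_partial_monophyly_flags_and_spurious_region(self):
        t = read_newick("(((a1,a2),b1),(b2,(c1,c2)));")
        p = prune_to_ancestors(t, self.OM)
        assert p.topology.leaves == {"A", "C"}
        assert p.missing == {"B"}
        assert not p.monophyly["B"].monophyletic
        # B's MRCA is the root: the A-C path crosses it, so it is compromised
        assert ("A", "C") in p.compromised_pairs()

    def test_unmapped_leaf_rejected(self):
        t = read_newick("((a1,a2),(b1,zz));")
        with pytest.raises(TreeError, match="orthoset map"):
            prune_to_ancestors(t, self.OM)

    def test_invariant_to_leaf_order(self, rng):
        base = "(((a1,a2),b1),(b2,(c1,c2)));"
        p0 = prune_to_ancestors(read_newick(base), self.OM)
        scrambles = ["((b2,(c2,c1)),(b1,(a2,a1)));",
                     "(((a2,a1),b1),((c1,c2),b2));"]
        for s in scrambles:
            p = prune_to_ancestors(read_newick(s), self.OM)
            assert p.topology == p0.topology
            assert p.missing == p0.missing
            assert p.compromised_pairs() == p0.compromised_pairs()

    def test_localized_spurious_region_spares_outside_paths(self):
        # D interleaves with C below one deep node; A-B paths stay clean
        t = read_newick(
            "(((a1,a2),(b1,b2)),(((c1,d1),c2),(d2,(e1,e2))));")
        om = OrthosetMap({k: k[0].upper() for k in
                          ["a1", "a2", "b1", "b2", "c1", "c2",
                           "d1", "d2", "e1", "e2"]})
        p = prune_to_ancestors(t, om)
        assert p.missing == {"C", "D"}
        assert p.topology.leaves == {"A", "B", "E"}
        assert ("A", "B") not in p.compromised_pairs()


def _brute_force_splits(t: Topology):
    """Independent split enumeration: every clade except root and leaves."""
    leaves = t.leaves
    out = set()
    for clade in t.clades():
        if clade == leaves or len(clade) < 2 or len(leaves - clade) < 2:
            continue
        out.add(frozenset((clade, frozenset(leaves - clade))))
    return out


def _dendropy_rf(newick_a: str, newick_b: str) -> int:
    taxa = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick",
                           taxon_namespace=taxa, preserve_underscores=True)
    tb = dendropy.Tree.get(data=newick_b, schema="newick",
                           taxon_namespace=taxa, preserve_underscores=True)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


class TestRFStar:
    def test_identity_is_zero(self, rng):
        for n in (4, 6, 9):
            t = as_pruned(random_topology(labels_for(n), rng))
            r = rf_star(t, t)
            assert (r.x, r.y, r.z, r.zprime) == (0, 0, 0, 0)
            assert r.distance == 0.0
            assert r.classic

    def test_matches_brute_force_and_dendropy(self, rng):
        # well-formed pairs: RF* must equal the classic split comparison,
        # checked against both a hand enumeration and dendropy
        for n in (4, 5, 6, 7, 8):
            for _ in range(15):
                a = random_topology(labels_for(n), rng)
                b = random_topology(labels_for(n), rng)
                res = rf_star(as_pruned(a), as_pruned(b))
                sa, sb = _brute_force_splits(a), _brute_force_splits(b)
                assert res.x == len(sa - sb)
                assert res.y == len(sb - sa)
                assert res.distance == (res.x + res.y) / (2 * n - 6)
                assert res.x + res.y == _dendropy_rf(
                    write_newick(a), write_newick(b))

    def test_symmetry(self, rng):
        for _ in range(25):
            a = as_pruned(random_topology(labels_for(6), rng))
            b = as_pruned(random_topology(labels_for(6), rng))
            assert rf_star(a, b).distance == rf_star(b, a).distance

    def test_missing_ancestor_adds_z_term(self):
        # five-ancestor universe; B lacks ancestor E but is otherwise
        # compatible with A restricted to the shared leaves
        universe = tuple("ABCDE")
        a = PrunedTopology(read_newick("(((A,B),C),(D,E));"), universe)
        b = PrunedTopology(read_newick("(((A,B),C),D);"), universe,
                           missing=frozenset({"E"}))
        res = rf_star(a, b)
        assert (res.z, res.zprime) == (0, 1)
        assert not res.classic
        # restricted to {A,B,C,D} both reduce to the same splits
        assert (res.x, res.y) == (0, 0)
        assert res.distance == 1 / (2 * 5 - 6)
        sym = rf_star(b, a)
        assert (sym.z, sym.zprime) == (1, 0)
        assert sym.distance == res.distance

    def test_too_few_ancestors_rejected(self):
        a = as_pruned(read_newick("((A,B),C);"))
        with pytest.raises(TreeError, match="RF"):
            rf_star(a, a)

    def test_mismatched_universe_rejected(self, rng):
        a = as_pruned(random_topology(labels_for(5), rng))
        b = as_pruned(random_topology(list("VWXYZ"), rng))
        with pytest.raises(TreeError, match="universe"):
            rf_star(a, b)


class TestAccuracyPrecision:
    def test_identical_trees_give_one(self, rng):
        t = as_pruned(random_topology(labels_for(7), rng))
        assert accuracy(t, t) == 1.0

    def test_maximally_different_trees_give_zero(self):
        # caterpillar vs a tree sharing no non-trivial split
        a = as_pruned(read_newick("(((((A,B),C),D),E),F);"))
        b = as_pruned(read_newick("(((((C,F),A),E),B),D);"))
        res = rf_star(a, b)
        assert res.x == res.y == 3
        assert accuracy(a, b) == 0.0

    def test_single_nni_on_fifteen_ancestors(self, rng):
        # one rearranged split -> one split unique to each side
        t = random_topology(labels_for(15), rng)
        from aspen.simulate import _random_nni

        other = t.copy()
        _random_nni(other, np.random.default_rng(3))
        res = rf_star(as_pruned(t), as_pruned(other))
        if res.distance > 0:  # an NNI can be a no-op across the root
            assert (res.x, res.y) == (1, 1)
            assert accuracy(as_pruned(t), as_pruned(other)) == 1 - 2 / 24

    def test_precision_of_self_ensemble(self, rng):
        t = as_pruned(random_topology(labels_for(6), rng))
        assert precision(t, [t] * 5) == 1.0

    def test_precision_is_mean_complement(self, rng):
        ref = as_pruned(read_newick("(((A,B),C),(D,(E,F)));"))
        m1 = as_pruned(read_newick("(((A,C),B),(D,(E,F)));"))  # one NNI
        d1 = rf_star(ref, m1).distance
        m2 = as_pruned(read_newick("(((A,B),D),(C,(E,F)));"))
        d2 = rf_star(ref, m2).distance
        assert precision(ref, [m1, m2]) == pytest.approx(1 - (d1 + d2) / 2)

    def test_bounds_on_random_pairs(self, rng):
        for _ in range(50):
            a = as_pruned(random_topology(labels_for(6), rng))
            b = as_pruned(random_topology(labels_for(6), rng))
            assert 0.0 <= accuracy(a, b) <= 1.0

    def test_empty_ensemble_rejected(self, rng):
        t = as_pruned(random_topology(labels_for(5), rng))
        with pytest.raises(TreeError):
            precision(t, [])


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_counts_match_double_factorial(self, n, count):
        ts = list(enumerate_topologies(labels_for(n)))
        assert len(ts) == count
        assert len(set(ts)) == count  # all distinct

    def test_all_trees_cover_labels(self):
        for t in enumerate_topologies(list("WXYZ")):
            assert t.leaves == {"W", "X", "Y", "Z"}
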