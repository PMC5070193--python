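"""Distances, neighbor joining, bootstrap, rooting, monophyly and the
quartet-vote confidence surrogate.

NJ is validated against two oracles: exact recovery on additive matrices
and agreement with a brute-force least-squares topology search for up to
six taxa.
"""

import itertools
import math

import dendropy
import numpy as np
import pytest

from tandemaaa.seqio import MultipleAlignment, read_newick
from tandemaaa import phylo
from tandemaaa.phylo import (DistanceMatrix, bipartitions, bootstrap,
                             canonical_split, distance_matrix,
                             is_monophyletic, nj_tree, pairwise_distance,
                             quartet_support, root_with_outgroup)


def tree_distance_matrix(newick: str) -> DistanceMatrix:
    t = dendropy.Tree.get(data=newick, schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    taxa = list(t.taxon_namespace)
    M = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
    return DistanceMatrix([x.label for x in taxa], M)


class TestPairwiseDistance:
    def test_identical_rows_zero_under_all_models(self):
        for model in ("p-distance", "poisson", "gamma"):
            assert pairwise_distance("MKVL", "MKVL", model) == 0.0

    def test_poisson_closed_form(self):
        # p = 0.5 -> -ln(0.5)
        assert pairwise_distance("AAAA", "AAVV", "poisson") == \
            pytest.approx(-math.log(0.5), abs=1e-12)

    def test_gamma_closed_form(self):
        # p = 0.5, alpha = 1 -> 1/(1-p) - 1 = 1
        assert pairwise_distance("AAAA", "AAVV", "gamma", alpha=1.0) == \
            pytest.approx(1.0, abs=1e-12)

    def test_gaps_excluded_from_shared_columns(self):
        assert pairwise_distance("A-KV", "AL-V", "p-distance") == 0.0

    def test_saturation_error_under_correction(self):
        with pytest.raises(ValueError, match="saturated"):
            pairwise_distance("AAAA", "VVVV", "poisson")

    def test_matrix_matches_scalar(self):
        aln = MultipleAlignment({"a": "MKVLT", "b": "MKALT", "c": "GKVLF"})
        D = distance_matrix(aln)
        for i, x in enumerate(aln.ids):
            for j, y in enumerate(aln.ids):
                if i != j:
                    assert D.matrix[i, j] == pytest.approx(
                        pairwise_distance(aln.rows[x], aln.rows[y]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        t = nj_tree(D)
        lengths = {l.taxon.label: l.edge.length
                   for l in t.tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 3.0})

    def test_additive_five_taxon_exact_recovery(self):
        src = "((A:1,B:2):1,(C:1,D:1.5):2,E:3);"
        D = tree_distance_matrix(src)
        t = nj_tree(D)
        want = read_newick(src)
        assert set(bipartitions(t)) == set(bipartitions(want))
        # branch lengths recovered exactly on additive input
        lengths = {l.taxon.label: l.edge.length
                   for l in t.tree.leaf_node_iter()}
        assert lengths["B"] == pytest.approx(2.0, abs=1e-9)
        assert lengths["E"] == pytest.approx(3.0, abs=1e-9)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        D = tree_distance_matrix(
            "((A:1,B:2):0.5,((C:1,D:2):0.7,E:1.2):0.4,F:2);")
        base = set(bipartitions(nj_tree(D)))
        for _ in range(5):
            perm = rng.permutation(len(D.labels))
            Dp = DistanceMatrix([D.labels[i] for i in perm],
                                D.matrix[np.ix_(perm, perm)])
            assert set(bipartitions(nj_tree(Dp))) == base

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_agrees_with_brute_force_least_squares(self, n_taxa):
        """NJ topology equals the global least-squares optimum over all
        unrooted topologies on noisy-additive matrices."""
        rng = np.random.default_rng(100 + n_taxa)
        for rep in range(3):
            labels = [chr(65 + i) for i in range(n_taxa)]
            nwk = _random_additive_newick(rng, labels)
            D = tree_distance_matrix(nwk)
            noise = rng.normal(0, 0.01, D.matrix.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            M = np.abs(D.matrix + noise)
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            Dn = DistanceMatrix(D.labels, M)
            nj_splits = set(bipartitions(nj_tree(Dn)))
            best_splits = _best_ls_topology(Dn)
            assert nj_splits == best_splits


def _random_additive_newick(rng, labels):
    nodes = [f"{l}:{rng.uniform(0.5, 2):.4f}" for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        pair = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.5, 2):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [pair]
    return "(" + ",".join(nodes) + ");"


def _all_topologies(labels):
    """All unrooted binary topologies as split sets (leaf-addition)."""
    if len(labels) == 3:
        yield []
        return
    # represent a topology as a list of edges; each edge = frozenset of
    # leaves on one side; grow by attaching each new leaf to each edge of
    # the star-resolved tree, tracked via dendropy for simplicity
    base = f"({labels[0]},{labels[1]},{labels[2]});"
    trees = [dendropy.Tree.get(data=base, schema="newick")]
    for lab in labels[3:]:
        new_trees = []
        for t in trees:
            edges = [e for e in t.preorder_edge_iter()
                     if e.head_node.parent_node is not None]
            for k in range(len(edges)):
                t2 = t.clone(depth=1)
                e2 = [e for e in t2.preorder_edge_iter()
                      if e.head_node.parent_node is not None][k]
                mid = dendropy.Node()
                parent = e2.tail_node
                child = e2.head_node
                parent.remove_child(child)
                parent.add_child(mid)
                mid.add_child(child)
                leaf = dendropy.Node(
                    taxon=t2.taxon_namespace.require_taxon(lab))
                mid.add_child(leaf)
                new_trees.append(t2)
        trees = new_trees
    for t in trees:
        yield t


def _splits_of_dendropy(t, all_leaves):
    ref = min(all_leaves)
    out = set()
    for node in t.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if ref not in below else all_leaves - below
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def _best_ls_topology(D: DistanceMatrix):
    """Enumerate topologies, fit branch lengths by least squares, return
    the split set of the minimum-residual topology."""
    labels = D.labels
    all_leaves = frozenset(labels)
    pos = {l: i for i, l in enumerate(labels)}
    pairs = list(itertools.combinations(labels, 2))
    best = (math.inf, None)
    for t in _all_topologies(labels):
        edges = [e for e in t.preorder_edge_iter()
                 if e.head_node.parent_node is not None]
        A = np.zeros((len(pairs), len(edges)))
        sides = []
        for e in edges:
            sides.append(frozenset(l.taxon.label
                                   for l in e.head_node.leaf_iter()))
        for r, (x, y) in enumerate(pairs):
            for c, side in enumerate(sides):
                if (x in side) != (y in side):
                    A[r, c] = 1.0
        d = np.array([D.matrix[pos[x], pos[y]] for x, y in pairs])
        blen, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = ((A @ blen - d) ** 2).sum()
        if resid < best[0]:
            best = (resid, _splits_of_dendropy(t, all_leaves))
    return best[1]


class TestBootstrap:
    def test_unanimous_columns_give_full_support(self):
        # every column supports the split {A,B} | {C,D}
        aln = MultipleAlignment({"A": "AAAA", "B": "AAAA",
                                 "C": "VVVV", "D": "VVVV"})
        st = bootstrap(aln, n_reps=25, seed=1)
        assert st.support_of({"A", "B"}) == 100.0

    def test_zero_replicates_rejected(self):
        aln = MultipleAlignment({"A": "AV", "B": "AV", "C": "VA", "D": "VV"})
        with pytest.raises(ValueError):
            bootstrap(aln, n_reps=0)

    def test_deterministic_under_seed(self, small_dataset):
        from tandemaaa.synthgen import true_alignment
        aln = true_alignment(small_dataset, "NSF", "D1")
        s1 = bootstrap(aln, n_reps=10, seed=42)
        s2 = bootstrap(aln, n_reps=10, seed=42)
        assert s1.supports == s2.supports
        assert s1.newick_with_support() == s2.newick_with_support()


class TestRooting:
    def test_root_between_cherries(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_with_outgroup(t, ["C", "D"])
        kids = rooted.tree.seed_node.child_nodes()
        sides = {frozenset(l.taxon.label for l in k.leaf_iter())
                 for k in kids}
        assert frozenset({"C", "D"}) in sides

    def test_non_monophyletic_outgroup_rejected(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError, match="monophyletic"):
            root_with_outgroup(t, ["A", "C"])

    def test_root_then_unroot_preserves_topology(self):
        nwk = "((A:1,B:1):1,(C:1,(D:1,E:1):0.5):1);"
        t = read_newick(nwk)
        rooted = root_with_outgroup(t, ["D", "E"])
        back = phylo.unroot(rooted)
        assert set(bipartitions(back)) == set(bipartitions(read_newick(nwk)))

    def test_missing_outgroup_label_rejected(self):
        t = read_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="absent"):
            root_with_outgroup(t, ["Z"])


class TestMonophyly:
    @pytest.mark.parametrize("labels,expected", [
        (["A"], True),
        (["A", "B", "C", "D"], True),
        (["A", "C"], False),
        (["A", "B"], True),
    ])
    def test_four_taxon_cases(self, labels, expected):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(t, labels) is expected

    def test_unknown_label_rejected(self):
        t = read_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="unknown"):
            is_monophyletic(t, ["A", "Z"])


class TestQuartetSupport:
    def test_additive_distances_fully_concordant(self):
        nwk = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        # build an alignment whose p-distances are tree-like: use the
        # split structure directly via synthetic columns
        t = read_newick(nwk)
        aln = _alignment_from_tree(nwk)
        split = {"A", "B", "C", "D"}
        f = quartet_support(aln, t, split, n_quartets=80, seed=0)
        assert f[0] == pytest.approx(1.0)
        assert sum(f) == pytest.approx(1.0, abs=1e-12)

    def test_noise_distances_vote_uniformly(self):
        # the tree is fixed a priori; the alignment (hence the distances)
        # is independent i.i.d. noise, so no topology is favored
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(12)]
        tree = read_newick(
            "(((t0,t1),(t2,t3),t4),((t5,t6),(t7,t8)),(t9,(t10,t11)));")
        split = canonical_split({"t0", "t1", "t2", "t3", "t4"},
                                frozenset(labels))
        # a single noise matrix offers few distinct quartets, so average
        # the vote fractions over independent noise datasets
        n_rep, n_q = 15, 60
        acc = np.zeros(3)
        for r in range(n_rep):
            aln = MultipleAlignment({
                l: "".join("ACDEFGHIKLMNPQRSTVWY"[k]
                           for k in rng.integers(0, 20, 400))
                for l in labels})
            f = quartet_support(aln, tree, split, n_quartets=n_q, seed=r)
            assert sum(f) == pytest.approx(1.0, abs=1e-12)
            acc += np.array(f)
        acc /= n_rep
        se = math.sqrt((1 / 3) * (2 / 3) / n_rep)   # between-dataset spread
        for frac in acc:
            assert abs(frac - 1 / 3) <= 3 * se

    def test_fractions_always_sum_to_one(self, small_dataset):
        from tandemaaa.synthgen import true_alignment
        aln = true_alignment(small_dataset, "Spaf", "D2")
        tree = nj_tree(distance_matrix(aln))
        for split in list(bipartitions(tree))[:5]:
            f = quartet_support(aln, tree, split, n_quartets=40, seed=1)
            assert sum(f) == pytest.approx(1.0, abs=1e-12)


def _alignment_from_tree(nwk: str, scale: int = 30) -> MultipleAlignment:
    """Columns encode each edge of the tree `scale` times, so p-distances
    are proportional to path lengths (perfectly additive)."""
    t = read_newick(nwk)
    leaves = sorted(t.leaf_labels)
    cols = {l: [] for l in leaves}
    for node in t.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        for _ in range(scale):
            for l in leaves:
                cols[l].append("A" if l in below else "V")
    return MultipleAlignment({l: "".join(v) for l, v in cols.items()})


class TestPhylipRoundTrip:
    def test_square_matrix_round_trip(self):
        D = tree_distance_matrix("((A:1,B:2):1,C:2,D:4);")
        text = D.to_phylip()
        back = DistanceMatrix.from_phylip(text)
        assert back.labels == D.labels
        np.testing.assert_allclose(back.matrix, D.matrix, atol=1e-6)
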