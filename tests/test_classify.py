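"""Similarity graph, hierarchical clustering, reconciliation, per-domain
assignment and the iterative retraining loop."""

import math

import networkx as nx
import numpy as np
import pytest

from tandemaaa.seqio import AMINO_ACIDS, MultipleAlignment, ProteinSequence
from tandemaaa import classify as cl
from tandemaaa.classify import (ClassifyConfig, SimilarityGraph, Subgroup,
                                SubgroupHierarchy, all_vs_all,
                                classify_domains, cluster_at_cutoffs,
                                group_hits, iterate, reconcile,
                                resolve_ambiguous)
from tandemaaa.domain_scan import DomainHit
from tandemaaa.phylo import SupportedTree, canonical_split, nj_from_alignment


def _random_seq(rng, n=100):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))


class TestAllVsAll:
    def test_identical_sequences_edge_at_every_cutoff(self):
        rng = np.random.default_rng(1)
        s = _random_seq(rng)
        segs = [ProteinSequence("a", s), ProteinSequence("b", s),
                ProteinSequence("c", _random_seq(rng))]
        g = all_vs_all(segs)
        assert g.graph.has_edge("a", "b")
        ev = g.graph.edges["a", "b"]["evalue"]
        assert ev <= min(g.cutoff_levels)
        for cutoff in g.cutoff_levels:
            comps = g.components_at(cutoff)
            assert any({"a", "b"} <= c for c in comps)

    def test_unrelated_random_pairs_rarely_linked(self):
        rng = np.random.default_rng(7)
        segs = [ProteinSequence(f"r{i}", _random_seq(rng))
                for i in range(30)]
        g = all_vs_all(segs, cutoff_levels=(1e-3,))
        # 435 independent null pairs: essentially none at E <= 1e-3
        assert g.graph.number_of_edges() <= 2

    def test_symmetric_evalues(self):
        rng = np.random.default_rng(3)
        segs = [ProteinSequence(f"s{i}", _random_seq(rng, 120))
                for i in range(4)]
        g = all_vs_all(segs, cutoff_levels=(1e3,))  # keep everything
        for u, v, d in g.graph.edges(data=True):
            assert g.graph.edges[v, u]["evalue"] == d["evalue"]

    def test_short_segments_excluded_with_warning(self):
        rng = np.random.default_rng(0)
        segs = [ProteinSequence("ok1", _random_seq(rng)),
                ProteinSequence("ok2", _random_seq(rng)),
                ProteinSequence("tiny", "MKV")]
        with pytest.warns(UserWarning, match="tiny"):
            g = all_vs_all(segs)
        assert "tiny" not in g.graph


def _graph_from_edges(nodes, edges):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, ev in edges:
        g.add_edge(u, v, weight=-math.log10(ev), evalue=ev)
    return g


class TestClustering:
    def test_two_cliques_stay_separate(self):
        nodes = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        edges = [(f"a{i}", f"a{j}", 1e-50) for i in range(5)
                 for j in range(i + 1, 5)]
        edges += [(f"b{i}", f"b{j}", 1e-50) for i in range(5)
                  for j in range(i + 1, 5)]
        g = SimilarityGraph(_graph_from_edges(nodes, edges),
                            (1e-5, 1e-20, 1e-40))
        h = cluster_at_cutoffs(g)
        for level in g.cutoff_levels:
            assert len(h.at_level(level)) == 2

    def test_weak_bridge_breaks_at_strict_cutoff(self):
        nodes = ["a1", "a2", "b1", "b2"]
        edges = [("a1", "a2", 1e-40), ("b1", "b2", 1e-40),
                 ("a2", "b1", 1e-8)]
        g = SimilarityGraph(_graph_from_edges(nodes, edges), (1e-5, 1e-20))
        h = cluster_at_cutoffs(g)
        assert len(h.at_level(1e-5)) == 1
        assert len(h.at_level(1e-20)) == 2

    def test_nesting_property_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(5, 25))
            nodes = [f"n{i}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.25:
                        ev = 10.0 ** (-rng.uniform(0, 60))
                        edges.append((nodes[i], nodes[j], ev))
            g = SimilarityGraph(_graph_from_edges(nodes, edges),
                                (1e-5, 1e-15, 1e-30, 1e-45))
            h = cluster_at_cutoffs(g)
            # independent check: brute-force components per level nest
            prev = None
            for cutoff in g.cutoff_levels:
                comps = {s.members for s in h.at_level(cutoff)}
                # each component must lie inside one looser component
                if prev is not None:
                    for c in comps:
                        assert sum(1 for p in prev if c <= p) == 1
                # cross-check against networkx on the thresholded graph
                w = -math.log10(cutoff)
                sub = nx.Graph()
                sub.add_nodes_from(nodes)
                sub.add_edges_from((u, v) for u, v, d
                                   in g.graph.edges(data=True)
                                   if d["weight"] >= w)
                want = {frozenset(c)
                        for c in nx.connected_components(sub)}
                assert comps == want
                prev = comps


def _supported_tree(newick: str, supports: dict) -> SupportedTree:
    from tandemaaa.seqio import read_newick
    t = read_newick(newick)
    leaves = frozenset(t.leaf_labels)
    sup = {canonical_split(k, leaves): v for k, v in supports.items()}
    return SupportedTree(tree=t, supports=sup)


class TestReconcile:
    def test_clusters_identical_to_clades(self):
        tree = _supported_tree(
            "((a1:1,a2:1):1,(b1:1,b2:1):1,c:3);",
            {frozenset({"a1", "a2"}): 100, frozenset({"b1", "b2"}): 100})
        g = SimilarityGraph(_graph_from_edges(
            ["a1", "a2", "b1", "b2", "c"],
            [("a1", "a2", 1e-40), ("b1", "b2", 1e-40)]), (1e-5, 1e-20))
        h = reconcile(cluster_at_cutoffs(g), tree)
        groups = {s.members for s in h.unified}
        assert frozenset({"a1", "a2"}) in groups
        assert frozenset({"b1", "b2"}) in groups
        assert all(s.provenance == "reconciled" for s in h.unified
                   if len(s.members) == 2)

    def test_cluster_conflicting_with_tree_resolved_by_tree(self):
        # x is cluster-linked to the a's but sits in the b clade
        tree = _supported_tree(
            "((a1:1,a2:1):1,(b1:1,(b2:1,x:1):0.5):1,c:3);",
            {frozenset({"a1", "a2"}): 100,
             frozenset({"b1", "b2", "x"}): 100,
             frozenset({"b2", "x"}): 95})
        g = SimilarityGraph(_graph_from_edges(
            ["a1", "a2", "b1", "b2", "x", "c"],
            [("a1", "a2", 1e-40), ("a1", "x", 1e-40),
             ("b1", "b2", 1e-40)]), (1e-5, 1e-20))
        h = reconcile(cluster_at_cutoffs(g), tree)
        # the {a1,a2,x} cluster is not a clade; the tree decides
        label_of = h.membership()
        assert label_of["a1"] == label_of["a2"]
        assert label_of["x"] != label_of["a1"]
        provs = {s.provenance for s in h.unified if "x" in s.members}
        assert provs <= {"clade-only"}

    def test_disjointness_of_unified_subgroups(self, small_dataset,
                                               small_state):
        from tandemaaa import pipeline as pl
        segs = pl.firm_domain_segments(small_state, small_dataset.proteins)
        aln = pl.joint_domain_alignment(small_state, segs)
        tree = pl.domain_tree(aln, n_reps=20, seed=2)
        h = pl.unified_domain_subgroups(segs, tree)
        seen = set()
        for s in h.unified:
            assert not (s.members & seen)
            seen |= s.members


def _hit(seq_id, model, start, end, bits, ev):
    return DomainHit(seq_id, model, start, end, bits, ev)


class TestClassifyDomains:
    @pytest.fixture()
    def library(self, small_library):
        return small_library

    def test_clear_winner_is_firm(self, library):
        groups = [[_hit("s", "Cdc48_D1", 0, 200, 100.0, 1e-40),
                   _hit("s", "NVL_D1", 0, 200, 40.0, 1e-10)]]
        (a,) = classify_domains(groups, library, margin_min=10.0)
        assert a.status == "firm" and a.label == "Cdc48_D1"
        assert a.margin_bits == pytest.approx(60.0)

    def test_close_competitors_are_ambiguous(self, library):
        groups = [[_hit("s", "Cdc48_D1", 0, 200, 52.0, 1e-8),
                   _hit("s", "NVL_D1", 0, 200, 50.0, 1e-7)]]
        (a,) = classify_domains(groups, library, margin_min=10.0)
        assert a.status == "ambiguous"

    def test_nothing_under_soft_bound_is_unclassified(self, library):
        groups = [[_hit("s", "Cdc48_D1", 0, 200, 5.0, 0.5)]]
        (a,) = classify_domains(groups, library, margin_min=10.0)
        assert a.status == "unclassified" and a.label == ""

    def test_under_soft_but_not_strict_is_provisional(self, library):
        groups = [[_hit("s", "Cdc48_D1", 0, 200, 20.0, 1e-4)]]
        (a,) = classify_domains(groups, library, margin_min=10.0)
        assert a.status == "provisional"


class TestGroupHits:
    def test_overlapping_envelopes_grouped(self):
        hits = [_hit("s", "m1", 0, 100, 50, 1e-20),
                _hit("s", "m2", 5, 95, 40, 1e-15),
                _hit("s", "m3", 200, 300, 60, 1e-25)]
        groups = group_hits(hits)
        assert len(groups) == 2
        assert {h.model_name for h in groups[0]} == {"m1", "m2"}


class TestResolveAmbiguous:
    def test_exact_exemplar_match_assigns(self):
        rng = np.random.default_rng(4)
        a_seq = _random_seq(rng, 120)
        b_seq = _random_seq(rng, 120)
        seg = ProteinSequence("q", a_seq)
        r = resolve_ambiguous(
            seg, ["A", "B"],
            {"A": [ProteinSequence("ea", a_seq)],
             "B": [ProteinSequence("eb", b_seq)]})
        assert r.label == "A" and r.status == "provisional"

    def test_symmetric_tie_stays_ambiguous(self):
        rng = np.random.default_rng(4)
        ex = _random_seq(rng, 120)
        seg = ProteinSequence("q", _random_seq(rng, 120))
        r = resolve_ambiguous(
            seg, ["A", "B"],
            {"A": [ProteinSequence("ea", ex)],
             "B": [ProteinSequence("eb", ex)]})
        assert r.status == "ambiguous"

    def test_majority_mixture_recovers_dominant_subgroup(self):
        # an intermediate built from 60 % of one exemplar and 40 % of
        # another is assigned to the majority source
        rng = np.random.default_rng(10)
        wins = 0
        trials = 10
        for k in range(trials):
            rng_k = np.random.default_rng(100 + k)
            a_seq = _random_seq(rng_k, 150)
            b_seq = _random_seq(rng_k, 150)
            cut = 90   # 60 %
            mix = a_seq[:cut] + b_seq[cut:]
            r = resolve_ambiguous(
                ProteinSequence("q", mix), ["A", "B"],
                {"A": [ProteinSequence("ea", a_seq)],
                 "B": [ProteinSequence("eb", b_seq)]})
            if r.label == "A" and r.status != "ambiguous":
                wins += 1
        assert wins >= 8   # >= 80 % of seeds

    def test_requires_two_candidates(self):
        seg = ProteinSequence("q", "MKVLT" * 10)
        with pytest.raises(ValueError):
            resolve_ambiguous(seg, ["A"], {})


class TestIterate:
    def test_database_of_seeds_is_a_fixed_point(self, small_dataset):
        from tandemaaa import pipeline as pl
        seeds = pl.seed_truth_alignments(small_dataset, k_species=6)
        db = [aln.degapped(rid) for name, aln in seeds.items()
              for rid in list(aln.rows)[:3]]
        # make ids unique across the two domain alignments of a protein
        db = [ProteinSequence(f"{s.id}#{i}", s.residues)
              for i, s in enumerate(db)]
        cfg = ClassifyConfig(seed=1, calibration_n=1000, max_iter=4)
        state = iterate(seeds, db, cfg)
        assert state.converged
        assert state.changed_count == 0
        assert state.iteration == 1

    def test_converged_labels_match_planted_families(self, small_dataset,
                                                     small_state):
        from tandemaaa.domain_scan import model_family
        truth = {r.protein_id: r.family
                 for _, r in small_dataset.truth.iterrows()}
        firm = small_state.firm()
        n_domains = 2 * len(small_dataset.proteins)
        correct = sum(1 for a in firm
                      if model_family(a.label) == truth[a.seq_id])
        assert small_state.converged
        assert correct / n_domains >= 0.95

    def test_firm_training_set_grows_monotonically(self, small_state):
        sizes = [a["new_firm_rows"] for a in small_state.audit
                 if "new_firm_rows" in a]
        assert all(s >= 0 for s in sizes)
        # determinism: rebuilding from the same config gives the same table
        # (covered in acceptance; here check the audit is self-consistent)
        counts = [a["status_counts"] for a in small_state.audit
                  if "status_counts" in a]
        assert counts[-1].get("firm", 0) >= counts[0].get("firm", 0)

    def test_deterministic_under_seed(self, small_dataset):
        from tandemaaa import pipeline as pl
        cfg = ClassifyConfig(seed=7, calibration_n=1000, max_iter=3)
        s1 = pl.run_iterative_classification(small_dataset, cfg)
        s2 = pl.run_iterative_classification(small_dataset, cfg)
        t1 = s1.assignment_table()
        t2 = s2.assignment_table()
        assert t1.equals(t2)
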