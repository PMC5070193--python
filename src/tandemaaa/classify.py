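"""The core classification loop: similarity clustering + tree clades
reconciled into subgroups, per-domain assignment with strict/soft E-value
bounds and bit-score margins, and iterative model retraining to a fixed
point.

Two independent groupings of the domain segments are built -- connected
components of a Smith-Waterman similarity graph at a ladder of E-value
cutoffs, and supported clades of a domain tree -- and reconciled top-down:
a subgroup is accepted when it is simultaneously a connected cluster at
some cutoff and a monophyletic group with sufficient support; a cluster
that conflicts with the tree is split along the next stricter cutoff
level (the smallest set satisfying both wins the conflict).

The pairwise engine is an in-repo affine Smith-Waterman over BLOSUM62
(11/1 gap costs) with Karlin-Altschul style E-values
``E = K * m * n * 2^(-S_bits)``; only the relative ordering of E-values
matters for clustering, so K is a fixed nuisance constant.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from . import _kernels
from .domain_scan import DomainHit, model_role, scan_sequence
from .profile_hmm import (ProfileHMM, blosum62_matrix, build_hmm, calibrate,
                          encode_sequence, filter_alignment, viterbi,
                          viterbi_bits)
from .phylo import SupportedTree
from .seqio import MultipleAlignment, ProteinSequence

__all__ = [
    "SimilarityGraph",
    "Subgroup",
    "SubgroupHierarchy",
    "SubgroupAssignment",
    "ClassificationState",
    "ClassifyConfig",
    "all_vs_all",
    "cluster_at_cutoffs",
    "reconcile",
    "classify_domains",
    "resolve_ambiguous",
    "iterate",
    "group_hits",
]

#: Default E-value cutoff ladder, loosest first (strictly increasing
#: stringency).
DEFAULT_CUTOFFS = (1e-5, 1e-10, 1e-20, 1e-30, 1e-45)

#: Gapped Karlin-Altschul slope for BLOSUM62 with 11/1 gap costs
#: (nats per raw score unit); K is an arbitrary fixed scale.
KA_LAMBDA = 0.267
KA_K = 0.1


@dataclass
class SimilarityGraph:
    """Undirected segment-similarity graph.

    Edge weights are ``-log10 E`` (clamped at 0); ``cutoff_levels`` is the
    descending ladder of E-value thresholds used for hierarchical
    clustering.
    """

    graph: nx.Graph
    cutoff_levels: tuple[float, ...] = DEFAULT_CUTOFFS

    def components_at(self, cutoff: float) -> list[frozenset]:
        w = -math.log10(cutoff)
        sub = nx.Graph()
        sub.add_nodes_from(self.graph.nodes)
        sub.add_edges_from(
            (u, v) for u, v, d in self.graph.edges(data=True)
            if d["weight"] >= w)
        return [frozenset(c) for c in nx.connected_components(sub)]


def sw_bits(raw_score: float) -> float:
    return KA_LAMBDA * raw_score / math.log(2.0)


def karlin_altschul_evalue(bits: float, m: int, n: int, K: float = KA_K) -> float:
    return K * m * n * math.pow(2.0, -bits)


def all_vs_all(segments: Sequence[ProteinSequence],
               gap_open: float = 11.0, gap_extend: float = 1.0,
               K: float = KA_K,
               cutoff_levels: Sequence[float] = DEFAULT_CUTOFFS,
               min_length: int = 10) -> SimilarityGraph:
    """All-pairs local-alignment similarity graph.

    Segments shorter than ``min_length`` are excluded with a warning.
    An edge is kept when its E-value is at or below the loosest cutoff.
    """
    keep = []
    for s in segments:
        if len(s) < min_length:
            warnings.warn(f"segment {s.id!r} shorter than {min_length}; excluded")
        else:
            keep.append(s)
    if len(keep) < 2:
        raise ValueError("need at least 2 segments")
    levels = tuple(cutoff_levels)
    if any(levels[i] <= levels[i + 1] for i in range(len(levels) - 1)):
        raise ValueError("cutoff_levels must be strictly decreasing E-values")
    n = len(keep)
    maxlen = max(len(s) for s in keep)
    padded = np.zeros((n, maxlen), dtype=np.int8)
    lengths = np.empty(n, dtype=np.int64)
    for i, s in enumerate(keep):
        enc = encode_sequence(s.residues)
        padded[i, :len(enc)] = enc
        lengths[i] = len(enc)
    raw = _kernels.sw_all_pairs(padded, lengths, blosum62_matrix(),
                                float(gap_open), float(gap_extend))
    g = nx.Graph()
    g.add_nodes_from(s.id for s in keep)
    loosest = max(levels)
    for i in range(n):
        for j in range(i + 1, n):
            bits = sw_bits(raw[i, j])
            ev = karlin_altschul_evalue(bits, int(lengths[i]),
                                        int(lengths[j]), K)
            if ev <= loosest:
                g.add_edge(keep[i].id, keep[j].id,
                           weight=max(0.0, -math.log10(max(ev, 1e-300))),
                           evalue=ev, bits=bits)
    return SimilarityGraph(graph=g, cutoff_levels=levels)


@dataclass(frozen=True)
class Subgroup:
    label: str
    members: frozenset
    level: float | None = None
    provenance: str = "cluster-only"    # cluster-only | clade-only | reconciled
    parent: str | None = None


@dataclass
class SubgroupHierarchy:
    """Labeled subgroups, nested over cutoff levels."""

    subgroups: list[Subgroup]
    cutoff_levels: tuple[float, ...] = ()

    def at_level(self, cutoff: float) -> list[Subgroup]:
        return [s for s in self.subgroups if s.level == cutoff]

    @property
    def unified(self) -> list[Subgroup]:
        """Subgroups without a parent in the hierarchy (the classification
        actually used downstream)."""
        labels = {s.label for s in self.subgroups}
        return [s for s in self.subgroups
                if s.parent is None or s.parent not in labels]

    def membership(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for s in self.unified:
            for m in s.members:
                out[m] = s.label
        return out


def cluster_at_cutoffs(graph: SimilarityGraph,
                       cutoff_levels: Sequence[float] | None = None
                       ) -> SubgroupHierarchy:
    """Connected components at each cutoff, nested into a hierarchy.

    Components at stricter cutoffs nest inside looser ones (edges only
    disappear as the threshold tightens), which yields the parent links.
    """
    levels = tuple(cutoff_levels) if cutoff_levels is not None \
        else graph.cutoff_levels
    if any(levels[i] <= levels[i + 1] for i in range(len(levels) - 1)):
        raise ValueError("cutoff_levels must be strictly decreasing E-values")
    subgroups: list[Subgroup] = []
    parent_of: dict[frozenset, str] = {}
    for li, cutoff in enumerate(levels):
        comps = sorted(graph.components_at(cutoff),
                       key=lambda c: (-len(c), min(c)))
        for k, comp in enumerate(comps):
            label = f"L{li}.{k}"
            parent = None
            if li > 0:
                for pcomp, plabel in parent_of.items():
                    if comp <= pcomp:
                        parent = plabel
                        break
            subgroups.append(Subgroup(label, comp, cutoff, "cluster-only",
                                      parent))
        parent_of = {s.members: s.label for s in subgroups
                     if s.level == cutoff}
    return SubgroupHierarchy(subgroups=subgroups, cutoff_levels=levels)


def reconcile(clusters: SubgroupHierarchy, tree: SupportedTree,
              support_min: float = 70.0,
              prefer: str = "tree") -> SubgroupHierarchy:
    """Reconcile the cluster hierarchy with the domain tree.

    Top-down: each loosest-level component that is monophyletic in the
    tree (support >= ``support_min``) becomes a unified subgroup with
    provenance "reconciled"; a component in conflict with the tree is
    split into its sub-components at the next stricter cutoff and the
    test recurses (preferring the smallest set satisfying both).  A set
    still unacceptable at the strictest level is resolved by the tree
    (maximal supported clades inside it, provenance "clade-only") when
    ``prefer='tree'``, else accepted as "cluster-only".
    """
    leaves = frozenset(tree.leaf_labels)
    levels = clusters.cutoff_levels
    supported = tree.supported_clades(support_min)
    by_level = [sorted(clusters.at_level(c), key=lambda s: (-len(s.members),
                                                            min(s.members)))
                for c in levels]

    def is_accepted_clade(mem: frozenset) -> bool:
        mt = mem & leaves
        if not mt or mt != mem:
            return False
        if len(mt) == 1:
            return True
        # the full leaf set and its trivial complements are not subgroups,
        # and no single subgroup may absorb the majority of all domains
        # (an unrooted bipartition whose small side is a clade would
        # otherwise accept the large side via its complement)
        if len(mt) >= len(leaves) - 1 or len(mt) > len(leaves) // 2:
            return False
        from .phylo import canonical_split
        return canonical_split(mt, leaves) in supported

    accepted: list[Subgroup] = []

    def maximal_supported_within(mem: frozenset) -> list[frozenset]:
        cands = [c for c in supported
                 if (c <= mem or (leaves - c) <= mem)]
        sets = []
        for c in cands:
            s = c if c <= mem else (leaves - c)
            sets.append(s)
        sets += [frozenset([m]) for m in mem]
        sets.sort(key=lambda s: (-len(s), min(s)))
        out: list[frozenset] = []
        covered: set = set()
        for s in sets:
            if s and not (s & covered):
                out.append(s)
                covered |= s
        return out

    def descend(mem: frozenset, li: int) -> None:
        if is_accepted_clade(mem):
            accepted.append(Subgroup(f"U{len(accepted)}", mem,
                                     levels[li] if li < len(levels) else None,
                                     "reconciled"))
            return
        for lj in range(li + 1, len(levels)):
            subs = [s.members & mem for s in by_level[lj]
                    if s.members & mem]
            subs = [s for s in subs if s]
            if len(subs) > 1:
                for s in subs:
                    descend(s, lj)
                return
        # bottom of the ladder: cluster and tree still conflict
        if prefer == "tree" and (mem & leaves):
            for s in maximal_supported_within(mem & leaves):
                accepted.append(Subgroup(f"U{len(accepted)}", s, None,
                                         "clade-only"))
            rest = mem - leaves
            if rest:
                accepted.append(Subgroup(f"U{len(accepted)}", rest, None,
                                         "cluster-only"))
        else:
            accepted.append(Subgroup(f"U{len(accepted)}", mem, None,
                                     "cluster-only"))

    for s in by_level[0]:
        descend(s.members, 0)
    return SubgroupHierarchy(subgroups=accepted, cutoff_levels=levels)


# ---------------------------------------------------------------------------
# Per-domain assignment

@dataclass
class SubgroupAssignment:
    """Classification of one domain segment."""

    seq_id: str
    start: int
    end: int
    label: str
    best_bits: float
    margin_bits: float
    evalue: float
    status: str        # firm | provisional | ambiguous | unclassified

    @property
    def segment_id(self) -> str:
        return f"{self.seq_id}/{self.start}-{self.end}"


def group_hits(hits: Iterable[DomainHit]) -> list[list[DomainHit]]:
    """Group hits by > 50 % reciprocal envelope overlap (best hit first)."""
    groups: list[list[DomainHit]] = []
    for h in sorted(hits, key=lambda h: (h.evalue, -h.bits, h.model_name)):
        for g in groups:
            if h.overlap_frac(g[0]) > 0.5:
                g.append(h)
                break
        else:
            groups.append([h])
    groups.sort(key=lambda g: g[0].start)
    return groups


def classify_domains(hit_groups: Iterable[list[DomainHit]],
                     library: Mapping[str, ProfileHMM],
                     margin_min: float = 10.0) -> list[SubgroupAssignment]:
    """Assign each envelope group to its best model.

    firm: best E-value within the model's strict bound and the bit-score
    margin over the runner-up model at least ``margin_min``; ambiguous:
    two or more models under their soft bounds separated by less than the
    margin; provisional: under the soft but not the strict bound;
    unclassified: no model under its soft bound.
    """
    out: list[SubgroupAssignment] = []
    for group in hit_groups:
        if not group:
            continue
        best = group[0]
        under_soft = [h for h in group
                      if h.evalue <= library[h.model_name].soft_evalue]
        if not under_soft:
            out.append(SubgroupAssignment(
                best.seq_id, best.start, best.end, "", best.bits,
                math.inf, best.evalue, "unclassified"))
            continue
        best = under_soft[0]
        runners = [h for h in group if h.model_name != best.model_name]
        margin = best.bits - runners[0].bits if runners else math.inf
        strict_ok = best.evalue <= library[best.model_name].strict_evalue
        n_soft_models = len({h.model_name for h in under_soft})
        if margin < margin_min and n_soft_models >= 2:
            status = "ambiguous"
        elif strict_ok and margin >= margin_min:
            status = "firm"
        else:
            status = "provisional"
        out.append(SubgroupAssignment(
            best.seq_id, best.start, best.end, best.model_name,
            best.bits, margin, best.evalue, status))
    return out


def resolve_ambiguous(segment: ProteinSequence,
                      candidates: Sequence[str],
                      exemplars: Mapping[str, Sequence[ProteinSequence]],
                      k_nearest: int = 3, min_gap_bits: float = 2.0,
                      gap_open: float = 11.0, gap_extend: float = 1.0
                      ) -> SubgroupAssignment:
    """Refine an ambiguous segment by pairwise alignment to exemplars.

    The segment is aligned to the ``k_nearest`` best-scoring exemplars of
    each candidate subgroup; it is assigned to the subgroup with the
    highest mean bit score if the gap to the runner-up mean is at least
    ``min_gap_bits``, otherwise it stays ambiguous.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate subgroups")
    sub = blosum62_matrix()
    enc = encode_sequence(segment.residues)
    means: dict[str, float] = {}
    for cand in candidates:
        scores = []
        for ex in exemplars.get(cand, ()):
            raw = _kernels.sw_score(enc, encode_sequence(ex.residues), sub,
                                    float(gap_open), float(gap_extend))
            scores.append(sw_bits(raw))
        if not scores:
            continue
        scores.sort(reverse=True)
        means[cand] = float(np.mean(scores[:k_nearest]))
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) >= 2 and ranked[0][1] - ranked[1][1] >= min_gap_bits:
        label, bits = ranked[0]
        status = "provisional"   # exemplar-resolved; never trains
        margin = ranked[0][1] - ranked[1][1]
    elif len(ranked) == 1:
        label, bits = ranked[0]
        status = "provisional"
        margin = math.inf
    else:
        label, bits = (ranked[0] if ranked else ("", 0.0))
        status = "ambiguous"
        margin = ranked[0][1] - ranked[1][1] if len(ranked) >= 2 else 0.0
    return SubgroupAssignment(segment.id, 0, len(segment), label,
                              bits, margin, math.nan, status)


# ---------------------------------------------------------------------------
# Iterative retraining

@dataclass
class ClassifyConfig:
    """Knobs of the iterative classification loop."""

    margin_min: float = 10.0
    max_iter: int = 10
    pseudocount_strength: float = 20.0
    calibration_n: int = 1000
    calibration_length: int = 400
    strict_evalue: float = 1e-6
    soft_evalue: float = 1e-3
    seed: int = 0
    col_gap_max: float = 0.5
    row_gap_max: float = 0.5


@dataclass
class ClassificationState:
    """State of the iterative loop after (partial) convergence."""

    iteration: int
    library: dict[str, ProfileHMM]
    assignments: list[SubgroupAssignment]
    changed_count: int
    converged: bool
    training: dict[str, MultipleAlignment]
    audit: list[dict] = field(default_factory=list)

    def assignment_table(self) -> "object":
        import pandas as pd
        return pd.DataFrame([{
            "seq_id": a.seq_id, "start": a.start, "end": a.end,
            "label": a.label, "bits": round(a.best_bits, 2),
            "margin": (round(a.margin_bits, 2)
                       if math.isfinite(a.margin_bits) else math.inf),
            "evalue": a.evalue, "status": a.status,
        } for a in sorted(self.assignments,
                          key=lambda a: (a.seq_id, a.start))])

    def firm(self) -> list[SubgroupAssignment]:
        return [a for a in self.assignments if a.status == "firm"]


def _build_library(training: Mapping[str, MultipleAlignment],
                   cfg: ClassifyConfig, seed: int
                   ) -> dict[str, ProfileHMM]:
    library: dict[str, ProfileHMM] = {}
    for name, aln in training.items():
        hmm = build_hmm(aln, name,
                        pseudocount_strength=cfg.pseudocount_strength)
        hmm.strict_evalue = cfg.strict_evalue
        hmm.soft_evalue = cfg.soft_evalue
        rng = np.random.default_rng(
            [seed, zlib.crc32(name.encode()) % (2 ** 31)])
        calibrate(hmm, n_random=cfg.calibration_n,
                  length_law=("fixed", cfg.calibration_length), seed=rng)
        library[name] = hmm
    return library


def _scan_db(database: Sequence[ProteinSequence],
             library: Mapping[str, ProfileHMM], cfg: ClassifyConfig
             ) -> dict[str, list[list[DomainHit]]]:
    """Per-protein envelope groups; a cheap score-only prefilter skips
    models whose whole-sequence score cannot pass the soft bound."""
    n_db = len(database)
    groups: dict[str, list[list[DomainHit]]] = {}
    for seq in database:
        passing = {}
        for name, hmm in library.items():
            bits = viterbi_bits(hmm, seq.residues)
            if hmm.evalue(bits, n_db) <= hmm.soft_evalue:
                passing[name] = hmm
        if not passing:
            groups[seq.id] = []
            continue
        hits = scan_sequence(seq, passing, max_reported=4, n_database=n_db)
        hits = [h for h in hits
                if h.evalue <= library[h.model_name].soft_evalue]
        groups[seq.id] = group_hits(hits)
    return groups


def _signature(assignments: Iterable[SubgroupAssignment]) -> tuple:
    per_seq: dict[str, list] = {}
    for a in assignments:
        per_seq.setdefault(a.seq_id, []).append((a.start, a.label, a.status))
    return tuple(sorted((sid, tuple(sorted(v)))
                        for sid, v in per_seq.items()))


def _labels_of(assignments: Iterable[SubgroupAssignment]
               ) -> dict[tuple[str, int], tuple[str, str]]:
    out: dict[tuple[str, int], tuple[str, str]] = {}
    per_seq: dict[str, list[SubgroupAssignment]] = {}
    for a in assignments:
        per_seq.setdefault(a.seq_id, []).append(a)
    for sid, lst in per_seq.items():
        for k, a in enumerate(sorted(lst, key=lambda a: a.start)):
            out[(sid, k)] = (a.label, a.status)
    return out


def iterate(seed_alignments: Mapping[str, MultipleAlignment],
            database: Sequence[ProteinSequence],
            config: ClassifyConfig | None = None) -> ClassificationState:
    """Build + calibrate subgroup models, scan, classify, grow the
    training alignments with firm members, and repeat to a fixed point.

    Only firm assignments ever enter the training alignments (provisional
    and ambiguous members never train), and the firm training set grows
    monotonically.  Convergence is zero label/status changes; oscillation
    (a repeated assignment table) stops the loop and returns the best
    state by changed count.
    """
    if not seed_alignments:
        raise ValueError("need at least one seed alignment")
    cfg = config or ClassifyConfig()
    # pin the match-column system once: filter the seed alignments here and
    # never re-filter, so firm member rows (rendered on the model's match
    # columns) stay width-compatible across iterations
    seeds = {name: filter_alignment(aln, cfg.col_gap_max, cfg.row_gap_max)[0]
             for name, aln in seed_alignments.items()}
    firm_rows: dict[str, dict[str, str]] = {n: {} for n in seeds}
    prev_labels: dict | None = None
    seen_signatures: dict[tuple, int] = {}
    audit: list[dict] = []
    best_state: ClassificationState | None = None

    for it in range(cfg.max_iter):
        training = {}
        for name, seed_aln in seeds.items():
            rows = dict(seed_aln.rows)
            for rid, row in firm_rows[name].items():
                if rid not in rows:
                    rows[rid] = row
            training[name] = MultipleAlignment(rows, meta=seed_aln.meta)
        library = _build_library(training, cfg, cfg.seed)
        groups_by_seq = _scan_db(database, library, cfg)
        assignments = [a for groups in groups_by_seq.values()
                       for a in classify_domains(groups, library,
                                                 cfg.margin_min)]
        # route ambiguous segments through exemplar-based refinement
        seq_by_id = {s.id: s for s in database}
        groups_flat = {f"{g[0].seq_id}/{g[0].start}-{g[0].end}": g
                       for groups in groups_by_seq.values()
                       for g in groups if g}
        exemplars = {
            name: [aln.degapped(rid) for rid in list(aln.rows)[:3]]
            for name, aln in training.items()}
        for k, a in enumerate(assignments):
            if a.status != "ambiguous":
                continue
            g = groups_flat.get(a.segment_id)
            if not g:
                continue
            cands = sorted({h.model_name for h in g
                            if h.evalue <= library[h.model_name].soft_evalue})
            if len(cands) < 2:
                continue
            seq = seq_by_id[a.seq_id]
            seg = ProteinSequence(a.segment_id,
                                  seq.residues[a.start:a.end],
                                  species=seq.species)
            r = resolve_ambiguous(seg, cands, exemplars)
            if r.status != "ambiguous":
                assignments[k] = SubgroupAssignment(
                    a.seq_id, a.start, a.end, r.label, a.best_bits,
                    r.margin_bits, a.evalue, "provisional")
        labels = _labels_of(assignments)
        if prev_labels is None:
            changed = len(labels)
        else:
            keys = set(labels) | set(prev_labels)
            changed = sum(1 for k in keys
                          if labels.get(k) != prev_labels.get(k))
        # grow training sets with newly firm members, re-aligned to the
        # current model's match columns
        by_group: dict[str, list[DomainHit]] = {}
        for sid, groups in groups_by_seq.items():
            for g in groups:
                if g:
                    key = f"{g[0].seq_id}/{g[0].start}-{g[0].end}"
                    by_group[key] = g
        n_new = 0
        for a in assignments:
            if a.status != "firm":
                continue
            g = by_group.get(a.segment_id)
            if not g:
                continue
            hit = g[0]
            if hit.path is None:
                continue
            seq = next(s for s in database if s.id == a.seq_id)
            row = hit.path.aligned_row(seq.residues, library[a.label].L)
            rid = a.segment_id
            if rid not in firm_rows[a.label]:
                firm_rows[a.label][rid] = row
                n_new += 1
        state = ClassificationState(
            iteration=it + 1, library=library, assignments=assignments,
            changed_count=changed, converged=(changed == 0),
            training=training, audit=audit)
        n_status = {}
        for a in assignments:
            n_status[a.status] = n_status.get(a.status, 0) + 1
        audit.append({"iteration": it + 1, "changed": changed,
                      "new_firm_rows": n_new, "status_counts": n_status,
                      "n_segments": len(assignments)})
        if best_state is None or changed < best_state.changed_count:
            best_state = state
        if prev_labels is not None and changed == 0:
            state.iteration = it   # classification stabilized one pass ago
            return state
        sig = _signature(assignments)
        if sig in seen_signatures:
            audit.append({"oscillation_detected_at": it + 1,
                          "first_seen": seen_signatures[sig]})
            return best_state
        seen_signatures[sig] = it + 1
        prev_labels = labels
    return best_state
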