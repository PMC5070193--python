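"""End-to-end pipeline drivers.

Glue that connects the stages on a dataset with known seed material:
seed alignments -> iterative classification -> firm domain segments ->
similarity graph + domain tree -> reconciled subgroups -> presence/absence
matrix -> ancestral repertoires.  Used by the command-line interface, the
acceptance script and the examples; every stage is also usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classify import (ClassificationState, ClassifyConfig, all_vs_all,
                       cluster_at_cutoffs, iterate, reconcile,
                       SubgroupHierarchy, DEFAULT_CUTOFFS)
from .domain_scan import model_family, model_role
from .phylo import SupportedTree, bootstrap
from .profile_hmm import ProfileHMM, align_profiles, build_hmm, \
    filter_alignment, viterbi
from .seqio import MultipleAlignment, ProteinSequence
from .synthgen import Dataset, true_alignment

__all__ = [
    "seed_truth_alignments",
    "run_iterative_classification",
    "firm_domain_segments",
    "general_domain_model",
    "align_segments_to_model",
    "joint_domain_alignment",
    "domain_tree",
    "unified_domain_subgroups",
    "count_subgroups",
    "PipelineResult",
    "run_full_pipeline",
]


def seed_truth_alignments(dataset: Dataset, k_species: int = 6,
                          segments: Sequence[str] = ("D1", "D2"),
                          include_accessory: bool = False
                          ) -> dict[str, MultipleAlignment]:
    """Per-family-domain seed alignments from the generator's truth.

    Takes the first ``k_species`` (alphabetically) possessing each family
    and extracts the true per-segment alignment; model names follow the
    ``<family>_<role>`` convention.  With ``include_accessory`` the
    N-domain alignments and the shared tail-helix alignment are added.
    """
    seeds: dict[str, MultipleAlignment] = {}
    for fam in dataset.config.families:
        have = sorted(dataset.truth[dataset.truth.family == fam.name]
                      .species.unique())[:k_species]
        want = list(segments)
        if include_accessory and fam.has_N_domain:
            want.append("N")
        for seg in want:
            try:
                aln = true_alignment(dataset, fam.name, seg, species=have)
            except KeyError:
                continue
            seeds[f"{fam.name}_{seg}"] = aln
    if include_accessory:
        tail_fams = [f.name for f in dataset.config.families if f.tail_helix]
        rows = {}
        width = None
        for fam in tail_fams[:3]:
            have = sorted(dataset.truth[dataset.truth.family == fam]
                          .species.unique())[:k_species]
            aln = true_alignment(dataset, fam, "tail", species=have)
            # families with a C-terminal HbYX extension have 3 extra
            # columns; pool on the shared tail-helix core
            width = aln.ncols if width is None else min(width, aln.ncols)
            rows.update(aln.rows)
        if rows:
            seeds["tail_helix"] = MultipleAlignment(
                {rid: row[:width] for rid, row in rows.items()})
    return seeds


def run_iterative_classification(dataset: Dataset,
                                 config: ClassifyConfig | None = None,
                                 k_species: int = 6) -> ClassificationState:
    """Seed from truth alignments and iterate to convergence."""
    cfg = config or ClassifyConfig(seed=dataset.seed)
    seeds = seed_truth_alignments(dataset, k_species=k_species)
    return iterate(seeds, dataset.proteins, cfg)


def firm_domain_segments(state: ClassificationState,
                         database: Sequence[ProteinSequence],
                         roles: Sequence[str] = ("D1", "D2")
                         ) -> list[ProteinSequence]:
    """Firm D-domain envelopes cut out as stand-alone segments."""
    by_id = {p.id: p for p in database}
    out = []
    for a in state.firm():
        if model_role(a.label) not in roles:
            continue
        p = by_id[a.seq_id]
        out.append(ProteinSequence(a.segment_id,
                                   p.residues[a.start:a.end],
                                   species=p.species))
    return out


def general_domain_model(seeds: Mapping[str, MultipleAlignment],
                         reference_family: str = "Cdc48") -> ProfileHMM:
    """The 'general AAA domain' model: the reference family's D1 and D2
    seed alignments joined by profile-profile alignment, then compiled
    into a single profile HMM used as a common coordinate system."""
    d1 = seeds[f"{reference_family}_D1"]
    d2 = seeds[f"{reference_family}_D2"]
    d1f, _ = filter_alignment(d1)
    d2f, _ = filter_alignment(d2)
    d2f = MultipleAlignment({f"{rid}::d2": row for rid, row in d2f.rows.items()})
    joined = align_profiles(d1f, d2f)
    joined_f, _ = filter_alignment(joined)
    return build_hmm(joined_f, "AAA_general")


def align_segments_to_model(segments: Sequence[ProteinSequence],
                            model: ProfileHMM) -> MultipleAlignment:
    """Implied multiple alignment: each segment rendered on the model's
    match columns via its glocal Viterbi path."""
    rows = {}
    meta = {}
    for s in segments:
        path = viterbi(model, s.residues)
        rows[s.id] = path.aligned_row(s.residues, model.L)
        meta[s.id] = s
    return MultipleAlignment(rows, meta=meta)


def joint_domain_alignment(state: ClassificationState,
                           segments: Sequence[ProteinSequence]
                           ) -> MultipleAlignment:
    """One joint alignment of all firm domain segments.

    Each segment is rendered on the match columns of the subgroup model
    it was firmly assigned to (exact within-subgroup homology), and the
    per-subgroup alignments are then joined progressively by
    profile-profile alignment into a single general D-domain alignment,
    largest subgroup first.
    """
    label_of = {a.segment_id: a.label for a in state.firm()}
    by_label: dict[str, dict[str, str]] = {}
    meta: dict[str, ProteinSequence] = {}
    for s in segments:
        lab = label_of.get(s.id)
        if lab is None or lab not in state.library:
            continue
        model = state.library[lab]
        path = viterbi(model, s.residues)
        by_label.setdefault(lab, {})[s.id] = path.aligned_row(s.residues,
                                                              model.L)
        meta[s.id] = s
    alns = [MultipleAlignment(rows) for lab, rows in
            sorted(by_label.items(), key=lambda kv: (-len(kv[1]), kv[0]))]
    if not alns:
        raise ValueError("no firm segments to align")
    joined = alns[0]
    for nxt in alns[1:]:
        joined = align_profiles(joined, nxt)
    joined.meta = meta
    return joined


def domain_tree(aln: MultipleAlignment, n_reps: int = 50,
                seed: int = 0) -> SupportedTree:
    """NJ + bootstrap tree of aligned domain segments."""
    return bootstrap(aln, n_reps=n_reps, seed=seed)


def unified_domain_subgroups(segments: Sequence[ProteinSequence],
                             tree: SupportedTree,
                             cutoff_levels: Sequence[float] = DEFAULT_CUTOFFS,
                             support_min: float = 70.0) -> SubgroupHierarchy:
    """Cluster the segments, build the hierarchy, reconcile with the tree."""
    graph = all_vs_all(segments, cutoff_levels=cutoff_levels)
    clusters = cluster_at_cutoffs(graph)
    return reconcile(clusters, tree, support_min=support_min)


def count_subgroups(hierarchy: SubgroupHierarchy, min_size: int = 2) -> int:
    """Number of unified subgroups with at least ``min_size`` members.

    A subgroup below that size cannot train a profile HMM, so stray
    fragments do not count toward the classification."""
    return sum(1 for s in hierarchy.unified if len(s.members) >= min_size)


@dataclass
class PipelineResult:
    """Everything the full synthetic-recovery pipeline produces."""

    dataset: Dataset
    state: ClassificationState
    segments: list[ProteinSequence]
    tree: SupportedTree
    hierarchy: SubgroupHierarchy
    n_eukaryotic_families: int
    n_unified_subgroups: int


def run_full_pipeline(seed: int = 0, config=None,
                      classify_config: ClassifyConfig | None = None,
                      n_boot: int = 50, support_min: float = 70.0
                      ) -> PipelineResult:
    """Generate a dataset, classify it, and reconcile subgroups.

    ``n_eukaryotic_families`` counts the distinct eukaryotic families
    with at least one firm full-tandem member in the converged
    classification; ``n_unified_subgroups`` counts the reconciled
    D-domain subgroups (archaeal outgroup included).
    """
    from .synthgen import generate
    ds = generate(config, seed=seed)
    state = run_iterative_classification(
        ds, classify_config or ClassifyConfig(seed=seed))
    arch_fams = {f.name for f in ds.config.families if f.archaeal}
    fams = {model_family(a.label) for a in state.firm()
            if model_role(a.label) in ("D1", "D2")}
    n_euk = len(fams - arch_fams)
    segments = firm_domain_segments(state, ds.proteins)
    seg_aln = joint_domain_alignment(state, segments)
    tree = domain_tree(seg_aln, n_reps=n_boot, seed=seed + 17)
    hierarchy = unified_domain_subgroups(segments, tree,
                                         support_min=support_min)
    return PipelineResult(
        dataset=ds, state=state, segments=segments, tree=tree,
        hierarchy=hierarchy, n_eukaryotic_families=n_euk,
        n_unified_subgroups=count_subgroups(hierarchy))
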