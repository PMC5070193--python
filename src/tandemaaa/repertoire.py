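"""Phyletic-pattern analytics: presence/absence matrices, Dollo ancestral
repertoires, the root (LECA) set, loss/duplication events, and the minimal
core shared by every genome.

Ancestral gene content is reconstructed under Dollo parsimony: each family
is gained exactly once -- at the most recent common ancestor of the
species possessing it -- and may subsequently be lost any number of times.
Given the single-gain constraint this placement minimizes the number of
losses.  Cells flagged as "uncertain absence" (e.g. incomplete genomes)
still count as absences for presence bookkeeping but are excluded from
loss calls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .classify import SubgroupAssignment
from .seqio import SpeciesTree

__all__ = [
    "PresenceAbsenceMatrix",
    "AncestralRepertoire",
    "build_matrix",
    "dollo_ancestral",
    "leca_set",
    "minimal_core",
    "find_duplications",
]


@dataclass
class PresenceAbsenceMatrix:
    """Species x family phyletic pattern with optional copy numbers."""

    data: pd.DataFrame       # bool, species rows x family columns
    copy_number: pd.DataFrame | None = None
    uncertain: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = self.data.astype(bool)
        if self.copy_number is not None:
            cn = self.copy_number.astype(int)
            a, d = cn.values, self.data.values
            if (a[d] < 1).any():
                raise ValueError("copy_number must be >= 1 where present")
            if (a[~d] != 0).any():
                raise ValueError("copy_number must be 0 where absent")
            self.copy_number = cn

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def families(self) -> list[str]:
        return list(self.data.columns)

    def row_set(self, species: str) -> frozenset:
        row = self.data.loc[species]
        return frozenset(row.index[row])

    def possessing(self, family: str) -> frozenset:
        col = self.data[family]
        return frozenset(col.index[col])

    def to_tsv(self, path: str | Path | None = None, counts: bool = False) -> str:
        df = self.copy_number if (counts and self.copy_number is not None) \
            else self.data.astype(int)
        text = df.to_csv(sep="\t")
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, source: str | Path) -> "PresenceAbsenceMatrix":
        text = str(source)
        if "\n" not in text:
            text = Path(source).read_text()
        import io
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
        counts = df.astype(int)
        return cls(data=counts > 0, copy_number=counts)


def build_matrix(assignments: Iterable[SubgroupAssignment],
                 species_map: Mapping[str, str],
                 families: Sequence[str] | None = None,
                 include_provisional: bool = False,
                 family_of_label=None) -> PresenceAbsenceMatrix:
    """Presence/absence matrix from converged subgroup assignments.

    A family is present in a species when at least one firm assignment
    (optionally also provisional) maps a protein of that species to the
    family; ``copy_number`` counts distinct proteins.  ``species_map``
    maps seq ids to species names; ``family_of_label`` converts an
    assignment label (e.g. ``Cdc48_D1``) to its family (default: strip
    the ``_D1``/``_D2``/``_N`` suffix).
    """
    from .domain_scan import model_family
    fam_of = family_of_label or model_family
    statuses = {"firm"} | ({"provisional"} if include_provisional else set())
    cells: dict[tuple[str, str], set[str]] = {}
    fams: set[str] = set(families or ())
    species_seen: set[str] = set()
    for a in assignments:
        if a.status not in statuses or not a.label:
            continue
        sp = species_map.get(a.seq_id)
        if sp is None:
            warnings.warn(f"{a.seq_id}: species unknown; grouped as 'unmapped'")
            sp = "unmapped"
        fam = fam_of(a.label)
        species_seen.add(sp)
        if families is None:
            fams.add(fam)
        elif fam not in fams:
            continue
        cells.setdefault((sp, fam), set()).add(a.seq_id)
    sp_list = sorted(species_seen) if species_seen else list(species_map.values())
    sp_list = sorted(set(sp_list))
    fam_list = list(families) if families is not None else sorted(fams)
    data = pd.DataFrame(False, index=sp_list, columns=fam_list)
    counts = pd.DataFrame(0, index=sp_list, columns=fam_list)
    for (sp, fam), ids in cells.items():
        if sp in data.index and fam in data.columns:
            data.loc[sp, fam] = True
            counts.loc[sp, fam] = len(ids)
    return PresenceAbsenceMatrix(data=data, copy_number=counts)


@dataclass
class AncestralRepertoire:
    """Per-node family sets plus the event ledger.

    Nodes are identified by the frozenset of leaf labels below them.
    Under Dollo each family has exactly one gain; losses lie strictly
    below it.
    """

    node_sets: dict[frozenset, frozenset]
    events: list[tuple[str, frozenset, str]]   # (family, branch-leafset, type)
    root_leaves: frozenset

    @property
    def root_set(self) -> frozenset:
        return self.node_sets[self.root_leaves]

    def losses(self, family: str | None = None
               ) -> list[tuple[str, frozenset, str]]:
        return [e for e in self.events if e[2] == "loss"
                and (family is None or e[0] == family)]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "root": sorted(self.root_set),
            "events": [{"family": f, "branch_to": sorted(b), "type": t}
                       for f, b, t in self.events],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _leafset(node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def dollo_ancestral(matrix: PresenceAbsenceMatrix, tree: SpeciesTree
                    ) -> AncestralRepertoire:
    """Dollo reconstruction of ancestral repertoires on a rooted tree.

    Per family: one gain at the MRCA of all possessing leaves; the family
    is present at every node on paths from that gain to possessing
    leaves; a loss is charged to every maximal branch below the gain
    leading only to non-possessing leaves.  Cells in
    ``matrix.uncertain`` are excluded from loss calls.
    """
    if len(tree.tree.seed_node.child_nodes()) != 2:
        raise ValueError("tree must be rooted (bifurcating root)")
    leaves = frozenset(tree.leaf_labels)
    missing = set(matrix.species) - leaves
    if missing:
        raise ValueError(f"matrix species not in tree: {sorted(missing)}")
    node_sets: dict[frozenset, set] = {}
    events: list[tuple[str, frozenset, str]] = []
    nodes = list(tree.tree.preorder_node_iter())
    for node in nodes:
        node_sets[_leafset(node)] = set()
    covered_species = set(matrix.species)
    for fam in matrix.families:
        have = matrix.possessing(fam)
        if not have:
            warnings.warn(f"family {fam!r} possessed by no species; skipped")
            continue
        mrca = tree.tree.mrca(taxon_labels=sorted(have)) if len(have) > 1 \
            else next(l for l in tree.tree.leaf_node_iter()
                      if l.taxon.label in have)
        gain_leaves = _leafset(mrca)
        events.append((fam, gain_leaves, "gain"))

        def mark(node) -> bool:
            """Present-below flag; fills node sets and loss events."""
            ls = _leafset(node)
            if node.is_leaf():
                lab = next(iter(ls))
                present = lab in have
                if present:
                    node_sets[ls].add(fam)
                return present or lab not in covered_species
            child_flags = [(c, mark(c)) for c in node.child_nodes()]
            present = any(f for _, f in child_flags)
            if present:
                node_sets[ls].add(fam)
                for child, f in child_flags:
                    if not f:
                        below = _leafset(child)
                        uncertain = all(
                            (sp, fam) in matrix.uncertain
                            for sp in below & covered_species)
                        if not uncertain:
                            events.append((fam, below, "loss"))
            return present

        mark(mrca)
    node_sets_frozen = {k: frozenset(v) for k, v in node_sets.items()}
    return AncestralRepertoire(node_sets=node_sets_frozen, events=events,
                               root_leaves=leaves)


def leca_set(ancestral: AncestralRepertoire) -> frozenset:
    """The repertoire at the root node of the reconstruction."""
    return ancestral.root_set


def minimal_core(matrix: PresenceAbsenceMatrix) -> frozenset:
    """Families present in every species: the intersection of row sets."""
    if not matrix.species:
        raise ValueError("matrix has no species")
    core = matrix.row_set(matrix.species[0])
    for sp in matrix.species[1:]:
        core &= matrix.row_set(sp)
    return core


def find_duplications(matrix: PresenceAbsenceMatrix | None = None,
                      tree: SpeciesTree | None = None,
                      gene_trees: Mapping[str, SpeciesTree] | None = None,
                      paralog_clades: Mapping[str, tuple[Iterable[str],
                                                         Iterable[str]]]
                      | None = None
                      ) -> list[tuple[str, object, str]]:
    """Report duplication events.

    Copy-number mode (``matrix`` with copy numbers): every species with
    copy_number >= 2 of a family is reported; when a species tree is
    given, contiguous multi-copy species are lifted to their MRCA (a
    lineage-level duplication covering >= 2 species).

    Tree mode (``gene_trees`` + ``paralog_clades``): for each family,
    the two paralog leaf-label sets are checked for monophyly in the gene
    tree and, when each covers >= 2 species, the duplication is mapped to
    the species-tree MRCA of the species involved.
    """
    events: list[tuple[str, object, str]] = []
    if matrix is not None and matrix.copy_number is not None:
        cn = matrix.copy_number
        for fam in matrix.families:
            multi = [sp for sp in matrix.species if cn.loc[sp, fam] >= 2]
            if not multi:
                continue
            if tree is not None and len(multi) >= 2:
                mrca = tree.tree.mrca(taxon_labels=multi)
                below = _leafset(mrca)
                events.append((fam, below, "duplication"))
            else:
                for sp in multi:
                    events.append((fam, sp, "duplication"))
    if gene_trees and paralog_clades:
        from .phylo import is_monophyletic
        for fam, (cladeA, cladeB) in paralog_clades.items():
            gt = gene_trees.get(fam)
            if gt is None:
                continue
            a, b = set(cladeA), set(cladeB)
            if is_monophyletic(gt, a) and is_monophyletic(gt, b) and \
                    len(a) >= 2 and len(b) >= 2:
                events.append((fam, frozenset(a | b), "duplication"))
    return events
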