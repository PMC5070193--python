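"""Readers/writers for the external formats the pipeline touches.

Three container types travel through the whole pipeline:

* :class:`ProteinSequence` -- a raw protein with species/lineage metadata
  carried in the FASTA header (``id|species|lineage1;lineage2;...``),
* :class:`MultipleAlignment` -- an ordered id -> aligned-row map,
* :class:`SpeciesTree` -- a thin wrapper around a dendropy tree.

All coordinates in the package are 0-based, half-open.  Parsing is strict:
duplicate ids, ragged alignments and unbalanced trees raise ``SeqIOError``
instead of being silently coerced.  The single documented coercion is the
mapping of uncommon residue letters (U, O, B, Z, J, *) to ``X``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "SeqIOError",
    "ProteinSequence",
    "MultipleAlignment",
    "SpeciesTree",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "write_newick",
    "read_species_map",
]

#: The 20 standard amino acids, in the fixed column order used by every
#: matrix in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Model alphabet: the 20 standard residues plus X for unknown.
ALPHABET = AMINO_ACIDS + "X"

GAP_CHARS = "-."

# letters tolerated on input and mapped to X (selenocysteine, pyrrolysine,
# ambiguity codes, stop)
_X_MAPPED = set("UOBZJ*")

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class SeqIOError(ValueError):
    """Raised on any malformed input."""


def _clean_residues(raw: str, record_id: str, map_x: bool = True) -> str:
    out = []
    warned = False
    for ch in raw.upper():
        if ch in AA_INDEX or ch == "X":
            out.append(ch)
        elif ch in _X_MAPPED and map_x:
            if not warned:
                warnings.warn(
                    f"{record_id}: uncommon residue letter(s) mapped to X",
                    stacklevel=3,
                )
                warned = True
            out.append("X")
        else:
            raise SeqIOError(f"{record_id}: invalid residue letter {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with species bookkeeping.

    ``residues`` is over the 20 amino-acid letters plus X; gap characters
    are forbidden (aligned rows live in :class:`MultipleAlignment`).
    """

    id: str
    residues: str
    species: str = ""
    lineage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence id must be nonempty")
        if len(self.residues) < 1:
            raise SeqIOError(f"{self.id}: empty sequence")
        for ch in self.residues:
            if ch not in AA_INDEX and ch != "X":
                raise SeqIOError(f"{self.id}: invalid residue letter {ch!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def header(self) -> str:
        """Round-trippable FASTA header ``id|species|lin1;lin2``."""
        parts = [self.id]
        if self.species or self.lineage:
            parts.append(self.species)
        if self.lineage:
            parts.append(";".join(self.lineage))
        return "|".join(parts)

    @classmethod
    def from_header(cls, header: str, residues: str) -> "ProteinSequence":
        fields = header.split("|")
        seq_id = fields[0].strip()
        species = fields[1].strip() if len(fields) > 1 else ""
        lineage: tuple[str, ...] = ()
        if len(fields) > 2 and fields[2].strip():
            lineage = tuple(t.strip() for t in fields[2].split(";") if t.strip())
        return cls(id=seq_id, residues=residues, species=species, lineage=lineage)


class MultipleAlignment:
    """An ordered map id -> aligned row over residues + ``-``.

    All rows share the same length ``ncols``; ``.`` and lowercase gaps are
    normalized to ``-`` on construction.  De-gapping any row yields a valid
    :class:`ProteinSequence` residue string.
    """

    def __init__(self, rows: Mapping[str, str] | Iterable[tuple[str, str]],
                 meta: Mapping[str, ProteinSequence] | None = None) -> None:
        items = list(rows.items()) if isinstance(rows, Mapping) else list(rows)
        if not items:
            raise SeqIOError("alignment has no rows")
        self.rows: dict[str, str] = {}
        ncols = None
        for rid, row in items:
            if rid in self.rows:
                raise SeqIOError(f"duplicate alignment row id {rid!r}")
            norm = row.upper().replace(".", "-")
            if ncols is None:
                ncols = len(norm)
            elif len(norm) != ncols:
                raise SeqIOError(
                    f"ragged alignment: row {rid!r} has length {len(norm)}, "
                    f"expected {ncols}")
            degapped = norm.replace("-", "")
            cleaned = _clean_residues(degapped, rid) if degapped else ""
            # re-insert the cleaned residues around the gaps
            it = iter(cleaned)
            norm = "".join(next(it) if ch != "-" else "-" for ch in norm)
            self.rows[rid] = norm
        if ncols is None or ncols < 1:
            raise SeqIOError("alignment has zero columns")
        self.ncols = ncols
        self.meta = dict(meta) if meta else {}

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def degapped(self, rid: str) -> ProteinSequence:
        meta = self.meta.get(rid)
        res = self.rows[rid].replace("-", "")
        if meta is not None:
            return ProteinSequence(rid, res, meta.species, meta.lineage)
        return ProteinSequence.from_header(rid, res)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows.values())

    def take_columns(self, cols: Iterable[int]) -> "MultipleAlignment":
        cols = list(cols)
        return MultipleAlignment(
            {rid: "".join(row[j] for j in cols) for rid, row in self.rows.items()},
            meta=self.meta,
        )


@dataclass
class SpeciesTree:
    """A rooted or unrooted tree with unique leaf labels.

    Wraps a :class:`dendropy.Tree`; branch lengths (nonnegative) and node
    supports (0-100) are optional annotations carried by dendropy.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise SeqIOError(f"duplicate leaf labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise SeqIOError("negative branch length")

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def clone(self) -> "SpeciesTree":
        return SpeciesTree(self.tree.clone(depth=1))

    def __str__(self) -> str:
        return write_newick(self)


# ---------------------------------------------------------------------------
# FASTA

def _iter_fasta(text: str):
    header = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].strip()
            chunks = []
        elif header is None:
            raise SeqIOError("FASTA text does not start with a header line")
        else:
            chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def read_fasta(path: str | Path, map_x: bool = True) -> list[ProteinSequence]:
    """Read a protein FASTA file into :class:`ProteinSequence` records.

    The header convention is ``id|species|lineage1;lineage2;...`` with the
    fields after ``id`` optional.  Duplicate ids and empty records are hard
    errors; non-amino-acid letters are errors unless ``map_x`` maps the
    uncommon set (U/O/B/Z/J/*) to X.
    """
    text = Path(path).read_text()
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for header, raw in _iter_fasta(text):
        seq_id = header.split("|")[0].strip()
        if not raw:
            raise SeqIOError(f"empty record {seq_id!r}")
        if seq_id in seen:
            raise SeqIOError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        residues = _clean_residues(raw, seq_id, map_x=map_x)
        records.append(ProteinSequence.from_header(header, residues))
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path,
                width: int = 60) -> None:
    lines = []
    for s in seqs:
        lines.append(">" + s.header)
        for i in range(0, len(s.residues), width):
            lines.append(s.residues[i:i + width])
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Alignments (aligned FASTA / Stockholm)

def read_alignment(path: str | Path, dialect: str | None = None) -> MultipleAlignment:
    """Read an alignment in aligned-FASTA or Stockholm dialect.

    ``dialect`` is auto-detected from the first line when not given.
    ``.`` and lowercase gap characters are normalized to ``-``.
    """
    text = Path(path).read_text()
    if dialect is None:
        dialect = "stockholm" if text.lstrip().startswith("# STOCKHOLM") else "afa"
    if dialect not in ("afa", "aligned-FASTA", "stockholm", "Stockholm"):
        raise SeqIOError(f"unknown alignment dialect {dialect!r}")
    rows: list[tuple[str, str]] = []
    meta: dict[str, ProteinSequence] = {}
    if dialect.lower().startswith("s"):
        acc: dict[str, list[str]] = {}
        order: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line == "//":
                continue
            try:
                name, chunk = line.split(None, 1)
            except ValueError as exc:
                raise SeqIOError(f"malformed Stockholm line: {line!r}") from exc
            if name not in acc:
                acc[name] = []
                order.append(name)
            acc[name].append(chunk.strip())
        rows = [(n, "".join(acc[n])) for n in order]
    else:
        for header, raw in _iter_fasta(text):
            ps_id = header.split("|")[0].strip()
            rows.append((ps_id, raw))
            degapped = raw.replace("-", "").replace(".", "")
            if degapped:
                meta[ps_id] = ProteinSequence.from_header(
                    header, _clean_residues(degapped, ps_id))
    if not rows:
        raise SeqIOError(f"no alignment rows in {path}")
    return MultipleAlignment(rows, meta=meta)


def write_alignment(aln: MultipleAlignment, path: str | Path,
                    dialect: str = "afa") -> None:
    if dialect.lower().startswith("s"):
        width = max(len(r) for r in aln.rows) + 2
        body = "\n".join(f"{rid:<{width}}{row}" for rid, row in aln.rows.items())
        Path(path).write_text(f"# STOCKHOLM 1.0\n{body}\n//\n")
    else:
        lines = []
        for rid, row in aln.rows.items():
            header = aln.meta[rid].header if rid in aln.meta else rid
            lines.append(">" + header)
            lines.append(row)
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trees

def _parse_newick(text: str) -> SpeciesTree:
    if text.count("(") != text.count(")"):
        raise SeqIOError("unbalanced parentheses in Newick text")
    if ";" not in text:
        raise SeqIOError("Newick text lacks terminating semicolon")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "uplicate" in msg:
            raise SeqIOError(f"duplicate leaf labels: {msg}") from exc
        raise SeqIOError(f"malformed Newick: {msg}") from exc
    if len(tree.seed_node.child_nodes()) == 2:
        tree.is_rooted = True
    return SpeciesTree(tree)


def read_newick(source: str | Path) -> SpeciesTree:
    """Parse a Newick tree (from a path or a literal string)."""
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    return _parse_newick(text)


def write_newick(tree: SpeciesTree, path: str | Path | None = None) -> str:
    text = tree.tree.as_string(
        schema="newick", suppress_rooting=True,
        unquoted_underscores=True).strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Species map

def read_species_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a TSV with columns ``species`` and ``lineage_path``.

    ``lineage_path`` is a ``;``-separated root-to-tip list of taxon names.
    """
    out: dict[str, tuple[str, ...]] = {}
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip() or (i == 0 and line.lower().startswith("species")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise SeqIOError(f"species map line {i + 1}: expected 2 columns")
        out[parts[0]] = tuple(t for t in parts[1].split(";") if t)
    return out
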