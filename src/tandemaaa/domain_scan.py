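"""Locate D-domains in full-length proteins, call tandem architectures,
and compute motif diagnostics and sequence logos.

A model library is a mapping name -> calibrated ProfileHMM.  Model names
follow the convention ``<family>_<role>`` with role in {D1, D2, N}; a
model named ``tail_helix`` is treated as the reference profile for the
C-terminal tail helix with its conserved central tyrosine.

The motif degeneracy score of an observed motif segment against a
position frequency matrix (PFM) is

    deg = 1 - mean_c f_c(obs_c) / max_a f_c(a)    in [0, 1]

i.e. 0 for a consensus-identical segment and -> 1 for a segment that
avoids the preferred residues of a near-deterministic PFM.  This is the
package's quantitative rendering of qualitative "severely degenerated"
motif statements.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .profile_hmm import DomainPath, ProfileHMM, viterbi
from .seqio import AA_INDEX, AMINO_ACIDS, MultipleAlignment, ProteinSequence

__all__ = [
    "DomainHit",
    "DomainArchitecture",
    "MotifLogo",
    "model_role",
    "model_family",
    "scan_sequence",
    "call_architecture",
    "detect_hbyx",
    "detect_tail_helix_tyr",
    "extract_motifs",
    "compute_logo",
    "hits_to_tsv",
]

LOG2_20 = math.log2(20.0)
HYDROPHOBIC = set("AVLIMFWYC")

#: Domain roles recognized in model names ``<family>_<role>``.
ROLES = ("D1", "D2", "N")


def model_role(name: str) -> str:
    tail = name.rsplit("_", 1)[-1]
    return tail if tail in ROLES else "other"


def model_family(name: str) -> str:
    if model_role(name) == "other":
        return name
    return name.rsplit("_", 1)[0]


@dataclass
class DomainHit:
    """A located model envelope on a sequence (0-based, half-open)."""

    seq_id: str
    model_name: str
    start: int
    end: int
    bits: float
    evalue: float
    rank: int = 0
    path: DomainPath | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad envelope [{self.start}, {self.end})")

    def overlap_frac(self, other: "DomainHit") -> float:
        """Reciprocal overlap: shared span over the shorter envelope."""
        shared = min(self.end, other.end) - max(self.start, other.start)
        if shared <= 0:
            return 0.0
        return shared / min(self.end - self.start, other.end - other.start)


def _scan_model(seq: ProteinSequence, hmm: ProfileHMM, n_database: int,
                max_hits: int, min_len: int = 30) -> list[DomainHit]:
    """Multi-hit glocal scan: best envelope, then recurse into the flanks."""
    hits: list[DomainHit] = []

    def scan_range(lo: int, hi: int, keep_weak: bool) -> None:
        if hi - lo < min_len or len(hits) >= max_hits:
            return
        path = viterbi(hmm, seq.residues[lo:hi])
        ev = hmm.evalue(path.score_bits, n_database)
        if path.end <= path.start:
            return
        if not keep_weak and ev > hmm.soft_evalue:
            return
        start, end = lo + path.start, lo + path.end
        path.start, path.end = start, end
        path.steps = [(st, mc, sp + lo if sp >= 0 else -1)
                      for st, mc, sp in path.steps]
        hits.append(DomainHit(seq.id, hmm.name, start, end,
                              path.score_bits, ev, path=path))
        scan_range(lo, start, False)
        scan_range(end, hi, False)

    scan_range(0, len(seq), True)
    return hits


def scan_sequence(seq: ProteinSequence, library: Mapping[str, ProfileHMM],
                  max_reported: int = 4, n_database: int = 1) -> list[DomainHit]:
    """Score every library model against the sequence.

    Each model is scanned glocally with masked re-scans of the flanks for
    additional envelopes.  Hits whose envelopes share > 50 % reciprocal
    overlap are grouped; within a group hits are sorted by E-value and at
    most ``max_reported`` are reported with ranks 1..max_reported.
    Disjoint envelopes are all reported.
    """
    if not library:
        raise ValueError("empty model library")
    for m in library.values():
        if not m.calibrated:
            raise ValueError(f"model {m.name!r} in library is not calibrated")
    raw: list[DomainHit] = []
    for hmm in library.values():
        raw.extend(_scan_model(seq, hmm, n_database, max_hits=max_reported))
    raw.sort(key=lambda h: (h.evalue, -h.bits, h.model_name))
    groups: list[list[DomainHit]] = []
    for h in raw:
        for g in groups:
            if h.overlap_frac(g[0]) > 0.5:
                g.append(h)
                break
        else:
            groups.append([h])
    out: list[DomainHit] = []
    for g in groups:
        for rank, h in enumerate(g[:max_reported], start=1):
            h.rank = rank
            out.append(h)
    out.sort(key=lambda h: (h.start, h.rank))
    return out


def detect_hbyx(seq: ProteinSequence | str, allow_phe: bool = False) -> bool:
    """True iff the C-terminal tripeptide matches Hb-Y-X.

    Hb is a hydrophobic residue (AVLIMFWYC); the middle residue must be Y
    (optionally also F with ``allow_phe``); the last residue is free.
    """
    res = seq.residues if isinstance(seq, ProteinSequence) else seq
    if len(res) < 3:
        raise ValueError("sequence shorter than 3 residues")
    hb, y, _x = res[-3], res[-2], res[-1]
    mid_ok = y == "Y" or (allow_phe and y == "F")
    return hb in HYDROPHOBIC and mid_ok


def detect_tail_helix_tyr(seq: ProteinSequence, d2_hit: DomainHit | None,
                          library: Mapping[str, ProfileHMM],
                          tail_model: str = "tail_helix",
                          tyr_col: int | None = None,
                          min_bits: float = 5.0) -> bool:
    """Check for the conserved central tyrosine of the C-terminal tail helix.

    Aligns the region C-terminal of the D2 envelope to the reference
    tail-helix profile and requires a Y in the column homologous to the
    conserved tail tyrosine (by default the profile column with maximal
    P(Y)).  Returns False when there is no D2 hit, the tail region is
    missing/too short, or the alignment is too weak to be homologous.
    """
    if d2_hit is None or tail_model not in library:
        return False
    hmm = library[tail_model]
    lo = max(0, d2_hit.end - 5)
    region = seq.residues[lo:]
    if len(region) < 3:
        return False
    if tyr_col is None:
        tyr_col = int(np.argmax(hmm.match_emissions[:, AA_INDEX["Y"]]))
    path = viterbi(hmm, region)
    if path.score_bits < min_bits:
        return False
    m = path.match_map()
    if tyr_col not in m:
        return False
    return region[m[tyr_col]] == "Y"


def extract_motifs(seq: ProteinSequence, hit: DomainHit, model: ProfileHMM,
                   motif_annotations: Mapping[str, Mapping]
                   ) -> dict[str, tuple[str, float]]:
    """Aligned substring and degeneracy score per annotated motif.

    ``motif_annotations`` maps motif name -> {"start": c0, "end": c1,
    "pfm": optional (c1-c0) x 20 frequency rows}.  Without an explicit
    PFM the model's own match emissions over the range are used.
    Deleted motif columns appear as '-' and score frequency 0.
    """
    path = hit.path if hit.path is not None else viterbi(model, seq.residues)
    m = path.match_map()
    out: dict[str, tuple[str, float]] = {}
    for name, ann in motif_annotations.items():
        c0, c1 = int(ann["start"]), int(ann["end"])
        if not (0 <= c0 < c1 <= model.L):
            raise ValueError(
                f"motif {name!r} range [{c0}, {c1}) outside model length "
                f"{model.L}")
        pfm = np.asarray(ann["pfm"], float) if "pfm" in ann and \
            ann["pfm"] is not None else model.match_emissions[c0:c1]
        if pfm.shape != (c1 - c0, 20):
            raise ValueError(f"motif {name!r}: PFM shape mismatch")
        obs = []
        score = 0.0
        for k, c in enumerate(range(c0, c1)):
            if c in m:
                ch = seq.residues[m[c]]
                obs.append(ch)
                a = AA_INDEX.get(ch)
                f = pfm[k, a] if a is not None else 0.0
            else:
                obs.append("-")
                f = 0.0
            top = pfm[k].max()
            score += (f / top) if top > 0 else 0.0
        deg = 1.0 - score / (c1 - c0)
        out[name] = ("".join(obs), float(min(max(deg, 0.0), 1.0)))
    return out


@dataclass
class DomainArchitecture:
    """Per-protein tandem-domain architecture with motif flags."""

    seq_id: str
    calls: list[tuple[str, DomainHit]]      # (label in {N, D1, D2, other}, hit)
    has_tandem_D1D2: bool = False
    has_N_domain: bool = False
    has_tail_helix_tyr: bool = False
    has_hbyx: bool = False
    insert_lengths: dict[str, int] = field(default_factory=dict)
    motif_states: dict[str, tuple[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "seq_id": self.seq_id,
            "calls": [
                {"label": lab, "model": h.model_name, "start": h.start,
                 "end": h.end, "bits": round(h.bits, 3),
                 "evalue": h.evalue}
                for lab, h in self.calls],
            "has_tandem_D1D2": self.has_tandem_D1D2,
            "has_N_domain": self.has_N_domain,
            "has_tail_helix_tyr": self.has_tail_helix_tyr,
            "has_hbyx": self.has_hbyx,
            "insert_lengths": self.insert_lengths,
            "motif_states": {k: {"observed": v[0], "degeneracy": round(v[1], 4)}
                             for k, v in self.motif_states.items()},
        }, indent=1)


def _insert_length(path: DomainPath, c0: int, c1: int) -> int:
    """Number of insert-state residues emitted between model columns."""
    return sum(1 for st, mc, _ in path.steps if st == "I" and c0 <= mc < c1)


def call_architecture(seq: ProteinSequence, hits: Iterable[DomainHit],
                      library: Mapping[str, ProfileHMM],
                      motif_annotations: Mapping[str, Mapping] | None = None,
                      insert_regions: Mapping[str, tuple[int, int]] | None = None,
                      ) -> DomainArchitecture:
    """Assemble a domain architecture from scan hits.

    Hits with E-value <= the model's strict bound are firm; between strict
    and soft bounds they are provisional (kept as calls but not counted
    for the tandem flag).  The tandem flag requires a firm D1 call before
    a firm D2 call.  ``insert_regions`` maps region name ->
    (model_col_start, model_col_end); insert lengths are counted from the
    Viterbi path of the matching call.
    """
    hits = [h for h in hits if h.seq_id == seq.id]
    hits.sort(key=lambda h: h.evalue)
    accepted: list[tuple[str, DomainHit, bool]] = []
    for h in hits:
        model = library.get(h.model_name)
        if model is None or h.model_name == "tail_helix":
            continue
        firm = h.evalue <= model.strict_evalue
        provisional = h.evalue <= model.soft_evalue
        if not provisional:
            continue
        if any(h.overlap_frac(a[1]) > 0.1 for a in accepted):
            continue
        accepted.append((model_role(h.model_name), h, firm))
    accepted.sort(key=lambda t: t[1].start)
    calls = [(lab, h) for lab, h, _ in accepted]
    firm_d1 = [h for lab, h, firm in accepted if lab == "D1" and firm]
    firm_d2 = [h for lab, h, firm in accepted if lab == "D2" and firm]
    has_tandem = any(d1.end <= d2.start for d1 in firm_d1 for d2 in firm_d2)
    has_n = any(lab == "N" for lab, _, _ in accepted)
    d2_hit = min(firm_d2, key=lambda h: h.evalue) if firm_d2 else None
    arch = DomainArchitecture(
        seq_id=seq.id,
        calls=calls,
        has_tandem_D1D2=has_tandem,
        has_N_domain=has_n,
        has_hbyx=detect_hbyx(seq) if len(seq) >= 3 else False,
        has_tail_helix_tyr=detect_tail_helix_tyr(seq, d2_hit, library),
    )
    if insert_regions:
        for lab, h, _firm in accepted:
            if h.path is None:
                continue
            for rname, (c0, c1) in insert_regions.items():
                model = library[h.model_name]
                if c1 <= model.L:
                    arch.insert_lengths[f"{lab}:{rname}"] = \
                        _insert_length(h.path, c0, c1)
    if motif_annotations:
        for lab, h, _firm in accepted:
            if lab not in ("D1", "D2"):
                continue
            model = library[h.model_name]
            usable = {k: v for k, v in motif_annotations.items()
                      if int(v["end"]) <= model.L}
            for mname, state in extract_motifs(seq, h, model, usable).items():
                arch.motif_states[f"{lab}:{mname}"] = state
    return arch


# ---------------------------------------------------------------------------
# Logos

@dataclass
class MotifLogo:
    """Per-column residue frequencies and information content.

    ``info_bits[c] = log2(20) - H(column c)`` in [0, log2 20]; the letter
    height of residue a in column c is ``columns[c, a] * info_bits[c]``.
    All-gap columns have undefined information, recorded as 0 with the
    ``undefined`` flag set.
    """

    columns: np.ndarray       # (L, 20)
    info_bits: np.ndarray     # (L,)
    n_sequences: int
    undefined: np.ndarray     # (L,) bool

    def letter_heights(self) -> np.ndarray:
        return self.columns * self.info_bits[:, None]

    def to_tsv(self, path: str | Path | None = None) -> str:
        header = "column\tinfo_bits\t" + "\t".join(AMINO_ACIDS)
        lines = [header]
        for c in range(self.columns.shape[0]):
            lines.append(
                f"{c}\t{self.info_bits[c]:.4f}\t"
                + "\t".join(f"{x:.4f}" for x in self.columns[c]))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def compute_logo(aln: MultipleAlignment,
                 column_range: tuple[int, int] | None = None,
                 small_sample_correction: bool = False) -> MotifLogo:
    """Sequence-logo statistics for (a range of) alignment columns.

    Gaps are excluded from the counts.  With ``small_sample_correction``
    the information content is reduced by the standard small-n correction
    ``(20 - 1) / (2 ln 2 n)``.
    """
    if aln.nrows < 2:
        raise ValueError("need at least 2 rows for a logo")
    c0, c1 = column_range if column_range is not None else (0, aln.ncols)
    if not (0 <= c0 < c1 <= aln.ncols):
        raise ValueError(f"bad column range [{c0}, {c1})")
    L = c1 - c0
    freqs = np.zeros((L, 20))
    undefined = np.zeros(L, dtype=bool)
    info = np.zeros(L)
    for k, j in enumerate(range(c0, c1)):
        col = aln.column(j)
        counts = np.zeros(20)
        n = 0
        for ch in col:
            a = AA_INDEX.get(ch)
            if a is not None:
                counts[a] += 1
                n += 1
        if n == 0:
            undefined[k] = True
            continue
        f = counts / n
        freqs[k] = f
        nz = f[f > 0]
        h = -(nz * np.log2(nz)).sum()
        e = (19.0 / (2.0 * math.log(2.0) * n)) if small_sample_correction else 0.0
        info[k] = max(0.0, LOG2_20 - h - e)
    return MotifLogo(columns=freqs, info_bits=info,
                     n_sequences=aln.nrows, undefined=undefined)


def hits_to_tsv(hits: Iterable[DomainHit], path: str | Path | None = None) -> str:
    lines = ["seq_id\tmodel\tstart\tend\tbits\tevalue\trank"]
    for h in hits:
        lines.append(f"{h.seq_id}\t{h.model_name}\t{h.start}\t{h.end}\t"
                     f"{h.bits:.2f}\t{h.evalue:.3g}\t{h.rank}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
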