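"""Per-subgroup profile HMMs: construction, glocal scoring, E-value
calibration, and profile-profile alignment.

The model is a plan7-style glocal architecture: global with respect to the
model (every match column is visited via match or delete states), local
with respect to the sequence (unaligned flanks are free).  Scores are
log-odds against an i.i.d. background model, reported in bits.  E-values
come from a maximum-likelihood Gumbel fit to the score distribution of
random background sequences:

    E(S, N) = N * (1 - exp(-exp(-lambda * (S - mu))))

with ``lambda`` (per-bit slope) and ``mu`` (location, bits) stored on the
model after :func:`calibrate`.

Design choices fixed here (the upstream literature delegates them to an
HMM package "with standard settings"): position-based sequence weighting,
background-proportional emission pseudocounts, Laplace transition
pseudocounts, emission floor 1e-6, and deterministic M > D > I
tie-breaking in the dynamic programming.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import _kernels
from .seqio import (ALPHABET, AMINO_ACIDS, AA_INDEX, MultipleAlignment,
                    ProteinSequence)

__all__ = [
    "BACKGROUND",
    "ProfileHMM",
    "ColumnMask",
    "DomainPath",
    "filter_alignment",
    "build_hmm",
    "viterbi",
    "forward_score",
    "calibrate",
    "align_profiles",
    "encode_sequence",
    "blosum62_matrix",
]

LN2 = math.log(2.0)
EMISSION_FLOOR = 1e-6

# Standard amino-acid background frequencies (Robinson & Robinson style),
# in AMINO_ACIDS order, renormalized to sum exactly to 1.
_BG = {
    "A": 0.0787, "C": 0.0157, "D": 0.0535, "E": 0.0665, "F": 0.0405,
    "G": 0.0695, "H": 0.0229, "I": 0.0590, "K": 0.0592, "L": 0.0964,
    "M": 0.0237, "N": 0.0448, "P": 0.0484, "Q": 0.0396, "R": 0.0512,
    "S": 0.0682, "T": 0.0541, "V": 0.0673, "W": 0.0113, "Y": 0.0304,
}
BACKGROUND = np.array([_BG[a] for a in AMINO_ACIDS])
BACKGROUND = BACKGROUND / BACKGROUND.sum()


_ENC_TABLE = np.full(128, 20, dtype=np.int8)
for _a, _i in AA_INDEX.items():
    _ENC_TABLE[ord(_a)] = _i


def encode_sequence(residues: str) -> np.ndarray:
    """Encode residues to int8 indices; X (and anything unknown) -> 20."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _ENC_TABLE[raw]


def encode_alignment(aln: MultipleAlignment) -> np.ndarray:
    """Encode an alignment to (nrows, ncols) int8; gap -> -1, X -> 20."""
    out = np.empty((aln.nrows, aln.ncols), dtype=np.int8)
    for r, row in enumerate(aln.rows.values()):
        for c, ch in enumerate(row):
            out[r, c] = -1 if ch == "-" else AA_INDEX.get(ch, 20)
    return out


_BLOSUM62 = None


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a (21, 21) float array in AMINO_ACIDS+X order."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices
        m = substitution_matrices.load("BLOSUM62")
        out = np.zeros((21, 21))
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                out[i, j] = m[a, b]
        _BLOSUM62 = out
    return _BLOSUM62


@dataclass
class ColumnMask:
    """Boolean keep-mask over the columns of the alignment it was made from."""

    keep: np.ndarray
    gap_threshold: float

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep)


def filter_alignment(aln: MultipleAlignment, col_gap_max: float = 0.5,
                     row_gap_max: float = 0.5
                     ) -> tuple[MultipleAlignment, ColumnMask]:
    """Drop gappy columns, then gappy rows.

    A column is removed when its gap fraction is strictly greater than
    ``col_gap_max`` ("more than 50 % gaps" at the default); afterwards a
    row is removed when its gap fraction over the kept columns is strictly
    greater than ``row_gap_max``.
    """
    enc = encode_alignment(aln)
    gap_frac = (enc == -1).mean(axis=0)
    keep = gap_frac <= col_gap_max
    if not keep.any():
        raise ValueError("column filtering removed every column")
    kept = enc[:, keep]
    row_gap = (kept == -1).mean(axis=1)
    keep_rows = row_gap <= row_gap_max
    if not keep_rows.any():
        raise ValueError("row filtering removed every row")
    ids = [rid for rid, k in zip(aln.rows, keep_rows) if k]
    cols = np.flatnonzero(keep)
    out = MultipleAlignment(
        {rid: "".join(aln.rows[rid][j] for j in cols) for rid in ids},
        meta=aln.meta)
    return out, ColumnMask(keep, col_gap_max)


@dataclass
class ProfileHMM:
    """A per-subgroup profile HMM with Gumbel E-value calibration.

    ``transitions`` holds seven per-position probability arrays of length
    L (index 0 is the begin state): M->M, M->I, M->D, I->M, I->I, D->M,
    D->D.  Emission rows, the background, and every state's outgoing
    transition distribution each sum to 1.
    """

    name: str
    match_emissions: np.ndarray          # (L, 20)
    insert_emissions: np.ndarray         # (L + 1, 20)
    transitions: dict[str, np.ndarray]   # keys mm, mi, md, im, ii, dm, dd
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    gumbel_lambda: float | None = None
    gumbel_mu: float | None = None
    strict_evalue: float = 1e-6
    soft_evalue: float = 1e-3

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.validate()
        self._lo_cache: tuple | None = None

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        L = self.L
        tol = 1e-9
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=tol):
            raise ValueError(f"{self.name}: match emission rows must sum to 1")
        if not np.allclose(self.insert_emissions.sum(axis=1), 1.0, atol=tol):
            raise ValueError(f"{self.name}: insert emission rows must sum to 1")
        if abs(self.background.sum() - 1.0) > tol:
            raise ValueError(f"{self.name}: background must sum to 1")
        t = self.transitions
        # begin state: B->M1 + B->D1
        if abs(t["mm"][0] + t["md"][0] - 1.0) > tol:
            raise ValueError(f"{self.name}: begin-state transitions must sum to 1")
        if L > 1:
            out_m = t["mm"][1:] + t["mi"][1:] + t["md"][1:]
            if not np.allclose(out_m, 1.0, atol=tol):
                raise ValueError(f"{self.name}: M-state transitions must sum to 1")
            if not np.allclose(t["im"][1:] + t["ii"][1:], 1.0, atol=tol):
                raise ValueError(f"{self.name}: I-state transitions must sum to 1")
            if not np.allclose(t["dm"][1:] + t["dd"][1:], 1.0, atol=tol):
                raise ValueError(f"{self.name}: D-state transitions must sum to 1")
        if not self.strict_evalue <= self.soft_evalue:
            raise ValueError(f"{self.name}: strict_evalue must be <= soft_evalue")

    @property
    def calibrated(self) -> bool:
        return self.gumbel_lambda is not None and self.gumbel_mu is not None

    # -- scoring -----------------------------------------------------------

    def _log_odds(self):
        if self._lo_cache is None:
            with np.errstate(divide="ignore"):
                me = np.log(self.match_emissions / self.background)
            me_lo = np.zeros((self.L, 21))
            me_lo[:, :20] = me
            # X scores neutrally
            me_lo[:, 20] = 0.0
            t = self.transitions

            def _ln(x):
                with np.errstate(divide="ignore"):
                    return np.where(x > 0, np.log(np.maximum(x, 1e-300)),
                                    _kernels.NEG_INF)

            self._lo_cache = (
                np.ascontiguousarray(me_lo),
                _ln(t["mm"]), _ln(t["mi"]), _ln(t["md"]),
                _ln(t["im"]), _ln(t["ii"]),
                _ln(t["dm"]), _ln(t["dd"]),
            )
        return self._lo_cache

    def evalue(self, score_bits: float, n_database: int = 1) -> float:
        """Gumbel-tail E-value of a bit score against ``n_database`` targets."""
        if not self.calibrated:
            raise ValueError(f"model {self.name!r} is not calibrated")
        x = -self.gumbel_lambda * (score_bits - self.gumbel_mu)
        # stable 1 - exp(-exp(x))
        p = -math.expm1(-math.exp(min(x, 700.0)))
        return n_database * p

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "schema": "tandemaaa-profile-hmm/1",
            "name": self.name,
            "L": self.L,
            "alphabet": AMINO_ACIDS,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": {k: v.tolist() for k, v in self.transitions.items()},
            "background": self.background.tolist(),
            "gumbel_lambda": self.gumbel_lambda,
            "gumbel_mu": self.gumbel_mu,
            "strict_evalue": self.strict_evalue,
            "soft_evalue": self.soft_evalue,
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ProfileHMM":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        if doc.get("schema") != "tandemaaa-profile-hmm/1":
            raise ValueError("unrecognized model schema")
        return cls(
            name=doc["name"],
            match_emissions=np.array(doc["match_emissions"]),
            insert_emissions=np.array(doc["insert_emissions"]),
            transitions={k: np.array(v) for k, v in doc["transitions"].items()},
            background=np.array(doc["background"]),
            gumbel_lambda=doc["gumbel_lambda"],
            gumbel_mu=doc["gumbel_mu"],
            strict_evalue=doc["strict_evalue"],
            soft_evalue=doc["soft_evalue"],
        )


# ---------------------------------------------------------------------------
# Construction

def _position_based_weights(enc: np.ndarray) -> np.ndarray:
    """Henikoff position-based sequence weights, normalized to mean 1."""
    n, L = enc.shape
    w = np.zeros(n)
    for j in range(L):
        col = enc[:, j]
        mask = (col >= 0) & (col < 20)
        if not mask.any():
            continue
        vals, counts = np.unique(col[mask], return_counts=True)
        r = len(vals)
        cmap = dict(zip(vals.tolist(), counts.tolist()))
        for k in np.flatnonzero(mask):
            w[k] += 1.0 / (r * cmap[col[k]])
    if w.sum() <= 0:
        return np.ones(n)
    return w * (n / w.sum())


def build_hmm(aln: MultipleAlignment, name: str,
              weighting: str = "position-based",
              pseudocount_strength: float = 0.5,
              transition_pseudocount: float = 0.03,
              background: np.ndarray | None = None) -> ProfileHMM:
    """Build a profile HMM from an (already filtered) alignment.

    Match states are the alignment columns.  Sequence weights (Henikoff
    position-based by default) are normalized to total mass 1, so counts
    are weighted frequencies and duplicating every row leaves the model
    unchanged.  Emissions are these frequencies plus a
    background-proportional prior of mass ``pseudocount_strength``;
    transitions are observed M/D move frequencies plus a flat
    ``transition_pseudocount`` per move.  Insert states are unobserved in
    a match-column alignment and fall back to the background.
    """
    if aln.nrows < 2:
        raise ValueError("need at least 2 rows to build a model")
    bg = BACKGROUND.copy() if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    enc = encode_alignment(aln)
    n, L = enc.shape
    if ((enc == -1).all(axis=0)).any():
        raise ValueError("alignment contains an all-gap column")
    if weighting == "position-based":
        w = _position_based_weights(enc)
    elif weighting == "uniform":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()

    # emissions
    counts = np.zeros((L, 20))
    for j in range(L):
        col = enc[:, j]
        for k in range(n):
            a = col[k]
            if 0 <= a < 20:
                counts[j, a] += w[k]
    em = counts + pseudocount_strength * bg
    em = em / em.sum(axis=1, keepdims=True)
    em = np.maximum(em, EMISSION_FLOOR)
    em = em / em.sum(axis=1, keepdims=True)

    # transitions: per row, column j is M when residue, D when gap
    is_m = enc >= 0
    cmm = np.zeros(L)
    cmi = np.zeros(L)
    cmd = np.zeros(L)
    cdm = np.zeros(L)
    cdd = np.zeros(L)
    # begin -> first column
    b_m = float(w[is_m[:, 0]].sum())
    b_d = float(w[~is_m[:, 0]].sum())
    for j in range(1, L):
        prev_m = is_m[:, j - 1]
        cur_m = is_m[:, j]
        cmm[j] += w[prev_m & cur_m].sum()
        cmd[j] += w[prev_m & ~cur_m].sum()
        cdm[j] += w[~prev_m & cur_m].sum()
        cdd[j] += w[~prev_m & ~cur_m].sum()

    tmm = np.zeros(L)
    tmi = np.zeros(L)
    tmd = np.zeros(L)
    tim = np.zeros(L)
    tii = np.zeros(L)
    tdm = np.zeros(L)
    tdd = np.zeros(L)
    tp = transition_pseudocount
    tot = b_m + b_d + 2.0 * tp
    tmm[0] = (b_m + tp) / tot
    tmd[0] = (b_d + tp) / tot
    for j in range(1, L):
        tot = cmm[j] + cmi[j] + cmd[j] + 3.0 * tp
        tmm[j] = (cmm[j] + tp) / tot
        tmi[j] = (cmi[j] + tp) / tot
        tmd[j] = (cmd[j] + tp) / tot
        # fixed insert-extension prior (~0.23 bit per extended residue),
        # comparable to usual gap-extension costs; inserts are unobserved
        # in match-column training alignments
        tim[j] = 0.15
        tii[j] = 0.85
        tot = cdm[j] + cdd[j] + 2.0 * tp
        tdm[j] = (cdm[j] + tp) / tot
        tdd[j] = (cdd[j] + tp) / tot

    ins = np.tile(bg, (L + 1, 1))
    return ProfileHMM(
        name=name,
        match_emissions=em,
        insert_emissions=ins,
        transitions={"mm": tmm, "mi": tmi, "md": tmd, "im": tim,
                     "ii": tii, "dm": tdm, "dd": tdd},
        background=bg,
    )


# ---------------------------------------------------------------------------
# Scoring

@dataclass
class DomainPath:
    """A glocal Viterbi alignment of a model to a sequence region.

    ``steps`` is a list of ``(state, model_col, seq_pos)`` with state in
    {'M', 'I', 'D'}; model_col and seq_pos are 0-based; seq_pos is -1 for
    delete states.
    """

    score_bits: float
    start: int
    end: int
    steps: list[tuple[str, int, int]]

    def match_map(self) -> dict[int, int]:
        """model_col -> seq_pos for match states only."""
        return {mc: sp for st, mc, sp in self.steps if st == "M"}

    def aligned_row(self, residues: str, L: int) -> str:
        """The sequence rendered on the model's match-column coordinates
        (deleted columns as '-', insert-state residues dropped)."""
        m = self.match_map()
        return "".join(residues[m[c]] if c in m else "-" for c in range(L))


def _encoded(seq) -> np.ndarray:
    if isinstance(seq, ProteinSequence):
        return encode_sequence(seq.residues)
    if isinstance(seq, str):
        return encode_sequence(seq)
    return np.asarray(seq, dtype=np.int8)


def viterbi(hmm: ProfileHMM, seq, mode: str = "glocal") -> DomainPath:
    """Best glocal alignment: score in bits, envelope, and state path."""
    if mode != "glocal":
        raise ValueError("only glocal mode is supported")
    enc = _encoded(seq)
    if enc.shape[0] < 1:
        raise ValueError("empty sequence")
    args = hmm._log_odds()
    score, end_j, end_state, VM, VI, VD, PM, PI, PD = \
        _kernels.viterbi_glocal(*args, enc)
    steps: list[tuple[str, int, int]] = []
    i, j = hmm.L, end_j
    state = "M" if end_state == 0 else "D"
    K = _kernels
    while i > 0:
        if state == "M":
            steps.append(("M", i - 1, j - 1))
            ptr = PM[i, j]
            i, j = i - 1, j - 1
            if ptr == K.P_START:
                # composite entry: model columns before i entered via deletes
                for c in range(i - 1, -1, -1):
                    steps.append(("D", c, -1))
                break
            state = {K.P_MM: "M", K.P_IM: "I", K.P_DM: "D"}[ptr]
        elif state == "D":
            steps.append(("D", i - 1, -1))
            ptr = PD[i, j]
            i = i - 1
            state = {K.P_MD: "M", K.P_DD: "D"}[ptr]
        else:  # insert
            steps.append(("I", i - 1, j - 1))
            ptr = PI[i, j]
            j = j - 1
            state = {K.P_MI: "M", K.P_II: "I"}[ptr]
    steps.reverse()
    emitted = [sp for st, _, sp in steps if sp >= 0]
    start = emitted[0] if emitted else 0
    end = emitted[-1] + 1 if emitted else 0
    return DomainPath(score_bits=score / LN2, start=start, end=end, steps=steps)


def viterbi_bits(hmm: ProfileHMM, seq) -> float:
    """Score-only glocal Viterbi in bits."""
    enc = _encoded(seq)
    return _kernels.viterbi_score(*hmm._log_odds(), enc) / LN2


def forward_score(hmm: ProfileHMM, seq) -> float:
    """Glocal forward score in bits (log-sum over all paths)."""
    enc = _encoded(seq)
    if enc.shape[0] < 1:
        raise ValueError("empty sequence")
    return _kernels.forward_glocal(*hmm._log_odds(), enc) / LN2


# ---------------------------------------------------------------------------
# Calibration

def sample_background(rng: np.random.Generator, length: int,
                      background: np.ndarray | None = None) -> np.ndarray:
    bg = BACKGROUND if background is None else background
    return rng.choice(20, size=length, p=bg).astype(np.int8)


def calibrate(hmm: ProfileHMM, n_random: int = 5000,
              length_law: tuple[str, ...] = ("fixed", 400),
              seed: int | np.random.Generator = 0) -> ProfileHMM:
    """Fit a Gumbel law to scores of i.i.d. background sequences.

    ``length_law`` is ``("fixed", n)`` or ``("uniform", lo, hi)``.  The
    fitted ``gumbel_lambda`` / ``gumbel_mu`` are stored on the model
    (mutated in place and returned).
    """
    if n_random < 1000:
        raise ValueError("n_random must be >= 1000 for a stable fit")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    if length_law[0] == "fixed":
        lengths = np.full(n_random, int(length_law[1]))
    elif length_law[0] == "uniform":
        lengths = rng.integers(int(length_law[1]), int(length_law[2]) + 1,
                               size=n_random)
    else:
        raise ValueError(f"unknown length law {length_law!r}")
    args = hmm._log_odds()
    scores = np.empty(n_random)
    for k in range(n_random):
        enc = sample_background(rng, int(lengths[k]), hmm.background)
        scores[k] = _kernels.viterbi_score(*args, enc) / LN2
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate score distribution; cannot calibrate")
    loc, scale = stats.gumbel_r.fit(scores)
    hmm.gumbel_mu = float(loc)
    hmm.gumbel_lambda = float(1.0 / scale)
    return hmm


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """ML Gumbel fit; returns (lambda, mu)."""
    loc, scale = stats.gumbel_r.fit(np.asarray(scores, float))
    return 1.0 / scale, loc


# ---------------------------------------------------------------------------
# Profile-profile alignment

def _column_frequencies(aln: MultipleAlignment) -> np.ndarray:
    enc = encode_alignment(aln)
    L = enc.shape[1]
    f = np.zeros((L, 20))
    for j in range(L):
        col = enc[:, j]
        mask = (col >= 0) & (col < 20)
        if mask.any():
            np.add.at(f[j], col[mask], 1.0)
            f[j] /= f[j].sum()
        else:
            f[j] = BACKGROUND
    return f


def align_profiles(alnA: MultipleAlignment, alnB: MultipleAlignment,
                   gap_open: float = 10.0, gap_extend: float = 1.0
                   ) -> MultipleAlignment:
    """Join two alignments by global dynamic programming on their columns.

    The column-pair score is the expected substitution score
    ``sum_a sum_b fA(a) fB(b) BLOSUM62(a, b)``; gaps are affine.  The
    result stacks all rows of A and B on the merged column system, so the
    output has ``nrowsA + nrowsB`` rows and at least
    ``max(ncolsA, ncolsB)`` columns.
    """
    fA = _column_frequencies(alnA)
    fB = _column_frequencies(alnB)
    S = fA @ blosum62_matrix()[:20, :20] @ fB.T
    nA, nB = S.shape
    NEG = -1e30
    M = np.full((nA + 1, nB + 1), NEG)
    X = np.full((nA + 1, nB + 1), NEG)   # gap in B (A column alone)
    Y = np.full((nA + 1, nB + 1), NEG)   # gap in A
    PM = np.zeros((nA + 1, nB + 1), dtype=np.int8)
    PX = np.zeros((nA + 1, nB + 1), dtype=np.int8)
    PY = np.zeros((nA + 1, nB + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, nA + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        PX[i, 0] = 1
    for j in range(1, nB + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
        PY[0, j] = 0
    for i in range(1, nA + 1):
        for j in range(1, nB + 1):
            # match
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(prev))
            M[i, j] = prev[k] + S[i - 1, j - 1]
            PM[i, j] = k
            # A-column against gap
            o = M[i - 1, j] - gap_open
            e = X[i - 1, j] - gap_extend
            if o >= e:
                X[i, j] = o
                PX[i, j] = 0
            else:
                X[i, j] = e
                PX[i, j] = 1
            # B-column against gap
            o = M[i, j - 1] - gap_open
            e = Y[i, j - 1] - gap_extend
            if o >= e:
                Y[i, j] = o
                PY[i, j] = 0
            else:
                Y[i, j] = e
                PY[i, j] = 1
    i, j = nA, nB
    finals = (M[i, j], X[i, j], Y[i, j])
    state = int(np.argmax(finals))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops.append("M")
            state = int(PM[i, j])
            i, j = i - 1, j - 1
        elif state == 1 or (j == 0 and i > 0):
            ops.append("A")
            nxt = PX[i, j]
            i -= 1
            state = 1 if nxt == 1 else 0
        else:
            ops.append("B")
            nxt = PY[i, j]
            j -= 1
            state = 2 if nxt == 1 else 0
    ops.reverse()
    rows: dict[str, str] = {}
    for rid, row in alnA.rows.items():
        it = iter(row)
        rows[rid] = "".join(next(it) if op in ("M", "A") else "-" for op in ops)
    for rid, row in alnB.rows.items():
        if rid in rows:
            raise ValueError(f"row id {rid!r} present in both alignments")
        it = iter(row)
        rows[rid] = "".join(next(it) if op in ("M", "B") else "-" for op in ops)
    meta = {**alnA.meta, **alnB.meta}
    return MultipleAlignment(rows, meta=meta)
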