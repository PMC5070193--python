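"""Synthetic tandem-AAA-family datasets with machine-readable planted truth.

The generator emulates the study design of a Cdc48-family survey: a set of
gene families with tandem D1/D2 AAA domains (plus optional N-domain, tail
helix with its conserved central tyrosine, and C-terminal HbYX tripeptide)
evolved over a species tree of eukaryotes plus an archaeal outgroup, with
planted lineage-specific losses, a planted duplication, and planted motif
degeneracies (e.g. a scrambled Walker A in one family's D1, mirroring the
degenerate peroxin D1-domains).

Truth is exact: every emitted protein carries its family, copy number and
domain coordinates, and per-residue ancestry maps allow true per-domain
alignments to be extracted at any divergence (used as seed alignments and
as the reference coordinate system for motif annotations).

The substitution process replaces residues at Poisson(branch * rate *
site_scale) events using BLOSUM62-conditional replacement probabilities;
motif sites in non-degenerate families evolve under strong purifying
selection (site_scale = ``motif_rate_scale``) and are indel-protected so
that motif-coordinate truth survives evolution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
import yaml

from .profile_hmm import BACKGROUND, blosum62_matrix
from .seqio import AMINO_ACIDS, MultipleAlignment, ProteinSequence, SpeciesTree

__all__ = [
    "FamilySpec",
    "SynthConfig",
    "ProfileSet",
    "Dataset",
    "default_config",
    "make_profiles",
    "make_species_tree",
    "evolve",
    "apply_events",
    "generate",
    "true_alignment",
    "default_motif_annotations",
]

# motif patterns: (name, template) where lowercase x = random residue,
# h = random hydrophobic; placed at fixed relative positions in a D-domain
MOTIF_TEMPLATES = [
    ("walker_a", "GxxxxGKT", 0.12),
    ("walker_b", "hhhhDE", 0.45),
    ("pore_loop", "xGhx", 0.55),
    ("sensor_1", "xTx", 0.64),
    ("arg_finger", "RxxR", 0.73),
    ("sensor_2", "GAD", 0.84),
]
HYDRO = "AVLIMF"
TERM_HELIX_LEN = 14     # conserved terminal helix closing every D-domain
TAIL_LEN = 24
TAIL_TYR_POS = 12   # the conserved central tyrosine of the tail helix


@dataclass
class FamilySpec:
    """Architecture blueprint for one planted gene family."""

    name: str
    n_domains: int = 2
    domain_profiles: tuple[str, ...] = ()
    has_N_domain: bool = True
    tail_helix: bool = True
    hbyx: bool = False
    #: motifs to scramble, as "D1:walker_a"-style qualified names
    degenerate_motifs: tuple[str, ...] = ()
    #: optional (domain, region, length) insert, e.g. ("D1", "preterminal", 50)
    insert_spec: tuple[str, str, int] | None = None
    #: derive domain profiles from this family's profiles (sister family)
    parent_profile: str | None = None
    #: archaeal outgroup families evolve on the archaeal subtree
    archaeal: bool = False

    def __post_init__(self) -> None:
        if self.n_domains not in (1, 2):
            raise ValueError("n_domains must be 1 or 2")
        if not self.domain_profiles:
            doms = ("D1", "D2")[: self.n_domains]
            self.domain_profiles = tuple(f"{self.name}:{d}" for d in doms)
        if self.n_domains == 2 and \
                self.domain_profiles[0] == self.domain_profiles[1]:
            raise ValueError(f"{self.name}: tandem D1/D2 profiles must differ")


@dataclass
class SynthConfig:
    """Full generator configuration; round-trips through YAML."""

    families: list[FamilySpec] = field(default_factory=list)
    n_euk_species: int = 40
    n_arch_species: int = 6
    root_to_tip: float = 0.8          # expected substitutions/site, euk MRCA->tip
    arch_root_to_tip: float = 0.5
    stem_length: float = 0.45         # euk/archaea stems on either side of root
    rate: float = 1.0
    indel_rate: float = 0.002         # indel events per site per unit length
    motif_rate_scale: float = 0.05    # purifying selection at intact motif sites
    #: divergence (expected subs/site) from the common ancestral AAA core
    #: to each family-domain profile; all D-domains are homologous
    family_divergence: float = 1.25
    #: loss events: (families, clade_name); a clade name refers to
    #: a named clade chosen deterministically on the generated tree
    losses: list[tuple[tuple[str, ...], str]] = field(default_factory=list)
    #: duplication events: (family, clade_name)
    duplications: list[tuple[str, str]] = field(default_factory=list)

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SynthConfig":
        text = str(source)
        if "\n" not in text and Path(source).exists():
            text = Path(source).read_text()
        doc = yaml.safe_load(text)
        fams = [FamilySpec(**{**f,
                              "domain_profiles": tuple(f["domain_profiles"]),
                              "degenerate_motifs": tuple(f["degenerate_motifs"]),
                              "insert_spec": tuple(f["insert_spec"])
                              if f.get("insert_spec") else None})
                for f in doc.pop("families")]
        losses = [(tuple(fs), c) for fs, c in doc.pop("losses", [])]
        dups = [(f, c) for f, c in doc.pop("duplications", [])]
        return cls(families=fams, losses=losses, duplications=dups, **doc)

    def family(self, name: str) -> FamilySpec:
        for f in self.families:
            if f.name == name:
                return f
        raise KeyError(name)


def default_config() -> SynthConfig:
    """The default study conditions: 8 eukaryotic tandem families plus one
    archaeal outgroup family, a parasite clade retaining only the minimal
    {Cdc48, NSF, NVL} set, and one planted Yta7 duplication."""
    families = [
        FamilySpec("Cdc48", has_N_domain=True, tail_helix=True, hbyx=True),
        FamilySpec("NSF", has_N_domain=True, tail_helix=False, hbyx=False,
                   degenerate_motifs=("D2:sensor_2",)),
        FamilySpec("Pex1", has_N_domain=True, tail_helix=True, hbyx=False,
                   degenerate_motifs=("D1:walker_a", "D1:walker_b",
                                      "D1:arg_finger"),
                   insert_spec=("D2", "post_alpha7", 40)),
        FamilySpec("Pex6", has_N_domain=True, tail_helix=True, hbyx=False,
                   degenerate_motifs=("D1:walker_a", "D1:walker_b",
                                      "D1:arg_finger")),
        FamilySpec("Spaf", has_N_domain=True, tail_helix=True, hbyx=False),
        FamilySpec("Spaflike", has_N_domain=False, tail_helix=True,
                   hbyx=False),
        FamilySpec("NVL", has_N_domain=False, tail_helix=True, hbyx=False,
                   insert_spec=("D1", "preterminal", 50)),
        FamilySpec("Yta7", has_N_domain=False, tail_helix=False, hbyx=False),
        FamilySpec("VAT", has_N_domain=True, tail_helix=True, hbyx=True,
                   archaeal=True),
    ]
    return SynthConfig(
        families=families,
        losses=[(("Pex1", "Pex6", "Spaf", "Spaflike", "Yta7"), "parasite")],
        duplications=[("Yta7", "dup")],
    )


# ---------------------------------------------------------------------------
# Ancestral profiles

@dataclass
class DomainProfile:
    """An ancestral domain construct: residues, per-site rate scales,
    indel protection, and recorded motif coordinates."""

    pid: str
    residues: np.ndarray                 # int8 codes
    scale: np.ndarray                    # per-site substitution rate scale
    protected: np.ndarray                # indel protection
    motifs: dict[str, tuple[int, int]]   # name -> [start, end) in profile


@dataclass
class ProfileSet:
    config: SynthConfig
    profiles: dict[str, DomainProfile]
    seed: int


def _sample_bg(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(20, size=n, p=BACKGROUND).astype(np.int8)


def _encode(s: str) -> np.ndarray:
    return np.array([AMINO_ACIDS.index(c) for c in s], dtype=np.int8)


def _fill_template(rng: np.random.Generator, template: str) -> np.ndarray:
    out = []
    for ch in template:
        if ch == "x":
            out.append(int(rng.choice(20, p=BACKGROUND)))
        elif ch == "h":
            out.append(AMINO_ACIDS.index(HYDRO[rng.integers(len(HYDRO))]))
        else:
            out.append(AMINO_ACIDS.index(ch))
    return np.array(out, dtype=np.int8)


def _make_core(rng: np.random.Generator) -> DomainProfile:
    """The common ancestral AAA-domain core all D-domain profiles descend
    from (the family's domains are homologous)."""
    L = int(rng.integers(195, 211))
    res = _sample_bg(rng, L)
    motifs: dict[str, tuple[int, int]] = {}
    for mname, template, relpos in MOTIF_TEMPLATES:
        start = int(round(relpos * L))
        seg = _fill_template(rng, template)
        res[start:start + len(seg)] = seg
        motifs[mname] = (start, start + len(seg))
    motifs["terminal_helix"] = (L - TERM_HELIX_LEN, L)
    scale = np.ones(L)
    protected = np.zeros(L, dtype=bool)
    for s, e in motifs.values():
        protected[s:e] = True
    # the terminal helix is conserved but less strictly than the catalytic
    # motifs; it anchors alignments across the pre-terminal inserts
    scale[L - TERM_HELIX_LEN:] = 0.1
    return DomainProfile("core", res, scale, protected, motifs)


def _diverge(rng: np.random.Generator, res: np.ndarray, amount: float,
             motifs: dict, motif_scale: float) -> np.ndarray:
    """Substitute residues at Poisson(amount * site_scale) events (no
    indels, so motif coordinates are shared across profiles)."""
    cond = _conditional_replacement()
    out = res.copy()
    # the six catalytic motifs are frozen during the family radiation --
    # every non-degenerate family ancestor keeps the canonical instances
    # (e.g. Sensor 2 GAD) -- while the terminal helix diverges slowly
    scale = np.ones(len(res))
    for name, (s, e) in motifs.items():
        scale[s:e] = 0.1 if name == "terminal_helix" else 0.0
    counts = rng.poisson(amount * scale)
    for i in np.flatnonzero(counts):
        a = out[i]
        for _ in range(counts[i]):
            a = int(rng.choice(20, p=cond[a]))
        out[i] = a
    return out


def _make_domain(rng: np.random.Generator, pid: str,
                 motif_scale: float, degenerate: Iterable[str] = (),
                 base: DomainProfile | None = None,
                 divergence: float = 1.25) -> DomainProfile:
    """A family-domain profile: the ancestral core (or a sister family's
    profile) diverged by ``divergence`` substitutions/site, with the
    family's degenerate motifs scrambled."""
    if base is None:
        raise ValueError("domain profiles derive from the common core")
    degenerate = set(degenerate)
    res = _diverge(rng, base.residues, divergence, base.motifs, motif_scale)
    motifs = dict(base.motifs)
    L = len(res)
    scale = np.ones(L)
    protected = np.zeros(L, dtype=bool)
    for mname, (s, e) in motifs.items():
        protected[s:e] = True
        if mname in degenerate:
            # scramble: replace motif residues with background draws until
            # far from the canonical instance (Hamming >= half the length,
            # >= 4 of 8 for Walker A); degenerate sites evolve neutrally
            want = max(2, (e - s) // 2)
            for _ in range(100):
                cand = _sample_bg(rng, e - s)
                if (cand != res[s:e]).sum() >= max(want, min(4, e - s)):
                    break
            res[s:e] = cand
        else:
            scale[s:e] = 0.1 if mname == "terminal_helix" else motif_scale
    return DomainProfile(pid, res, scale, protected, motifs)


def make_profiles(config: SynthConfig, seed: int = 0) -> ProfileSet:
    """Ancestral constructs for every domain profile id in the config,
    plus the shared N-domain linkers and the common tail-helix profile."""
    rng = np.random.default_rng(seed)
    profiles: dict[str, DomainProfile] = {}
    # shared tail helix: conserved helix with central tyrosine
    tail_res = _sample_bg(rng, TAIL_LEN)
    tail_res[TAIL_TYR_POS] = AMINO_ACIDS.index("Y")
    tail_scale = np.full(TAIL_LEN, 0.25)   # helix under moderate selection
    tail_scale[TAIL_TYR_POS] = 0.0
    profiles["tail"] = DomainProfile(
        "tail", tail_res, tail_scale, np.ones(TAIL_LEN, dtype=bool),
        {"tail_tyr": (TAIL_TYR_POS, TAIL_TYR_POS + 1)})
    core = _make_core(rng)
    profiles["core"] = core
    # per-family domains (two passes so parents exist before children)
    for fam in config.families:
        if fam.parent_profile is not None:
            continue
        degs = {d.split(":")[0]: set() for d in fam.degenerate_motifs}
        for q in fam.degenerate_motifs:
            dom, m = q.split(":")
            degs[dom].add(m)
        for dom_label, pid in zip(("D1", "D2"), fam.domain_profiles):
            profiles[pid] = _make_domain(
                rng, pid, config.motif_rate_scale,
                degenerate=degs.get(dom_label, ()), base=core,
                divergence=config.family_divergence)
        if fam.has_N_domain:
            npid = f"{fam.name}:N"
            Ln = int(rng.integers(80, 96))
            profiles[npid] = DomainProfile(
                npid, _sample_bg(rng, Ln), np.ones(Ln),
                np.zeros(Ln, dtype=bool), {})
    for fam in config.families:
        if fam.parent_profile is None:
            continue
        parent = config.family(fam.parent_profile)
        degs = {d.split(":")[0]: set() for d in fam.degenerate_motifs}
        for q in fam.degenerate_motifs:
            dom, m = q.split(":")
            degs[dom].add(m)
        for dom_label, pid, ppid in zip(("D1", "D2"), fam.domain_profiles,
                                        parent.domain_profiles):
            profiles[pid] = _make_domain(
                rng, pid, config.motif_rate_scale,
                degenerate=degs.get(dom_label, ()), base=profiles[ppid],
                divergence=0.35)   # sister families split late
        if fam.has_N_domain:
            npid = f"{fam.name}:N"
            Ln = int(rng.integers(80, 96))
            profiles[npid] = DomainProfile(
                npid, _sample_bg(rng, Ln), np.ones(Ln),
                np.zeros(Ln, dtype=bool), {})
    return ProfileSet(config=config, profiles=profiles, seed=seed)


# ---------------------------------------------------------------------------
# Species tree

def _random_ultrametric(rng: np.random.Generator, labels: list[str],
                        depth: float, ns: dendropy.TaxonNamespace
                        ) -> dendropy.Node:
    """Random coalescent-shaped ultrametric subtree scaled to ``depth``."""
    nodes = []
    for lab in labels:
        n = dendropy.Node(taxon=ns.new_taxon(lab))
        n._h = 0.0
        nodes.append(n)
    h = 0.0
    k = len(nodes)
    raw_times = np.sort(rng.exponential(1.0, size=k - 1)).cumsum()
    raw_times = raw_times / raw_times[-1] * depth
    for t in raw_times:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        p = dendropy.Node()
        p._h = float(t)
        p.add_child(a)
        p.add_child(b)
        a.edge.length = p._h - a._h
        b.edge.length = p._h - b._h
        nodes = [n for n in nodes if n is not a and n is not b] + [p]
    return nodes[0]


def make_species_tree(config: SynthConfig, seed: int = 0
                      ) -> tuple[SpeciesTree, dict[str, frozenset]]:
    """Eukaryote + archaeal-outgroup species tree and named clades.

    Returns the rooted tree and a mapping of clade names ('parasite',
    'dup', 'eukaryotes', 'archaea') to leaf-label sets.
    """
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    euk_labels = [f"euk{i:02d}" for i in range(1, config.n_euk_species + 1)]
    arc_labels = [f"arc{i:02d}" for i in range(1, config.n_arch_species + 1)]
    euk_root = _random_ultrametric(rng, euk_labels, config.root_to_tip, ns)
    arc_root = _random_ultrametric(rng, arc_labels, config.arch_root_to_tip, ns)
    root = dendropy.Node()
    root.add_child(euk_root)
    root.add_child(arc_root)
    euk_root.edge.length = config.stem_length
    arc_root.edge.length = config.stem_length
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    stree = SpeciesTree(tree)
    clades: dict[str, frozenset] = {
        "eukaryotes": frozenset(euk_labels),
        "archaea": frozenset(arc_labels),
    }
    # deterministic named clades inside the eukaryote subtree
    cands = []
    for node in euk_root.preorder_iter():
        if node is euk_root or node.is_leaf():
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        cands.append(leaves)
    cands.sort(key=lambda s: (len(s), min(s)))
    parasite = next((s for s in cands if 4 <= len(s) <= 6), None)
    if parasite is None:
        parasite = min(cands, key=len)
    dup = next((s for s in cands
                if 3 <= len(s) <= 6 and not (s & parasite)), None)
    if dup is None:
        dup = next(s for s in cands if not (s & parasite))
    clades["parasite"] = parasite
    clades["dup"] = dup
    return stree, clades


# ---------------------------------------------------------------------------
# Evolution

_COND_REPLACE = None


def _conditional_replacement() -> np.ndarray:
    """P(b | a, change) derived from BLOSUM62 target frequencies."""
    global _COND_REPLACE
    if _COND_REPLACE is None:
        S = blosum62_matrix()[:20, :20]
        q = np.outer(BACKGROUND, BACKGROUND) * np.exp2(S / 2.0)
        np.fill_diagonal(q, 0.0)
        _COND_REPLACE = q / q.sum(axis=1, keepdims=True)
    return _COND_REPLACE


@dataclass
class _GeneState:
    """Mutable per-lineage gene state: parallel site arrays."""

    anc: np.ndarray        # ancestral construct position, -1 for inserted
    res: np.ndarray        # int8 residues
    scale: np.ndarray      # per-site substitution scale
    prot: np.ndarray       # indel protection

    def copy(self) -> "_GeneState":
        return _GeneState(self.anc.copy(), self.res.copy(),
                          self.scale.copy(), self.prot.copy())


@dataclass
class _Construct:
    """Ancestral full-protein construct with segment bookkeeping."""

    state: _GeneState
    segments: dict[str, tuple[int, int]]       # label -> [start, end) anc coords
    motifs: dict[str, tuple[int, int]]         # "D1:walker_a" -> anc range


def _build_construct(fam: FamilySpec, pset: ProfileSet,
                     rng: np.random.Generator) -> _Construct:
    cfg = pset.config
    parts: list[tuple[str, DomainProfile | int]] = []
    if fam.has_N_domain:
        parts.append(("N", pset.profiles[f"{fam.name}:N"]))
        parts.append(("linker", int(rng.integers(15, 26))))
    doms = ("D1", "D2")[: fam.n_domains]
    for k, (dom, pid) in enumerate(zip(doms, fam.domain_profiles)):
        parts.append((dom, pset.profiles[pid]))
        if k + 1 < len(doms):
            parts.append(("linker", int(rng.integers(20, 31))))
    if fam.tail_helix:
        parts.append(("tail", pset.profiles["tail"]))
    res_parts, scale_parts, prot_parts = [], [], []
    segments: dict[str, tuple[int, int]] = {}
    motifs: dict[str, tuple[int, int]] = {}
    pos = 0
    for label, payload in parts:
        if isinstance(payload, int):
            res_parts.append(_sample_bg(rng, payload))
            scale_parts.append(np.full(payload, 1.5))   # linkers drift faster
            prot_parts.append(np.zeros(payload, dtype=bool))
            pos += payload
            continue
        prof = payload
        res = prof.residues.copy()
        scale = prof.scale.copy()
        prot = prof.protected.copy()
        if fam.insert_spec and fam.insert_spec[0] == label:
            _dom, region, ilen = fam.insert_spec
            # insert before the last ~15 columns ("before the terminal
            # helix") or right after ~2/3 of the domain for post_alpha7
            at = len(res) - 15 if region == "preterminal" else \
                int(len(res) * 0.68)
            ins = _sample_bg(rng, int(ilen))
            res = np.concatenate([res[:at], ins, res[at:]])
            scale = np.concatenate([scale[:at], np.full(int(ilen), 1.2),
                                    scale[at:]])
            prot = np.concatenate([prot[:at], np.zeros(int(ilen), bool),
                                   prot[at:]])
        if label == "tail" and fam.hbyx:
            hb = AMINO_ACIDS.index(HYDRO[rng.integers(len(HYDRO))])
            tyr = AMINO_ACIDS.index("Y")
            last = int(rng.choice(20, p=BACKGROUND))
            res = np.concatenate([res, np.array([hb, tyr, last], np.int8)])
            scale = np.concatenate([scale, np.array([0.0, 0.0, 1.0])])
            prot = np.concatenate([prot, np.ones(3, bool)])
        segments[label] = (pos, pos + len(res))
        for mname, (s, e) in prof.motifs.items():
            offset = 0
            if fam.insert_spec and fam.insert_spec[0] == label:
                at = len(prof.residues) - 15 if fam.insert_spec[1] == \
                    "preterminal" else int(len(prof.residues) * 0.68)
                if s >= at:
                    offset = int(fam.insert_spec[2])
            motifs[f"{label}:{mname}"] = (pos + s + offset, pos + e + offset)
        res_parts.append(res)
        scale_parts.append(scale)
        prot_parts.append(prot)
        pos += len(res)
    res = np.concatenate(res_parts)
    state = _GeneState(
        anc=np.arange(len(res)),
        res=res,
        scale=np.concatenate(scale_parts),
        prot=np.concatenate(prot_parts),
    )
    return _Construct(state=state, segments=segments, motifs=motifs)


def _mutate(state: _GeneState, blen: float, rate: float, indel_rate: float,
            rng: np.random.Generator) -> _GeneState:
    st = state.copy()
    n = len(st.res)
    if n == 0 or blen <= 0:
        return st
    cond = _conditional_replacement()
    # substitutions: per-site Poisson events with site-specific scales
    lam = blen * rate * st.scale
    counts = rng.poisson(lam)
    for i in np.flatnonzero(counts):
        a = st.res[i]
        for _ in range(counts[i]):
            if a >= 20:
                break
            a = int(rng.choice(20, p=cond[a]))
        st.res[i] = a
    # indels outside protected sites
    n_indel = rng.poisson(blen * indel_rate * n)
    for _ in range(n_indel):
        length = 1 + int(rng.geometric(0.35))
        length = min(length, 10)
        if rng.random() < 0.5 and len(st.res) > length + 20:
            # deletion of unprotected run
            free = np.flatnonzero(~st.prot)
            if len(free) == 0:
                continue
            start = int(free[rng.integers(len(free))])
            stop = start
            while stop < len(st.res) and stop - start < length and \
                    not st.prot[stop]:
                stop += 1
            keep = np.ones(len(st.res), dtype=bool)
            keep[start:stop] = False
            st = _GeneState(st.anc[keep], st.res[keep],
                            st.scale[keep], st.prot[keep])
        else:
            at = int(rng.integers(len(st.res) + 1))
            # do not split a protected (motif) run
            if 0 < at < len(st.res) and st.prot[at - 1] and st.prot[at]:
                continue
            ins = _sample_bg(rng, length)
            st = _GeneState(
                np.concatenate([st.anc[:at], np.full(length, -1), st.anc[at:]]),
                np.concatenate([st.res[:at], ins, st.res[at:]]),
                np.concatenate([st.scale[:at], np.ones(length), st.scale[at:]]),
                np.concatenate([st.prot[:at], np.zeros(length, bool),
                                st.prot[at:]]),
            )
    return st


@dataclass
class Dataset:
    """Generated proteins plus the machine-readable truth."""

    config: SynthConfig
    tree: SpeciesTree
    clades: dict[str, frozenset]
    proteins: list[ProteinSequence]
    truth: pd.DataFrame
    constructs: dict[str, _Construct]                 # family -> ancestor
    node_states: dict[tuple[str, int], _GeneState]    # (family, node_id) states
    anc_maps: dict[str, dict[int, str]]               # protein -> anc col -> aa
    seed: int
    events: pd.DataFrame | None = None

    def truth_for(self, protein_id: str) -> pd.Series:
        return self.truth.set_index("protein_id").loc[protein_id]

    def write(self, outdir: str | Path) -> None:
        from .seqio import write_fasta, write_newick
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.fasta")
        write_newick(self.tree, outdir / "species.nwk")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.config.to_yaml(outdir / "config.yaml")


def _node_ids(tree: SpeciesTree) -> dict[dendropy.Node, int]:
    return {n: i for i, n in enumerate(tree.tree.preorder_node_iter())}


def evolve(pset: ProfileSet, tree: SpeciesTree, rate: float | None = None,
           indel_rate: float | None = None, seed: int = 0,
           clades: dict[str, frozenset] | None = None) -> Dataset:
    """Evolve every family over the species tree (no loss/duplication
    events yet -- see :func:`apply_events`).

    Eukaryotic families start at the MRCA of the eukaryote leaves,
    archaeal families at the MRCA of the archaeal leaves.  Internal-node
    states are retained so that events can re-evolve subtrees.
    """
    cfg = pset.config
    rate = cfg.rate if rate is None else rate
    indel_rate = cfg.indel_rate if indel_rate is None else indel_rate
    if clades is None:
        euk = frozenset(l for l in tree.leaf_labels if l.startswith("euk"))
        arc = frozenset(tree.leaf_labels) - euk
        clades = {"eukaryotes": euk, "archaea": arc}
    rng = np.random.default_rng(seed)
    nid = _node_ids(tree)
    constructs: dict[str, _Construct] = {}
    node_states: dict[tuple[str, int], _GeneState] = {}
    proteins: list[ProteinSequence] = []
    rows: list[dict] = []
    anc_maps: dict[str, dict[int, str]] = {}

    for fam in cfg.families:
        frng = np.random.default_rng([seed, zlib.crc32(fam.name.encode()) % (2**31)])
        con = _build_construct(fam, pset, frng)
        constructs[fam.name] = con
        target = clades["archaea"] if fam.archaeal else clades["eukaryotes"]
        # MRCA of the target leaves
        mrca = tree.tree.mrca(taxon_labels=sorted(target))
        node_states[(fam.name, nid[mrca])] = con.state

        def walk(node, state):
            for child in node.child_nodes():
                cst = _mutate(state, child.edge.length or 0.0, rate,
                              indel_rate, frng)
                node_states[(fam.name, nid[child])] = cst
                if child.is_leaf():
                    _emit(fam, con, child.taxon.label, cst, 1,
                          proteins, rows, anc_maps)
                else:
                    walk(child, cst)

        walk(mrca, con.state)

    truth = pd.DataFrame(rows)
    return Dataset(config=cfg, tree=tree, clades=dict(clades),
                   proteins=proteins, truth=truth, constructs=constructs,
                   node_states=node_states, anc_maps=anc_maps, seed=seed)


def _emit(fam: FamilySpec, con: _Construct, species: str, st: _GeneState,
          copy: int, proteins: list, rows: list, anc_maps: dict,
          event_note: str = "") -> None:
    pid = f"{species}_{fam.name}" + (f"_{copy}" if copy > 1 else "")
    residues = "".join(AMINO_ACIDS[a] for a in st.res)
    proteins.append(ProteinSequence(pid, residues, species=species))
    # segment coordinates in the leaf sequence via ancestry
    row = {"protein_id": pid, "species": species, "family": fam.name,
           "copy": copy, "length": len(residues), "events": event_note}
    anc_pos = {int(a): i for i, a in enumerate(st.anc) if a >= 0}
    for label, (s, e) in con.segments.items():
        here = [anc_pos[c] for c in range(s, e) if c in anc_pos]
        if here:
            row[f"{label.lower()}_start"] = int(min(here))
            row[f"{label.lower()}_end"] = int(max(here)) + 1
        else:
            row[f"{label.lower()}_start"] = -1
            row[f"{label.lower()}_end"] = -1
    rows.append(row)
    anc_maps[pid] = {int(a): residues[i] for i, a in enumerate(st.anc)
                     if a >= 0}


def apply_events(dataset: Dataset, config: SynthConfig | None = None,
                 seed: int | None = None) -> Dataset:
    """Apply the configured loss and duplication events.

    A loss deletes the family's gene in all leaves below the named clade's
    MRCA; a duplication copies the gene state at the clade MRCA and
    re-evolves the copy independently down the subtree.  The truth ledger
    records the applied events per protein.
    """
    cfg = dataset.config if config is None else config
    seed = dataset.seed if seed is None else seed
    tree = dataset.tree
    nid = _node_ids(tree)
    lost: dict[str, set[str]] = {}
    for fams, cname in cfg.losses:
        clade = dataset.clades[cname]
        for f in fams:
            prev = lost.setdefault(f, set())
            if clade <= prev:
                raise ValueError(
                    f"loss of {f} in {cname!r} is below a prior loss")
            prev.update(clade)
    keep_proteins = []
    keep_ids = set()
    for p in dataset.proteins:
        fam = dataset.truth_for(p.id)["family"]
        if p.species in lost.get(fam, ()):  # planted loss
            continue
        keep_proteins.append(p)
        keep_ids.add(p.id)
    truth = dataset.truth[dataset.truth.protein_id.isin(keep_ids)].copy()
    truth["events"] = truth["events"].astype(str)
    proteins = keep_proteins
    rows: list[dict] = []
    anc_maps = {k: v for k, v in dataset.anc_maps.items() if k in keep_ids}
    rate, indel_rate = cfg.rate, cfg.indel_rate
    for fam_name, cname in cfg.duplications:
        fam = cfg.family(fam_name)
        clade = dataset.clades[cname]
        if any(sp in lost.get(fam_name, ()) for sp in clade):
            raise ValueError(
                f"duplication of {fam_name} in {cname!r} below a loss")
        mrca = tree.tree.mrca(taxon_labels=sorted(clade))
        state = dataset.node_states.get((fam_name, nid[mrca]))
        if state is None:
            raise ValueError(f"no gene state for {fam_name} at {cname!r}")
        drng = np.random.default_rng([seed, 7919, zlib.crc32(fam_name.encode()) % (2**31)])
        con = dataset.constructs[fam_name]

        def walk(node, st):
            for child in node.child_nodes():
                cst = _mutate(st, child.edge.length or 0.0, rate,
                              indel_rate, drng)
                if child.is_leaf():
                    _emit(fam, con, child.taxon.label, cst, 2,
                          proteins, rows, anc_maps,
                          event_note=f"duplication@{cname}")
                else:
                    walk(child, cst)

        walk(mrca, _mutate(state, 0.02, rate, indel_rate, drng))
    if rows:
        truth = pd.concat([truth, pd.DataFrame(rows)], ignore_index=True)
    event_rows = []
    for fams, cname in cfg.losses:
        for f in fams:
            event_rows.append({"family": f, "clade": cname, "type": "loss"})
    for f, cname in cfg.duplications:
        event_rows.append({"family": f, "clade": cname, "type": "duplication"})
    ds = Dataset(config=cfg, tree=tree, clades=dataset.clades,
                 proteins=proteins, truth=truth,
                 constructs=dataset.constructs,
                 node_states=dataset.node_states,
                 anc_maps=anc_maps, seed=seed)
    ds.events = pd.DataFrame(event_rows)
    return ds


def generate(config: SynthConfig | None = None, seed: int = 0) -> Dataset:
    """End-to-end convenience: profiles + tree + evolution + events."""
    cfg = default_config() if config is None else config
    pset = make_profiles(cfg, seed=seed)
    tree, clades = make_species_tree(cfg, seed=seed + 1)
    ds = evolve(pset, tree, seed=seed + 2, clades=clades)
    return apply_events(ds)


# ---------------------------------------------------------------------------
# Truth-derived alignments and annotations

def true_alignment(dataset: Dataset, family: str, segment: str,
                   species: Iterable[str] | None = None) -> MultipleAlignment:
    """True per-segment alignment on the ancestral column system.

    Rows are the family's proteins (optionally restricted to ``species``);
    columns are the ancestral construct positions of ``segment`` (one of
    N, D1, D2, tail).  Residues inserted post-ancestrally are omitted;
    deletions appear as gaps.
    """
    con = dataset.constructs[family]
    if segment not in con.segments:
        raise KeyError(f"family {family!r} has no segment {segment!r}")
    s, e = con.segments[segment]
    rows = {}
    meta = {}
    for p in dataset.proteins:
        t = dataset.truth_for(p.id)
        if t["family"] != family:
            continue
        if species is not None and p.species not in set(species):
            continue
        amap = dataset.anc_maps[p.id]
        rows[p.id] = "".join(amap.get(c, "-") for c in range(s, e))
        meta[p.id] = p
    if not rows:
        raise ValueError(f"no proteins for family {family!r}")
    return MultipleAlignment(rows, meta=meta)


def default_motif_annotations(dataset: Dataset, family: str, domain: str
                              ) -> dict[str, dict]:
    """Motif annotations (model column ranges) for a family's domain,
    derived from the planted truth's ancestral coordinates."""
    con = dataset.constructs[family]
    s, _e = con.segments[domain]
    out = {}
    for qname, (ms, me) in con.motifs.items():
        dom, mname = qname.split(":")
        if dom == domain:
            out[mname] = {"start": ms - s, "end": me - s}
    return out
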