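"""tandemaaa: classification and evolutionary analysis of tandem
double-AAA-domain (Cdc48-family) proteins.

The package implements an iterative profile-HMM classification pipeline:
per-subgroup model training with Gumbel E-value calibration, glocal
domain scanning and tandem-architecture calling, similarity-graph
clustering reconciled against domain trees, AAA+ motif degeneracy
diagnostics, and Dollo reconstruction of ancestral gene-family
repertoires -- plus a synthetic-data generator with machine-readable
planted truth for end-to-end validation.
"""

from importlib import resources as _resources

from .seqio import (ProteinSequence, MultipleAlignment, SpeciesTree,
                    read_fasta, write_fasta, read_alignment, write_alignment,
                    read_newick, write_newick)
from .profile_hmm import (ProfileHMM, filter_alignment, build_hmm, viterbi,
                          forward_score, calibrate, align_profiles)
from .domain_scan import (DomainHit, DomainArchitecture, MotifLogo,
                          scan_sequence, call_architecture, detect_hbyx,
                          detect_tail_helix_tyr, extract_motifs, compute_logo)
from .classify import (SimilarityGraph, SubgroupHierarchy, SubgroupAssignment,
                       ClassificationState, ClassifyConfig, all_vs_all,
                       cluster_at_cutoffs, reconcile, classify_domains,
                       resolve_ambiguous, iterate)
from .phylo import (DistanceMatrix, SupportedTree, pairwise_distance,
                    distance_matrix, nj_tree, bootstrap, root_with_outgroup,
                    is_monophyletic, quartet_support)
from .repertoire import (PresenceAbsenceMatrix, AncestralRepertoire,
                         build_matrix, dollo_ancestral, leca_set,
                         minimal_core, find_duplications)
from . import synthgen, pipeline

__version__ = "0.1.0"


def packaged_data(name: str) -> str:
    """Path of a data file shipped with the package (as a string)."""
    return str(_resources.files("tandemaaa.data").joinpath(name))


def example_repertoire() -> PresenceAbsenceMatrix:
    """The curated parasite-lineage repertoire table."""
    return PresenceAbsenceMatrix.from_tsv(
        packaged_data("parasite_repertoire.tsv"))


def example_lineage_tree() -> SpeciesTree:
    """The rooted eukaryote lineage tree matching the example repertoire."""
    return read_newick(packaged_data("eukaryote_tree.nwk"))
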