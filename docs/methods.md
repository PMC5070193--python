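# Methods

This note documents the models and procedures implemented in `tandemaaa`,
the defaults and why they were chosen, and what the synthetic validation
does and does not show.

## Profile HMMs

Each subgroup model is a plan7-style profile HMM restricted to the
*glocal* regime: every match column must be visited (via match or delete
states), while the scored sequence may align any contiguous region, with
free flanks. Multi-hit and fully local modes, and the SSV/MSV acceleration
filters of production HMM packages, are out of scope; multiple envelopes
on one protein are found by masked re-scanning of the flanks instead.

**Construction.** Match states are the columns of the (filtered) training
alignment. Henikoff position-based sequence weights are normalized to
total mass 1, so emission and transition counts are weighted *frequencies*
and duplicating rows leaves the model unchanged. Emissions receive a
background-proportional prior of mass `pseudocount_strength` (default
0.5 — a third of the evidence when the alignment is unweighted, vanishing
as rows accumulate); transitions receive a flat prior of 0.03 per move.
Insert states are unobserved in a match-column alignment; their emissions
equal the background (so insert residues score zero log-odds) and their
extension probability is fixed at 0.85 (≈0.23 bits per extended residue,
comparable to common gap-extension costs). Emissions are floored at 1e-6
after normalization so unseen residues score finitely. Dynamic-programming
ties break in the fixed order M > D > I, making tracebacks deterministic.
Entries that pass through leading delete states are folded into a
composite B→D…D→M entry anchored at the first emitted residue; this keeps
every (envelope, state-path) pair counted exactly once in the forward sum
and excludes zero-emission paths.

**Column/row filtering.** Before training, columns with *more than* 50 %
gaps are removed, then rows with more than 50 % gaps over the kept
columns. The thresholds are configurable; the comparison is strict
(exactly half is kept). Inside the iterative loop the seed alignments are
filtered once and the match-column system is then pinned, so member rows
rendered on model columns remain width-compatible across iterations.

**Calibration.** Scores of `n_random` i.i.d. background sequences
(default 5000 for stand-alone use, 1000 inside the iterative loop; lengths
fixed at 400 by default) are fitted to a Gumbel law by maximum likelihood
(`scipy.stats.gumbel_r.fit`); `E(S, N) = N(1 − exp(−exp(−λ(S−μ))))`. The
background is a fixed standard amino-acid frequency vector, overridable.
Each model carries a strict and a soft E-value bound (defaults 1e-6 and
1e-3) separating firm from provisional matches.

**Profile–profile alignment.** Two alignments are joined by global
dynamic programming over their column frequency vectors with score
`Σ_a Σ_b f_A(a) f_B(b) BLOSUM62(a,b)` and affine gaps (10/1). This is the
mechanism for building a single "general D-domain" coordinate system and
for joining per-subgroup alignments into one joint domain alignment.

## Scanning, architectures, motifs

A library scan scores every calibrated model against a protein (score-only
prefilter first, full traceback only for models whose whole-sequence score
passes the soft bound), groups envelopes with >50 % reciprocal overlap,
and reports at most four ranked hits per group. Architecture calling
accepts hits within the strict bound as firm and between strict and soft
as provisional; the tandem flag requires a firm D1 envelope before a firm
D2 envelope. The HbYX test is the strict C-terminal tripeptide
hydrophobic–Y–any (F in place of Y optionally tolerated, off by default,
since the residue classes are not standardized). The tail-helix test
aligns the region after the D2 envelope to a reference tail-helix profile
and requires a tyrosine in the column with maximal P(Y); alignments below
5 bits are treated as absent. Insert lengths are counted as insert-state
residues between annotated model columns, which requires a conserved
downstream anchor (the terminal helix).

The degeneracy score of an observed motif segment against a position
frequency matrix is `1 − mean_c f_c(obs_c)/max_a f_c(a)`: exactly 0 for a
consensus-identical segment regardless of how sharp the PFM is, and → 1
for a segment avoiding the preferred residues of a near-deterministic
PFM. Deleted motif columns contribute frequency 0. Sequence logos report
per-column information `log2 20 − H` with gaps excluded; the small-sample
correction is available but off by default.

## Classification loop

Assignments per envelope group: *firm* requires the best model within its
strict bound and a bit-score margin over the runner-up of at least
`margin_min` (default 10 bits — "significantly better than any other" is
not quantified upstream, so the default is deliberately conservative);
*ambiguous* means two or more models under their soft bounds separated by
less than the margin (such segments are refined by Smith–Waterman against
subgroup exemplars and, if the mean-score gap reaches 2 bits, re-labelled
as provisional — exemplar-resolved members never train); *provisional*
covers soft-but-not-strict matches. Only firm members are added to the
training alignments, and the firm set grows monotonically, which prevents
model drift and stands in for the manual inspection step of interactive
workflows. Convergence is zero label/status changes between successive
scans; a repeated assignment table (oscillation) stops the loop and
returns the best state by changed count. Calibration random streams are
fixed per model name, so E-value thresholds do not jitter between
iterations.

## Similarity graph and reconciliation

The pairwise engine is an in-repo affine Smith–Waterman (BLOSUM62, 11/1)
with Karlin–Altschul-style E-values `E = K·m·n·2^(−S_bits)` using the
standard gapped slope λ=0.267 and a fixed K=0.1; only the relative
ordering of E-values matters for clustering. The default cutoff ladder is
1e-5, 1e-10, 1e-20, 1e-30, 1e-45 (loosest to strictest); connected
components at each cutoff nest into a hierarchy.

Reconciliation with the bootstrapped domain tree proceeds top-down: a
component is accepted as a unified subgroup when it is a supported clade
(bipartition support ≥ `support_min`, default 70); otherwise it is split
into its sub-components at the next stricter cutoff and the test recurses
— conflicts between cluster and clade evidence are thus resolved in favor
of the smallest set satisfying both, while agreement is kept at the
coarsest level, which avoids fragmenting subgroups into their internal
species clades. Two structural guards apply: the full leaf set and its
trivial complements are never subgroups, and no single subgroup may absorb
more than half of all domains (an unrooted bipartition whose small side is
a clade would otherwise accept the large side via its complement). Sets
still in conflict at the strictest cutoff are resolved by the tree
(maximal supported clades, provenance `clade-only`) by default, matching a
phylogeny-led final classification; subgroups with fewer than two members
cannot train a model and are reported but not counted.

The joint domain alignment behind the tree renders each firm segment on
its own subgroup model's match columns (exact within-subgroup homology)
and then joins the per-subgroup alignments progressively by
profile–profile alignment, largest first. A single-reference alignment
(all segments against one family's model) is also available but degrades
for distant subgroups.

## Trees

Desk-scale tree inference is distance-based: p-distance,
Poisson-corrected, or gamma-corrected (default α=1.0, retaining the
rate-heterogeneity idea of ML models without a fitted shape parameter)
distances; Saitou–Nei neighbor joining with negative branch lengths
clamped to zero; nonparametric column-resampling bootstrap (support = %
of replicate trees containing the bipartition, deterministic under seed);
outgroup rooting on the edge separating a checked-monophyletic outgroup.
Full maximum-likelihood search, multi-program consensus and AU-test
corrections are intentionally out of scope; a quartet-vote statistic
stands in for likelihood-mapping confidence: quartets drawn one leaf per
edge-induced group vote for the pairing minimizing the least-squares
residual of the quartet distances (equivalently the smallest four-point
sum), and the vote fractions (concordant, alt1, alt2) sum to 1.

## Dollo repertoires

Ancestral gene content uses Dollo parsimony: each family is gained exactly
once, at the MRCA of the species possessing it, and may be lost on any
branch below; this placement provably minimizes losses under the
single-gain constraint, and the implementation is oracle-tested against
exhaustive gain-placement search on small trees. The root-node set is the
inferred LECA repertoire; the minimal core is the intersection of all
species rows. Cells flagged "uncertain absence" (incomplete genomes) do
not generate loss calls. Root placement is user-supplied — the packaged
example tree is rooted between the Opisthokonta/Amoebozoa lineages and the
rest. Duplications are reported from copy numbers (≥2 copies; contiguous
multi-copy species lifted to their MRCA) or from paralog clades in
per-family gene trees. The divergent Cdc48-like variants discussed in the
field are not part of the default family list (their status as a real
subgroup is unresolved); the family list is fully configurable.

## Synthetic data: what it emulates and what it does not

`synthgen.default_config()` defines the study conditions: 8 eukaryotic
tandem families (Cdc48, NSF, Pex1, Pex6, Spaf, Spaflike, NVL, Yta7) plus
an archaeal outgroup family (VAT), a 40-leaf ultrametric eukaryote tree
(root-to-tip 0.8 expected substitutions/site — chosen as a realistic deep
divergence; no quantitative per-family level is reported upstream, and the
value is exposed in config) joined to a 6-leaf archaeal subtree, a
"parasite" clade (4–6 species) retaining only {Cdc48, NSF, NVL}, and one
Yta7 duplication in a small disjoint clade. All D-domain profiles descend
from one ancestral AAA core (divergence 1.25 substitutions/site per
family-domain profile), so cross-family alignment is anchored in genuine
homology; the six catalytic motifs (Walker A `GxxxxGK T`, Walker B
`hhhhDE`, pore loop, Sensor 1, arginine finger `RxxR`, Sensor 2 `GAD`) are
canonical and frozen during the family radiation, then evolve under strong
purifying selection (rate scale 0.05) on the species tree; a
moderately conserved terminal helix (rate scale 0.1) closes every domain
and anchors insert measurement. Planted degeneracies scramble the motif in
the family ancestor (Hamming ≥ 4 of 8 for Walker A) and release the sites
to neutral rates: Pex1/Pex6 D1 Walker A/B + arginine finger, NSF D2
Sensor 2. NVL carries a 50-residue D1 insert before the terminal helix,
Pex1 a 40-residue D2 insert; NSF and Yta7 lack the tail helix; Cdc48 and
VAT end in HbYX.

Substitutions follow site-wise Poisson event counts with
BLOSUM62-conditional replacement (always changing the residue, so the
changed-site fraction follows ≈ 1 − e^(−b) at small branch lengths);
rare indels (0.002 events/site per unit branch length, geometric lengths
capped at 10) avoid motif sites so coordinate truth survives. This is
deliberately simpler than a time-reversible rate matrix with heterotachy:
it is adequate for testing classification structure, not for estimating
evolutionary parameters. Real data additionally feature compositional
bias, heterotachy, domain shuffling, alignment error from real aligners,
fragmentary sequences and annotation noise — passing the synthetic suite
therefore demonstrates the pipeline's internal correctness and its
behavior under controlled divergence, not database-scale performance.

## Validation scales

The default synthetic dataset is ~300 proteins (~600 D-domains); the
module test suite uses a 12 + 4-species reduction. The acceptance script
runs three replicate default datasets for the modal unified-subgroup count
and one for the family count, with 50 bootstrap replicates on the domain
tree and calibration n = 1000 inside the loop — sizes chosen to keep the
whole recomputation at desk scale on a single CPU while leaving the
statistics (bootstrap supports near 100, margins of tens of bits) far from
their decision thresholds.

## Known limitations

* Glocal-only scoring underestimates homology for proteins sharing only a
  fragment of a domain.
* Single-linkage components are sensitive to single spurious strong edges;
  the tree veto in reconciliation is the safeguard.
* The quartet statistic uses distances, not likelihoods; it inherits the
  biases of distance corrections near saturation.
* Dollo parsimony cannot express gene transfer or regain; families lost
  and re-acquired would be misdated.
* The Newick writer emits supports as internal node labels; programs that
  expect them as comments need a converter.
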