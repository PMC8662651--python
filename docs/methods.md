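# Methods

## The constraint model

A *constraint* is a triple (alignment column, residue set of size ≤ 4,
weight in nats). A cluster is a set of sequences carrying a pattern of
constraints; clusters nest, and a node's *effective* constraint set is the
union of its own and all its ancestors' constraints, so a family inherits
its subgroup's motifs. Constraint weight is the binomial
log-likelihood-ratio contrast of the foreground against the background at
that column,

w = n_FR·ln(q_F/q_B) + (n_F−n_FR)·ln((1−q_F)/(1−q_B)),
q = (n_R + α)/(n + 2α),

with pseudocount α = 1 on each side. It is the log-likelihood gain of
modelling the foreground column with its own set frequency rather than the
background's: additive in sequences, zero for identical compositions,
and interpretable in natural units of information. Gaps and unknown
residues (`X`) are excluded from counts and never satisfy a constraint.

## Pattern selection and the complexity penalty

For each column the residue set is grown greedily (size 1→4), adding the
residue that most increases the contrast, stopping when no addition helps.
`select_pattern` returns all positive-weight columns sorted by weight and
truncated at `max_constraints_per_node` (20).

A greedy maximum over ~80 candidate sets per column across hundreds of
columns is strongly selection-biased: on homogeneous data the summed
positive "weight" of the best columns far exceeds any useful acceptance
threshold. Accepted clusters are therefore judged on a *penalized,
conservation-filtered* pattern: each constraint is charged a complexity
prior of ln(n_available_columns) + ln(C(20, |set|)) nats — the cost of
naming one column and one residue set among all candidates — and only
columns whose foreground set frequency is ≥ `min_fg_freq` (default 0.7)
are stored on the node. A candidate cluster is accepted when the summed
penalized weight of the filtered pattern reaches `minnat` (default 5
nats). The conservation filter has a second role: columns only partially
conserved in a node (e.g. a family motif seen in half a supercluster's
members) stay available to the node's descendants, which is what makes
nested constraints layer correctly. Stored constraint weights are the raw
contrasts, so downstream fit scores keep their weighted-fraction meaning.

## Partition sampling

`sample_partition` is a seeded coordinate ascent on a foreground/background
split: (i) reselect the pattern for the current foreground (all
positive-weight columns participate during sweeps); (ii) reassign each
sequence to the foreground when the summed log-odds of its residues under
the foreground versus background pattern frequencies is positive —
Σ[ln(q_F/q_B) if matched else ln((1−q_F)/(1−q_B))] > 0. Sweeps stop at a
fixed point or after `n_sweeps` (50); `n_sweeps = 0` scores the initial
split once. Degenerate foregrounds (< 2 or > n−2 members) reject.

Two design points were forced by experiment. A matched-weight-fraction
rule (join when ≥ ½ of the pattern weight is satisfied) collapses the
foreground immediately from any random start, because the initial pattern
is noise fitted to the random split; the log-odds rule is the standard
likelihood reassignment and has the true partitions as stable fixed
points. Second, a pattern refitted to a random split *memorizes* it (the
split becomes a fixed point that the finalize filter then rightly
rejects), so pure random restarts rarely reach a real basin. The first
restart of every node split therefore uses a deterministic spectral
initialization — the sign of the top principal component of the one-hot
encoded columns, which separates the dominant block of correlated residue
variation — and the remaining restarts (default 5 total) are random. On
homogeneous alignments both kinds of start converge to self-memorized
splits that fail the penalized acceptance test, so no clusters are
invented from noise (verified on 20 seeds).

## Hierarchy inference and consensus

`infer_hierarchy` splits recursively: at each node the best accepted split
(by penalized pattern weight across restarts) makes the foreground *and*
its complement children, each with its own finalized constraints, both
required to pass `minnat`; recursion continues to `max_depth` (4). Columns
constrained by an ancestor are excluded from descendant searches, so child
constraints are disjoint from ancestors'. Binary splitting was chosen over
repeated foreground extraction because extraction misplaces the
remainder's substructure (a subcluster of the complement would attach to
the grandparent); with the default two-by-two synthetic conditions the
planted topology is recovered exactly. A hierarchy with more than two
children per node is representable (consensus can produce it) but
inference proposes bifurcations.

`consensus_hierarchy` pools clusters from several runs, groups them by
best membership Jaccard (strictly > 0.5, so a subcluster covering exactly
half its parent is never conflated with it), keeps groups present in
≥ `min_support` of runs, nests kept groups by membership containment, and
re-estimates each kept cluster's constraints on the union membership
against its consensus siblings.

`total_lpr` reports the summed stored-constraint contrasts recomputed per
node (members vs all others), dropping negative columns; it is the
pattern-based evidence of the whole classification in nats.

## Scoring, cut-off, classification

`score_sequence` is the weighted fraction of a node's effective
constraints satisfied, exactly 1/0 at the extremes. `select_cutoff`
histograms a score sample (bin width 0.01) and returns the midpoint of the
lowest bin strictly between the two tallest well-separated modes
(separation ≥ 0.2), taking the middle of a flat valley floor; a
non-bimodal histogram falls back to the standard cut-off 0.7 with a flag.
`classify` assigns the deepest cluster whose whole root path scores at or
above the cut-off (ties: higher score, then smaller id); sequences
qualifying nowhere are "unclassified". A sequence classified into a family
is thereby also a member of every cluster above it, which is what makes
the similarity-matrix diagonal ≥ cut-off by construction and produces the
sub/supercluster asymmetry.

## Downstream analyses

- **Similarity matrix**: entry (A, B) is the mean fit score of A's
  classified members against B; deliberately non-symmetric.
- **Comparative logos**: per-column foreground/background residue
  distributions smoothed by a sample-size-free uniform blend
  (p = (empirical + α·uniform)/(1+α)); divergence is the relative entropy
  (nats), zero exactly for identical compositions; all-gap foreground
  columns are flagged with divergence 0.
- **Conservation matrix**: cluster × taxon cell is true when any sequence
  scoring ≥ the cut-off for the cluster has the taxon in its lineage
  (nodes.dmp parent traversal, cycle-safe); relaxing the cut-off can only
  add cells. Sequences without a usable OX are skipped and counted.
- **Domain frequencies**: consecutive identical domains in one protein are
  compressed before counting; a user synonym map is applied first; the
  display table hides domains under 3% of a cluster's members, the full
  table keeps everything.
- **Intron phases**: phase = cumulative coding length before the intron
  mod 3; codon position = floor(cum/3) places the intron on the residue it
  interrupts (phase 1/2) or precedes (phase 0); a walk over the record's
  residues converts that to a match column, or null for insert/outside
  positions (nulls are excluded from shared-intron groups and counted).
- **DE loops**: loop length = non-gap match residues strictly between the
  αD-end and αE-start anchors plus all insert residues attached between
  them; anchors are profile configuration, not inferred. Clade labels come
  from a user clade map when available; the median-length threshold
  (default 10, a heuristic with no canonical value) is the fallback and is
  marked as such in reports.

## Synthetic data: what it emulates, what it does not

The generator plants: a nested constraint hierarchy (columns sampled
without replacement across the tree; residue sets of size 1–2; weights
uniform in [2, 6] nats, a range that makes 5 constraints per node
comfortably exceed minnat = 5); member sequences that satisfy each
effective constraint with probability `fidelity` (default 0.95, 50
sequences per family, 200 columns, uniform background); organism
assignments drawn from species under each family's emergence clade in a
small holozoan-shaped taxonomy (Filasterea → … → Chordata); exon
structures placing clade-shared introns at chosen (column, phase) pairs
plus Poisson(0.5) random introns per gene; Poisson(70) vs Poisson(4)
DE-insert lengths for longDE/shortDE clades; and SH3–SH2–kinase vs
TM–IG×3–kinase domain architectures with a rare FN3 at 2% to exercise the
display threshold. Optional artifacts (two fragments truncated at the DFG
anchor, two duplicates) exercise the filtering stages.

Not emulated: substitution processes on a tree (sites are independent
draws, so there is no within-cluster phylogenetic correlation), alignment
error, realistic amino-acid composition, or indel variation in match
columns. Passing tests therefore demonstrate correctness of the machinery
and recoverability under the stated noise model — not performance on real
proteomes, where signal is weaker and cluster sizes are far more skewed.

## Numerical and interface choices

0-based columns internally, 1-based in every written table and the model
JSON. Ties in pattern selection break toward the lower column index and
lower residue index; classification ties toward the higher score then the
lexicographically smaller id. The identity purge is greedy in input order
(first seen kept), identity counted over mutually non-gap columns with `X`
never identical. All generators and the sampler are deterministic given
their seeds; pipeline outputs contain no timestamps, so reruns are
byte-identical. Problem sizes used throughout the test suite and the
acceptance script (200 × 200 default study, 1,000 random exon structures,
20-seed noise rejection) were chosen as the smallest sizes at which the
statistical properties under test are unambiguous.

## Known limitations

The exact Bayesian-posterior pattern-partition machinery of the original
omcBPPS/mcBPPS programs is not reproduced; the contrast statistic, the
complexity prior, and the coordinate ascent above are this package's own,
chosen to preserve the nats semantics, the minnat acceptance test, and the
hierarchical constraint structure. Dataset-scale quantities from full
proteome studies (total LPR of order 10^5 nats, tens of thousands of
sequences) are out of reach of the synthetic conditions by design.
Phylogeny inference is delegated entirely: the pipeline emits a
representative FASTA sample and can consume a clade map, but builds no
trees.
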