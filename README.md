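# ckinome — constraint-based classification of tyrosine kinomes

Tyrosine kinases diversified alongside animal multicellularity, and their
families are classically defined by phylogenetic trees. An alternative is a
*constraint-based* classification: clusters of sequences are defined by the
alignment positions (columns plus small residue sets) that are strongly
conserved inside the cluster but divergent outside it, organized into a
nested hierarchy — subgroup-specific motifs layered under family-specific
motifs. `ckinome` implements that whole analysis as a reusable, tested
library for anyone studying large protein families with profile alignments:

- **inference** of cluster-specific constraints and a cluster hierarchy from
  an A2M profile alignment (a seeded coordinate-ascent pattern-partition
  sampler with a `minnat` acceptance threshold, in nats);
- **scoring and classification**: a sequence's fit to a cluster is the
  weight of the satisfied constraints divided by the total constraint
  weight — 1 if it follows every constraint, 0 if none — with discrete
  assignment at a cut-off (default 0.7, relaxed preset 0.6) and an
  "unclassified" sink;
- **downstream evolutionary analyses**: the non-symmetric all-vs-all
  cluster similarity matrix, comparative sequence-logo data, cluster × taxon
  conservation matrices from NCBI-taxdump files, per-cluster protein-domain
  frequencies, intron phases (cumulative exon length mod 3) mapped onto
  alignment columns to find shared introns, and αD–αE (DE-insert) loop
  lengths separating longDE/shortDE clades;
- a **synthetic-data generator** that plants all of the above with known
  ground truth, so every stage is testable without external databases.

## The statistic at the core

For a foreground cluster *F* against background *B*, each column's
constraint weight is a binomial log-likelihood-ratio contrast

    w = n_FR · ln(q_F / q_B) + (n_F − n_FR) · ln((1 − q_F) / (1 − q_B))   [nats]

with pseudocounted residue-set frequencies `q = (n_R + α)/(n + 2α)`. The fit
score of sequence *s* against cluster *c* (with effective constraints = its
own plus its ancestors') is

    score(s, c) = Σ_{satisfied} w_i / Σ_{all} w_i  ∈ [0, 1].

A cluster is accepted during inference only if its penalized pattern weight
clears `minnat` (default 5 nats); the hierarchy's total LPR is the summed
recomputed constraint weight over all nodes.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with planted truth (each writes its tables under `results/`):

```sh
python analysis/01_simulate.py
python analysis/02_infer_hierarchy.py
```

prints

```
filtering: 204 -> 202 (fragments) -> 200 (98% purge)
run 0: 6 clusters, total LPR 4506.3 nats
...
consensus: 6 clusters, total LPR 4506.3 nats, ARI vs planted families 1.000
```

i.e. after removing fragmentary and redundant records, three independent
inference runs and their consensus recover the planted hierarchy (2
superclusters × 2 families) exactly — adjusted Rand index 1.0 against the
planted family labels — with ~4.5 knats of pattern-based evidence.
Continuing,

```sh
python analysis/04_cluster_similarity.py
```

```
similarity diagonal: min 0.955 (all >= 0.7: True)
  c0.c0 vs c0: 0.955   c0 vs c0.c0: 0.794
```

shows the expected signature of a nested classification: every cluster's
members average ≥ 0.7 against their own constraints, and subcluster members
score higher against their supercluster than the reverse.
`05_taxonomic_conservation.py` reproduces the planted emergence points
(e.g. one supercluster detected from premetazoans onward, the other only
from Bilateria), `06_intron_phases.py` finds the planted phase-2 intron at
the αH-helix column shared by exactly the longDE families, and
`07_de_loops.py` separates longDE (median loop > 30) from shortDE
(median ≈ 5) families perfectly at the threshold of 10.

Library use mirrors the scripts:

```python
from ckinome import InferenceConfig, classify, infer_hierarchy, read_a2m

aln = read_a2m("aln.a2m")
model = infer_hierarchy(aln, InferenceConfig(minnat=5, seed=0), max_depth=4)
result = classify(aln, model, cutoff=0.7)
```

A thin CLI (`ckinome simulate|classify|run`) wraps the same functions.

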