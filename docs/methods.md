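# Methods

## Model

`leonbis` treats every alignment column of a subfamily as a draw from one of
two hypotheses. Under **relatedness**, the column's residues are i.i.d. from
a single unknown composition θ with a Dirichlet-mixture prior
(components `q_j`, parameters `α_j`); integrating θ out gives the
Dirichlet-multinomial marginal likelihood

    Q(x) = Σ_j q_j · [Γ(|α_j|) / Γ(|α_j| + M)] · Π_a Γ(α_ja + c_a) / Γ(α_ja)

for residue counts `c` with total `M`. Under **independence**, residues come
from the background `p`, with probability `P(x) = Π_a p_a^{c_a}`. The BILD
score `S = log Q − log P` (nats) is the log-odds between the two; it is
exchangeable in the observations, so columns are represented as count
vectors. The identity `Q(x + r)/Q(x) = posterior predictive of r` connects
the closed form to the sequential-product view and is tested exhaustively
over permutations.

All higher-level decisions reduce to this machinery:

* **Column-pair relatedness** `R(x, y) = log[Q(xy)/(Q(x)Q(y))]` (the
  background cancels); two overlapping core blocks are related when the sum
  of `R` over their shared columns is strictly positive.
* **Segment consistency** uses leave-one-out posterior predictives: a
  sequence's residues are removed from the column counts before its own
  segment is scored, so a sequence can never validate itself. The
  unrelatedness baseline is the expected score of a uniformly random residue
  per column, `Σ_a (1/20)·p_post(a) = 1/20` exactly (the posterior
  predictive normalizes), hence `N·log(1/20)` for `N` paired positions.
  Gapped positions are skipped and the baseline shortened to the same `N`,
  keeping the comparison length-matched. The baseline is the deterministic
  expectation, not one sampled random sequence: reproducible, and equal to
  the Monte-Carlo mean (checked in the tests).

## Score normalization

Core-block detection thresholds a normalized per-column score in [0, 1] at
0.05. The transform used is

    prob = clip(S / S_max(M), 0, 1)

where `S_max(M)` is the BILD score of the best perfectly conserved column
with the same number of observations (maximized over the 20 residues,
cached per mixture). Anything at or below background maps to 0, maximal
conservation to 1, and the scale is comparable across subfamilies of
different sizes; the 0.05 threshold reads as "at least 5 % of the maximal
attainable conservation". Centered sigmoid transforms of `S` were examined
and rejected: they map unconserved background-composition columns to
0.3–0.5, which makes a 0.05 threshold vacuous. Columns with fewer than two
observations are forced to `prob = 0` — a single-observation score is
dominated by the prior, and with the mixture-implied background it is
exactly zero anyway — so singleton subfamilies cannot self-certify blocks.

## Priors

Mixtures are read from the UCSC flat-file format (`Order`, `Mixture=`,
`Alpha=` lines; `Alpha=` may carry 21 numbers, |α| followed by the 20
components, or the bare 20). When no `Background=` line is present the
background is the mixture-implied marginal `p_a = Σ_j q_j α_ja/|α_j|`,
which is self-consistent and makes every single-observation score exactly
zero. The pair relative entropy
`H = Σ_{x,y} Q₂(x,y) log₂[Q₂(x,y)/(p_x p_y)]`, with `Q₂` the normalized
two-observation likelihood, places a prior on the conventional PAM scale
(bits). The shipped 3-component test mixture (`tests/data/toy3.comp`:
one sparse component for conserved columns, one background-shaped
component, one diffuse) has `H = 0.60` bits; production runs should use a
published protein mixture such as the 20-component `recode3.20comp`.

## Clustering

Subfamilies come from average-linkage hierarchical clustering on the
fractional-identity distance (pairs with fewer than 10 mutually ungapped
columns are treated as maximally distant). The tree is cut at the largest
gap in the sorted merge heights, but only when that gap exceeds
`min_split_gap = 0.1`: smaller height variation is identity noise within a
single family and the tree is left uncut. Singleton clusters produced by
the cut are absorbed into their nearest cluster by mean distance, so
subfamily statistics rest on at least two sequences wherever possible.
Orphans — sequences at distance ≥ 0.85 from everything — are set aside
before clustering and later scored directly against the query subfamily's
blocks. A query that would be an orphan becomes a singleton query subfamily
instead (the pipeline is defined relative to the query and cannot drop it);
in that degenerate case the query subfamily yields no blocks, a warning is
logged, and all non-query sequences are removed. Ties throughout are broken
by lowest sequence index, making the partition invariant to input order.

This clustering stands in for the dissimilarity-decomposition clusterer the
original workflow delegated to an external program; it reproduces the
functional contract (automatic subfamily count from the tree) and is
pluggable — `cluster_subfamilies` accepts any distance matrix.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window` | 7 columns | sliding-window length for block detection; shorter than the minimum region span, long enough to suppress single-column noise |
| `block_threshold` | 0.05 | strict lower bound on the window mean of normalized scores |
| `max_gap` | 40 columns | largest inter-block gap (`next.start − prev.end`) joined into one region |
| `min_region_length` | 21 columns | smallest region column span kept (inclusive) |
| `score_cutoff` | 0 | a sequence is retained iff some region score strictly exceeds this |
| `orphan_threshold` | 0.85 | identity distance above which a sequence is an orphan |
| `min_split_gap` | 0.1 | smallest merge-height jump that cuts the cluster tree |

Gap distances are measured in alignment columns, since blocks live in
alignment space. A block counts for a sequence only if the sequence has at
least one non-gap, non-`X` residue inside it and was not flagged
inconsistent across it. An orphan that passes a query block receives that
block with score equal to its own segment log-odds over the baseline
(≥ 0 when passing), so the `> 0` region cutoff applies uniformly to members
and orphans.

## Synthetic data

The generator emulates a curated homology benchmark at desk scale: 3
subfamilies × 6 members × 160 columns, with planted conserved blocks
(25–60 columns, consensus carried with probability 0.9 — domain-scale
conserved segments), up to 4 unrelated sequences drawn from a shaped
background and verified to share < 50 % identity with the query, and
corrupted segments where a related sequence's residues across a shared
block are overwritten with uniform draws. Non-block columns are i.i.d.
background by default, keeping planted-block coordinates sharp; the
`subfamily_similarity` knob adds subfamily-wide consensus similarity at
non-block columns for clustering tests. One explicit RNG stream per
fixture; a fixed seed yields byte-identical output.

What the generator does **not** model: indels (alignments are ungapped, so
coordinate bookkeeping is exercised by dedicated gapped unit fixtures, not
end-to-end), misalignment error, phylogenetic correlation among sequences
(members are conditionally independent given the consensus), domain
shuffling, and compositional bias along sequences. Passing recovery tests
therefore demonstrate the decision machinery under clean planted structure,
not performance on real, gappy, automatically aligned families.

## Numerics and edge cases

All likelihoods are computed in log space with `gammaln`/`logsumexp`;
probabilities are floored at 1e-300 before logs. The empty column has
`log Q = 0` and contributes nothing to pair scores (`R(x, ∅) = 0`).
Block boundary rules are strict as documented: window mean `> 0.05`,
relatedness sum `> 0`, region score `> cutoff`, span `≥ 21` inclusive,
gap `≤ 40` inclusive. Inconsistency is `log_score < log_baseline` (a
segment exactly at baseline passes). Score tracks are computed once;
flagged segments are excluded from chaining but tracks are not recomputed
iteratively.

## Problem sizes

The recovery benchmark (`scripts/acceptance.py` and the acceptance test)
pools 50 fixtures of 22 sequences × 160 columns — 900 related and 200
unrelated sequence decisions, 100 corrupted and ~2600 clean segment
verdicts — chosen as a desk-scale analogue of database-backed benchmarks
while keeping a full run under a minute.

## Known limitations

* The [0, 1] normalization is this package's construction; the published
  method asserts such a scale without defining the transform.
* The clustering reproduces the contract of dedicated subfamily-decomposition
  programs (automatic cluster count from a tree), not any particular one's
  internals.
* No iteration between flagging and track recomputation.
* Stockholm/Clustal input, ambiguity codes (B, Z, J), and alignment
  construction are out of scope; inputs must be pre-aligned FASTA.
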