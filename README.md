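# leonbis

Bayesian evaluation of homologous relations in protein multiple sequence
alignments (MSAs).

Automatically built MSAs of today's complex protein families mix sequences
that share only a single domain, fragments, and badly predicted gene models.
Downstream inference — structure modelling, functional annotation,
phylogenetics — silently degrades when non-homologous or misaligned stretches
are treated as homologous. Given an MSA and a user-designated **query
sequence**, `leonbis` answers, per sequence: *which parts of you are credibly
homologous to the query, and should you be kept at all?*

The pipeline:

1. **Subfamily clustering.** Sequences are grouped by average-linkage
   hierarchical clustering on fractional-identity distance, with an automatic
   largest-gap tree cut; highly divergent *orphan* sequences are set aside.
2. **Core-block detection.** For each subfamily, every alignment column gets a
   BILD (Bayesian Integral Log-odds) score under a Dirichlet-mixture prior
   over amino-acid compositions,

   $$S(\vec{x}) \;=\; \log\frac{Q(\vec{x})}{P(\vec{x})}
     \;=\; \log Q(\vec{x}) - \sum_a c_a \log p_a ,$$

   where $Q(\vec{x})=\sum_j q_j\,
   \frac{\Gamma(|\alpha_j|)}{\Gamma(|\alpha_j|+M)}
   \prod_a \frac{\Gamma(\alpha_{ja}+c_a)}{\Gamma(\alpha_{ja})}$ is the
   Dirichlet-multinomial marginal likelihood of the column's residue counts
   $c$ and $p$ is the background. Scores are normalized to $[0,1]$ and a
   sliding-window analysis (mean score > 0.05) delimits conserved *core
   blocks*.
3. **Block relatedness.** Overlapping blocks from different subfamilies are
   linked to the query subfamily when the summed column-pair score
   $R(\vec{x},\vec{y}) = \log\,[Q(\vec{xy})/(Q(\vec{x})Q(\vec{y}))]$ over the
   overlap is positive.
4. **Consistency filtering.** Each sequence's segment across each of its
   subfamily's blocks is scored by leave-one-out posterior-predictive
   probabilities; segments scoring below the uniform-random baseline
   ($N\log\frac{1}{20}$) are flagged *inconsistent* and excluded. Orphans are
   scored the same way directly against the query subfamily's blocks.
5. **Regions and filtering.** Query-related blocks are chained into *regions*
   (inter-block gap ≤ 40 columns, region span ≥ 21 columns); a sequence is
   kept iff one of its regions scores above the cutoff, and kept sequences
   are ranked by total region score.

## Worked example

Using the small alignment and the 3-component demonstration mixture shipped
with the test suite (22 sequences × 160 columns: three related subfamilies,
four unrelated sequences, two corrupted segments):

```sh
$ leonbis run tests/data/F1.fasta --query-id query \
      --mixture tests/data/toy3.comp -o out/F1
retained 18/22 sequences; report: out/F1.report.json
```

All 18 related sequences are retained and the 4 unrelated ones are removed.
The JSON report shows three core blocks in the query subfamily —
`(14, 61)`, `(70, 105)` and `(109, 151)` in 0-based column coordinates,
closely tracking the conserved segments planted at `(20, 55)`, `(75, 100)`
and `(115, 145)` — chained into one region per sequence. The two sequences
whose residues were overwritten across a block (`sub0_seq1`, `sub0_seq2`)
have that block flagged inconsistent and excluded from their regions
(`sub0_seq1` keeps `(70, 151)` only), dropping them to the bottom ranks
while still being recognized as related.

```sh
$ leonbis mixture-info tests/data/toy3.comp
components: 3
relative entropy: 0.6005 bits
```

The relative entropy places the prior's implied residue-pair scoring on the
conventional PAM scale. Other subcommands: `leonbis score` (per-column score
tracks as TSV) and `leonbis fixture` (synthetic alignments with ground
truth). Outputs per run: a JSON report, the filtered aligned FASTA, core
blocks as BED6, and blocks/regions/inconsistent segments as GFF3.

For production use, download a published protein Dirichlet mixture (e.g. the
20-component `recode3.20comp` from compbio.soe.ucsc.edu/dirichlets) and pass
it as `--mixture`; the parser reads the UCSC flat-file format.

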