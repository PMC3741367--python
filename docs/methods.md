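# Methods

`lincatlas` re-implements, as a reusable library, the post-assembly analysis
workflow used to build tissue-resolved catalogs of large intergenic noncoding
RNAs (lincRNAs) in mouse: starting from assembled transcript models and
per-tissue FPKM, it produces a filtered novel-lincRNA catalog, tissue-
specificity scores, replicate-recurrence statistics, TSS histone metagene
profiles, co-expression-module function assignments and neighbor
cis-regulation statistics. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data generator does and
does not emulate.

## Data model and coordinate conventions

All interval arithmetic uses 0-based half-open coordinates (the BED
convention); GTF input/output converts from/to 1-based inclusive at the file
boundary. A `Transcript` is a stranded chain of sorted, non-overlapping exons
on one chromosome; its introns are the gaps between consecutive exons.

Two transcripts are compared through their intron chains:

- **full** match: same chromosome and strand, identical intron chains —
  terminal exon lengths are free to differ (the `cuffcompare` `=` class-code
  analog). For a pair of intron-less (single-exon) transcripts the chains are
  both empty and carry no positional information, so a full match additionally
  requires ≥1 bp of exonic overlap.
- **partial** match: same chromosome and strand with at least one shared
  intron or ≥1 bp of same-strand exonic overlap.

Merging of assemblies groups multi-exon transcripts by (chromosome, strand,
intron chain), extending the representative's terminal exons to the extreme
termini seen in the group; single-exon transcripts are grouped by same-strand
overlap chaining. Gene loci are then reassigned by single-linkage clustering
of representatives sharing ≥1 bp of same-strand exonic overlap. The merge is
idempotent, which the tests assert on random inputs.

## The five-step detection cascade

Filters are pure predicates applied in the published order; each stage
records its attrition in a ledger whose counts telescope.

1. **Reliable expression.** Survivor iff max-over-tissues FPKM ≥ `min_fpkm`
   (default 1.0) and mean per-base read coverage ≥ `min_coverage` (default
   3.0). The original work used a trained decision tree whose features and
   training labels are not recoverable; this package replaces it with the
   transparent two-threshold rule above, both thresholds configurable. Read
   coverage is consumed as a per-transcript input.
2. **Annotation overlap.** Survivor iff zero exonic overlap (strand-blind,
   exon level — a transcript inside an annotated intron survives) with every
   catalog: coding, known noncoding, pseudogene. Eliminated transcripts are
   tagged by the first overlapping class in the priority order
   coding > known_noncoding > pseudogene.
3. **Coding potential.** Survivor iff the triplet classifier (below) labels
   the sequence noncoding; when an external per-transcript label file is
   supplied (e.g. from an alignment-based coding-potential tool) the two
   calls are intersected — a survivor must be noncoding by both.
4. **Structure.** Survivor iff exon count ≥ 2 and spliced length strictly
   greater than 200 nt ("longer than 200 bases" is read as strict, so a
   200-nt transcript is eliminated).
5. **Intergenic position.** Survivor iff the span-to-span gap to the nearest
   protein-coding gene is ≥ 1000 bp ("at least 1 kb" read as ≥), strand-blind.

Survivors are merged into gene loci to form the novel catalog. Combination
with a documented lincRNA catalog is a gene-level union in which any novel
locus with ≥1 bp exonic overlap to a documented lincRNA is deduplicated in
favor of the documented entry.

Steps 2–5 commute (pure predicates), which the tests assert by permuting
them on synthetic runs; step 1 is kept first because it consumes
per-transcript expression rows that the noise artifacts lack.

## Triplet coding-potential classifier

An alignment-free classifier in the spirit of signature-based
coding/noncoding indices: a sequence read in a fixed frame is a chain of
non-overlapping nucleotide triplets, and coding sequences show strongly
skewed statistics of which triplet follows which.

Training counts frame-0 transitions between adjacent triplets in each class,
smooths each 64-wide row with a pseudocount (default 1), and stores
`log2(P_coding(j|i) / P_noncoding(j|i))` as a 64×64 table. Swapping the
training classes negates the table exactly. Scoring evaluates, for each of
the three forward frames, per-step scores over consecutive triplet pairs and
takes the maximal-scoring contiguous segment (Kadane's algorithm, empty
segment allowed with score 0 and segment `(0, 0)`); the sequence score is the
maximum over frames, ties broken by lower frame then leftmost segment.
Reverse-strand frames are not scored by default because stranded assemblies
are assumed; a 6-frame mode can be had by scoring the reverse complement
explicitly.

**Decision threshold.** The likelihood-ratio-neutral threshold 0 is *not*
usable with a best-segment statistic: the maximum over segments of any long
random walk is ≥ 0 and almost surely > 0, so a zero cut labels nearly every
long sequence coding regardless of class. The threshold is therefore
calibrated during training as the cut maximizing balanced accuracy over the
training-set scores (lowest maximizer for determinism). When the two classes
are statistically identical this degenerates gracefully: held-out accuracy
stays at chance, which the null test (zero triplet bias → 50% ± 5%) checks.
`TripletCodingClassifier` exposes the model as a scikit-learn estimator
(`fit`/`predict`/`decision_function`).

## Tissue specificity and recurrence

For an expression pattern `e` over `T` tissues, let `p = e / Σe`. The
specificity score is

```
JS(p) = max_t [ 1 − sqrt( JSD(p, δ_t) ) ]
```

with `δ_t` the idealized pattern expressed only in tissue `t` and JSD the
Jensen-Shannon divergence using base-2 logarithms (so JSD ∈ [0, 1]; any base
works up to rescaling, and bits match the metric as originally defined).
The score is 1 exactly for a one-tissue pattern, ≈0.1908 for uniform
expression over six tissues, and ≈0.4421 for an even two-tissue split —
hence below the 0.5 cutoff used to call a transcript tissue-specific
(`≥ 0.5`, the cutoff being stated without strictness). All-zero patterns are
flagged undefined and excluded from fraction denominators. Gene-level scores
aggregate as the max over the gene's transcripts (`collapse_to_genes` sums
isoform FPKM first when a gene-level matrix is wanted).

Recurrence asks how reproducibly a transcript is re-assembled: a hit in
(tissue, replicate) is any assembled transcript matching at level ≥ partial,
and the recurrence is the maximum per-tissue hit count, histogrammed over
0..R replicates.

## Histone metagene profiles

A bedGraph track is held as per-chromosome sorted disjoint intervals with an
implicit 0 elsewhere; queries integrate exactly. The metagene profile uses a
±5 kb window in 100-bp bins around each TSS (the window and bin size are not
published for the original figure; these are conventional promoter-profile
parameters and both are configurable), strand-oriented so upstream/downstream
are comparable across strands. Each region contributes the exact mean track
value per bin (gaps count as 0); bins extending past the chromosome start are
excluded for that region only; the profile is the unweighted mean over
regions, so for a single region `Σ(bin_mean · bin_size)` equals the track
integral over the window exactly. The random control samples intergenic
positions ≥1 kb from coding genes, stratified per chromosome to the lincRNA
TSS distribution when one is supplied.

## Co-expression modules and function assignment

The "two-color" network has genes as nodes colored coding or lincRNA and an
edge wherever `|Pearson r| ≥ 0.9` on log2(FPKM+1) across tissues (the edge
rule is not published; with only six tissue conditions a high cutoff controls
spurious edges, and the threshold is configurable). Constant-expression genes
get no edges.

Markov clustering is implemented from scratch: self-loops of weight 1,
column normalization, then iterate expansion (matrix squaring) and inflation
(entrywise power 1.8 by default + column renormalization) with pruning of
entries < 1e-5, until the max-abs change drops below 1e-6 (cap 100
iterations, warning on non-convergence). Clusters are the connected
components of the limit matrix's nonzero structure. Columns remain stochastic
after every iteration and the clustering is equivariant under node
relabeling; both are asserted in tests. `MarkovClustering` wraps this as a
scikit-learn clusterer over a precomputed affinity matrix.

Modules are clusters with ≥6 genes. Enrichment tests the module's *coding*
genes against the coding background per GO term (hypergeometric upper tail,
`P(X ≥ k)`), with Benjamini-Hochberg correction across the module's terms
and q ≤ 0.05 called enriched; a second term map (e.g. pathways) is handled
identically. lincRNAs carry no annotation of their own and inherit all
enriched terms of their module — the natural reading of the two-color
scheme.

## Neighbor cis-correlation

Each lincRNA gene is paired with the minimal span-gap coding gene
(strand-blind, ties to the leftmost gene start) and the pair's log2(FPKM+1)
profiles are Pearson-correlated across tissues; constant profiles are
flagged undefined. Highly correlated means `r ≥ 0.8` (the source material
uses "correlation coefficient of 0.8" in the text and "> 0.8" in a figure
legend; `≥` is the default with a `strict` flag for the other reading). A
pair "shares GO" when both members are annotated — the lincRNA via module
inheritance — and the term sets intersect. The null redraws 10,000 uniform
pairs of annotated genes (seeded); the reported p-value is the binomial
upper tail of the observed sharing count at the null sharing fraction.

## Synthetic data: what it emulates, what it does not

The generators mirror the study design: six tissues × six biological
replicates, with configurable locus counts (defaults: 50 coding, 20 known
noncoding, 10 pseudogenes, 20 planted novel lincRNAs on a 20-Mb two-
chromosome genome). Planted lincRNAs have 2–4 exons with mean exon count 2.5
and mean exon length 620 nt (matching the reported catalog averages), and by
construction are multi-exonic, >200 nt, ≥1 kb from every coding gene, and
disjoint from all catalogs. Every generator is a pure function of its
arguments and a seed.

- *Expression*: a planted fraction of lincRNAs (default 0.5) and coding
  genes (default 0.25, echoing the real-data contrast) get one dominant
  tissue carrying ≥90% of their mass; the rest are near-uniform; lincRNA
  FPKM is drawn with a lower median than coding FPKM. Planted co-expression
  modules put 6 coding + 2 lincRNA genes (4 modules by default) on one
  shared tissue profile in log space, driving within-module correlations
  near 1.
- *Assemblies*: each transcript expressed in a tissue appears in each of its
  replicates with probability 1 − dropout (default 0.1); noise artifacts are
  single-exon fragments inside coding-gene introns (unspliced pre-mRNA
  contamination — exercised by filters 1, 4 and 5) and truncated exon runs
  of coding transcripts (partial assemblies — exercised by filter 2).
- *Sequences*: coding (and pseudogene) sequences come from a first-order
  Markov chain over non-overlapping triplets whose transition skew scales
  with a bias-strength parameter (default 1.0); noncoding sequences come
  from the uniform chain. At bias 0 the classes are statistically
  indistinguishable by construction.
- *Histone tracks*: a tiled background of mean 1 (Gamma noise, CV 0.1) with
  tiles within ±1 kb of expressed-gene TSSs scaled by the enrichment factor
  (default 3).
- *GO labels*: random background terms per coding gene plus one dedicated
  shared term per planted module.

What the simulation does **not** model: read-level noise and sequencing
error, isoform complexity (one transcript per simulated locus), biased
genomic base composition, genome sequence context for the noise fragments
(noise sequences are drawn from the noncoding chain rather than the host
intron), overlapping or nested loci, and the correlation structure of real
tissue panels. Passing recovery tests therefore demonstrates that the
pipeline machinery is correct and self-consistent under the declared
generative model — not that real-data counts (e.g. the published locus and
module totals) would be reproduced, which depend on the original reads and
database snapshots.

## Problem sizes and determinism

The test suite and the acceptance script run end-to-end on desk-scale
problems chosen as representative: the default 50-coding/20-lincRNA study
for pipeline recovery, 2,000 lincRNAs for the specificity fraction, 500
transcripts for the recurrence histogram, 200 TSSs for the metagene
enrichment, and 1,000 + 1,000 sequences (half for training, half held out)
for classifier accuracy. All randomness flows through explicit integer
seeds; sub-generators receive seeds derived via `numpy.random.SeedSequence`.

## Known limitations

- The expression filter is a fixed two-threshold rule, not a learned model;
  with real data the thresholds should be tuned against spike-ins or
  annotation-based positives.
- The triplet model is first-order over adjacent triplets; it does not use
  ORF structure, start/stop context, or protein-database evidence, and its
  threshold is only as good as the training sequences' representativeness.
- MCL cluster granularity beyond the inflation parameter (expansion order,
  pruning threshold) follows common defaults and is configurable but not
  auto-tuned.
- Neighbor analysis pools upstream/downstream and ignores promoter
  architecture (divergent/convergent orientation is out of scope).
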