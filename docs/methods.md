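# Methods

## The analysis problem

In an F1 interspecies hybrid every autosomal gene is present as two
homologous alleles, one per parental species.  Bulk RNA-seq reads from
hybrid cells can be attributed to a parental allele wherever they
overlap at least one divergent site; reads from perfectly conserved
regions are ambiguous.  The pipeline classifies reads competitively
between the two parental transcript sets, builds per-allele count
matrices from the unambiguous reads, aligns them over one-to-one
homologs, and tests two questions per gene: does the allele's
expression change between cell conditions (differential expression),
and do the two alleles of one gene express unequally within a condition
(allelic bias)?  Set operations then isolate the genes whose allelic
behaviour is specific to the reprogrammed state.

## Read classification

With zero mismatches allowed, transcript-space alignment is exactly
substring matching: a read maps to a parent iff the read or its reverse
complement occurs verbatim in at least one of that parent's
transcripts.  Classification is set-theoretic — specific to parent 1,
specific to parent 2, shared, or unmapped — with multi-transcript hits
within one parent recorded but not affecting the class.  Matching is
unstranded (either strand counts); reads containing `N` are unmapped by
definition, since exact matching cannot satisfy ambiguity codes.

The index is a seed-and-verify k-mer table (default k = 31): every
k-mer start position in every transcript is recorded at construction;
a query is located by looking up its first k-mer and verifying the full
query at each candidate position, with a plain linear scan for queries
shorter than k.  Any k gives identical answers; the structure is tested
for read-for-read equivalence against a naive per-transcript scan,
exhaustively on a toy reference and on simulated read sets.

## Count model and quantification

Only parent-specific reads are quantified: shared reads cannot be
attributed to an allele.  A specific read increments its gene iff all
its hit transcripts in that parent belong to a single gene; reads
spanning two or more genes are discarded into an `ambiguous` tally.
A per-sample ledger (assigned + ambiguous + shared + unmapped +
other-parent = input reads) makes the accounting auditable.  FPKM is
`count / (length_kb × library_size_millions)` with gene length the
maximum transcript length of the gene; TPM rescales length-normalized
rates to 10⁶ per sample.  Normalized values are reporting units only —
all testing runs on counts.

## Differential testing

The exact conditional NB test: counts are scaled to the geometric-mean
library size and summed within groups.  A sum of n i.i.d. NB(μ, φ)
variables is NB(nμ, φ/n), and two NB variables with a common success
parameter — which equal per-replicate means imply after library
equalization — satisfy

    A | A + B = t  ~  BetaBinomial(t, n_a/φ, n_b/φ),

with the Binomial(t, n_a/(n_a+n_b)) limit at φ = 0.  The two-sided
p-value sums the conditional probabilities of all outcomes no more
likely than the observed one; enumeration is exact for t ≤ 10,000 and a
normal approximation with continuity correction (variance
t·w(1−w)·(α+β+t)/(α+β+1)) is used beyond.  Measured calibration: type-I
error 0.043–0.055 at α = 0.05 across seeds on 2,000 null NB genes
(φ = 0.1, mean 100, 3 vs 3), and the null p-value distribution passes a
KS uniformity check at mean 300, where the test's inherent discreteness
is negligible.

The common dispersion φ (variance μ + φμ²) is estimated by method of
moments on scaled counts: per gene φ_g = max(0, (s² − m̄)/m̄²), common
φ = median over genes with positive mean.  When group labels are
supplied, s² is the within-group pooled variance so between-condition
signal does not inflate φ; with a single group the estimator is the
plain one-sample form.  Median-of-moments is deliberately robust rather
than efficient; with three replicates per group it underestimates a
true φ = 0.2 by ≈ 0.03–0.05 (skew of s² at low df), which the recovery
tests account for by the ±0.1 acceptance band.

Fold changes are log2 of library-size-normalized group means with a 0.5
pseudo-count per mean; significance is |log2FC| > 1 and raw p < 0.05.
BH q-values are reported but never used for flags, matching the raw
threshold convention of the analysis being reproduced.  TMM
normalization and tagwise dispersion shrinkage are intentionally out of
scope; library size is the total parent-specific assigned reads.

## Allelic-bias testing

Both parental alleles of a sample come from the same sequencing
library, so their within-sample depth ratio is 1: the pipeline pools
raw allele counts across the samples of one condition and tests the
pooled parent-1 count against Binomial(n, 0.5), two-sided.  (The
`allelic_bias_test` function also accepts per-allele library sizes and
scales the minority library to the majority before pooling, for callers
whose matrices really do come from different libraries — but
normalizing by the per-parent assigned-read totals would let
genome-wide bias itself drag every truly biased gene's ratio toward
0.5, which is why the pipeline passes equal sizes.)  A gene is biased
toward the parent with the larger pooled count when p < 0.05; the bias
score is the pseudo-counted log2 ratio.  A gene with zero counts on
both alleles returns p = 1, no call.

## Set filtering and enrichment

`ipsc_specific_deas` is the set difference (iPSC-contrast DEAs minus
fibroblast-contrast DEAs): differences already present between the
somatic states are inherited, not induced by reprogramming.
`bias_de_intersection` intersects biased genes with differential genes.
Enrichment is the upper-tail hypergeometric probability of the observed
overlap between the query and each GMT set, drawn from a background
universe that defaults to the harmonized common-gene list (the natural
choice when no background is stated), BH-corrected across sets.

## Synthetic data generator

The generator emulates a horse × donkey-like design.  Parent 2
transcripts are parent 1 transcripts with i.i.d. substitutions at the
divergence rate, uniform over the three alternative bases.  Expression:
for gene g in condition c, μ_gc = 2^(baseline + s_g·Δ·1[c = iPSC]) with
s_g ∈ {−1, 0, +1} the signed DE status.  Per sample, gene weights are
μ_gc multiplied by Gamma(1/φ, φ) noise (mean 1), gene totals are
multinomial over the fixed read budget, and each total is split between
alleles binomially at the gene's true parent-1 ratio.  This hierarchy
makes each allele count marginally NB(pμ, φ) while keeping the sample
total exact and the allele split conditionally binomial — the three
properties the recovery benchmarks rely on.  Reads are sampled at
uniform starts on the origin transcript, uniform strand, optional
per-base substitution errors (default 0, because zero-mismatch
classification would only route erroneous reads to `UNMAPPED`); read
ids are opaque shuffled integers and ground truth lives only in the
truth-table sidecar.

Defaults, chosen once as the study conditions: 200 genes, transcript
lengths 500–1500 bp, divergence 0.01 (a free parameter — the true
horse–donkey transcript divergence is not established here), 2
conditions × 3 replicates, baseline 2⁸ expected fragments per gene,
10% DE genes at |log2FC| = 2, 20% biased genes at parent-1 ratio 0.8,
φ = 0.2, 100-bp single-end reads, 50,000 reads per sample.  At these
settings a read overlaps ≥ 1 divergent site with probability
1 − 0.99¹⁰⁰ ≈ 0.63, giving specific/shared proportions near 1/3 each.
Because all biased genes favour parent 1, the two specific classes
differ by ~7 percentage points — an intended asymmetry, not an error.

What the generator does **not** emulate: indels and structural
divergence, paralogs, multi-isoform genes, positional/3′ coverage bias,
paired-end reads, quality-score variation, and mapping-reference bias.
Passing tests therefore demonstrate the correctness of the
classification, counting and testing logic under the stated model, not
performance on real genomes with repeats and annotation errors.

## Numerical and design choices

- All randomness flows from one seed through named substreams
  (references / counts / reads / gene-sets), so stages are individually
  reproducible and reruns are byte-identical.
- Two-sided discrete p-values use the minimum-likelihood rule (sum of
  probabilities ≤ observed, with a 1 + 1e−12 tolerance factor) and are
  clipped into (0, 1].
- Library scaling uses the geometric mean of library sizes; scaled
  counts are rounded to integers before exact testing.
- Harmonization drops many-to-many homolog tangles entirely rather than
  collapsing them, and applies no expression floor — filtering happens
  only through the tests.
- Colony summaries round half-up to one decimal; the pooled-variance
  (not Welch) t-test is used, the variant consistent with the reported
  day-10 significance bound at n = 2 vs 3.  Two of the printed SDs in
  the source table's narrative (day-14 AF, day-18 PF) do not recompute
  from the counts under any standard convention; this package reports
  the recomputed values (51.6, 6.5) and never forces the printed ones.
- Single-threaded throughout; determinism outranks speed at desk scale.

## Problem sizes

The shipped benchmarks use 10,000 reads for classifier-oracle
agreement, 2,000 null genes for type-I calibration, 5,000 for the KS
uniformity property, and the default 200-gene / 300,000-read pipeline
for recovery scoring — sizes at which every quantity of interest is
stable across seeds while a full suite run stays in tens of seconds.
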