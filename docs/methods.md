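# Methods

## Scope and data model

`macscan` analyses two DNA modifications jointly. 6mA input is a table of
strand-specific per-site calls (contig, position, strand, read coverage,
methylated-read count, optional modification quality score mQv); 5mC input
is a CX-report-style table of per-cytosine methylated/unmethylated read
counts. All coordinates are 0-based half-open internally; 1-based
conventions (GFF3, the tabular site formats) are converted only at the I/O
boundary, and fraction-valued inputs are converted to read counts by
round-half-even, a deterministic, bias-free rule. Rows whose reference base
is not an adenine (or cytosine) on the stated strand are rejected and
counted; a rejection rate above 1% aborts, since it almost always signals a
coordinate-convention mismatch rather than bad calls. The exact column
layout of upstream modification-call files varies by platform release, so
the canonical input is a versioned TSV and a modification-GFF dialect is
accepted read-only.

## Site filtering

A 6mA call is retained when coverage ≥ 15 reads and mQv > 25 (strict
inequality); a fallback policy of coverage ≥ 5 and mQv > 20 is provided for
shallow runs. Sites with no quality score pass by default (configurable):
simulated tables carry no mQv and should remain first-class. For 5mC, a
cytosine counts as a *methylated site* when coverage ≥ 5 and methylation
ratio ≥ 10%, both bounds inclusive. This filter defines site *counts* only;
pooled weighted levels always use unfiltered counts, because filtering on
the ratio before pooling would inflate the level.

## Strand symmetry

Symmetry is defined at ApT dinucleotides only: 5'-AT-3' is its own reverse
complement, so the two adenines are physically opposed. Each ApT with at
least one filtered call yields one pair record (watson = plus-strand A,
crick = minus-strand A at the next position); the pair is symmetric when
both adenines are called. All other methylated adenines are asymmetric by
construction. Whether opposed adenine pairs outside ApT should ever count
as symmetric is left open deliberately; the restricted definition matches
the ApT-dominated motif of high-6mA genomes. The per-site tally satisfies
an exact partition: symmetric-pair sites + hemi sites + non-ApT sites =
all filtered sites, which the test suite asserts as an invariant.

## Context summary

±6 nt windows around each site (reverse complemented for minus-strand
sites, so the methylated A is always the central column) yield a 13-column
position frequency matrix. The IUPAC consensus merges, per column, all
bases with frequency ≥ 0.25. This replaces expectation-maximization motif
discovery with a deterministic summary; on strongly biased context sets it
produces the expected degenerate codes. Note that the 0.25 threshold
interacts with base composition: in a 40% GC genome, C and G (marginal
frequency 0.2) only enter a column's code when actively enriched.

## MAC detection

Plus-strand occurrences of the AT motif are enumerated left-to-right
(overlap is impossible for AT; the rule is stated for generality); an
occurrence is methylated when either of its adenines carries a filtered
site. For relative distance *d* — the number of unmethylated occurrences
permitted between consecutive methylated ones, a motif count, not a bp
distance — clusters are maximal chains with ≥ 2 methylated motifs (one
site is not a cluster; the stricter ≥ 10 threshold applies only to
gene-selection for term enrichment). The scan over d = 1..40 scores each
distance as recall × purity:

* recall(d): methylated motifs inside clusters / all methylated motifs,
* purity(d): methylated motifs inside clusters / all motifs spanned.

Recall is provably non-decreasing and purity non-increasing in d, so
either alone would always select a boundary distance; their product is the
density-times-efficiency trade-off with an interior optimum. Ties break
toward the smallest d (determinism; smaller d is the more conservative
clustering). The scoring function operates on the emitted per-d table, so
alternative definitions can be audited against the same numbers. The
50–500 bp cluster size range is annotated on each MAC, never enforced: it
is an observed property of clusters, not a calling criterion. Clusters
never span contig boundaries, and a track with zero methylated occurrences
is an explicit "nothing to cluster" error (the pipeline reports zero MACs
in that case rather than aborting).

## Feature partition and enrichment

Every base receives exactly one label with precedence exon > 5'UTR/3'UTR >
intron > repeat > promoter > intergenic; promoters are the 600 bp upstream
of the TSS, truncated at contig edges. Gene structure outranks repeats
because enrichment treats them as disjoint tracks. Expected counts are
base-composition aware: a class is expected to collect sites in proportion
to its eligible bases (adenines on both strands for 6mA; context-matched
cytosines for 5mC), not its length — the defensible null for base-specific
modifications. Classes with zero eligible bases are reported as undefined
(NaN), observed-zero classes as −inf. Observed and expected counts each
sum exactly to the total site count.

## Windows, profiles, weighted levels

TSS windows are strand-oriented and half-open in forward coordinates:
[TSS−150, TSS+400) for plus-strand genes, [TSS−400, TSS+150) for
minus-strand genes — the lower bound is closed, so a site exactly 150 bp
upstream counts. Metagene profiles scale each element body onto a common
bin grid (default 60 body bins; 20 flank bins per 0.5 kb flank for genes,
60 per 3 kb flank for transposon metaplots) with unscaled flanks;
minus-strand elements are orientation-flipped. 6mA profiles use site
frequency (count per bp per bin, averaged over elements; the count-based
reading of "frequency per bin", with mean-ratio mode available through the
5mC path); 5mC metaplots pool reads per bin and report the per-bin weighted
level. Elements shorter than the body bin count are skipped and counted.
The weighted level is methylated reads / (methylated + unmethylated reads)
pooled over the set — invariant to splitting or merging sites and equal to
the mean of per-site ratios exactly when coverage is uniform. An empty
subset is reported as missing, never as zero.

## Expression integration

Genes are ranked by abundance (ties broken by gene id, so stratification
is deterministic and invariant to monotone transforms); quartile Q1 is the
most expressed, zero-abundance genes are flagged silent and placed in Q4,
and top/bottom-400 sets are truncated to disjoint halves with a warning
when fewer than 800 genes exist. Welch's unequal-variance t statistic, the
Welch–Satterthwaite degrees of freedom and the two-tailed p are computed
from first principles (the t distribution supplies the tail); degenerate
zero-variance inputs return t = 0, p = 1 for equal means and ±inf, p = 0
otherwise. Between-condition ratio shifts match sites by (contig,
position, strand) inside the TSS windows of each differential-expression
gene set; fold = ratio_treatment / ratio_control, sites absent from one
condition or with a zero control ratio are excluded and counted. The
fold-change reading of the per-site "ratio" is the default; per-gene
count ratios can be derived from the TSS-window count tables the pipeline
already emits. MAC gain/loss between conditions is presence-based per gene
(a MAC shifted within the window is "stable"). Term enrichment is
one-sided Fisher (hypergeometric upper tail) with p < 0.05, no
multiple-testing correction by default and optional Benjamini–Hochberg —
the one-sided choice targets enrichment specifically.

## In-silico digest and telomeres

The isoschizomer digest partitions GATC occurrences into methylated (a
filtered site on either adenine of the palindrome) and unmethylated; DpnI
cuts the former, DpnII the latter. The cut sits at the palindromic center
(GA^TC, the blunt DpnI cut). Any fixed offset preserves the fragment-size
contrast the digest exposes, but only the central cut keeps fragment
multisets invariant under reverse complementation of the genome, which the
suite verifies. Telomeric repeats are maximal tandem runs of ≥ 2 units of
TTAGGG (or its reverse complement) reported with strand and distance to
the contig end.

## Synthetic methylomes

The generator emits FASTA/GFF3/BED/TSV files in exactly the dialects the
readers accept, plus a truth bundle that exactly describes the planted
sites and clusters. Genomes are i.i.d. base sequences at a target GC
(default 0.4, A/T-rich as in the fungal genomes this emulates) with
non-overlapping genes (1–5 exons, 0.8–2 kb) and repeats laid out with
random gaps; an infeasible layout errors before emission. Default problem
size is one 500 kb contig with 200 genes and 50 repeats — large enough
that ~3300 planted sites resolve fractions to three digits while the whole
simulate-plus-characterize cycle stays in seconds.

The symmetric/clustered regime (defaults: 1.1% of adenines methylated,
symmetric fraction 0.92, in-cluster fraction 0.92) selects genes with
probability rising with expression quartile (0.9/0.6/0.3/0.05) and walks
AT occurrences downstream of the TSS (start offset 0–150 bp, span ≤ 500
bp), methylating both strands with per-site ratio drawn from 0.85–1.0 and
at most one unmethylated motif between consecutive methylated ones. A soft
context preference against T at −1 and A at +2 biases the summarized
consensus without ever lengthening gaps. Scattered background sites
(symmetric ApT pairs as needed, then hemi sites, 70% at ApT) bring the
genome to the exact target level; background picks keep ≥ 41 motif
occurrences away from clusters and from each other, so planted clusters
are unambiguous at every scanned distance — this is the regime's
"inter-cluster gap ≫ internal gap" premise made explicit, and it makes
in-cluster and symmetric fractions exact by construction. The
asymmetric/scattered regime (0.26% level, symmetric fraction 0.003) draws
sites over adenines with multiplicative flank weights (×6 toward A at
−3..−1 and +2, ×6 toward C at +1, ×0.3 against T at +1, via Gumbel-top-k
weighted sampling) and ratios from 0.3–0.7. Planted sites always receive
coverage from a negative binomial (mean 30, dispersion 5) truncated at the
filter threshold and mQv in 30–60, so they pass the default filter;
additionally, 10% extra noise sites carry sub-threshold coverage (1–14) or
quality (mQv 5–20) and exercise the filter realistically. 5mC planting
gives repeats high CG and moderate CHH levels (0.8/0.1/0.2), couples gene
levels inversely to a log-normal expression table (most-expressed genes
least methylated), and draws binomial read counts under the same coverage
model.

What the generator does not emulate: sequencing-error and read-level
structure (counts are drawn directly), kinetic mQv semantics (scores are
draws from a band, not recalibrated qualities), overlapping or nested gene
models, repeat families with internal structure, and any biological
coupling beyond the planted ones. Passing recovery tests therefore
demonstrates the correctness of the bookkeeping — filters, pairing,
clustering, counting, pooling — under realistic coverage noise, not the
robustness of MAC calling to messy real annotations or miscalled bases.

## Determinism and reproducibility

All randomness flows from integer seeds through `numpy` generators; the
dataset emitter derives child seeds for its three stages from one base
seed. No stage depends on iteration order of unordered containers, file
outputs use fixed float formats, and re-running simulate + characterize
with the same resolved configuration reproduces every output byte for
byte, which the suite asserts. Test problem sizes (500 kb fixtures for
recovery, 120 kb for the determinism check, 200 random tracks for the
clustering oracle) were chosen so the whole suite completes in well under
a minute.

## Known limitations

* The recall × purity score is one concrete reading of
  "density × efficiency"; the per-distance table is emitted so other
  scores can be compared, but the scan optimum is only as meaningful as
  the score.
* Occurrence-count distances ignore bp gaps: a cluster may span a long
  AT-free stretch without penalty.
* The feature partition forces single labels; bases in overlapping
  annotations are resolved by precedence, not fractionally.
* Term enrichment treats annotations as flat labels (no ontology graph
  propagation) and, by default, applies no multiple-testing correction.
* GFF3 parsing covers the gene/mRNA/exon/UTR subset the pipeline needs,
  not the full feature grammar.
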