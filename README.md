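# macscan

Dual-methylome characterization for genomes that carry both DNA
N6-methyladenine (6mA) and 5-methylcytosine (5mC) — the situation in many
early-diverging fungi, ciliates and green algae, where 6mA is a major
epigenetic mark. `macscan` takes a genome (FASTA), gene models (GFF3),
repeat intervals (BED), per-site 6mA calls, a bisulfite CX report and an
expression table, and answers the questions an epigenomics analyst asks of
such data:

* How much 6mA is there (`%` of adenines on both strands), and is it
  **strand-symmetric**?  An ApT dinucleotide (5'-AT-3', which reads AT on
  both strands) places one adenine on each strand; methylation of both is a
  symmetric site, one alone is hemi-methylation, and methylated adenines
  outside ApT are asymmetric by construction.
* Is 6mA organized into **methylated adenine clusters (MACs)** — runs of
  methylated AT motifs with few unmethylated motifs between them — and
  where do MACs sit relative to transcription start sites?
* How is 6mA distributed over genomic features (exon, intron, UTRs,
  repeats, 600-bp promoters, intergenic), as log2(observed/expected) with a
  base-composition-aware expectation?
* What are the **weighted 5mC levels** per cytosine context (CG/CHG/CHH),
  i.e. pooled methylated reads over pooled total reads?
* How do 6mA sites, MACs and 5mC couple to **gene expression** (quartiles,
  top/bottom-400 sets, MAC gain/loss between conditions, per-site
  methylation-ratio shifts tested with Welch's *t*, Fisher-exact term
  enrichment)?

### MAC calling

Sites passing the per-site filter (coverage ≥ 15 reads and modification
quality > 25 by default) flag AT-motif occurrences as methylated.  For each
relative distance *d* ∈ 1..40 — the number of unmethylated motifs permitted
between consecutive methylated motifs inside one cluster — clusters are the
maximal chains with ≥ 2 methylated motifs, and the scan scores

&nbsp;&nbsp;&nbsp;&nbsp;score(*d*) = recall(*d*) × purity(*d*)

where recall is the fraction of methylated motifs recovered into clusters
(non-decreasing in *d*) and purity the fraction of spanned motifs that are
methylated (non-increasing in *d*).  The product has an interior optimum;
ties break toward the smaller, more conservative *d*.  The full per-*d*
table is always written so alternative scores can be audited.

A seeded synthetic-methylome generator (`macscan.synthetic_data`) plants
both archetypal regimes with complete ground truth — a high, symmetric,
clustered methylome (~1.1% 6mA, 92% symmetric, MACs just downstream of the
TSS of preferentially highly expressed genes) and a low, asymmetric,
scattered one (~0.26% 6mA, AAA_CA-like context, per-site ratio ≈ 0.5) — so
every stage is testable without any external download.

## Worked example

```python
from macscan import synthetic_data as syn
from macscan import genome_io as gio, site_classification as sc, mac_detection as md

paths = syn.simulate_dataset("demo", syn.phycomyces_like(7),
                             contig_len=200_000, n_genes=80, n_repeats=20)
genome = gio.load_genome(paths["genome"])
raw = gio.load_modification_calls(paths["sites"], genome)
sites, removed = sc.filter_sites(raw, sc.FilterPolicy(min_coverage=15, min_mqv=25.0))
print(f"{len(raw)} calls loaded, {len(sites)} pass the filter (removed: {removed})")
print(f"global 6mA level: {sc.global_level(sites, genome):.3f}% of adenines")
sym = sc.classify_symmetry(sites, genome)
print(f"symmetric fraction: {sym.fraction_symmetric:.3f}  (ApT fraction: {sym.fraction_apt:.3f})")
motif = sc.summarize_contexts(sites, genome)
print(f"consensus context:  {motif.consensus}")
scan, macs = md.detect_macs(genome, sites)
print(f"optimal distance d* = {scan.d_star}; {len(macs)} MACs, median size "
      f"{sorted(m.size for m in macs)[len(macs)//2]} bp")
```

prints

```
1453 calls loaded, 1321 pass the filter (removed: {'low_coverage': 76, 'low_mqv': 56})
global 6mA level: 1.100% of adenines
symmetric fraction: 0.921  (ApT fraction: 0.977)
consensus context:  WWWWWAATTWWWW
optimal distance d* = 1; 34 MACs, median size 282 bp
```

Reading the output: the filter removed the low-coverage/low-quality noise
calls; 1.1% of all adenines carry 6mA; 92% of sites form strand-symmetric
ApT pairs and 97.7% sit in ApT context (the central `AT` of the consensus,
flanked by the A/T-rich `W` columns of this 40% GC genome); the distance
scan selects d\* = 1 and the clusters fall in the 50–500 bp size range.

The same analyses run from the shell: `macscan simulate`,
`macscan characterize` (full pipeline, TSV/BED outputs plus a text report
and the resolved config), `macscan compare` (two conditions: MAC gain/loss
and Welch-tested ratio shifts), `macscan call-macs`, and
`macscan classify-sites`.

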