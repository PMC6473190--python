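# Methods

This note documents the models and procedures implemented in
`capture-atlas`, the assumptions behind them, the defaults of the
synthetic-data generator, and the numerical choices that were genuinely open.

## Coordinates and data model

All internal coordinates are 0-based half-open (BED convention); the GTF
readers/writers shift by one at the I/O boundary and nowhere else. The core
container is the *exon chain*: an ordered, strand-aware tuple of exon
intervals with ≥ 1 bp gaps (introns) between consecutive exons. Reads,
consensus transcripts and annotation entries are all exon chains; a splice
junction is an intron keyed by (chromosome, strand, donor, acceptor).
Unstranded records are accepted on input; every operation that needs
orientation (clustering, classification, TSS logic) rejects them explicitly.

## Haplotype blocks and probes

A block is the closed span of a sentinel SNP and all LD partners with
LD measure strictly above 0.5 and within 500 kb of the sentinel; a
partnerless SNP yields a 1 bp block. The LD column is consumed as-is —
whether it holds r or r² is a property of the upstream LD table, not of this
package. Overlapping *or book-ended* blocks merge (a discrete,
non-overlapping output set requires a convention for adjacency; touching
blocks describe one contiguous capture region, so they merge). Categories
are assigned with exon overlap on either strand taking precedence, then
containment within a transcript span (intronic), else intergenic; the three
categories partition the block set. Probe tiling walks each maximal
sub-interval of the block minus exclusions left-to-right with probe length =
step = 120 nt (1× tiling); a terminal sub-interval shorter than one probe is
left untiled.

## Isoform clustering and consensus

Reads co-cluster only if they have identical intron counts; two reads link
when every corresponding splice-site boundary differs by ≤ d (default 10 nt)
and both transcript ends differ by ≤ e (default 30 nt). Clusters are the
connected components of this relation — single linkage, chosen because the
relation is symmetric and the cloud of reads from one transcript is dense,
and fixed here for reproducibility. Components are grown breadth-first with
a sorted window on one splice column, so the worst case is O(n·w) vectorised
row comparisons rather than per-pair work. Clusters below c = 3 reads are
dropped; then a cluster representing less than p = 1% of the clustered reads
whose spans overlap its own span is dropped (the "locus" denominator is
defined by span overlap — the simplest testable choice).

The consensus takes, per boundary column, the median of member boundaries,
using the *lower* median for even counts so that consensus coordinates stay
on observed splice sites (splice sites are integers; averaging would invent
coordinates). The lower median is very slightly biased toward smaller
coordinates for even-sized clusters; the junction corrector downstream
removes this.

## Junction correction and collapse

Supported splice sites are the donors and acceptors of the annotated
junction set united with the short-read junction table, indexed per
(chromosome, strand, site kind). Each read splice site snaps independently
to the nearest supported site within ±10 bp; ties at equal distance prefer
annotated sites, then higher short-read counts, then the smaller coordinate
(the tie policy must be fixed for determinism; annotated-first reflects the
greater prior weight of curated junctions). A read is discarded when any
site has no supported target within the window, or when snapping collapses
an exon or intron to non-positive length. Collapse groups corrected reads by
exact intron chain — correction has already quantised boundaries, so the
matching tolerance is 0 — and emits one transcript per group with ≥ 3
supporting reads, its ends the lower medians of member read ends. Output
intron chains are unique by construction.

## Filtering and classification

The seven criteria run in order: (i) ≥ 1 bp exonic overlap with ≥ 1 capture
probe required; (ii) ≥ 3 exons; (iii) no intron > 1,000,000 nt (strictly
greater is removed; exactly 1 Mb is retained); (iv) every junction motif in
{GT-AG, GC-AG, AT-AC}, read from the genome on the transcript strand
(reverse-complemented for −); (v) class code not in {e, p, r, s}; (vi)
length ≥ 200 nt (exactly 200 is retained); (vii) redundancy — a transcript
is removed when its intron chain is a contiguous, boundary-exact subset of
another survivor's chain and its span lies within the other's span; ties
keep the longer transcript, equal structures keep the lexicographically
smallest id. Criteria (i)–(vi) are per-transcript predicates, so survival
through them is independent of application order; (vii) runs last among the
survivors.

Class codes follow the published gffcompare conventions, with precedence
`= c j e o i s x p r u`. 's' (antisense intron-chain match) is checked
before 'x' (antisense exonic overlap): an antisense intron-chain match
always entails antisense exonic overlap, so the reverse order could never
assign 's'. 'r' (≥ 50% of exonic bases repeat-masked) is only assigned when
a repeat mask is provided; otherwise it is skipped with a logged warning.
Novelty derives from the code: '='/'c' are known; 'u' is novel intergenic;
'x', and 's' without any same-strand exonic overlap, are novel antisense;
everything else is a novel isoform. The feature census counts unique introns
by exact coordinates and internal exons excluding both terminal exons of
every transcript (terminal boundaries are imprecise in long reads).

## Quantification and spike-in diagnostics

Quantification is a minimal compatibility quantifier adequate for
diagnostics: a read is compatible with a transcript when the read's intron
chain appears as a consecutive run in the transcript's chain and the read's
span stays inside the flanking exons of that run (single-exon reads must sit
inside one exon). Multi-compatible reads split fractionally equally.
TPM_i = (count_i / length_i) / Σ_j (count_j / length_j) × 10⁶ per sample.

*Dose–response*: OLS of log10(mean TPM across samples) on log10(input
concentration), separately for captured and non-captured spike-ins;
undetected isoforms (mean TPM = 0) are excluded and reported.

*Enrichment fold*: at each shared concentration point, the ratio of the mean
captured TPM to the mean non-captured TPM; the estimate is the unweighted
mean of those ratios. A point is *shared* only when, on each side, at least
half of that side's isoforms there are reliably detected — TPM > 0 in more
than one sample, the same rule the limit of detection uses. Without this
guard a point whose non-captured mean rests on a single straggler read
enters the mean with an essentially arbitrary ratio; conditioning on
majority detection keeps the included points in the regime where the
Poisson ratio is stable.

*Limit of detection*: the lowest input concentration among spike-ins
detected (TPM > 0) in more than one sample; a sentinel is returned when
nothing qualifies. Detection is deliberately binary (assigned count ≥ 1) —
no numeric threshold is imposed beyond multi-sample support.

*CV* is the across-sample standard deviation over the mean (undefined, and
flagged, at mean 0); *RPG10K* is reads per gene per 10⁴ aligned reads;
*on-target rate* is the fraction of reads with ≥ 1 bp exonic overlap with
the target regions; *error rates* are summed mismatch (resp. insertion +
deletion) counts over summed aligned bases from the per-read sidecar.
Coverage uniformity computes, per targeted exon, the CV of per-base coverage
on each platform and compares platforms with a two-tailed paired t-test over
exons covered on both (zero-mean exons excluded pairwise; identical
platforms return statistic 0, p 1).

*Assembly evaluation* reports sensitivity = TP/(TP+FN) and precision =
TP/(TP+FP) at five levels: exonic base sets (merged intervals per
chromosome/strand), internal exons by exact boundaries, introns by exact
junctions, transcripts by intron-chain identity, and genes (a truth gene
matched when ≥ 1 of its transcripts is matched; a predicted locus — a group
of span-overlapping same-strand predictions — precise when it contains a
matched transcript). Empty predictions report precision 0 with a
`precision_defined = False` flag.

## Independent evidence

The TSS anchor is the 1 bp position immediately upstream of the strand-aware
5′ end. A hit is any peak within ±500 bp of the anchor (same strand required
for CAGE; the three promoter marks reuse the same window unstranded — the
window is adopted uniformly since no separate mark-specific distance is
defined). The permutation null redraws the same number of anchors uniformly
at random (length-weighted) within the captured-target universe with uniform
random strands, pooled over n_perm = 100 permutations; the odds ratio is
(a/b)/(c/d) with the Haldane–Anscombe +0.5 correction when any cell is
zero. CRS overlap requires ≥ 1 bp *exonic* overlap; mean conservation
averages the per-base track over exonic bases, scoring uncovered bases 0.

## Exon coordination

For a pair of non-adjacent internal exons of a reference transcript, only
*spanning* reads are counted: the read must start before the first exon's
upstream flanking junction and end beyond the second exon's downstream
flanking junction, so a read that merely stops short (truncation) can never
be mistaken for exon skipping. A read contains an exon when one of its exons
matches the reference exon exactly (tolerance 0 — the reads have been
junction-corrected). The two-sided Fisher p sums hypergeometric point
probabilities ≤ the observed one (relative slack 1e−7 against floating-point
equality at the boundary). Pair scans test every non-adjacent internal pair
with ≥ 20 spanning reads, apply Benjamini–Hochberg across tested pairs
(correction on by default, and a flag to disable it when reproducing
single-test analyses), and call dMEP/dMAP by the sign of the
+0.5-corrected odds ratio at q ≤ α.

## The synthetic-data generator

The generator works at the alignment level — spliced exon chains, not base
sequences — because that is the layer the pipeline consumes; per-read error
*counts* (binomial at mismatch rate 0.0511 and indel rate 0.057633, the
nanopore error regime the diagnostics expect) ride in a sidecar table for
the error-rate estimators. Defaults define the study conditions:

- **Genes.** 30 endogenous genes on one chromosome (5–9 exons of 60–300 nt,
  introns 120–1,200 nt), each with 1–2 isoforms (extra isoforms skip one
  internal exon); isoform-0 of every gene is in the public annotation, the
  other isoforms of a "novel" gene (fraction 0.6) are not. Splice motifs are
  planted in the genome per gene (GT-AG majority, some GC-AG and AT-AC, 2%
  deliberately non-canonical), strand-aware, so motif filters read real
  sequence. Expression is lognormal(0, 1); the half of genes inside targeted
  blocks carry a small share (5 × 10⁻⁴) of the endogenous mass — targeted
  blocks harbour lowly expressed non-coding transcription, which is the
  premise of capture enrichment.
- **Spike-ins.** 164 isoforms from 78 genes on a dedicated chromosome, 49
  isoforms from 25 genes targeted for capture, chosen round-robin across the
  ladder so every concentration point carries both captured and non-captured
  isoforms. The ladder has 12 rungs spanning 4.5 orders of magnitude from
  0.059 attomoles/μL; all isoforms of a gene sit on the gene's rung, so each
  point pools ~14 isoforms — enough for stable point ratios at desk-scale
  depth. Spike mass (concentration × length) is scaled to 2% of the total.
- **Reads.** `depth` is the total read count across the experiment (4
  samples); per-transcript counts are independent Poissons with mean ∝
  expression × exonic length × effective enrichment. The length factor makes
  sampling fragment-like, so measured TPM is proportional to input
  concentration (dose–response slope ≈ 1), the regime in which TPM-based
  enrichment ratios estimate the enrichment factor directly. Captured
  transcripts are enriched 230-fold; optional probe saturation damps this
  hyperbolically, E_eff = E / (1 + c/c_sat) — no particular functional form
  is canonical, and any monotone damping would do; this one is simple and
  testable. Boundary jitter is a rounded Normal(0, 2 nt) clipped at ±8 nt
  (inside the 10 bp correction window) and clamped to midpoint cells so
  chains stay valid at any setting; terminal truncation removes a uniform
  fraction of a terminal exon with probability 0.1 per end, independently —
  no 5′/3′ asymmetry is asserted. Truncation never deletes a junction.
- **Short reads.** Junction tables carry exact coordinates; every expressed
  junction receives count max(1, Poisson(expression share × depth)) —
  short-read junction detection is modelled as sensitive and exact over
  expressed transcripts, which is the property the correction stage relies
  on.
- **Evidence tracks.** CAGE peaks are planted within 500 bp of a fraction
  (default 0.75) of *distinct* TSSs, same strand; background peaks are a
  Poisson process calibrated so a random anchor hits at the background rate
  (density doubled for stranded tracks, since only same-strand peaks count),
  and background avoids the ±window neighbourhood of every true TSS so the
  planted fraction *is* the true TSS hit rate and closed-form odds ratios
  hold exactly. Marks reuse the same mechanism unstranded. Conservation
  scores cover merged exonic intervals; CRS intervals sit inside exons of a
  random subset of transcripts. SNP/LD tables are laid out so the built
  blocks tile the genes, with a few intron-contained and intergenic blocks
  for category coverage.

What the generator does **not** emulate: base-level sequences and their
alignment artifacts (systematic splice-site misalignment near repeats,
homopolymer indels), 5′/3′ positional truncation bias, library-level GC and
length bias, inter-sample batch effects, and genuinely novel junctions
absent from both the annotation and the short-read table. Passing tests
therefore demonstrate the correctness and statistical behaviour of the
estimators and transforms on data with the assumed structure — not
performance on real nanopore alignments.

## Benchmark and test-size choices

The clustering benchmark (raw reads vs consensus transcripts through the
five-level evaluation) runs on the endogenous genes at 60,000 total reads
against the *detectable annotation*: truth transcripts whose expected read
count is at least 3× the cluster-support threshold. On a staggered
spike-in ladder the bottom rungs always contain transcripts with 1–2 reads;
those appear in raw-read sensitivity but can never form 3-read clusters, so
including them measures the detection floor of ladder × depth rather than
clustering quality. Against the detectable truth the benchmark shows the
expected direction: large precision gains at every level with sensitivity
drops under 10 percentage points.

Enrichment recovery uses 100,000 total reads on the spike chromosome,
correction against the spike annotation, and the compatibility quantifier;
50 seeded replicates put the estimator mean within a few percent of the
injected 230×. The depth-monotonicity of the limit of detection is checked
with *coupled* runs — binomial thinning of one simulation — because
detection in the thinned run implies detection in the full run, making the
monotonicity exact rather than probabilistic. Fisher's exact test is
verified against exhaustive enumeration of all 2×2 tables with total ≤ 30
and against an independent library implementation on random tables.

Problem sizes throughout (20,000-read default experiments, 60–100k-read
benchmarks, 100 permutations, 50-seed replicate sets) were chosen so the
full suite runs in minutes on one CPU while keeping Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

- The quantifier ignores positional read biases and has no EM over
  ambiguous assignments; it is a diagnostics-grade stand-in, not an
  expression estimator for real data.
- Coding probability is consumed as an external per-transcript score (the
  0.364 cutoff is exposed in `FilterParams`); no coding-potential model is
  trained or applied internally.
- The 'e' class code approximates exon/intron boundary context from exon
  adjacency rather than a full reference model; single-exon codes other than
  'e' are conservative.
- `min_isoform_percent` uses span overlap to define loci; nested but
  non-overlapping gene architectures (genes within introns of other genes)
  will share a denominator.
- Block construction trusts the input LD table; it does not compute LD and
  does not extend block intervals beyond the outermost passing SNP.
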