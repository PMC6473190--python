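# capture-atlas

Targeted hybrid long/short-read transcriptome analysis of GWAS haplotype
blocks.

Most GWAS SNPs for neuropsychiatric traits fall in non-coding DNA, inside
haplotype blocks whose transcription is poorly annotated. Targeted RNA
capture (CaptureSeq) enriches transcripts from those blocks before
sequencing; nanopore long reads then give full-length isoform structures
while matched short reads supply accurate splice junctions. `capture-atlas`
implements the complete analysis around that design for computational
biologists working with spliced alignments:

- **Block construction** — haplotype blocks as the span of a sentinel SNP
  and all LD partners with r > 0.5 within 500 kb, merged into discrete
  non-overlapping blocks, categorised (exonic-overlap / intronic /
  intergenic) and tiled with capture probes that skip exons and repeats.
- **Isoform clustering** — single-linkage clustering of spliced exon chains
  with identical intron counts, linking reads whose splice boundaries agree
  within *d* = 10 nt (ends within *e* = 30 nt), and a per-cluster consensus
  taking the median of each exon boundary (defaults `-c 3 -d 10 -e 30 -p 1`).
- **Junction correction + collapse** — every read splice site is snapped to
  the nearest annotated or short-read-supported site within a 10 bp window
  (unsalvageable reads discarded), and corrected reads collapse into a
  non-redundant transcriptome keyed by exact intron chains.
- **Filtering + classification** — the seven-criterion high-confidence
  filter (probe overlap; ≥ 3 exons; no intron > 1 Mb; canonical GT-AG/GC-AG/
  AT-AC junctions; no class code in {e, p, r, s}; ≥ 200 nt; non-redundant)
  and gffcompare-style class codes with novelty calls (known, novel isoform,
  novel antisense, novel intergenic), summarised per block.
- **Spike-in diagnostics** — with a staggered synthetic spike-in ladder
  (164 isoforms / 78 genes, 49 isoforms targeted for capture): log-log
  dose–response fits of TPM on input concentration, capture enrichment fold
  (mean over shared concentration points of captured/non-captured TPM
  ratios), limit of detection (lowest concentration detected in more than
  one sample), per-isoform CV, RPG10K, on-target rate, error rates and
  per-exon coverage uniformity with a paired *t*-test.
- **Independent evidence** — CAGE peak and epigenetic-mark proximity to
  TSSs (±500 bp, strand-aware for CAGE), permutation odds ratios against
  randomised positions in the target space, conserved-RNA-structure overlap
  and mean per-base conservation.
- **Exon coordination** — for distant pairs of internal exons, spanning
  reads are partitioned into a 2×2 table (both / first only / second only /
  neither) and tested with a two-sided Fisher's exact test
  (p = Σ hypergeometric probabilities ≤ that of the observed table);
  Benjamini–Hochberg-significant pairs are called dMAP (odds ratio > 1) or
  dMEP (odds ratio < 1).

A fully seeded synthetic-data module generates the toy genome, annotation,
spike-in ladder, capture design, ONT-like exon-chain reads (boundary jitter,
terminal truncation, binomial error counts at 5.11% mismatch / 5.7633%
indel rates, ~230× capture enrichment with optional probe saturation) and
exact short-read junction tables, so the whole pipeline runs end-to-end on a
laptop with known ground truth.

## Worked example

```python
from capture_atlas.simulate import (SimulationConfig, simulate_genome_and_annotation,
                                    simulate_long_reads, simulate_short_read_junctions)
from capture_atlas.correct import (correct_chains, collapse,
                                   junctions_from_annotation, junction_validation_rate)
from capture_atlas.coordination import ContingencyTable2x2, fisher_exact

cfg = SimulationConfig(seed=1)          # 20,000 reads, 4 samples, staggered spike ladder
exp = simulate_genome_and_annotation(cfg)
reads = simulate_long_reads(exp)
short = simulate_short_read_junctions(exp)

before = junction_validation_rate(reads.reads, short)
corrected, report = correct_chains(
    reads.reads, junctions_from_annotation(exp.annotation), short
)
after = junction_validation_rate(corrected, short)
models = collapse(corrected)

print(f"reads corrected:        {report.n_corrected} ({report.corrected_fraction:.1%})")
print(f"junction validation:    {before:.1%} -> {after:.1%}")
print(f"collapsed transcripts:  {len(models)}")

p = fisher_exact(ContingencyTable2x2(both=0, first_only=19, second_only=37, neither=50))
print(f"exon-pair Fisher p:     {p:.3g}")
```

prints

```
reads corrected:        19997 (100.0%)
junction validation:    1.6% -> 100.0%
collapsed transcripts:  90
exon-pair Fisher p:     0.000123
```

Raw nanopore-like junctions rarely match the short-read table exactly
(1.6%); after window-10 correction every surviving junction is supported,
and collapsing recovers the 90 expressed transcripts with ≥ 3 reads. The
Fisher example is the classic mutually exclusive exon pair: reads never
carry both exons, and the two-sided exact test gives p = 1.23 × 10⁻⁴.

The same pipeline is available from the shell:

```bash
capture-atlas run-all --seed 1 --outdir results/run1
```

which executes simulate → blocks → cluster → correct → collapse →
filter/classify → spike-in diagnostics → evidence → coordination and writes
a JSON manifest recording parameters, seeds, input hashes and per-stage
record counts (`--resume` skips stages whose inputs are unchanged).

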