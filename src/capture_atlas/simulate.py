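"""Seeded synthetic data: toy genome, annotation, spike-in ladder, capture
design, ONT-like exon-chain reads and short-read junction tables.

The generator works at the *alignment* level: long reads are emitted as
spliced exon chains (BED12-equivalent) with boundary jitter, terminal-exon
truncation and a per-read error-count sidecar, not as base sequences. This is
the layer the downstream pipeline consumes, so no aligner is needed.

Defaults mirror the experimental regime the pipeline targets: a staggered
spike-in ladder spanning >= 4 orders of magnitude at 2% fractional abundance
(164 isoforms from 78 synthetic genes, 49 isoforms from 25 genes targeted
for capture), ~230-fold capture enrichment, and ONT-like error rates
(mismatch 5.11%, indel 5.7633%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    CANONICAL_MOTIFS,
    ExonChain,
    GenomicInterval,
    SpliceJunction,
    TranscriptModel,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Neuropsychiatric trait labels for synthetic GWAS rows.
_TRAITS = (
    "schizophrenia",
    "alzheimers_disease",
    "parkinsons_disease",
    "alcohol_dependence",
    "smoking_behaviour",
    "bipolar_disorder",
)


def plant_motif(seq: bytearray, donor: int, acceptor: int, motif: str,
                strand: str) -> None:
    """Write a splice-site dinucleotide pair into the genome sequence.

    ``motif`` is given on the transcript strand; for '-' the reverse
    complement is written to the sense strand.
    """
    d_nt, a_nt = motif.split("-")
    if strand == "-":
        d_nt, a_nt = revcomp(a_nt), revcomp(d_nt)
    seq[donor : donor + 2] = d_nt.encode()
    seq[acceptor - 2 : acceptor] = a_nt.encode()


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment.

    ``depth`` is the total long-read count across the whole experiment
    (all samples pooled); per-sample depth is ``depth / n_samples``.
    """

    seed: int = 0

    # genome & annotation
    n_genes: int = 30
    min_exons_per_gene: int = 5
    max_exons_per_gene: int = 9
    isoforms_per_gene: int = 2
    min_isoforms_per_gene: int = 1
    exon_len_range: Tuple[int, int] = (60, 300)
    intron_len_range: Tuple[int, int] = (120, 1200)
    intergenic_gap_range: Tuple[int, int] = (2000, 6000)
    noncanonical_fraction: float = 0.02
    gc_ag_fraction: float = 0.08
    at_ac_fraction: float = 0.04
    novel_isoform_fraction: float = 0.6
    captured_gene_fraction: float = 0.5
    target_expression_share: float = 5e-4

    # spike-ins (Mix A-like staggered ladder)
    include_spikeins: bool = True
    n_spike_genes: int = 78
    n_spike_isoforms: int = 164
    n_captured_spike_genes: int = 25
    n_captured_spike_isoforms: int = 49
    ladder_min_concentration: float = 0.059
    ladder_orders: float = 4.5
    ladder_rungs: int = 12
    spike_fraction: float = 0.02

    # long reads
    n_samples: int = 4
    depth: int = 20000
    boundary_jitter_sd: float = 2.0
    junction_wobble_max: int = 8
    truncation_prob: float = 0.1
    mismatch_rate: float = 0.0511
    indel_rate: float = 0.057633
    capture_enrichment: float = 230.0
    capture_saturation_concentration: Optional[float] = None

    # short reads
    short_read_depth: int = 50000

    # GWAS / evidence tracks
    n_intronic_blocks: int = 3
    n_intergenic_blocks: int = 5
    cage_fraction: float = 0.75
    cage_background_rate: float = 0.1
    cage_window: int = 500
    crs_fraction: float = 0.15
    probe_length: int = 120

    def __post_init__(self) -> None:
        for name in ("noncanonical_fraction", "gc_ag_fraction", "at_ac_fraction",
                     "novel_isoform_fraction", "captured_gene_fraction",
                     "truncation_prob", "mismatch_rate", "indel_rate",
                     "spike_fraction", "cage_fraction", "cage_background_rate",
                     "crs_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.capture_enrichment < 1:
            raise ValueError("capture_enrichment must be >= 1")
        if self.ladder_orders < 4:
            raise ValueError("spike-in ladder must span >= 4 orders of magnitude")
        if self.min_exons_per_gene < 4:
            raise ValueError("genes need >= 4 exons so skip isoforms stay multi-exonic")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


@dataclass
class SyntheticExperiment:
    """Ground truth of one simulated experiment."""

    config: SimulationConfig
    sequences: Dict[str, str]
    transcripts: List[TranscriptModel]
    annotation: List[TranscriptModel]
    expression: Dict[str, float]
    captured: Dict[str, bool]
    concentration: Dict[str, float]
    spikeins: pd.DataFrame
    target_regions: List[GenomicInterval]
    junction_motifs: Dict[Tuple[str, str, int, int], str]

    @property
    def transcripts_by_id(self) -> Dict[str, TranscriptModel]:
        return {t.id: t for t in self.transcripts}

    def effective_enrichment(self, tid: str) -> float:
        """Capture enrichment with optional probe-saturation damping.

        E_eff = E / (1 + c / c_sat); hyperbolic damping of enrichment at
        high input concentration.
        """
        cfg = self.config
        if not self.captured[tid]:
            return 1.0
        e = cfg.capture_enrichment
        c_sat = cfg.capture_saturation_concentration
        if c_sat is not None:
            c = self.concentration.get(tid, 0.0)
            if c and not math.isnan(c):
                e = e / (1.0 + c / c_sat)
        return max(e, 1.0)

    def read_weights(self) -> Dict[str, float]:
        """Relative expected read share per transcript.

        Sampling is fragment-like: weight = molar expression x exonic length
        x effective enrichment, so measured TPM is proportional to input
        concentration (dose-response slope ~ 1), matching the behaviour of
        TPM quantification on captured cDNA libraries.
        """
        return {
            t.id: self.expression[t.id] * t.length
            * self.effective_enrichment(t.id)
            for t in self.transcripts
        }

    def expressed_junctions(self) -> Dict[Tuple[str, str, int, int], float]:
        """Expressed unique junctions mapped to summed expression weight."""
        out: Dict[Tuple[str, str, int, int], float] = {}
        for t in self.transcripts:
            w = self.expression[t.id]
            if w <= 0:
                continue
            for d, a in t.chain.introns:
                key = (t.chrom, t.strand, d, a)
                out[key] = out.get(key, 0.0) + w
        return out

    def probes(self) -> List[GenomicInterval]:
        """1x tiling probes across the target regions."""
        plen = self.config.probe_length
        out = []
        for iv in self.target_regions:
            pos = iv.start
            while pos + plen <= iv.end:
                out.append(GenomicInterval(iv.chrom, pos, pos + plen))
                pos += plen
        return out


def _random_sequence(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, n)].tobytes())


def _pick_motif(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    u = rng.random()
    if u < cfg.noncanonical_fraction:
        return "CC-GG"  # deliberately non-canonical on either strand
    u -= cfg.noncanonical_fraction
    if u < cfg.gc_ag_fraction:
        return "GC-AG"
    if u < cfg.gc_ag_fraction + cfg.at_ac_fraction:
        return "AT-AC"
    return "GT-AG"


def _build_gene(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    cursor: int,
) -> Tuple[Tuple[Tuple[int, int], ...], str, str, int]:
    """Lay out one gene's master exon set from ``cursor``.

    Returns (exons, strand, motif, new_cursor).
    """
    n_exons = int(rng.integers(cfg.min_exons_per_gene, cfg.max_exons_per_gene + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    motif = _pick_motif(rng, cfg)
    exons = []
    pos = cursor
    for i in range(n_exons):
        elen = int(rng.integers(*cfg.exon_len_range))
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_exons - 1:
            pos += int(rng.integers(*cfg.intron_len_range))
    return tuple(exons), strand, motif, pos


def _isoforms_for_gene(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    master: Tuple[Tuple[int, int], ...],
    n_isoforms: int,
) -> List[Tuple[Tuple[int, int], ...]]:
    """Isoform 0 is the full exon set; each extra isoform skips one distinct
    internal exon."""
    isoforms = [master]
    internal = list(range(1, len(master) - 1))
    n_extra = min(n_isoforms - 1, len(internal))
    skipped = rng.choice(internal, size=n_extra, replace=False)
    for idx in sorted(int(i) for i in skipped):
        isoforms.append(tuple(e for j, e in enumerate(master) if j != idx))
    return isoforms


def simulate_genome_and_annotation(cfg: SimulationConfig) -> SyntheticExperiment:
    """Build the toy genome, gene models, spike-in ladder and capture design.

    Splice motifs are planted at every intron (canonical at >= 1 -
    ``noncanonical_fraction`` of genes); every transcript's exact structure
    is retained as ground truth. Deterministic under ``cfg.seed``.
    """
    rng = cfg.rng(1)

    sequences: Dict[str, str] = {}
    transcripts: List[TranscriptModel] = []
    annotation: List[TranscriptModel] = []
    expression: Dict[str, float] = {}
    captured: Dict[str, bool] = {}
    concentration: Dict[str, float] = {}
    junction_motifs: Dict[Tuple[str, str, int, int], str] = {}
    target_regions: List[GenomicInterval] = []
    gene_spans: Dict[str, Tuple[str, int, int]] = {}

    def emit_gene(chrom, seq, gene_id, exons, strand, motif, n_iso, annotated_mask):
        for d, a in zip([e for _, e in exons[:-1]], [s for s, _ in exons[1:]]):
            plant_motif(seq, d, a, motif, strand)
        isoforms = _isoforms_for_gene(rng, cfg, exons, n_iso)
        tids = []
        for k, iso_exons in enumerate(isoforms):
            tid = f"{gene_id}.{k + 1}"
            chain = ExonChain(tid, chrom, strand, iso_exons)
            tm = TranscriptModel(tid, gene_id, chain)
            transcripts.append(tm)
            if annotated_mask[k]:
                annotation.append(tm)
            for d, a in chain.introns:
                junction_motifs[(chrom, strand, d, a)] = (
                    motif if motif in CANONICAL_MOTIFS else "other"
                )
            tids.append(tid)
        gene_spans[gene_id] = (chrom, exons[0][0], exons[-1][1])
        return tids

    # ---- endogenous genes on chr1 -------------------------------------
    chrom = "chr1"
    est_len = cfg.n_genes * (
        cfg.max_exons_per_gene * cfg.exon_len_range[1]
        + (cfg.max_exons_per_gene - 1) * cfg.intron_len_range[1]
        + cfg.intergenic_gap_range[1]
    ) + 20000
    seq = _random_sequence(rng, est_len)
    cursor = 5000
    n_captured_genes = int(round(cfg.n_genes * cfg.captured_gene_fraction))
    captured_gene_ids = set(range(n_captured_genes))  # first genes are in blocks
    endo_tids: List[str] = []
    for g in range(cfg.n_genes):
        cursor += int(rng.integers(*cfg.intergenic_gap_range))
        exons, strand, motif, cursor = _build_gene(rng, cfg, cursor)
        gene_id = f"GENE{g + 1:03d}"
        n_iso = int(rng.integers(cfg.min_isoforms_per_gene,
                                 cfg.isoforms_per_gene + 1))
        novel_gene = rng.random() < cfg.novel_isoform_fraction
        mask = [True] + [not novel_gene] * (n_iso - 1)
        tids = emit_gene(chrom, seq, gene_id, exons, strand, motif, n_iso, mask)
        is_captured = g in captured_gene_ids
        for tid in tids:
            captured[tid] = is_captured
            concentration[tid] = float("nan")
            expression[tid] = float(rng.lognormal(0.0, 1.0))
        endo_tids.extend(tids)
        if is_captured:
            span = gene_spans[gene_id]
            target_regions.append(
                GenomicInterval(span[0], max(0, span[1] - 500), span[2] + 500)
            )
    sequences[chrom] = seq[: cursor + 5000].decode()

    # rescale captured endogenous genes to the (small) targeted mass share:
    # targeted blocks harbour lowly expressed non-coding transcription.
    lengths = {t.id: t.length for t in transcripts}
    cap_ids = [t for t in endo_tids if captured[t]]
    non_ids = [t for t in endo_tids if not captured[t]]
    if cap_ids and non_ids and cfg.target_expression_share > 0:
        s = cfg.target_expression_share
        w_cap = sum(expression[t] * lengths[t] for t in cap_ids)
        w_non = sum(expression[t] * lengths[t] for t in non_ids)
        scale = (s / (1 - s)) * w_non / w_cap
        for t in cap_ids:
            expression[t] *= scale

    # ---- spike-in genes on chrIS --------------------------------------
    spike_rows = []
    if cfg.include_spikeins:
        chrom = "chrIS"
        est_len = cfg.n_spike_genes * (
            cfg.max_exons_per_gene * cfg.exon_len_range[1]
            + (cfg.max_exons_per_gene - 1) * cfg.intron_len_range[1]
            + cfg.intergenic_gap_range[1]
        ) + 20000
        seq = _random_sequence(rng, est_len)
        cursor = 5000

        # isoform count per gene chosen to hit n_spike_isoforms exactly
        extra = cfg.n_spike_isoforms - 2 * cfg.n_spike_genes
        iso_counts = [3] * extra + [2] * (cfg.n_spike_genes - extra)
        # captured genes chosen round-robin over ladder rungs so every
        # concentration point carries both captured and non-captured isoforms
        n_cap_genes = min(cfg.n_captured_spike_genes, cfg.n_spike_genes)
        cap_list: List[int] = []
        offset = 0
        while len(cap_list) < n_cap_genes:
            for r in range(cfg.ladder_rungs):
                g = r + offset * cfg.ladder_rungs
                if g < cfg.n_spike_genes and g not in cap_list:
                    cap_list.append(g)
                    if len(cap_list) == n_cap_genes:
                        break
            offset += 1
        # distribute the captured-isoform budget over the captured genes so
        # each captured gene contributes at least one captured isoform
        base, extra = divmod(cfg.n_captured_spike_isoforms, n_cap_genes)
        cap_quota = {
            g: base + (1 if i < extra else 0) for i, g in enumerate(cap_list)
        }
        cap_genes = set(cap_list)
        ratio = 10 ** (cfg.ladder_orders / (cfg.ladder_rungs - 1))
        rungs = cfg.ladder_min_concentration * ratio ** np.arange(cfg.ladder_rungs)

        n_cap_iso = 0
        for g in range(cfg.n_spike_genes):
            cursor += int(rng.integers(*cfg.intergenic_gap_range))
            exons, strand, _motif, cursor = _build_gene(rng, cfg, cursor)
            motif = "GT-AG"  # sequin-style loci: canonical splicing throughout
            gene_id = f"S{g + 1:03d}"
            n_iso = iso_counts[g]
            mask = [True] * n_iso  # the spike annotation is fully known
            tids = emit_gene(chrom, seq, gene_id, exons, strand, motif, n_iso, mask)
            # all isoforms of a gene sit on the gene's ladder rung, so each
            # concentration point pools enough isoforms for stable ratios
            gene_conc = float(rungs[g % cfg.ladder_rungs])
            for k, tid in enumerate(tids):
                conc = gene_conc
                is_cap = g in cap_genes and k < cap_quota[g]
                if is_cap:
                    n_cap_iso += 1
                captured[tid] = is_cap
                concentration[tid] = conc
                expression[tid] = conc
                spike_rows.append(
                    {"isoform_id": tid, "gene_id": gene_id,
                     "concentration": conc, "captured": is_cap}
                )
            if g in cap_genes:
                span = gene_spans[gene_id]
                target_regions.append(
                    GenomicInterval(span[0], max(0, span[1] - 500), span[2] + 500)
                )
        sequences[chrom] = seq[: cursor + 5000].decode()

        # scale spike expression to the configured fractional abundance
        # (a mass fraction: expression x exonic length)
        lengths = {t.id: t.length for t in transcripts}
        spike_ids = [r["isoform_id"] for r in spike_rows]
        w_spike = sum(expression[t] * lengths[t] for t in spike_ids)
        w_endo = sum(expression[t] * lengths[t] for t in endo_tids)
        f = cfg.spike_fraction
        scale = (f / (1 - f)) * w_endo / w_spike
        for t in spike_ids:
            expression[t] *= scale

    spikeins = pd.DataFrame(
        spike_rows, columns=["isoform_id", "gene_id", "concentration", "captured"]
    )
    return SyntheticExperiment(
        config=cfg,
        sequences=sequences,
        transcripts=transcripts,
        annotation=annotation,
        expression=expression,
        captured=captured,
        concentration=concentration,
        spikeins=spikeins,
        target_regions=target_regions,
        junction_motifs=junction_motifs,
    )


# ---------------------------------------------------------------------------
# Long reads


@dataclass
class LongReadSet:
    """Simulated spliced long reads plus the per-read error sidecar.

    The sidecar has columns read_id, sample, transcript_id, aligned_bases,
    mismatches, insertions, deletions.
    """

    reads: List[ExonChain]
    sidecar: pd.DataFrame

    def reads_for_sample(self, sample: int) -> List[ExonChain]:
        ids = set(self.sidecar.loc[self.sidecar["sample"] == sample, "read_id"])
        return [r for r in self.reads if r.id in ids]


def _jitter_chain(
    rng: np.random.Generator,
    exons: np.ndarray,
    n: int,
    sd: float,
    wobble: int,
    trunc_prob: float,
) -> np.ndarray:
    """Vectorised boundary jitter + terminal truncation for ``n`` reads of
    one transcript. ``exons`` is a (k, 2) array; returns (n, k, 2)."""
    bounds = exons.reshape(-1).astype(np.int64)  # length 2k, strictly increasing
    m = bounds.size
    if sd > 0:
        jit = np.rint(rng.normal(0.0, sd, size=(n, m))).astype(np.int64)
        jit = np.clip(jit, -wobble, wobble)
    else:
        jit = np.zeros((n, m), dtype=np.int64)
    pos = bounds[None, :] + jit
    # clamp each boundary inside the midpoint cell around its true position
    # so chains stay valid (ordered exons, >= 1 bp introns) for any sd
    mids = (bounds[:-1] + bounds[1:]) // 2
    lo = np.concatenate(([0], mids + 1))
    hi = np.concatenate((mids, [bounds[-1] + 10 * (wobble + 1)]))
    pos = np.clip(pos, lo[None, :], hi[None, :])
    if trunc_prob > 0:
        first_len = pos[:, 1] - pos[:, 0]
        last_len = pos[:, -1] - pos[:, -2]
        cut5 = (rng.random(n) < trunc_prob) * np.floor(
            rng.random(n) * (first_len - 1)
        ).astype(np.int64)
        cut3 = (rng.random(n) < trunc_prob) * np.floor(
            rng.random(n) * (last_len - 1)
        ).astype(np.int64)
        pos[:, 0] += np.maximum(cut5, 0)
        pos[:, -1] -= np.maximum(cut3, 0)
    return pos.reshape(n, m // 2, 2)


def simulate_long_reads(
    exp: SyntheticExperiment,
    seed: Optional[int] = None,
    depth: Optional[int] = None,
    chroms: Optional[Sequence[str]] = None,
) -> LongReadSet:
    """Draw ONT-like exon-chain reads from the truth.

    Per sample, each transcript receives Poisson(weight / total x per-sample
    depth) reads, where weight = expression x effective capture enrichment.
    Exon boundaries are jittered by a rounded, wobble-clipped Normal(0, sd);
    terminal exons are truncated by a uniform fraction with the configured
    per-end probability. Error counts are drawn binomially per read at the
    configured mismatch/indel rates.

    ``chroms`` restricts emission to transcripts on those chromosomes while
    keeping each transcript's expected read count from the full experiment
    (the per-transcript counts are independent Poissons, so the restricted
    set has exactly the marginal law of the full run's subset).
    """
    cfg = exp.config
    rng = np.random.default_rng(
        [cfg.seed if seed is None else seed, 2]
    )
    total_depth = cfg.depth if depth is None else depth
    per_sample = total_depth / cfg.n_samples

    weights = exp.read_weights()
    all_tids = [t.id for t in exp.transcripts]
    w = np.array([weights[t] for t in all_tids], dtype=float)
    lam_all = w / w.sum() * per_sample
    if chroms is None:
        tids, lam = all_tids, lam_all
    else:
        allowed = set(chroms)
        by_id = exp.transcripts_by_id
        keep = [i for i, t in enumerate(all_tids)
                if by_id[t].chrom in allowed]
        tids = [all_tids[i] for i in keep]
        lam = lam_all[keep]

    reads: List[ExonChain] = []
    rows = {
        "read_id": [], "sample": [], "transcript_id": [],
        "aligned_bases": [], "mismatches": [], "insertions": [], "deletions": [],
    }
    by_id = exp.transcripts_by_id
    for s in range(cfg.n_samples):
        counts = rng.poisson(lam)
        for tid, n in zip(tids, counts):
            if n == 0:
                continue
            t = by_id[tid]
            exons = np.array(t.chain.exons, dtype=np.int64)
            chains = _jitter_chain(
                rng, exons, int(n), cfg.boundary_jitter_sd,
                cfg.junction_wobble_max, cfg.truncation_prob,
            )
            lens = (chains[:, :, 1] - chains[:, :, 0]).sum(axis=1)
            mm = rng.binomial(lens, cfg.mismatch_rate)
            ind = rng.binomial(lens, cfg.indel_rate)
            ins = rng.binomial(ind, 0.5)
            base = len(reads)
            for i in range(int(n)):
                rid = f"s{s}_r{base + i}"
                reads.append(
                    ExonChain(rid, t.chrom, t.strand,
                              tuple(map(tuple, chains[i])))
                )
                rows["read_id"].append(rid)
                rows["sample"].append(s)
                rows["transcript_id"].append(tid)
                rows["aligned_bases"].append(int(lens[i]))
                rows["mismatches"].append(int(mm[i]))
                rows["insertions"].append(int(ins[i]))
                rows["deletions"].append(int(ind[i] - ins[i]))
    return LongReadSet(reads=reads, sidecar=pd.DataFrame(rows))


def thin_reads(readset: LongReadSet, keep_fraction: float,
               seed: int) -> LongReadSet:
    """Binomially thin a read set (coupled shallower sequencing run).

    Thinning the same run guarantees depth-monotonicity of detection-based
    statistics, which independent re-simulation would not.
    """
    rng = np.random.default_rng([seed, 9])
    keep = rng.random(len(readset.reads)) < keep_fraction
    kept_ids = {r.id for r, k in zip(readset.reads, keep) if k}
    return LongReadSet(
        reads=[r for r in readset.reads if r.id in kept_ids],
        sidecar=readset.sidecar[readset.sidecar["read_id"].isin(kept_ids)]
        .reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Short-read junction evidence


def simulate_short_read_junctions(
    exp: SyntheticExperiment, seed: Optional[int] = None
) -> List[SpliceJunction]:
    """Exact-coordinate junction table emulating a spliced short-read aligner.

    Every expressed junction receives count max(1, Poisson(share x depth)):
    short-read junction detection is modelled as exact and sensitive over
    expressed transcripts, its counts proportional to expression.
    """
    cfg = exp.config
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 3])
    expressed = exp.expressed_junctions()
    total_w = sum(exp.expression[t.id] for t in exp.transcripts)
    annotated_keys = {
        (t.chrom, t.strand, d, a)
        for t in exp.annotation
        for d, a in t.chain.introns
    }
    out = []
    for key in sorted(expressed):
        chrom, strand, d, a = key
        lam = expressed[key] / total_w * cfg.short_read_depth
        count = max(1, int(rng.poisson(lam)))
        out.append(
            SpliceJunction(
                chrom=chrom, donor=d, acceptor=a, strand=strand,
                motif=exp.junction_motifs.get(key, "unknown"),
                short_read_count=count,
                annotated=key in annotated_keys,
            )
        )
    return out


# ---------------------------------------------------------------------------
# GWAS / evidence inputs


@dataclass
class GwasInputs:
    snps: pd.DataFrame          # rsid, chrom, pos, trait
    ld: pd.DataFrame            # rsid, partner_pos, r
    cage_peaks: List[GenomicInterval]
    marks: Dict[str, List[GenomicInterval]]
    crs: List[GenomicInterval]
    conservation: List[Tuple[str, int, int, float]]
    expected_block_spans: List[GenomicInterval]


def _plant_peaks_near_tss(
    rng: np.random.Generator,
    transcripts: Sequence[TranscriptModel],
    fraction: float,
    window: int,
    stranded: bool,
    chrom_lens: Dict[str, int],
    background_rate: float,
) -> List[GenomicInterval]:
    """Peaks near a fraction of TSSs plus uniform background peaks.

    Background peaks avoid the +/-(window + margin) neighbourhood of every
    TSS so the planted fraction is exactly the TSS hit rate.
    """
    peaks: List[GenomicInterval] = []
    width = 20
    tss_by_chrom: Dict[str, List[int]] = {}
    # one planting decision per distinct TSS (isoforms of a gene share it)
    anchors = sorted({(t.chrom, t.tss, t.strand) for t in transcripts})
    for chrom, tss, strand in anchors:
        tss_by_chrom.setdefault(chrom, []).append(tss)
        if rng.random() < fraction:
            offset = int(rng.integers(-(window - width - 10), window - width - 10))
            start = max(0, tss + offset)
            peaks.append(
                GenomicInterval(chrom, start, start + width,
                                strand if stranded else ".")
            )
    # Poisson background with per-anchor hit rate ~= background_rate;
    # stranded tracks need double density since only same-strand peaks count
    lam_per_bp = -math.log(max(1e-12, 1.0 - background_rate)) / (2 * window + width)
    if stranded:
        lam_per_bp *= 2
    margin = window + width + 50
    for chrom, clen in chrom_lens.items():
        n_bg = rng.poisson(lam_per_bp * clen)
        sites = np.sort(rng.integers(0, max(1, clen - width), size=n_bg))
        excl = np.array(sorted(tss_by_chrom.get(chrom, [])), dtype=np.int64)
        for s in sites:
            if excl.size:
                i = int(np.searchsorted(excl, s))
                near = []
                if i < excl.size:
                    near.append(abs(int(excl[i]) - int(s)))
                if i > 0:
                    near.append(abs(int(excl[i - 1]) - int(s)))
                if near and min(near) <= margin:
                    continue
            strand = ("+" if rng.random() < 0.5 else "-") if stranded else "."
            peaks.append(GenomicInterval(chrom, int(s), int(s) + width, strand))
    return peaks


def simulate_gwas_inputs(
    exp: SyntheticExperiment, seed: Optional[int] = None
) -> GwasInputs:
    """SNP/LD tables whose built blocks tile the genes, plus CAGE peaks,
    promoter marks, conserved-structure intervals and a conservation track."""
    cfg = exp.config
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 4])

    snp_rows, ld_rows, expected = [], [], []
    rs = 1000

    gene_spans: Dict[str, Tuple[str, int, int, TranscriptModel]] = {}
    for t in exp.transcripts:
        if t.chrom == "chrIS":
            continue
        key = t.gene_id
        if key not in gene_spans:
            gene_spans[key] = (t.chrom, t.chain.start, t.chain.end, t)
        else:
            c, s, e, t0 = gene_spans[key]
            gene_spans[key] = (c, min(s, t.chain.start), max(e, t.chain.end), t0)

    # the first n_intronic_blocks genes get an intron-contained block (SNP
    # and partners inside one intron); the rest get a gene-spanning
    # (exonic-overlap) block -- separating the two keeps intronic blocks from
    # being merged into a gene-wide block
    genes = sorted(gene_spans)
    intronic_genes = set(genes[: cfg.n_intronic_blocks])
    for gid, (chrom, start, end, t) in sorted(gene_spans.items()):
        if gid in intronic_genes:
            introns = t.chain.introns
            mids = [iv for iv in introns if iv[1] - iv[0] >= 60]
            if not mids:
                intronic_genes.discard(gid)
            else:
                d, a = mids[len(mids) // 2]
                rsid = f"rs{rs}"
                rs += 1
                snp_rows.append({"rsid": rsid, "chrom": t.chrom,
                                 "pos": (d + a) // 2,
                                 "trait": _TRAITS[rs % len(_TRAITS)]})
                for ppos in (d + 10, a - 11):
                    ld_rows.append({"rsid": rsid, "partner_pos": int(ppos),
                                    "r": float(rng.uniform(0.55, 0.95))})
                expected.append(GenomicInterval(chrom, d + 10, a - 10))
                continue
        rsid = f"rs{rs}"
        rs += 1
        pos = int(rng.integers(start, end))
        trait = _TRAITS[rs % len(_TRAITS)]
        snp_rows.append({"rsid": rsid, "chrom": chrom, "pos": pos, "trait": trait})
        for ppos in (start, end - 1):
            ld_rows.append({"rsid": rsid, "partner_pos": int(ppos),
                            "r": float(rng.uniform(0.55, 0.95))})
        expected.append(GenomicInterval(chrom, min(start, pos), max(end - 1, pos) + 1))

    # intergenic blocks: far from any transcript
    chrom = "chr1"
    clen = len(exp.sequences[chrom])
    occupied = sorted((s, e) for c, s, e, _ in gene_spans.values() if c == chrom)
    for _ in range(cfg.n_intergenic_blocks):
        for _attempt in range(50):
            pos = int(rng.integers(1000, clen - 1000))
            if all(not (s - 1500 <= pos <= e + 1500) for s, e in occupied):
                break
        rsid = f"rs{rs}"
        rs += 1
        snp_rows.append({"rsid": rsid, "chrom": chrom, "pos": pos,
                         "trait": _TRAITS[rs % len(_TRAITS)]})
        for off in (-200, 200):
            ld_rows.append({"rsid": rsid, "partner_pos": pos + off,
                            "r": float(rng.uniform(0.55, 0.95))})

    chrom_lens = {c: len(s) for c, s in exp.sequences.items()}
    endo = [t for t in exp.transcripts if t.chrom != "chrIS"]
    cage = _plant_peaks_near_tss(
        rng, endo, cfg.cage_fraction, cfg.cage_window, True, chrom_lens,
        cfg.cage_background_rate,
    )
    marks = {
        name: _plant_peaks_near_tss(
            rng, endo, frac, cfg.cage_window, False, chrom_lens,
            cfg.cage_background_rate,
        )
        for name, frac in
        (("H3K4me1", 0.7), ("H3K4me3", 0.8), ("H3K27ac", 0.6))
    }

    crs: List[GenomicInterval] = []
    for t in endo:
        if rng.random() < cfg.crs_fraction:
            s, e = t.chain.exons[int(rng.integers(0, t.chain.n_exons))]
            if e - s >= 40:
                start = int(rng.integers(s, e - 30))
                crs.append(GenomicInterval(t.chrom, start, start + 30))

    # conservation: merged exonic intervals get a uniform positive score
    conservation: List[Tuple[str, int, int, float]] = []
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for t in exp.transcripts:
        by_chrom.setdefault(t.chrom, []).extend(t.chain.exons)
    for chrom in sorted(by_chrom):
        merged: List[List[int]] = []
        for s, e in sorted(by_chrom[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            conservation.append((chrom, s, e, float(rng.uniform(0.2, 1.0))))

    return GwasInputs(
        snps=pd.DataFrame(snp_rows),
        ld=pd.DataFrame(ld_rows),
        cage_peaks=cage,
        marks=marks,
        crs=crs,
        conservation=conservation,
        expected_block_spans=expected,
    )
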