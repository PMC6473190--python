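"""Haplotype-block construction from GWAS SNPs and LD partners, block
categorisation against an annotation, and capture-probe tiling.

A block is the closed span of a sentinel SNP and every LD partner passing the
LD threshold (strict ``r > threshold``) within the maximum pairing distance
(500 kb by default). Overlapping or book-ended blocks merge. Blocks are
categorised with exon overlap taking precedence over intronic containment;
everything else is intergenic (no overlap on either strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .core import GenomicInterval, TranscriptModel

CATEGORIES = ("exonic-overlap", "intronic", "intergenic")


class RejectedRecordError(ValueError):
    """An LD partner is inconsistent with its sentinel SNP (e.g. different
    chromosome)."""


@dataclass
class SNPRecord:
    rsid: str
    chrom: str
    pos: int
    trait: str = ""
    ld_partners: List[Tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, r in self.ld_partners:
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"LD r-value out of [0, 1]: {r}")


@dataclass
class HaplotypeBlock:
    block_id: str
    interval: GenomicInterval
    member_snps: List[str]
    traits: List[str]
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")


@dataclass(frozen=True)
class Probe:
    probe_id: str
    interval: GenomicInterval

    def __len__(self) -> int:
        return len(self.interval)


def snp_records_from_tables(
    snps: pd.DataFrame, ld: pd.DataFrame
) -> List[SNPRecord]:
    """Join an SNP TSV (rsid, chrom, pos, trait) with an LD TSV
    (rsid, partner_pos, r)."""
    partners: Dict[str, List[Tuple[int, float]]] = {}
    for row in ld.itertuples(index=False):
        partners.setdefault(row.rsid, []).append(
            (int(row.partner_pos), float(row.r))
        )
    return [
        SNPRecord(
            rsid=row.rsid,
            chrom=row.chrom,
            pos=int(row.pos),
            trait=getattr(row, "trait", ""),
            ld_partners=partners.get(row.rsid, []),
        )
        for row in snps.itertuples(index=False)
    ]


def build_block(
    snp: SNPRecord,
    ld_threshold: float = 0.5,
    max_dist: int = 500_000,
) -> HaplotypeBlock:
    """Span of the sentinel SNP and all partners with r strictly above the
    threshold and within ``max_dist``. A partnerless SNP yields a 1 bp block.

    The LD measure is whichever column the input table carries (r or r^2);
    the threshold is applied to it as-is.
    """
    positions = [snp.pos]
    for pos, r in snp.ld_partners:
        if r > ld_threshold and abs(pos - snp.pos) <= max_dist:
            positions.append(pos)
    lo, hi = min(positions), max(positions)
    return HaplotypeBlock(
        block_id=f"block_{snp.rsid}",
        interval=GenomicInterval(snp.chrom, lo, hi + 1),
        member_snps=[snp.rsid],
        traits=[snp.trait] if snp.trait else [],
    )


def merge_blocks(blocks: Sequence[HaplotypeBlock]) -> List[HaplotypeBlock]:
    """Merge overlapping or book-ended blocks per chromosome.

    Output is sorted and pairwise disjoint; member SNPs and traits are
    unioned. Idempotent.
    """
    ordered = sorted(blocks, key=lambda b: (b.interval.chrom, b.interval.start))
    out: List[HaplotypeBlock] = []
    for b in ordered:
        if (
            out
            and b.interval.chrom == out[-1].interval.chrom
            and b.interval.start <= out[-1].interval.end  # book-ended merges
        ):
            prev = out[-1]
            prev.interval = GenomicInterval(
                prev.interval.chrom,
                prev.interval.start,
                max(prev.interval.end, b.interval.end),
            )
            prev.member_snps = sorted(set(prev.member_snps) | set(b.member_snps))
            prev.traits = sorted(set(prev.traits) | set(b.traits))
        else:
            out.append(
                HaplotypeBlock(
                    block_id=b.block_id,
                    interval=b.interval,
                    member_snps=list(b.member_snps),
                    traits=list(b.traits),
                    category=b.category,
                )
            )
    for i, b in enumerate(out, 1):
        b.block_id = f"block_{i:04d}"
    return out


def build_blocks(
    snps: Sequence[SNPRecord],
    ld_threshold: float = 0.5,
    max_dist: int = 500_000,
) -> List[HaplotypeBlock]:
    """build_block over all SNPs followed by merge_blocks."""
    for snp in snps:
        # partners arrive as positions on the sentinel's chromosome; a table
        # join that produced cross-chromosome partners is rejected upstream
        if snp.pos < 0:
            raise RejectedRecordError(f"negative position for {snp.rsid}")
    return merge_blocks(
        [build_block(s, ld_threshold, max_dist) for s in snps]
    )


def categorize_block(
    block: HaplotypeBlock, annotation: Sequence[TranscriptModel]
) -> str:
    """exonic-overlap if the block intersects any annotated exon on either
    strand; else intronic if it lies entirely within some transcript's span;
    else intergenic."""
    iv = block.interval
    within_span = False
    for t in annotation:
        c = t.chain
        if c.chrom != iv.chrom or c.start >= iv.end or c.end <= iv.start:
            continue
        for s, e in c.exons:
            if s < iv.end and iv.start < e:
                return "exonic-overlap"
        if c.start <= iv.start and iv.end <= c.end:
            within_span = True
    return "intronic" if within_span else "intergenic"


def categorize_blocks(
    blocks: Sequence[HaplotypeBlock], annotation: Sequence[TranscriptModel]
) -> None:
    for b in blocks:
        b.category = categorize_block(b, annotation)


def design_probes(
    block: HaplotypeBlock,
    exclusions: Sequence[GenomicInterval] = (),
    probe_len: int = 120,
    step: Optional[int] = None,
) -> Tuple[List[Probe], int]:
    """Tile probes left-to-right across the block minus excluded intervals
    (annotated protein-coding exons, repeats).

    Returns (probes, total tiled bp). A maximal sub-interval shorter than
    ``probe_len`` yields no probe.
    """
    if probe_len < 1:
        raise ValueError("probe_len must be >= 1")
    step = probe_len if step is None else step
    iv = block.interval
    cuts = sorted(
        (max(e.start, iv.start), min(e.end, iv.end))
        for e in exclusions
        if e.chrom == iv.chrom and e.start < iv.end and iv.start < e.end
    )
    subs: List[Tuple[int, int]] = []
    pos = iv.start
    for s, e in cuts:
        if s > pos:
            subs.append((pos, s))
        pos = max(pos, e)
    if pos < iv.end:
        subs.append((pos, iv.end))

    probes: List[Probe] = []
    tiled = 0
    for s, e in subs:
        p = s
        while p + probe_len <= e:
            probes.append(
                Probe(
                    probe_id=f"{block.block_id}_p{len(probes) + 1}",
                    interval=GenomicInterval(iv.chrom, p, p + probe_len),
                )
            )
            tiled += probe_len
            p += step
    return probes, tiled


def category_counts(blocks: Sequence[HaplotypeBlock]) -> Dict[str, int]:
    out = {c: 0 for c in CATEGORIES}
    for b in blocks:
        if b.category is None:
            raise ValueError(f"block {b.block_id} not categorised")
        out[b.category] += 1
    return out
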