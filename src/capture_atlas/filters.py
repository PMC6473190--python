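"""Seven-criterion transcript filtering and reference-based classification.

Transcripts are classified against a reference annotation with single-letter
class codes in the gffcompare tradition, then filtered by, in order:
(i) no overlap with any capture probe, (ii) fewer than 3 exons, (iii) an
intron longer than 1 Mb (strict), (iv) a non-canonical splice junction
(not GT-AG / GC-AG / AT-AC on the transcript strand), (v) class code in
{e, p, r, s}, (vi) length below 200 nt (strict), and (vii) redundancy —
an intron chain wholly contained (contiguously, boundary-exact) within
another surviving transcript. Novelty classes derive from the codes:
'='/'c' are known; 'x' (and 's' without same-strand overlap) are novel
antisense; 'u' is novel intergenic; everything else is a novel isoform.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .blocks import HaplotypeBlock
from .core import (
    CANONICAL_MOTIFS,
    GenomicInterval,
    TranscriptModel,
    motif_of,
)

CODE_PRECEDENCE = ("=", "c", "j", "e", "o", "i", "s", "x", "p", "r", "u")

CRITERIA = (
    "i_no_probe_overlap",
    "ii_lt3_exons",
    "iii_intron_gt_1mb",
    "iv_noncanonical_junction",
    "v_excluded_class_code",
    "vi_lt200_nt",
    "vii_redundant",
)


@dataclass
class FilterParams:
    min_length: int = 200
    min_exons: int = 3
    max_intron: int = 1_000_000
    canonical_motifs: frozenset = CANONICAL_MOTIFS
    excluded_codes: frozenset = frozenset({"e", "p", "r", "s"})
    coding_cutoff: float = 0.364

    def __post_init__(self) -> None:
        if min(self.min_length, self.min_exons, self.max_intron) <= 0:
            raise ValueError("filter thresholds must be positive")


@dataclass
class ClassifiedTranscript:
    transcript: TranscriptModel
    code: str

    @property
    def novelty(self) -> str:
        return self._novelty

    _novelty: str = field(default="", repr=False)


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    for s1, e1 in a.chain.exons:
        for s2, e2 in b.chain.exons:
            if s1 < e2 and s2 < e1:
                return True
    return False


def _is_contiguous_subchain(sub: tuple, full: tuple) -> bool:
    """True when ``sub`` appears as a consecutive run inside ``full``.

    The empty chain (single-exon transcript) counts as a subchain.
    """
    if not sub:
        return True
    n, m = len(sub), len(full)
    for i in range(m - n + 1):
        if full[i : i + n] == sub:
            return True
    return False


class AnnotationIndex:
    """Reference transcripts indexed by chromosome for overlap queries."""

    def __init__(self, annotation: Sequence[TranscriptModel]):
        from intervaltree import IntervalTree

        self._trees: Dict[str, "IntervalTree"] = {}
        for t in annotation:
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            tree.addi(t.chain.start, t.chain.end, t)

    def overlapping(self, chrom: str, start: int, end: int,
                    pad: int = 0) -> List[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start - pad, end + pad)),
            key=lambda t: (t.chain.start, t.chain.end, t.id),
        )


def classify(
    transcript: TranscriptModel,
    annotation: AnnotationIndex | Sequence[TranscriptModel],
    repeat_mask: Optional[Sequence[GenomicInterval]] = None,
) -> str:
    """Assign the single class code of highest precedence that applies."""
    if transcript.strand not in ("+", "-"):
        raise ValueError(f"transcript {transcript.id} is unstranded")
    index = (
        annotation
        if isinstance(annotation, AnnotationIndex)
        else AnnotationIndex(annotation)
    )
    t = transcript
    span_s, span_e = t.chain.start, t.chain.end
    refs = index.overlapping(t.chrom, span_s, span_e, pad=2000)
    same = [r for r in refs if r.strand == t.strand]
    anti = [r for r in refs if r.strand != t.strand]
    introns = t.chain.introns

    overlapping_same = [
        r for r in same if r.chain.start < span_e and span_s < r.chain.end
    ]
    overlapping_anti = [
        r for r in anti if r.chain.start < span_e and span_s < r.chain.end
    ]

    # '=': identical intron chain on the same strand
    if introns and any(r.chain.introns == introns for r in overlapping_same):
        return "="
    # 'c': contained -- contiguous intron sub-chain, span within ref span
    for r in overlapping_same:
        if (
            r.chain.start <= span_s
            and span_e <= r.chain.end
            and _is_contiguous_subchain(introns, r.chain.introns)
        ):
            if introns or any(
                s <= span_s and span_e <= e for s, e in r.chain.exons
            ):
                return "c"
    # 'j': shares at least one splice junction on the same strand
    if introns:
        tset = set(introns)
        if any(tset & set(r.chain.introns) for r in overlapping_same):
            return "j"
    # 'e': single-exon overlap of a reference exon, reaching >= 10 bp into
    # its flanking intron
    if not introns:
        for r in overlapping_same:
            exons = r.chain.exons
            for k, (s, e) in enumerate(exons):
                if not (span_s < e and s < span_e):
                    continue
                if (k > 0 and s - span_s >= 10) or (
                    k < len(exons) - 1 and span_e - e >= 10
                ):
                    return "e"
    # 'o': any other same-strand exonic overlap
    if any(_exonic_overlap(t, r) for r in overlapping_same):
        return "o"
    # 'i': fully inside an intron of a same-strand reference
    for r in overlapping_same:
        if any(d <= span_s and span_e <= a for d, a in r.chain.introns):
            return "i"
    # 's': intron chain matches a reference on the opposite strand (checked
    # before 'x' -- an antisense intron-chain match always implies antisense
    # exonic overlap, so the reverse order would make 's' unreachable)
    if introns and any(r.chain.introns == introns for r in overlapping_anti):
        return "s"
    # 'x': exonic overlap on the opposite strand only
    if any(_exonic_overlap(t, r) for r in overlapping_anti):
        return "x"
    # 'p': no overlap but within 2 kb downstream of a reference 3' end
    for r in same:
        three_prime = r.chain.end if r.strand == "+" else r.chain.start
        if r.strand == "+":
            lo, hi = three_prime, three_prime + 2000
        else:
            lo, hi = three_prime - 2000, three_prime
        if span_s < hi and lo < span_e and not (
            r.chain.start < span_e and span_s < r.chain.end
        ):
            return "p"
    # 'r': mostly repeat-masked exonic sequence
    if repeat_mask is not None:
        masked = 0
        for s, e in t.chain.exons:
            for rm in repeat_mask:
                if rm.chrom == t.chrom and rm.start < e and s < rm.end:
                    masked += min(e, rm.end) - max(s, rm.start)
        if masked >= 0.5 * t.length:
            return "r"
    return "u"


def novelty_of(
    transcript: TranscriptModel,
    code: str,
    annotation: AnnotationIndex,
) -> str:
    if code in ("=", "c"):
        return "known"
    if code == "u":
        return "novel-intergenic"
    if code == "x":
        return "novel-antisense"
    if code == "s":
        refs = annotation.overlapping(
            transcript.chrom, transcript.chain.start, transcript.chain.end
        )
        same = [
            r for r in refs
            if r.strand == transcript.strand and _exonic_overlap(transcript, r)
        ]
        if not same:
            return "novel-antisense"
    return "novel-isoform"


def classify_transcripts(
    transcripts: Sequence[TranscriptModel],
    annotation: Sequence[TranscriptModel],
    repeat_mask: Optional[Sequence[GenomicInterval]] = None,
) -> List[ClassifiedTranscript]:
    index = AnnotationIndex(annotation)
    out = []
    for t in transcripts:
        code = classify(t, index, repeat_mask)
        t.class_code = code
        ct = ClassifiedTranscript(transcript=t, code=code)
        ct._novelty = novelty_of(t, code, index)
        out.append(ct)
    return out


def _has_probe_overlap(
    t: TranscriptModel, probes: Sequence[GenomicInterval]
) -> bool:
    for p in probes:
        if p.chrom != t.chrom:
            continue
        for s, e in t.chain.exons:
            if s < p.end and p.start < e:
                return True
    return False


def _drop_redundant(
    survivors: List[TranscriptModel],
) -> Tuple[List[TranscriptModel], int]:
    """Criterion (vii): remove transcripts whose intron chain is a contiguous
    boundary-exact subset of another survivor's chain with span containment.
    Ties keep the longer transcript; equal structures keep the smallest id."""
    order = sorted(survivors, key=lambda t: (-t.length, t.id))
    kept: List[TranscriptModel] = []
    removed = 0
    for t in order:
        redundant = False
        for k in kept:
            if (
                k.chrom == t.chrom
                and k.strand == t.strand
                and k.chain.start <= t.chain.start
                and t.chain.end <= k.chain.end
                and _is_contiguous_subchain(t.chain.introns, k.chain.introns)
            ):
                redundant = True
                break
        if redundant:
            removed += 1
        else:
            kept.append(t)
    kept.sort(key=lambda t: (t.chrom, t.chain.start, t.chain.end, t.id))
    return kept, removed


def apply_filters(
    transcripts: Sequence[TranscriptModel],
    probes: Sequence[GenomicInterval],
    genome,
    annotation: Sequence[TranscriptModel],
    repeat_mask: Optional[Sequence[GenomicInterval]] = None,
    params: FilterParams = FilterParams(),
) -> Tuple[List[TranscriptModel], "OrderedDict[str, int]"]:
    """Apply criteria (i)-(vii) in order; returns survivors and per-criterion
    removal counts.

    Criteria (i)-(vi) are per-transcript and order-stable; (vii) runs last
    among the remaining transcripts. When no repeat mask is provided the 'r'
    code is never assigned.
    """
    counts: "OrderedDict[str, int]" = OrderedDict((c, 0) for c in CRITERIA)
    index = AnnotationIndex(annotation)

    survivors: List[TranscriptModel] = []
    for t in transcripts:
        if not _has_probe_overlap(t, probes):
            counts["i_no_probe_overlap"] += 1
            continue
        if t.chain.n_exons < params.min_exons:
            counts["ii_lt3_exons"] += 1
            continue
        if any(a - d > params.max_intron for d, a in t.chain.introns):
            counts["iii_intron_gt_1mb"] += 1
            continue
        if t.chrom not in genome:
            raise KeyError(f"genome lacks chromosome {t.chrom!r}")
        if any(
            motif_of(genome, t.chrom, d, a, t.strand)
            not in params.canonical_motifs
            for d, a in t.chain.introns
        ):
            counts["iv_noncanonical_junction"] += 1
            continue
        code = classify(t, index, repeat_mask)
        t.class_code = code
        if code in params.excluded_codes:
            counts["v_excluded_class_code"] += 1
            continue
        if t.length < params.min_length:
            counts["vi_lt200_nt"] += 1
            continue
        survivors.append(t)

    survivors, n_redundant = _drop_redundant(survivors)
    counts["vii_redundant"] = n_redundant
    return survivors, counts


def novelty_by_block(
    classified: Sequence[ClassifiedTranscript],
    blocks: Sequence[HaplotypeBlock],
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-block novelty census: counts by novelty class of transcripts with
    exonic overlap, a has_novel flag, and aggregate fractions (overall and
    for intergenic blocks)."""
    rows = []
    for b in blocks:
        iv = b.interval
        counts = {
            "known": 0, "novel-isoform": 0,
            "novel-antisense": 0, "novel-intergenic": 0,
        }
        for ct in classified:
            t = ct.transcript
            if t.chrom != iv.chrom:
                continue
            if any(s < iv.end and iv.start < e for s, e in t.chain.exons):
                counts[ct.novelty] += 1
        has_novel = any(
            counts[k] for k in
            ("novel-isoform", "novel-antisense", "novel-intergenic")
        )
        rows.append(
            {
                "block_id": b.block_id,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "category": b.category,
                **{k.replace("-", "_"): v for k, v in counts.items()},
                "has_novel": has_novel,
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "n_blocks": float(len(df)),
        "fraction_blocks_with_novel": (
            float(df["has_novel"].mean()) if len(df) else float("nan")
        ),
    }
    inter = df[df["category"] == "intergenic"] if len(df) else df
    summary["fraction_intergenic_blocks_with_novel"] = (
        float(inter["has_novel"].mean()) if len(inter) else float("nan")
    )
    return df, summary


def feature_census(
    transcripts: Sequence[TranscriptModel],
) -> Tuple[int, int, int]:
    """(n transcripts, n unique introns, n discrete internal exons).

    Internal exons exclude both terminal exons of each transcript (their
    boundaries are imprecise) and deduplicate by exact coordinates.
    """
    introns = set()
    internal = set()
    for t in transcripts:
        for d, a in t.chain.introns:
            introns.add((t.chrom, t.strand, d, a))
        for s, e in t.chain.exons[1:-1]:
            internal.add((t.chrom, t.strand, s, e))
    return len(transcripts), len(introns), len(internal)
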