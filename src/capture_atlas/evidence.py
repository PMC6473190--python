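"""Independent evidence of transcription: CAGE/epigenetic-mark proximity to
TSSs, enrichment odds ratios against randomised positions, conserved-RNA-
structure overlap and mean per-base conservation.

The TSS anchor is the 1 bp position immediately upstream of the strand-aware
5' end; a hit is any peak within ``window`` bp of the anchor (same strand
when required). The permutation null places the same number of anchors
uniformly at random within the captured-target universe with random strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenomicInterval, TranscriptModel
from .io import ScoreTrack


def tss_anchor(transcript: TranscriptModel) -> Tuple[str, int, str]:
    """(chrom, position, strand) of the 1 bp anchor immediately upstream of
    the TSS."""
    t = transcript
    if t.strand == "+":
        return (t.chrom, max(0, t.chain.start - 1), "+")
    if t.strand == "-":
        return (t.chrom, t.chain.end, "-")
    raise ValueError(f"transcript {t.id} is unstranded")


class _PeakIndex:
    def __init__(self, peaks: Sequence[GenomicInterval]):
        self._by: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
        grouped: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
        for p in peaks:
            grouped.setdefault((p.chrom, p.strand), []).append((p.start, p.end))
        for key, ivs in grouped.items():
            ivs.sort()
            self._by[key] = (
                np.array([s for s, _ in ivs]),
                np.array([e for _, e in ivs]),
            )

    def any_within(self, chrom: str, pos: int, window: int,
                   strand: Optional[str]) -> bool:
        keys = (
            [(chrom, strand)]
            if strand is not None
            else [(chrom, "+"), (chrom, "-"), (chrom, ".")]
        )
        for key in keys:
            if key not in self._by:
                continue
            starts, ends = self._by[key]
            # distance from the anchor base to the peak interval
            i = int(np.searchsorted(ends, pos + 1, side="left"))
            for j in (i - 1, i):
                if 0 <= j < len(starts):
                    dist = max(starts[j] - pos, pos + 1 - ends[j], 0)
                    if dist <= window:
                        return True
        return False


def tss_evidence(
    transcripts: Sequence[TranscriptModel],
    peaks: Sequence[GenomicInterval],
    window: int = 500,
    same_strand: bool = True,
) -> pd.Series:
    """Per-transcript flag: a peak lies within ``window`` bp of the TSS
    anchor (strict window: distance window+1 misses)."""
    index = _PeakIndex(peaks)
    flags = {}
    for t in transcripts:
        chrom, pos, strand = tss_anchor(t)
        flags[t.id] = index.any_within(
            chrom, pos, window, strand if same_strand else None
        )
    return pd.Series(flags, dtype=bool)


@dataclass
class EnrichmentResult:
    observed_hits: int
    observed_total: int
    random_hits: int
    random_total: int
    odds_ratio: float
    n_permutations: int
    seed: int

    @property
    def random_hit_rate(self) -> float:
        return self.random_hits / self.random_total if self.random_total else float("nan")


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a/b) / (c/d) with the Haldane-Anscombe +0.5 correction when any cell
    is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / b) / (c / d)


def enrichment_odds_ratio(
    transcripts: Sequence[TranscriptModel],
    peaks: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    window: int = 500,
    same_strand: bool = True,
    n_perm: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """Odds ratio of TSS peak proximity versus randomised anchor positions.

    The null pools ``n_perm`` placements of len(transcripts) anchors drawn
    uniformly within the universe (strand uniform at random).
    """
    if not universe:
        raise ValueError("empty universe")
    flags = tss_evidence(transcripts, peaks, window, same_strand)
    a = int(flags.sum())
    b = int(len(flags) - a)

    rng = np.random.default_rng(seed)
    index = _PeakIndex(peaks)
    lengths = np.array([len(iv) for iv in universe], dtype=float)
    probs = lengths / lengths.sum()
    n = len(transcripts)
    c = 0
    for _ in range(n_perm):
        which = rng.choice(len(universe), size=n, p=probs)
        for w in which:
            iv = universe[int(w)]
            pos = int(rng.integers(iv.start, iv.end))
            strand = "+" if rng.random() < 0.5 else "-"
            if index.any_within(iv.chrom, pos, window,
                                strand if same_strand else None):
                c += 1
    total_rand = n * n_perm
    d = total_rand - c
    return EnrichmentResult(
        observed_hits=a,
        observed_total=a + b,
        random_hits=c,
        random_total=total_rand,
        odds_ratio=float(_odds_ratio(a, b, c, d)),
        n_permutations=n_perm,
        seed=seed,
    )


def crs_overlap(
    transcripts: Sequence[TranscriptModel],
    crs: Sequence[GenomicInterval],
) -> pd.Series:
    """Flag per transcript: >= 1 bp exonic overlap with a conserved RNA
    structure interval (intronic-only overlap does not count)."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in crs:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    flags = {}
    for t in transcripts:
        ivs = by_chrom.get(t.chrom, [])
        flags[t.id] = any(
            s < ce and cs < e for s, e in t.chain.exons for cs, ce in ivs
        )
    return pd.Series(flags, dtype=bool)


def mean_conservation(
    transcripts: Sequence[TranscriptModel],
    track: ScoreTrack,
) -> pd.Series:
    """Mean per-base conservation over each transcript's exonic bases."""
    return pd.Series(
        {t.id: track.mean_over_exons(t.chain) for t in transcripts},
        dtype=float,
    )


def evidence_table(
    transcripts: Sequence[TranscriptModel],
    cage: Sequence[GenomicInterval],
    marks: Dict[str, Sequence[GenomicInterval]],
    crs: Sequence[GenomicInterval],
    track: Optional[ScoreTrack] = None,
    window: int = 500,
) -> pd.DataFrame:
    """Per-transcript evidence summary: CAGE, each mark, CRS, conservation."""
    out = pd.DataFrame(
        {"cage": tss_evidence(transcripts, cage, window, same_strand=True)}
    )
    for name, peaks in sorted(marks.items()):
        out[name.lower()] = tss_evidence(
            transcripts, peaks, window, same_strand=False
        )
    out["crs"] = crs_overlap(transcripts, crs)
    if track is not None:
        out["conservation"] = mean_conservation(transcripts, track)
    return out
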