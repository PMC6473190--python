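"""Correct long-read splice sites against annotated and short-read-supported
junctions within a fixed window, then collapse corrected reads into a
non-redundant transcript set.

Each read splice site snaps to the nearest supported site of its kind
(donor/acceptor, per chromosome and strand) within ``window`` bp. Ties at
equal distance prefer annotated sites, then higher short-read counts, then
the smaller coordinate. A read with any splice site lacking a supported site
within the window is discarded, as is a read whose corrected chain is no
longer a valid exon chain. Collapse groups corrected reads by exact intron
chain; groups with at least ``min_collapse_support`` reads emit one
transcript whose ends are the medians of member read ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .core import (
    ExonChain,
    SpliceJunction,
    TranscriptModel,
    group_by_locus,
    lower_median,
)


@dataclass
class CorrectionParams:
    window: int = 10
    min_collapse_support: int = 3

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.min_collapse_support < 1:
            raise ValueError("min_collapse_support must be >= 1")


@dataclass
class CorrectionReport:
    n_input: int = 0
    n_corrected: int = 0
    n_discarded: int = 0
    n_unspliced: int = 0

    @property
    def corrected_fraction(self) -> float:
        spliced = self.n_input - self.n_unspliced
        return self.n_corrected / spliced if spliced else float("nan")


def junctions_from_annotation(
    transcripts: Sequence[TranscriptModel],
) -> List[SpliceJunction]:
    """Unique annotated junctions of a transcript set."""
    seen = {}
    for t in transcripts:
        for d, a in t.chain.introns:
            seen[(t.chrom, t.strand, d, a)] = SpliceJunction(
                t.chrom, d, a, t.strand, annotated=True
            )
    return [seen[k] for k in sorted(seen)]


class _SiteIndex:
    """Supported donor/acceptor positions per (chrom, strand), with
    annotated flags and short-read counts for tie-breaking."""

    def __init__(self, junctions: Iterable[SpliceJunction]):
        acc: Dict[Tuple[str, str, str], Dict[int, Tuple[bool, int]]] = {}
        for j in junctions:
            for kind, pos in (("donor", j.donor), ("acceptor", j.acceptor)):
                d = acc.setdefault((j.chrom, j.strand, kind), {})
                ann, cnt = d.get(pos, (False, 0))
                d[pos] = (ann or j.annotated, cnt + j.short_read_count)
        self._idx: Dict[Tuple[str, str, str],
                        Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, d in acc.items():
            pos = np.array(sorted(d), dtype=np.int64)
            ann = np.array([d[p][0] for p in pos], dtype=bool)
            cnt = np.array([d[p][1] for p in pos], dtype=np.int64)
            self._idx[key] = (pos, ann, cnt)

    def snap(
        self, chrom: str, strand: str, kind: str, query: np.ndarray, window: int
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Vectorised nearest-site snap. Returns (snapped, ok)."""
        key = (chrom, strand, kind)
        if key not in self._idx:
            return query.copy(), np.zeros(query.shape, dtype=bool)
        pos, ann, cnt = self._idx[key]
        i = np.searchsorted(pos, query)
        li = np.clip(i - 1, 0, len(pos) - 1)
        ri = np.clip(i, 0, len(pos) - 1)
        dl = np.where(i > 0, query - pos[li], np.iinfo(np.int64).max)
        dr = np.where(i < len(pos), pos[ri] - query, np.iinfo(np.int64).max)
        # equal-distance ties: annotated first, then higher count, then the
        # smaller coordinate (the left candidate)
        tie_left = (
            (ann[li] & ~ann[ri])
            | ((ann[li] == ann[ri]) & (cnt[li] >= cnt[ri]))
        )
        take_left = (dl < dr) | ((dl == dr) & tie_left)
        choice = np.where(take_left, li, ri)
        dist = np.minimum(dl, dr)
        return pos[choice], dist <= window


def correct_chains(
    chains: Sequence[ExonChain],
    annotated_junctions: Sequence[SpliceJunction],
    short_read_junctions: Sequence[SpliceJunction],
    params: CorrectionParams = CorrectionParams(),
) -> Tuple[List[ExonChain], CorrectionReport]:
    """Snap every splice site of every spliced read to supported sites.

    Donor and acceptor of an intron are corrected independently; a read is
    discarded when a site has no supported target within the window or when
    snapping collapses an exon or intron to length <= 0. Unspliced
    (single-exon) reads are set aside and counted separately.
    """
    index = _SiteIndex(list(annotated_junctions) + list(short_read_junctions))
    report = CorrectionReport(n_input=len(chains))
    corrected: List[ExonChain] = []

    groups: Dict[Tuple[str, str], List[ExonChain]] = {}
    for c in chains:
        if c.n_exons < 2:
            report.n_unspliced += 1
            continue
        groups.setdefault((c.chrom, c.strand), []).append(c)

    for (chrom, strand), members in sorted(groups.items()):
        donors = np.concatenate([[d for d, _ in m.introns] for m in members])
        acceptors = np.concatenate([[a for _, a in m.introns] for m in members])
        counts = np.array([m.n_exons - 1 for m in members])
        offsets = np.concatenate([[0], np.cumsum(counts)])
        starts = np.array([m.start for m in members])
        ends = np.array([m.end for m in members])
        sd, okd = index.snap(chrom, strand, "donor", donors, params.window)
        sa, oka = index.snap(chrom, strand, "acceptor", acceptors, params.window)

        # vectorised validity: every site snapped, introns/exons stay > 0 bp
        read_of = np.repeat(np.arange(len(members)), counts)
        ok_site = okd & oka
        ok = np.ones(len(members), dtype=bool)
        np.logical_and.at(ok, read_of, ok_site)
        intron_ok = sa - sd >= 1
        np.logical_and.at(ok, read_of, intron_ok)
        # middle exons: donor[k+1] - acceptor[k] within one read
        same_read = read_of[1:] == read_of[:-1]
        mid_ok = np.where(same_read, sd[1:] - sa[:-1] >= 1, True)
        np.logical_and.at(ok, read_of[1:], mid_ok)
        first_ok = sd[offsets[:-1]] - starts >= 1
        last_ok = ends - sa[offsets[1:] - 1] >= 1
        ok &= first_ok & last_ok

        for mi in np.nonzero(ok)[0]:
            m = members[mi]
            lo, hi = offsets[mi], offsets[mi + 1]
            bounds = np.empty(2 * m.n_exons, dtype=np.int64)
            bounds[0] = m.start
            bounds[-1] = m.end
            bounds[1:-1:2] = sd[lo:hi]
            bounds[2:-1:2] = sa[lo:hi]
            exons = tuple(zip(bounds[0::2].tolist(), bounds[1::2].tolist()))
            corrected.append(ExonChain(m.id, chrom, strand, exons))
        n_ok = int(ok.sum())
        report.n_corrected += n_ok
        report.n_discarded += len(members) - n_ok
    return corrected, report


def collapse(
    chains: Sequence[ExonChain],
    params: CorrectionParams = CorrectionParams(),
) -> List[TranscriptModel]:
    """Collapse corrected reads into a non-redundant transcript set.

    Reads group by exact intron chain (chromosome, strand, intron
    coordinates); groups with >= ``min_collapse_support`` members emit one
    transcript whose start/end are the (lower) medians of member read ends.
    Gene ids are assigned per locus of span-overlapping transcripts on one
    strand.
    """
    groups: Dict[Tuple, List[ExonChain]] = {}
    for c in chains:
        if c.n_exons < 2:
            continue
        groups.setdefault(c.intron_key, []).append(c)

    models: List[TranscriptModel] = []
    for key in sorted(groups, key=lambda k: (k[0], k[1], k[2])):
        members = groups[key]
        if len(members) < params.min_collapse_support:
            continue
        chrom, strand, introns = key
        start = lower_median(m.start for m in members)
        end = lower_median(m.end for m in members)
        bounds = [start]
        for d, a in introns:
            bounds.extend((d, a))
        bounds.append(end)
        exons = tuple(
            (bounds[2 * i], bounds[2 * i + 1]) for i in range(len(introns) + 1)
        )
        chain = ExonChain("", chrom, strand, exons)
        models.append(
            TranscriptModel(id="", gene_id="", chain=chain)
        )

    models.sort(key=lambda t: (t.chrom, t.strand, t.chain.start, t.chain.end))
    # assign transcript and locus (gene) identifiers
    for strand in ("+", "-"):
        sub = [t for t in models if t.strand == strand]
        loci = group_by_locus([t.chain.span for t in sub])
        for li, idxs in enumerate(loci):
            for i in idxs:
                sub[i].gene_id = f"locus{strand}{li + 1:04d}"
    for i, t in enumerate(models, 1):
        t.id = f"tx_{i:05d}"
        t.chain = t.chain.with_id(t.id)
    return models


def junction_validation_rate(
    chains: Sequence[ExonChain],
    short_read_junctions: Sequence[SpliceJunction],
) -> float:
    """Share of unique long-read junctions present in the short-read table."""
    long_j = {
        (c.chrom, c.strand, d, a) for c in chains for d, a in c.introns
    }
    if not long_j:
        return float("nan")
    short = {(j.chrom, j.strand, j.donor, j.acceptor)
             for j in short_read_junctions}
    return len(long_j & short) / len(long_j)
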