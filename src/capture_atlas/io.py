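"""Readers and writers for the plain-text genomic formats the pipeline uses.

BED/BED12/BedGraph and the junction table are 0-based half-open; GTF is
1-based closed and the +/-1 shift happens here and only here. Round-trip
write-then-read is the identity on valid records.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ExonChain,
    GenomicInterval,
    SpliceJunction,
    TranscriptModel,
)


class ParseError(ValueError):
    """Raised for a malformed line; names the file and line number."""

    def __init__(self, path: str, lineno: int, msg: str):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.path = path
        self.lineno = lineno


# ---------------------------------------------------------------------------
# BED / BED12


def read_bed(path: str) -> List[GenomicInterval]:
    """Read BED3/BED6 into intervals (strand '.' if absent)."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(path, lineno, "BED needs >= 3 columns")
            try:
                strand = f[5] if len(f) >= 6 else "."
                out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
            except (ValueError, IndexError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str,
              names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed12(path: str) -> List[ExonChain]:
    """Read BED12 exon chains (block arithmetic per the BED12 standard)."""
    out: List[ExonChain] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(path, lineno, "BED12 needs 12 columns")
            try:
                chrom, start = f[0], int(f[1])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise ValueError("blockCount disagrees with block lists")
                exons = tuple(
                    (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
                )
                out.append(ExonChain(name, chrom, strand, exons))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return out


def write_bed12(chains: Sequence[ExonChain], path: str) -> None:
    with open(path, "w") as fh:
        for c in chains:
            start, end = c.start, c.end
            sizes = ",".join(str(e - s) for s, e in c.exons)
            starts = ",".join(str(s - start) for s, _ in c.exons)
            fh.write(
                f"{c.chrom}\t{start}\t{end}\t{c.id}\t0\t{c.strand}"
                f"\t{start}\t{end}\t0\t{c.n_exons}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str) -> List[TranscriptModel]:
    """Read transcripts from GTF (exon features grouped by transcript_id).

    GTF is 1-based closed; internal coordinates come out 0-based half-open.
    Uses gffutils for attribute-safe parsing.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: Dict[str, dict] = {}
    order: List[str] = []
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        rec = grouped.get(tid)
        if rec is None:
            rec = {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand,
                   "exons": []}
            grouped[tid] = rec
            order.append(tid)
        rec["exons"].append((feat.start - 1, feat.end))
    out: List[TranscriptModel] = []
    for tid in order:
        rec = grouped[tid]
        exons = tuple(sorted(rec["exons"]))
        chain = ExonChain(tid, rec["chrom"], rec["strand"], exons)
        out.append(TranscriptModel(tid, rec["gene_id"], chain))
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], path: str,
              source: str = "capture_atlas") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            c = t.chain
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.id}";'
            fh.write(
                f"{c.chrom}\t{source}\ttranscript\t{c.start + 1}\t{c.end}\t."
                f"\t{c.strand}\t.\t{attrs}\n"
            )
            for s, e in c.exons:
                fh.write(
                    f"{c.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{c.strand}"
                    f"\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Junction TSV

JUNCTION_COLUMNS = ["chrom", "start", "end", "strand", "motif", "annotated", "count"]


def read_junction_tsv(path: str) -> List[SpliceJunction]:
    """Read a spliced-aligner-style junction table.

    Tab-separated: chrom, intron start (0-based), intron end, strand, motif,
    annotated flag (0/1), unique read count. Extra columns are ignored.
    """
    out: List[SpliceJunction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ParseError(path, lineno, "junction TSV needs >= 7 columns")
            try:
                out.append(
                    SpliceJunction(
                        chrom=f[0],
                        donor=int(f[1]),
                        acceptor=int(f[2]),
                        strand=f[3],
                        motif=f[4],
                        annotated=bool(int(f[5])),
                        short_read_count=int(f[6]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return out


def write_junction_tsv(junctions: Sequence[SpliceJunction], path: str) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.donor}\t{j.acceptor}\t{j.strand}\t{j.motif}"
                f"\t{int(j.annotated)}\t{j.short_read_count}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


class GenomeAccessor:
    """Random access to genome sequence, 0-based half-open."""

    def __init__(self, path: str):
        import pyfaidx

        self._fa = pyfaidx.Fasta(path)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fa:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        return str(self._fa[chrom][start:end]).upper()

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    def chrom_length(self, chrom: str) -> int:
        return len(self._fa[chrom])


def read_fasta(path: str) -> GenomeAccessor:
    return GenomeAccessor(path)


def write_fasta(sequences: Dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BedGraph


class ScoreTrack:
    """Per-base scores from BedGraph intervals; uncovered bases score 0."""

    def __init__(self, records: Iterable[Tuple[str, int, int, float]]):
        by_chrom: Dict[str, list] = {}
        for chrom, start, end, score in records:
            by_chrom.setdefault(chrom, []).append((start, end, score))
        self._index: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs])
            ends = np.array([r[1] for r in recs])
            scores = np.array([r[2] for r in recs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping BedGraph intervals on {chrom}")
            self._index[chrom] = (starts, ends, scores)

    def sum_over(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base scores over [start, end)."""
        if chrom not in self._index:
            return 0.0
        starts, ends, scores = self._index[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        total = 0.0
        for i in range(lo, hi):
            ov = min(end, ends[i]) - max(start, starts[i])
            if ov > 0:
                total += ov * scores[i]
        return total

    def mean_over_exons(self, chain: ExonChain) -> float:
        """Mean per-base score over a chain's exonic bases (missing = 0)."""
        total = sum(self.sum_over(chain.chrom, s, e) for s, e in chain.exons)
        return total / chain.length


def read_bedgraph(path: str) -> ScoreTrack:
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(path, lineno, "BedGraph needs 4 columns")
            try:
                recs.append((f[0], int(f[1]), int(f[2]), float(f[3])))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return ScoreTrack(recs)


def write_bedgraph(records: Sequence[Tuple[str, int, int, float]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, score in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{score:g}\n")


# ---------------------------------------------------------------------------
# Spike-in ladder TSV

SPIKEIN_COLUMNS = ["isoform_id", "gene_id", "concentration", "captured"]


def read_spikein_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SPIKEIN_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"spike-in TSV missing columns {sorted(missing)}")
    df["captured"] = df["captured"].astype(bool)
    return df


def write_spikein_tsv(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out["captured"] = out["captured"].astype(int)
    out.to_csv(path, sep="\t", index=False)
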