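"""Shared hand-built fixtures for filter, classification and coordination
tests."""

import math
from typing import Dict, List, Tuple

from capture_atlas.core import ExonChain, GenomicInterval, TranscriptModel


class SparseGenome:
    """Genome accessor backed by a sparse base dict (default 'A')."""

    def __init__(self, planted: Dict[Tuple[str, int], str]):
        self._planted = planted
        self._chroms = {c for c, _ in planted}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return "".join(
            self._planted.get((chrom, i), "A") for i in range(start, end)
        )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms


def plant(planted, chrom, donor, acceptor, strand="+", motif="GT-AG"):
    d_nt, a_nt = motif.split("-")
    if strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        d_nt, a_nt = (
            "".join(comp[b] for b in reversed(a_nt)),
            "".join(comp[b] for b in reversed(d_nt)),
        )
    planted[(chrom, donor)] = d_nt[0]
    planted[(chrom, donor + 1)] = d_nt[1]
    planted[(chrom, acceptor - 2)] = a_nt[0]
    planted[(chrom, acceptor - 1)] = a_nt[1]


def tx(name, exons, strand="+", gene=None, chrom="chr1"):
    return TranscriptModel(
        name, gene or f"g_{name}", ExonChain(name, chrom, strand, tuple(exons))
    )


def seven_criterion_fixture():
    """A reference transcript, probes, genome and 8 transcripts of which each
    of seven violates exactly one filter criterion and one is clean.

    Returns (transcripts, probes, genome, annotation); transcripts are listed
    in criterion order (i)..(vii) with the clean survivor last.
    """
    planted: Dict[Tuple[str, int], str] = {}
    ref = tx("REF", ((1000, 1200), (2000, 2200), (3000, 3200), (4000, 4200)))
    annotation = [ref]

    probes = [
        GenomicInterval("chr1", s, s + 120) for s in range(900, 12000, 120)
    ]

    def with_motifs(t: TranscriptModel) -> TranscriptModel:
        for d, a in t.chain.introns:
            plant(planted, t.chrom, d, a, t.strand)
        return t

    clean = with_motifs(
        tx("T_clean", ((1000, 1200), (2000, 2200), (3000, 3200)))
    )
    v_probe = with_motifs(
        tx("T_noprobe", ((50000, 50200), (51000, 51200), (52000, 52200)))
    )
    v_exons = with_motifs(tx("T_2exon", ((3000, 3200), (4000, 4200))))
    v_intron = with_motifs(
        tx("T_bigintron", ((1000, 1200), (2000, 2200), (1202300, 1202500)))
    )
    # intron (2200, 2500) deliberately left unplanted -> non-canonical;
    # its other junction (1200, 2000) is already planted via T_clean
    v_motif = tx("T_noncanon", ((1000, 1200), (2000, 2200), (2500, 2700)))
    v_code = with_motifs(
        tx("T_runon", ((4400, 4600), (5000, 5200), (5400, 5600)))
    )  # 'p': within 2 kb downstream of REF's 3' end, no overlap
    v_length = with_motifs(
        tx("T_short", ((9000, 9050), (9500, 9550), (10000, 10060)))
    )  # 160 exonic nt
    v_redundant = with_motifs(
        tx("T_contained", ((1010, 1200), (2000, 2200), (3000, 3190)))
    )  # same intron chain as T_clean, span inside it

    transcripts = [
        v_probe, v_exons, v_intron, v_motif, v_code, v_length, v_redundant,
        clean,
    ]
    return transcripts, probes, SparseGenome(planted), annotation


# ---------------------------------------------------------------------------
# coordination fixtures


def coordination_reference():
    """An 11-exon reference; internal exon pair (6, 8) is distant."""
    return TranscriptModel(
        "ref", "g",
        ExonChain("ref", "chr13", "+",
                  tuple((1000 * i, 1000 * i + 100) for i in range(1, 12))),
    )


def coordination_reads(both, first_only, second_only, neither, i=7, j=9):
    """Spanning reads with/without the exons at 1000*i and 1000*j."""
    out = []
    combos = [(True, True, both), (True, False, first_only),
              (False, True, second_only), (False, False, neither)]
    for has_i, has_j, n in combos:
        exons = tuple(
            (1000 * k, 1000 * k + 100)
            for k in range(1, 12)
            if not (k == i and not has_i) and not (k == j and not has_j)
        )
        for m in range(n):
            out.append(ExonChain(f"r{has_i}{has_j}{m}", "chr13", "+", exons))
    return out


def fisher_enumeration_p(a, b, c, d):
    """Independent oracle: enumerate every 2x2 table with the observed
    margins and sum the probabilities no larger than the observed one."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def prob(x):
        b_ = row1 - x
        c_ = col1 - x
        d_ = n - row1 - c_
        if min(b_, c_, d_) < 0:
            return 0.0
        return math.comb(row1, x) * math.comb(n - row1, c_) / math.comb(n, col1)

    p_obs = prob(a)
    return sum(
        p for x in range(0, min(row1, col1) + 1)
        if (p := prob(x)) <= p_obs * (1 + 1e-7)
    )
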