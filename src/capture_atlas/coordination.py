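"""Coordination between distant pairs of internal exons on single molecules.

Long reads spanning both exons' flanking junctions are partitioned into a
2x2 table (both exons / first only / second only / neither); independence is
tested with a two-sided Fisher's exact test, and significant pairs are called
dMAP (distant mutually associated pair, positive association) or dMEP
(distant mutually exclusive pair, negative association).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import ExonChain, GenomicInterval, TranscriptModel

#: Relative slack when comparing point probabilities in the two-sided sum.
_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Spanning-read counts for an exon pair."""

    both: int
    first_only: int
    second_only: int
    neither: int

    def __post_init__(self) -> None:
        if min(self.both, self.first_only, self.second_only, self.neither) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.both + self.first_only + self.second_only + self.neither

    @property
    def cells(self) -> Tuple[int, int, int, int]:
        return (self.both, self.first_only, self.second_only, self.neither)

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.both, self.second_only, self.first_only, self.neither
        )

    def odds_ratio(self) -> float:
        """Haldane-Anscombe-corrected odds ratio (+0.5 to every cell)."""
        a, b, c, d = (x + 0.5 for x in self.cells)
        return (a * d) / (b * c)


def fisher_exact(table: ContingencyTable2x2 | Tuple[int, int, int, int]) -> float:
    """Two-sided Fisher's exact p: the sum of hypergeometric probabilities of
    all tables with the observed margins whose point probability does not
    exceed the observed one (within relative tolerance)."""
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.cells
    n = table.total
    if n == 0:
        raise ValueError("all-zero table")
    row1 = a + b
    col1 = a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0  # only one table has these margins
    k = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(k, n, col1, row1)
    p_obs = float(stats.hypergeom.pmf(a, n, col1, row1))
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return min(1.0, p)


def categorize_reads(
    reference: TranscriptModel,
    first_exon_index: int,
    second_exon_index: int,
    chains: Sequence[ExonChain],
) -> ContingencyTable2x2:
    """Partition spanning reads by presence of two non-adjacent internal
    exons of a reference transcript.

    A read is *spanning* when its chain starts before the first exon's
    upstream flanking junction and ends beyond the second exon's downstream
    flanking junction, so absence of an exon is distinguishable from
    truncation. A read contains an exon when one of its exons matches the
    reference exon exactly (tolerance 0, post-correction coordinates).
    """
    exons = reference.chain.exons
    i, j = first_exon_index, second_exon_index
    if not (0 < i < len(exons) - 1 and 0 < j < len(exons) - 1):
        raise ValueError("exon pair must be internal exons")
    if j < i:
        i, j = j, i
    if j - i < 2:
        raise ValueError("exon pair must be non-adjacent")
    introns = reference.chain.introns
    upstream_start = introns[i - 1][0]   # donor of intron before exon i
    downstream_end = introns[j][1]       # acceptor of intron after exon j
    e1, e2 = exons[i], exons[j]

    both = first = second = neither = 0
    for r in chains:
        if r.chrom != reference.chrom or r.strand != reference.strand:
            continue
        if not (r.start < upstream_start and r.end > downstream_end):
            continue
        rex = set(r.exons)
        has1, has2 = e1 in rex, e2 in rex
        if has1 and has2:
            both += 1
        elif has1:
            first += 1
        elif has2:
            second += 1
        else:
            neither += 1
    return ContingencyTable2x2(both, first, second, neither)


@dataclass
class CoordinationCall:
    exon_pair: Tuple[GenomicInterval, GenomicInterval]
    reference_id: str
    table: ContingencyTable2x2
    p_value: float
    q_value: float
    odds_ratio: float
    call: str  # dMAP | dMEP | none


def scan_pairs(
    references: Sequence[TranscriptModel],
    chains: Sequence[ExonChain],
    alpha: float = 0.05,
    min_spanning: int = 20,
    correct: bool = True,
) -> List[CoordinationCall]:
    """Test every non-adjacent internal exon pair of each reference with
    enough spanning reads; Benjamini-Hochberg across tested pairs (optional);
    dMEP when q <= alpha and OR < 1, dMAP when q <= alpha and OR > 1."""
    tested: List[CoordinationCall] = []
    seen: set = set()
    for ref in references:
        n = ref.chain.n_exons
        if n < 5:
            continue
        for i, j in combinations(range(1, n - 1), 2):
            if j - i < 2:
                continue
            e1, e2 = ref.chain.exons[i], ref.chain.exons[j]
            key = (ref.chrom, ref.strand, e1, e2)
            if key in seen:
                continue
            seen.add(key)
            table = categorize_reads(ref, i, j, chains)
            if table.total < min_spanning:
                continue
            p = fisher_exact(table)
            tested.append(
                CoordinationCall(
                    exon_pair=(
                        GenomicInterval(ref.chrom, *e1, ref.strand),
                        GenomicInterval(ref.chrom, *e2, ref.strand),
                    ),
                    reference_id=ref.id,
                    table=table,
                    p_value=p,
                    q_value=p,
                    odds_ratio=table.odds_ratio(),
                    call="none",
                )
            )
    if not tested:
        return tested
    if correct and len(tested) > 1:
        qs = stats.false_discovery_control(
            [c.p_value for c in tested], method="bh"
        )
        for call, q in zip(tested, qs):
            call.q_value = float(q)
    for c in tested:
        if c.q_value <= alpha:
            c.call = "dMEP" if c.odds_ratio < 1 else (
                "dMAP" if c.odds_ratio > 1 else "none"
            )
    return tested
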