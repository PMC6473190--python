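"""Cluster spliced long-read exon chains with similar intron structure and
emit median-boundary consensus transcripts.

Only chains with identical intron counts can co-cluster. Two chains are
linked when every corresponding internal (splice-site) boundary differs by at
most ``internal_boundary_tol`` and both transcript ends differ by at most
``terminal_boundary_tol``; clusters are the connected components of that link
graph (single linkage). Clusters below ``min_cluster_size`` are dropped, then
clusters representing less than ``min_isoform_percent`` of the clustered
reads overlapping their span are dropped. The consensus takes the per-column
median of member boundaries (lower median for even counts, so consensus
coordinates stay on observed splice sites).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import ExonChain, GenomicInterval, lower_median


@dataclass
class ClusterParams:
    min_cluster_size: int = 3          # -c
    internal_boundary_tol: int = 10    # -d
    terminal_boundary_tol: int = 30    # -e
    min_isoform_percent: float = 1.0   # -p

    def __post_init__(self) -> None:
        if min(self.min_cluster_size, self.internal_boundary_tol,
               self.terminal_boundary_tol) < 0:
            raise ValueError("cluster parameters must be non-negative")
        if not (0.0 <= self.min_isoform_percent <= 100.0):
            raise ValueError("min_isoform_percent must lie in [0, 100]")


@dataclass
class ReadCluster:
    cluster_id: str
    members: List[ExonChain]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.members[0].chrom,
            min(m.start for m in self.members),
            max(m.end for m in self.members),
            self.members[0].strand,
        )


@dataclass
class ConsensusTranscript:
    chain: ExonChain
    support: int
    cluster_id: str


def _components(
    bounds: np.ndarray, d: int, e: int
) -> List[List[int]]:
    """Connected components of the compatibility graph over boundary rows
    (single linkage).

    ``bounds`` is (n, 2k); columns 0 and -1 are transcript ends (tolerance
    e), interior columns are splice sites (tolerance d). Components are grown
    breadth-first; candidates are pruned with a sorted window on one splice
    column, then checked in full, so each accepted row triggers exactly one
    vectorised window scan.
    """
    n, m = bounds.shape
    if n == 1:
        return [[0]]
    # sort key: a column every compatible pair must agree on within its tol
    key_col = 1 if m > 2 else 0
    key_tol = d if m > 2 else e
    order = np.argsort(bounds[:, key_col], kind="stable")
    b = bounds[order]
    keys = b[:, key_col]
    if m > 2:
        interior = b[:, 1:-1]
        ends = b[:, [0, -1]]
    else:
        interior = None
        ends = b

    visited = np.zeros(n, dtype=bool)
    comps: List[List[int]] = []
    for start in range(n):
        if visited[start]:
            continue
        visited[start] = True
        comp = [start]
        frontier = [start]
        while frontier:
            f = frontier.pop()
            lo = int(np.searchsorted(keys, keys[f] - key_tol, side="left"))
            hi = int(np.searchsorted(keys, keys[f] + key_tol, side="right"))
            cand = np.nonzero(~visited[lo:hi])[0]
            if cand.size == 0:
                continue
            cand = cand + lo
            ok = np.all(np.abs(ends[cand] - ends[f]) <= e, axis=1)
            if interior is not None:
                ok &= np.all(np.abs(interior[cand] - interior[f]) <= d, axis=1)
            new = cand[ok]
            if new.size:
                visited[new] = True
                comp.extend(int(x) for x in new)
                frontier.extend(int(x) for x in new)
        comps.append([int(order[i]) for i in comp])
    return comps


def cluster_reads(
    chains: Sequence[ExonChain], params: ClusterParams = ClusterParams()
) -> Tuple[List[ReadCluster], int]:
    """Cluster reads; returns (clusters, number of rejected unstranded reads).

    Deterministic and independent of input order: cluster ids are assigned
    after sorting clusters by coordinates.
    """
    stranded = [c for c in chains if c.strand in ("+", "-")]
    n_rejected = len(chains) - len(stranded)

    groups: Dict[Tuple[str, str, int], List[ExonChain]] = {}
    for c in stranded:
        groups.setdefault((c.chrom, c.strand, c.n_exons), []).append(c)

    raw: List[List[ExonChain]] = []
    for key in sorted(groups):
        members = groups[key]
        rows = np.array([m.boundaries() for m in members], dtype=np.int64)
        # deduplicate identical chains before the pairwise stage
        uniq, inverse = np.unique(rows, axis=0, return_inverse=True)
        comps = _components(uniq, params.internal_boundary_tol,
                            params.terminal_boundary_tol)
        uniq_to_comp = {}
        for ci, comp in enumerate(comps):
            for u in comp:
                uniq_to_comp[u] = ci
        buckets: Dict[int, List[ExonChain]] = {}
        for ridx, u in enumerate(inverse):
            buckets.setdefault(uniq_to_comp[int(u)], []).append(members[ridx])
        raw.extend(buckets.values())

    kept = [m for m in raw if len(m) >= params.min_cluster_size]

    clusters = [
        ReadCluster(cluster_id="", members=sorted(m, key=lambda c: (c.start, c.end, c.id)))
        for m in kept
    ]
    clusters.sort(key=lambda cl: (cl.members[0].chrom, cl.members[0].strand,
                                  cl.span.start, cl.span.end, -cl.size))

    # locus-level minimum isoform share: a cluster must carry at least p% of
    # the clustered reads whose chains overlap its span
    if params.min_isoform_percent > 0 and clusters:
        spans = [cl.span for cl in clusters]
        keep = []
        for i, cl in enumerate(clusters):
            denom = sum(
                other.size
                for j, other in enumerate(clusters)
                if spans[j].overlaps(spans[i]) and spans[j].strand == spans[i].strand
            )
            if cl.size >= params.min_isoform_percent / 100.0 * denom:
                keep.append(cl)
        clusters = keep

    for i, cl in enumerate(clusters, 1):
        cl.cluster_id = f"cluster_{i:05d}"
    return clusters, n_rejected


def consensus(cluster: ReadCluster) -> ConsensusTranscript:
    """Median-boundary consensus of a cluster (lower median for even sizes).

    Exon count is preserved; all members must share one intron count.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    n_exons = cluster.members[0].n_exons
    if any(m.n_exons != n_exons for m in cluster.members):
        raise AssertionError("cluster members disagree on intron count")
    rows = np.array([m.boundaries() for m in cluster.members], dtype=np.int64)
    med = [lower_median(rows[:, j]) for j in range(rows.shape[1])]
    exons = tuple((med[2 * i], med[2 * i + 1]) for i in range(n_exons))
    chain = ExonChain(
        cluster.cluster_id,
        cluster.members[0].chrom,
        cluster.members[0].strand,
        exons,
    )
    return ConsensusTranscript(chain=chain, support=cluster.size,
                               cluster_id=cluster.cluster_id)


def consensus_transcripts(
    clusters: Sequence[ReadCluster],
) -> List[ConsensusTranscript]:
    return [consensus(cl) for cl in clusters]
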