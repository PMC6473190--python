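"""Spike-in-anchored quality metrics: dose-response fits, capture enrichment,
limit of detection, expression CV, RPG10K, on-target rate, error rates,
coverage uniformity, and assembly sensitivity/precision.

Quantification uses a minimal compatibility quantifier: each read is assigned
to the transcripts whose intron chain contains the read's (corrected,
boundary-exact) chain as a contiguous run, with the read's span inside the
matching exons; multi-compatible reads are split fractionally equally.
TPM_i = (count_i / length_i) / sum_j (count_j / length_j) x 10^6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExonChain, GenomicInterval, TranscriptModel


# ---------------------------------------------------------------------------
# Compatibility quantifier


def _read_compatible(read: ExonChain, t: TranscriptModel) -> bool:
    ti = t.chain.introns
    ri = read.introns
    if read.start < t.chain.start or read.end > t.chain.end:
        return False
    if not ri:
        return any(s <= read.start and read.end <= e for s, e in t.chain.exons)
    n, m = len(ri), len(ti)
    exons = t.chain.exons
    for i in range(m - n + 1):
        if ti[i : i + n] != ri:
            continue
        # terminal read exons must stay inside the flanking transcript exons
        if exons[i][0] <= read.start and read.end <= exons[i + n][1]:
            return True
    return False


def assign_reads(
    reads: Sequence[ExonChain],
    transcripts: Sequence[TranscriptModel],
) -> Tuple[pd.DataFrame, int]:
    """Fractional read-to-transcript assignment.

    Returns (DataFrame read_id -> [transcript ids, weight], n_unassigned).
    """
    from intervaltree import IntervalTree

    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for t in transcripts:
        trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
            t.chain.start, t.chain.end, t
        )
    rows = {"read_id": [], "transcript_id": [], "weight": []}
    n_unassigned = 0
    cache: Dict[Tuple, List[str]] = {}
    for r in reads:
        key = (r.chrom, r.strand, r.exons)
        hit = cache.get(key)
        if hit is None:
            tree = trees.get((r.chrom, r.strand))
            hit = []
            if tree is not None:
                for iv in tree.overlap(r.start, r.end):
                    if _read_compatible(r, iv.data):
                        hit.append(iv.data.id)
            hit.sort()
            cache[key] = hit
        if not hit:
            n_unassigned += 1
            continue
        w = 1.0 / len(hit)
        for tid in hit:
            rows["read_id"].append(r.id)
            rows["transcript_id"].append(tid)
            rows["weight"].append(w)
    return pd.DataFrame(rows), n_unassigned


def tpm_matrix(
    reads_by_sample: Dict[int, Sequence[ExonChain]],
    transcripts: Sequence[TranscriptModel],
) -> pd.DataFrame:
    """TPM per transcript (rows) and sample (columns)."""
    lengths = pd.Series({t.id: t.length for t in transcripts}, dtype=float)
    cols = {}
    for sample in sorted(reads_by_sample):
        assigned, _ = assign_reads(reads_by_sample[sample], transcripts)
        counts = (
            assigned.groupby("transcript_id")["weight"].sum()
            .reindex(lengths.index, fill_value=0.0)
            if len(assigned)
            else pd.Series(0.0, index=lengths.index)
        )
        rate = counts / lengths
        total = rate.sum()
        cols[sample] = rate / total * 1e6 if total > 0 else rate
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Dose-response, enrichment, LoD, CV


@dataclass
class DoseResponseFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    domain: str
    undetected: List[str]


def fit_dose_response(
    tpm: pd.DataFrame, spikeins: pd.DataFrame, domain: str
) -> DoseResponseFit:
    """OLS of log10(mean TPM across samples) on log10(input concentration).

    ``domain`` selects captured or non-captured spike-ins; isoforms with mean
    TPM = 0 are excluded from the fit and reported.
    """
    want = domain == "captured"
    sub = spikeins[spikeins["captured"] == want]
    mean_tpm = tpm.mean(axis=1).reindex(sub["isoform_id"]).fillna(0.0)
    detected = mean_tpm > 0
    undetected = list(sub["isoform_id"][~detected.to_numpy()])
    x = np.log10(sub["concentration"].to_numpy()[detected.to_numpy()])
    y = np.log10(mean_tpm.to_numpy()[detected.to_numpy()])
    if x.size < 2:
        raise ValueError(f"fewer than 2 detected {domain} spike-ins")
    fit = stats.linregress(x, y)
    return DoseResponseFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=int(x.size),
        domain=domain,
        undetected=undetected,
    )


def detection_table(tpm: pd.DataFrame, spikeins: pd.DataFrame) -> pd.DataFrame:
    """Per-isoform detection: samples with TPM > 0 and the 'reliably
    detected' flag (detected in more than one sample)."""
    n_det = (tpm > 0).sum(axis=1).reindex(spikeins["isoform_id"]).fillna(0)
    out = spikeins.copy()
    out["n_samples_detected"] = n_det.to_numpy().astype(int)
    out["detected"] = out["n_samples_detected"] > 1
    return out


def enrichment_fold(tpm: pd.DataFrame, spikeins: pd.DataFrame) -> float:
    """Mean over shared concentration points of (mean captured TPM) /
    (mean non-captured TPM).

    A point is shared when, on each side (captured / non-captured), at least
    half of that side's isoforms there are reliably detected (TPM > 0 in more
    than one sample, the LoD rule). A point whose mean rests on a single
    straggler isoform is not quantified and would only inject noise into the
    ratio.
    """
    det = detection_table(tpm, spikeins).set_index("isoform_id")
    mean_tpm = tpm.mean(axis=1)
    ratios = []
    for conc, grp in det.groupby("concentration"):
        cap = grp[grp["captured"]]
        non = grp[~grp["captured"]]
        if cap.empty or non.empty:
            continue
        if cap["detected"].mean() < 0.5 or non["detected"].mean() < 0.5:
            continue
        cap_mean = float(mean_tpm.reindex(cap.index).fillna(0.0).mean())
        non_mean = float(mean_tpm.reindex(non.index).fillna(0.0).mean())
        if non_mean > 0:
            ratios.append(cap_mean / non_mean)
    if not ratios:
        raise ValueError("no shared concentration points with detections")
    return float(np.mean(ratios))


def limit_of_detection(
    tpm: pd.DataFrame,
    spikeins: pd.DataFrame,
    domain: Optional[str] = None,
) -> Tuple[Optional[float], pd.DataFrame]:
    """Lowest input concentration among spike-ins detected (TPM > 0) in more
    than one sample. Returns (concentration or None, detection table)."""
    if tpm.shape[1] < 2:
        raise ValueError("LoD needs >= 2 samples")
    det = detection_table(tpm, spikeins)
    if domain is not None:
        det = det[det["captured"] == (domain == "captured")]
    hits = det[det["detected"]]
    if hits.empty:
        return None, det
    return float(hits["concentration"].min()), det


def cv_per_isoform(tpm: pd.DataFrame) -> pd.Series:
    """CV = sample SD / mean TPM across samples; NaN where the mean is 0."""
    if tpm.shape[1] < 2:
        raise ValueError("CV needs >= 2 samples")
    mean = tpm.mean(axis=1)
    sd = tpm.std(axis=1, ddof=1)
    cv = sd / mean
    cv[mean == 0] = np.nan
    return cv


def rpg10k(gene_counts: pd.Series, total_aligned: int) -> pd.Series:
    """Reads per gene per 10k aligned reads."""
    if total_aligned <= 0:
        raise ValueError("total_aligned must be positive")
    return gene_counts / total_aligned * 1e4


def on_target_rate(
    chains: Sequence[ExonChain], targets: Sequence[GenomicInterval]
) -> float:
    """Fraction of reads with >= 1 bp exonic overlap with the target regions."""
    if not chains:
        raise ValueError("no reads")
    from intervaltree import IntervalTree

    trees: Dict[str, IntervalTree] = {}
    for iv in targets:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    n_on = 0
    for c in chains:
        tree = trees.get(c.chrom)
        if tree is not None and any(tree.overlap(s, e) for s, e in c.exons):
            n_on += 1
    return n_on / len(chains)


def error_rates(sidecar: pd.DataFrame) -> Tuple[float, float]:
    """(mismatch rate, indel rate): summed error counts over aligned bases."""
    bases = sidecar["aligned_bases"].sum()
    if bases <= 0:
        raise ValueError("no aligned bases")
    mm = sidecar["mismatches"].sum() / bases
    ind = (sidecar["insertions"].sum() + sidecar["deletions"].sum()) / bases
    return float(mm), float(ind)


# ---------------------------------------------------------------------------
# Coverage uniformity


def per_base_coverage(
    chains: Sequence[ExonChain], exon: GenomicInterval
) -> np.ndarray:
    """Read coverage of every base of one exon from spliced alignments."""
    cov = np.zeros(len(exon), dtype=np.int64)
    for c in chains:
        if c.chrom != exon.chrom:
            continue
        for s, e in c.exons:
            lo, hi = max(s, exon.start), min(e, exon.end)
            if lo < hi:
                cov[lo - exon.start : hi - exon.start] += 1
    return cov


def coverage_uniformity(
    coverage_by_platform: Dict[str, Dict[str, np.ndarray]],
) -> Tuple[pd.DataFrame, float, float]:
    """Per-exon coefficient of variation of per-base coverage per platform,
    plus a paired two-tailed t-test across exons present on both platforms.

    Exons whose mean coverage is zero on either platform are excluded
    pairwise. Returns (cv table, t statistic, p value).
    """
    platforms = sorted(coverage_by_platform)
    if len(platforms) != 2:
        raise ValueError("expected exactly two platforms")
    exons = sorted(
        set(coverage_by_platform[platforms[0]])
        & set(coverage_by_platform[platforms[1]])
    )
    rows = []
    for ex in exons:
        row = {"exon": ex}
        for p in platforms:
            cov = coverage_by_platform[p][ex]
            mean = cov.mean()
            row[p] = cov.std(ddof=1) / mean if mean > 0 else np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("exon")
    paired = df.dropna()
    if len(paired) < 2:
        raise ValueError("fewer than 2 paired exons")
    a = paired[platforms[0]].to_numpy()
    b = paired[platforms[1]].to_numpy()
    if np.allclose(a, b):
        return df, 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return df, float(t), float(p)


# ---------------------------------------------------------------------------
# Assembly evaluation


def _merged_exonic_bp(
    transcripts: Iterable, key=None
) -> Dict[Tuple[str, str], List[Tuple[int, int]]]:
    by_cs: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for t in transcripts:
        chain = t.chain if isinstance(t, TranscriptModel) else t
        by_cs.setdefault((chain.chrom, chain.strand), []).extend(chain.exons)
    merged = {}
    for cs, exons in by_cs.items():
        out: List[List[int]] = []
        for s, e in sorted(exons):
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[cs] = [tuple(x) for x in out]
    return merged


def _interval_intersection_bp(a: List[Tuple[int, int]],
                              b: List[Tuple[int, int]]) -> int:
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _sens_prec(tp_t: int, n_truth: int, tp_p: int, n_pred: int) -> Tuple[float, float, bool]:
    sens = tp_t / n_truth if n_truth else float("nan")
    if n_pred == 0:
        return sens, 0.0, False
    return sens, tp_p / n_pred, True


def evaluate_assembly(
    predicted: Sequence,
    truth: Sequence[TranscriptModel],
) -> pd.DataFrame:
    """Sensitivity/precision at base, (internal) exon, intron, transcript and
    gene levels against a truth annotation.

    Transcript level requires intron-chain identity; gene level asks whether
    a truth gene has at least one matched transcript (sensitivity) and
    whether a predicted locus contains one (precision).
    """
    if not truth:
        raise ValueError("empty truth annotation")
    pred_models = [
        t if isinstance(t, TranscriptModel)
        else TranscriptModel(t.id, t.id, t)
        for t in predicted
    ]
    rows = []

    # base level: merged exonic base sets
    tm = _merged_exonic_bp(truth)
    pm = _merged_exonic_bp(pred_models)
    t_bp = sum(e - s for ivs in tm.values() for s, e in ivs)
    p_bp = sum(e - s for ivs in pm.values() for s, e in ivs)
    tp = sum(
        _interval_intersection_bp(tm[cs], pm[cs]) for cs in tm if cs in pm
    )
    sens, prec, ok = _sens_prec(tp, t_bp, tp, p_bp)
    rows.append(("base", sens, prec, ok))

    # internal-exon level: exact boundary match
    t_ex = {
        (t.chrom, t.strand, s, e) for t in truth for s, e in t.chain.exons[1:-1]
    }
    p_ex = {
        (t.chrom, t.strand, s, e)
        for t in pred_models
        for s, e in t.chain.exons[1:-1]
    }
    inter = len(t_ex & p_ex)
    sens, prec, ok = _sens_prec(inter, len(t_ex), inter, len(p_ex))
    rows.append(("exon", sens, prec, ok))

    # intron level: exact junction match
    t_in = {(t.chrom, t.strand, d, a) for t in truth for d, a in t.chain.introns}
    p_in = {
        (t.chrom, t.strand, d, a)
        for t in pred_models
        for d, a in t.chain.introns
    }
    inter = len(t_in & p_in)
    sens, prec, ok = _sens_prec(inter, len(t_in), inter, len(p_in))
    rows.append(("intron", sens, prec, ok))

    # transcript level: intron-chain identity
    t_chains = {t.chain.intron_key for t in truth if t.chain.introns}
    matched_pred = [
        t for t in pred_models
        if t.chain.introns and t.chain.intron_key in t_chains
    ]
    p_chains = {t.chain.intron_key for t in pred_models if t.chain.introns}
    matched_truth = [
        t for t in truth if t.chain.introns and t.chain.intron_key in p_chains
    ]
    n_truth_tx = sum(1 for t in truth if t.chain.introns)
    n_pred_tx = sum(1 for t in pred_models if t.chain.introns)
    sens, prec, ok = _sens_prec(
        len(matched_truth), n_truth_tx, len(matched_pred), n_pred_tx
    )
    rows.append(("transcript", sens, prec, ok))

    # gene level
    truth_genes = {t.gene_id for t in truth}
    matched_genes = {t.gene_id for t in matched_truth}
    from .core import group_by_locus

    loci_total = 0
    loci_matched = 0
    matched_pred_ids = {t.id for t in matched_pred}
    for strand in ("+", "-"):
        sub = [t for t in pred_models if t.strand == strand]
        for locus in group_by_locus([t.chain.span for t in sub]):
            loci_total += 1
            if any(sub[i].id in matched_pred_ids for i in locus):
                loci_matched += 1
    sens, prec, ok = _sens_prec(
        len(matched_genes), len(truth_genes), loci_matched, loci_total
    )
    rows.append(("gene", sens, prec, ok))

    return pd.DataFrame(
        rows, columns=["level", "sensitivity", "precision", "precision_defined"]
    ).set_index("level")
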