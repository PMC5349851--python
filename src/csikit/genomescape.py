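"""CSI genomescapes: scoring genomic intervals with k-mer CSI intensities.

A region's score under a dimer's profile is the maximum CSI intensity of any
k-mer window it contains (collapsed-strand profiles cover both orientations
implicitly).  ChIP-seq peaks scored this way are compared against flank
negatives — equal-length regions 5 kb up- and downstream of each peak center
that do not overlap any peak — via ROC curves, and each peak is assigned the
lowest false-positive-rate cutoff at which it would be called positive.

Intervals are BED-style: 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .selex import BindingProfile
from .seqcode import encode, revcomp_index_table, window_indices

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ScoredRegion:
    interval: GenomicInterval
    max_csi: dict[str, float]
    fpr_cutoff: dict[str, float] | None = None


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def score_interval(sequence: str, profile: BindingProfile) -> tuple[float, np.ndarray]:
    """Max CSI and the per-window CSI track of a sequence.

    Windows containing non-ACGT letters (assembly gaps) are NaN and excluded
    from the max; a sequence with no valid window scores NaN.
    """
    k = profile.k
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes = encode(sequence)[None, :]
    idx, ok = window_indices(codes, k)
    track = np.where(ok[0], profile.csi[idx[0]], np.nan)
    max_csi = float(np.nanmax(track)) if ok.any() else float("nan")
    return max_csi, track


def quantile_normalize(profiles: Sequence[BindingProfile]) -> list[BindingProfile]:
    """Replace each profile's CSI vector by the rank-aligned mean vector.

    Every output profile shares the same sorted value vector; within-profile
    rank order is preserved.  Collapsed-strand profiles are re-symmetrized by
    averaging reverse-complement pairs (ties between a k-mer and its reverse
    complement would otherwise be broken arbitrarily).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    k = profiles[0].k
    if any(p.k != k for p in profiles):
        raise ValueError("profiles have mixed k")
    sorted_mean = np.mean([np.sort(p.csi) for p in profiles], axis=0)
    out = []
    for p in profiles:
        v = np.empty_like(sorted_mean)
        v[np.argsort(p.csi, kind="stable")] = sorted_mean
        if p.strand_mode == "collapsed":
            rc = revcomp_index_table(k)
            v = 0.5 * (v + v[rc])
        out.append(p.replace(csi=v))
    return out


def flank_negatives(
    peaks: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    offset: int = 5000,
) -> tuple[list[GenomicInterval], int]:
    """Equal-length negative regions +/- ``offset`` from each peak center.

    Candidates that fall outside the chromosome or overlap any peak are
    dropped (not truncated), keeping the equal-length guarantee literal.
    Returns ``(negatives, n_dropped)``.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)

    negatives: list[GenomicInterval] = []
    dropped = 0
    for p in peaks:
        size = chrom_sizes[p.chrom]
        half = p.length // 2
        for sign in (-1, 1):
            c = p.center + sign * offset
            start, end = c - half, c - half + p.length
            if start < 0 or end > size:
                dropped += 1
                continue
            if trees[p.chrom].overlap(start, end):
                dropped += 1
                continue
            negatives.append(GenomicInterval(p.chrom, start, end, name="neg"))
    if dropped:
        logger.info("flank_negatives: dropped %d candidate regions", dropped)
    return negatives, dropped


def roc_curve(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> ROCResult:
    """ROC from two score lists: TPR/FPR = fraction of scores >= threshold.

    Thresholds sweep the union of observed scores (plus +inf so the curve
    starts at the origin); the trapezoidal AUC equals the Mann-Whitney
    statistic with half-credit for ties.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("positive and negative score lists must be nonempty")
    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate((pos, neg)))[::-1]))
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    tpr = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def fpr_cutoff(score: float, neg_scores: np.ndarray) -> float:
    """Lowest FPR at which a region with this score is called positive.

    Equals the fraction of negative scores >= the region's score (a region
    tied with the best negative therefore has FPR > 0).
    """
    neg = np.asarray(neg_scores, dtype=float)
    if np.isnan(score):
        return float("nan")
    return float(np.mean(neg >= score))


def fpr_cutoff_matrix(
    peaks: Sequence[ScoredRegion],
    neg_scores_per_dimer: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Peaks x dimers matrix of lowest FPR cutoffs.

    Rows are clusterable with :func:`csikit.compare.cluster_dimers`; columns
    missing a negative set raise.
    """
    if not peaks:
        raise ValueError("no peaks")
    dimers = list(peaks[0].max_csi)
    for d in dimers:
        if d not in neg_scores_per_dimer:
            raise ValueError(f"missing negative set for dimer {d}")
    neg = {d: np.asarray(neg_scores_per_dimer[d], dtype=float) for d in dimers}
    rows = []
    for p in peaks:
        rows.append([fpr_cutoff(p.max_csi[d], neg[d]) for d in dimers])
    index = [
        p.interval.name or f"{p.interval.chrom}:{p.interval.start}-{p.interval.end}"
        for p in peaks
    ]
    return pd.DataFrame(rows, index=index, columns=dimers)


def score_peaks(
    genome: Mapping[str, str],
    peaks: Sequence[GenomicInterval],
    profiles: Sequence[BindingProfile],
) -> list[ScoredRegion]:
    """Max-window CSI of each peak under each profile.

    ``genome`` maps chromosome names to sequences (a dict or a pyfaidx-style
    mapping).  Peaks with no valid window score NaN (counted and logged).
    """
    scored = []
    n_invalid = 0
    for p in peaks:
        seq = str(genome[p.chrom][p.start : p.end])
        maxes = {}
        for prof in profiles:
            m, _ = score_interval(seq, prof)
            maxes[prof.dimer_id] = m
        if any(np.isnan(v) for v in maxes.values()):
            n_invalid += 1
        scored.append(ScoredRegion(interval=p, max_csi=maxes))
    if n_invalid:
        logger.info("score_peaks: %d peaks had windows with no valid score", n_invalid)
    return scored


@dataclass
class OverlapResult:
    a_only: int
    b_only: int
    both: int  # intervals of `a` overlapping `b` by >= min_overlap
    both_b: int  # intervals of `b` overlapping `a`
    merged: list[GenomicInterval]


def _tree(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _overlaps(iv: GenomicInterval, trees: dict[str, IntervalTree], min_overlap: int) -> bool:
    tree = trees.get(iv.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(iv.start, iv.end):
        if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
            return True
    return False


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def overlap_sets(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> OverlapResult:
    """Count intervals private to each set and shared between them.

    An interval is shared when it overlaps at least one interval of the other
    set by >= ``min_overlap`` bases.  ``merged`` is the union of both sets
    merged per chromosome.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ta, tb = _tree(a), _tree(b)
    both_a = sum(_overlaps(iv, tb, min_overlap) for iv in a)
    both_b = sum(_overlaps(iv, ta, min_overlap) for iv in b)
    return OverlapResult(
        a_only=len(a) - both_a,
        b_only=len(b) - both_b,
        both=both_a,
        both_b=both_b,
        merged=merge_intervals(list(a) + list(b)),
    )


def venn_counts(
    sets: Mapping[str, Sequence[GenomicInterval]], min_overlap: int = 1
) -> dict[frozenset, int]:
    """Membership-pattern counts of merged regions across 2-4 interval sets."""
    if not 2 <= len(sets) <= 4:
        raise ValueError("venn_counts supports 2-4 sets")
    trees = {name: _tree(ivs) for name, ivs in sets.items()}
    merged = merge_intervals([iv for ivs in sets.values() for iv in ivs])
    counts: dict[frozenset, int] = {}
    for region in merged:
        members = frozenset(
            name for name, tree in trees.items() if _overlaps(region, tree, min_overlap)
        )
        counts[members] = counts.get(members, 0) + 1
    return counts
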