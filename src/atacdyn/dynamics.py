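"""Two-condition peak dynamics: newly opened regions, distal new peaks,
genes gaining peaks, distance-to-TSS statistics and positional shifts.

The central rule: a peak in the *after* condition is "new" iff its edge-to-edge
gap to every *before* peak on the same chromosome is at least ``min_dist``
(default 5,000 bp); after-condition peaks on chromosomes with no before peaks
are vacuously new.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    min_dist_intervals_to_points,
    min_gap_to_intervals,
)

__all__ = [
    "DynamicsResult",
    "MeanDistanceResult",
    "PeakShiftResult",
    "find_new_peaks",
    "find_lost_peaks",
    "find_distal_new_peaks",
    "genes_gaining_peak",
    "mean_tss_distance",
    "peak_count_ratio",
    "genes_with_peak_ratio",
    "peak_shift",
    "analyze_dynamics",
]

DEFAULT_MIN_DIST = 5000


def _min_gap_per_peak(query: PeakSet, target: PeakSet) -> np.ndarray:
    """Edge gap from each query peak to the nearest target peak (inf if none
    share its chromosome)."""
    out = np.full(query.count(), np.inf)
    target_by_chrom = target.by_chrom()
    for chrom, sub in query.df.groupby("chrom", sort=False):
        if chrom not in target_by_chrom:
            continue
        ts, te = target_by_chrom[chrom]
        out[sub.index.to_numpy()] = min_gap_to_intervals(
            sub["start"].to_numpy(), sub["end"].to_numpy(), ts, te
        )
    return out


def find_new_peaks(
    after: PeakSet, before: PeakSet, min_dist: int = DEFAULT_MIN_DIST
) -> tuple[PeakSet, PeakSet]:
    """Split the after-condition set into (new, retained) by the distance rule."""
    gaps = _min_gap_per_peak(after, before)
    is_new = gaps >= min_dist
    new = after.subset(is_new).relabel(f"{after.label}_new")
    retained = after.subset(~is_new).relabel(f"{after.label}_retained")
    return new, retained


def find_lost_peaks(
    before: PeakSet, after: PeakSet, min_dist: int = DEFAULT_MIN_DIST
) -> PeakSet:
    """Before-condition peaks with no after-condition peak within min_dist."""
    gaps = _min_gap_per_peak(before, after)
    return before.subset(gaps >= min_dist).relabel(f"{before.label}_lost")


def _tss_points_by_chrom(genes: Sequence[GeneModel]) -> dict[str, np.ndarray]:
    pts: dict[str, list[int]] = {}
    for g in genes:
        pts.setdefault(g.chrom, []).append(g.tss)
    return {c: np.sort(np.asarray(v)) for c, v in pts.items()}


def _min_tss_dist_per_peak(peaks: PeakSet, genes: Sequence[GeneModel]) -> np.ndarray:
    out = np.full(peaks.count(), np.inf)
    tss = _tss_points_by_chrom(genes)
    for chrom, sub in peaks.df.groupby("chrom", sort=False):
        if chrom not in tss:
            continue
        out[sub.index.to_numpy()] = min_dist_intervals_to_points(
            sub["start"].to_numpy(), sub["end"].to_numpy(), tss[chrom]
        )
    return out


def find_distal_new_peaks(
    new: PeakSet,
    genes: Sequence[GeneModel],
    before: PeakSet,
    min_dist: int = DEFAULT_MIN_DIST,
) -> PeakSet:
    """New peaks overlapping no gene body, >= min_dist from every TSS and
    from every before-condition peak."""
    if not genes:
        raise ValueError("no genes supplied")
    from .region_enrichment import RegionCatalog

    catalog = RegionCatalog.from_intervals(
        new.genome, {"gene_body": [g.body for g in genes]}
    )
    in_gene = catalog.peaks_in_class(new, "gene_body")
    tss_dist = _min_tss_dist_per_peak(new, genes)
    before_gap = _min_gap_per_peak(new, before)
    keep = ~in_gene & (tss_dist >= min_dist) & (before_gap >= min_dist)
    return new.subset(keep).relabel(f"{new.label}_distal")


def genes_gaining_peak(
    genes: Sequence[GeneModel],
    before: PeakSet,
    after: PeakSet,
    assoc_window: int = 1000,
) -> list[str]:
    """Genes with no before-condition peak but >=1 after-condition peak in the
    association region (gene body extended by assoc_window on both sides)."""
    if assoc_window < 0:
        raise ValueError("assoc_window must be >= 0")
    before_by = before.by_chrom()
    after_by = after.by_chrom()
    lengths = before.genome.lengths
    out = []
    for g in genes:
        lo = max(0, g.body.start - assoc_window)
        hi = min(lengths[g.chrom], g.body.end + assoc_window)

        def _has_peak(arrays) -> bool:
            if g.chrom not in arrays:
                return False
            ts, te = arrays[g.chrom]
            idx = np.searchsorted(ts, hi, side="left")
            return idx > 0 and bool(np.max(te[:idx]) > lo)

        if not _has_peak(before_by) and _has_peak(after_by):
            out.append(g.gene_id)
    return out


@dataclass(frozen=True)
class MeanDistanceResult:
    mean_bp: float
    n_peaks: int
    n_excluded: int  # peaks on chromosomes with no TSS


def mean_tss_distance(peaks: PeakSet, genes: Sequence[GeneModel]) -> MeanDistanceResult:
    """Mean over peaks of the distance to the nearest TSS point.

    Peaks on chromosomes carrying no TSS cannot contribute a distance; they
    are excluded and counted. All peaks excluded is an error.
    """
    dists = _min_tss_dist_per_peak(peaks, genes)
    usable = np.isfinite(dists)
    if not usable.any():
        raise ValueError("no peak shares a chromosome with any TSS")
    return MeanDistanceResult(
        float(dists[usable].mean()), int(usable.sum()), int((~usable).sum())
    )


def peak_count_ratio(set_a: PeakSet, set_b: PeakSet) -> float:
    """count(A) / count(B)."""
    if set_b.count() == 0:
        raise ValueError("denominator peak set is empty")
    return set_a.count() / set_b.count()


def genes_with_peak_ratio(
    genes: Sequence[GeneModel],
    set_a: PeakSet,
    set_b: PeakSet,
    assoc_window: int = 1000,
) -> float:
    """|genes with >=1 A peak in their association region| / |same for B|."""
    empty_a = PeakSet("empty", set_a.genome)
    n_a = len(genes_gaining_peak(genes, empty_a, set_a, assoc_window))
    n_b = len(genes_gaining_peak(genes, empty_a, set_b, assoc_window))
    if n_b == 0:
        raise ValueError("no gene is associated with a peak in the denominator set")
    return n_a / n_b


@dataclass
class PeakShiftResult:
    offsets: np.ndarray  # after midpoint - before midpoint, one per pair
    pairs: list[tuple[int, int]]  # (after row index, before row index)
    unpaired_after: list[int]
    unpaired_before: list[int]

    @property
    def median_offset(self) -> float:
        return float(np.median(self.offsets)) if len(self.offsets) else float("nan")


def peak_shift(
    before: PeakSet, after: PeakSet, max_pair_dist: int = 1000
) -> PeakShiftResult:
    """Greedy nearest-neighbour pairing of after peaks to before peaks.

    Candidate pairs (same chromosome, |midpoint offset| <= max_pair_dist) are
    taken in increasing |offset| order, ties broken by leftmost before then
    leftmost after midpoint; each peak is used at most once. The signed offset
    of a pair is after midpoint - before midpoint.
    """
    b_mid = before.midpoints()
    a_mid = after.midpoints()
    candidates = []  # (|offset|, before mid, after mid, before idx, after idx)
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, row in enumerate(b_mid.itertuples()):
        b_by_chrom.setdefault(row.chrom, []).append((int(row.mid), i))
    for c in b_by_chrom:
        b_by_chrom[c].sort()
    for j, row in enumerate(a_mid.itertuples()):
        if row.chrom not in b_by_chrom:
            continue
        mids = b_by_chrom[row.chrom]
        arr = np.asarray([m for m, _ in mids])
        lo = np.searchsorted(arr, row.mid - max_pair_dist, side="left")
        hi = np.searchsorted(arr, row.mid + max_pair_dist, side="right")
        for m, i in mids[lo:hi]:
            candidates.append((abs(int(row.mid) - m), m, int(row.mid), i, j))
    candidates.sort()
    used_b: set[int] = set()
    used_a: set[int] = set()
    offsets = []
    pairs = []
    for _d, m_b, m_a, i, j in candidates:
        if i in used_b or j in used_a:
            continue
        used_b.add(i)
        used_a.add(j)
        pairs.append((j, i))
        offsets.append(m_a - m_b)
    unpaired_after = [j for j in range(after.count()) if j not in used_a]
    unpaired_before = [i for i in range(before.count()) if i not in used_b]
    return PeakShiftResult(np.asarray(offsets), pairs, unpaired_after, unpaired_before)


@dataclass
class DynamicsResult:
    new_peaks: PeakSet
    retained_peaks: PeakSet
    lost_peaks: PeakSet
    distal_new_peaks: PeakSet
    genes_gaining_peak: list[str]
    mean_tss_distance_new: MeanDistanceResult
    mean_tss_distance_all_after: MeanDistanceResult


def analyze_dynamics(
    before: PeakSet,
    after: PeakSet,
    genes: Sequence[GeneModel],
    min_dist: int = DEFAULT_MIN_DIST,
    assoc_window: int = 1000,
) -> DynamicsResult:
    """Run the full two-condition comparison with one set of thresholds."""
    new, retained = find_new_peaks(after, before, min_dist)
    lost = find_lost_peaks(before, after, min_dist)
    distal = find_distal_new_peaks(new, genes, before, min_dist)
    gained = genes_gaining_peak(genes, before, after, assoc_window)
    return DynamicsResult(
        new_peaks=new,
        retained_peaks=retained,
        lost_peaks=lost,
        distal_new_peaks=distal,
        genes_gaining_peak=gained,
        mean_tss_distance_new=mean_tss_distance(new, genes),
        mean_tss_distance_all_after=mean_tss_distance(after, genes),
    )
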