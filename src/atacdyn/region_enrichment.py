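"""Peak annotation against genomic region classes and whole-genome enrichment.

A :class:`RegionCatalog` holds labelled, per-class *merged* interval sets
(TSS windows, enhancers, histone-mark domains, gene bodies, ...) with
genome-fraction bookkeeping. Fold enrichment of a peak set in a class is

    fold = (n_peaks_in_class / n_peaks_total) / (class_bp / total_bp)

so that uniformly placed peaks have expected fold 1. Significance uses a
hypergeometric model on a binned genome: the genome is tiled into bins of the
peak set's median width, the population is all bins, successes are bins
touching the class, draws are the peaks, and the observed count is the number
of peaks in the class (upper tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .genome_io import (
    FragmentSet,
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    merge_intervals,
)

__all__ = [
    "RegionCatalog",
    "EnrichmentResult",
    "build_tss_windows",
    "fold_enrichment",
    "fraction_regions_with_peak",
    "classify_peaks",
    "binned_coverage",
    "spearman_tracks",
    "tss_matrix",
    "cluster_samples",
]

INTERGENIC = "intergenic"


def _to_chrom_arrays(intervals: Iterable[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_intervals(intervals)
    out: dict[str, list[list[int]]] = {}
    for iv in merged:
        out.setdefault(iv.chrom, [[], []])
        out[iv.chrom][0].append(iv.start)
        out[iv.chrom][1].append(iv.end)
    return {c: (np.asarray(s), np.asarray(e)) for c, (s, e) in out.items()}


@dataclass
class RegionCatalog:
    """Labelled region classes over one genome; intervals merged per class."""

    genome: GenomeLayout
    classes: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, genome: GenomeLayout, classes: Mapping[str, Iterable[GenomicInterval]]
    ) -> "RegionCatalog":
        cat = cls(genome)
        for label, intervals in classes.items():
            cat.add_class(label, intervals)
        return cat

    def add_class(self, label: str, intervals: Iterable[GenomicInterval]) -> None:
        arrays = _to_chrom_arrays(intervals)
        for chrom in arrays:
            if chrom not in self.genome:
                raise ValueError(f"class {label!r}: unknown chromosome {chrom!r}")
        self.classes[label] = arrays

    def class_labels(self) -> list[str]:
        return list(self.classes)

    def class_bp(self, label: str) -> int:
        arrays = self.classes[label]
        return int(sum((e - s).sum() for s, e in arrays.values()))

    def class_genome_fraction(self, label: str) -> float:
        return self.class_bp(label) / self.genome.total_bp

    def peaks_in_class(self, peaks: PeakSet, label: str) -> np.ndarray:
        """Boolean mask (peak order) of peaks overlapping >=1 bp of the class."""
        arrays = self.classes[label]
        mask = np.zeros(peaks.count(), dtype=bool)
        df = peaks.df
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in arrays:
                continue
            ts, te = arrays[chrom]
            qs = sub["start"].to_numpy()
            qe = sub["end"].to_numpy()
            # class intervals are disjoint & sorted: the only candidate whose
            # start precedes the query end is the last one before it
            idx = np.searchsorted(ts, qe, side="left")
            hit = (idx > 0) & (te[np.maximum(idx - 1, 0)] > qs)
            mask[sub.index.to_numpy()] = hit
        return mask


@dataclass(frozen=True)
class EnrichmentResult:
    peakset_label: str
    class_label: str
    n_peaks_total: int
    n_peaks_in_class: int
    class_genome_fraction: float
    fold: float
    p_value: float
    fraction_regions_hit: float | None = None


def build_tss_windows(
    genes: Sequence[GeneModel], genome: GenomeLayout, half_width: int = 1000
) -> list[GenomicInterval]:
    """Per-gene TSS windows ``[tss - half_width, tss + half_width + 1)``.

    Windows are clipped to chromosome bounds and returned unmerged (one per
    gene, in gene order) so that per-region hit fractions stay per-gene;
    merge happens inside the catalog for bp bookkeeping.
    """
    if not genes:
        raise ValueError("no genes supplied")
    lengths = genome.lengths
    windows = []
    for g in genes:
        lo = max(0, g.tss - half_width)
        hi = min(lengths[g.chrom], g.tss + half_width + 1)
        windows.append(GenomicInterval(g.chrom, lo, hi))
    return windows


def _bins_overlapping_class(
    genome: GenomeLayout, arrays: dict[str, tuple[np.ndarray, np.ndarray]], bin_width: int
) -> tuple[int, int]:
    """(total bins, bins touching the class) for a left-to-right tiling."""
    total = 0
    in_class = 0
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        n_bins = -(-int(length) // bin_width)
        total += n_bins
        if chrom not in arrays:
            continue
        ts, te = arrays[chrom]
        lo = ts // bin_width
        hi = (te - 1) // bin_width
        # intervals are disjoint & sorted, but adjacent ones may share a bin
        count = 0
        prev_hi = -1
        for a, b in zip(lo, hi):
            a = max(int(a), prev_hi + 1)
            if b >= a:
                count += int(b) - a + 1
            prev_hi = max(prev_hi, int(b))
        in_class += count
    return total, in_class


def fold_enrichment(
    peaks: PeakSet,
    class_label: str,
    catalog: RegionCatalog,
    per_region_intervals: Sequence[GenomicInterval] | None = None,
    bin_width: int | None = None,
) -> EnrichmentResult:
    """Whole-genome-relative fold enrichment of a peak set in one region class.

    ``per_region_intervals`` (unmerged, e.g. per-gene TSS windows) additionally
    yields the fraction of individual regions hit by >=1 peak.
    """
    n_total = peaks.count()
    if n_total == 0:
        raise ValueError("empty peak set")
    class_bp = catalog.class_bp(class_label)
    if class_bp == 0:
        raise ValueError(f"class {class_label!r} covers zero bases")
    mask = catalog.peaks_in_class(peaks, class_label)
    n_in = int(mask.sum())
    frac = class_bp / catalog.genome.total_bp
    fold = (n_in / n_total) / frac

    if bin_width is None:
        widths = (peaks.df["end"] - peaks.df["start"]).to_numpy()
        bin_width = max(1, int(np.median(widths)))
    M, K = _bins_overlapping_class(catalog.genome, catalog.classes[class_label], bin_width)
    if n_total > M:
        raise ValueError(
            f"more peaks ({n_total}) than genome bins ({M}); decrease bin width"
        )
    p = float(stats.hypergeom.sf(n_in - 1, M, K, n_total))

    frh = None
    if per_region_intervals is not None:
        frh = fraction_regions_with_peak(per_region_intervals, peaks)
    return EnrichmentResult(
        peaks.label, class_label, n_total, n_in, frac, fold, p, frh
    )


def fraction_regions_with_peak(
    regions: Sequence[GenomicInterval], peaks: PeakSet
) -> float:
    """Fraction of individual (unmerged) regions overlapping >=1 peak."""
    if not regions:
        raise ValueError("no regions supplied")
    peak_arrays = _to_chrom_arrays(peaks.intervals()) if peaks.count() else {}
    n_hit = 0
    for r in regions:
        if r.chrom not in peak_arrays:
            continue
        ts, te = peak_arrays[r.chrom]
        idx = np.searchsorted(ts, r.end, side="left")
        if idx > 0 and te[idx - 1] > r.start:
            n_hit += 1
    return n_hit / len(regions)


def classify_peaks(
    peaks: PeakSet, catalog: RegionCatalog, precedence: Sequence[str]
) -> pd.Series:
    """Assign each peak the first precedence class it overlaps, else 'intergenic'."""
    unknown = [c for c in precedence if c not in catalog.classes]
    if unknown:
        raise ValueError(f"precedence names unknown classes: {unknown}")
    labels = pd.Series(INTERGENIC, index=peaks.df.index, dtype=object)
    unassigned = np.ones(peaks.count(), dtype=bool)
    for cls in precedence:
        if not unassigned.any():
            break
        hit = catalog.peaks_in_class(peaks, cls)
        take = hit & unassigned
        labels[take] = cls
        unassigned &= ~hit
    return labels


def binned_coverage(fragments: FragmentSet, genome: GenomeLayout, bin_width: int) -> np.ndarray:
    """Per-bin fragment-midpoint counts, chromosomes concatenated left to right.

    Each fragment is counted once, in the bin containing its midpoint
    (floor division, so a midpoint on a boundary goes to the right bin).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    n_bins = [-(-int(L) // bin_width) for L in genome.chrom_lengths]
    offsets = dict(zip(genome.chrom_names, np.concatenate([[0], np.cumsum(n_bins)[:-1]])))
    out = np.zeros(int(sum(n_bins)), dtype=np.int64)
    for chrom, mids in fragments.midpoints_by_chrom().items():
        if chrom not in offsets:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        idx = mids // bin_width + offsets[chrom]
        np.add.at(out, idx.astype(np.int64), 1)
    return out


def spearman_tracks(track_a: np.ndarray, track_b: np.ndarray) -> float:
    """Spearman rank correlation between two equal-length binned tracks."""
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance track: Spearman correlation undefined")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def tss_matrix(
    fragments: FragmentSet,
    genes: Sequence[GeneModel],
    window: int,
    bin_width: int,
) -> tuple[np.ndarray, list[str]]:
    """Genes x position-bins fragment-midpoint matrix around TSSs.

    Rows cover ``[tss - window/2, tss + window/2)``; minus-strand rows are
    reversed so columns run upstream -> downstream of the promoter.
    """
    if window % bin_width != 0:
        raise ValueError("window must be a multiple of bin width")
    half = window // 2
    n_bins = window // bin_width
    mids_by_chrom = fragments.midpoints_by_chrom()
    mat = np.zeros((len(genes), n_bins), dtype=np.int64)
    ids = []
    for i, g in enumerate(genes):
        ids.append(g.gene_id)
        mids = mids_by_chrom.get(g.chrom)
        if mids is None:
            continue
        lo, hi = g.tss - half, g.tss + half
        sel = mids[np.searchsorted(mids, lo) : np.searchsorted(mids, hi)]
        if len(sel) == 0:
            continue
        counts = np.bincount((sel - lo) // bin_width, minlength=n_bins)
        if g.strand == "-":
            counts = counts[::-1]
        mat[i] = counts
    return mat, ids


def cluster_samples(matrices: Mapping[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of samples by 1 - Spearman of flat profiles.

    Samples are ordered by label before clustering, so merge order (and leaf
    order) is deterministic under distance ties. Returns (scipy linkage
    matrix, sample labels in leaf-input order).
    """
    labels = sorted(matrices)
    if len(labels) < 2:
        raise ValueError("need at least two samples to cluster")
    flat = np.vstack([np.asarray(matrices[k], dtype=float).ravel() for k in labels])
    n = len(labels)
    dist = []
    for i in range(n):
        for j in range(i + 1, n):
            rho = stats.spearmanr(flat[i], flat[j]).statistic
            if np.isnan(rho):  # zero-variance profile: maximally uninformative
                rho = 0.0
            dist.append(1.0 - rho)
    Z = linkage(np.asarray(dist), method="average")
    return Z, labels
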