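"""Linking TSS accessibility to expression transitions.

Genes are partitioned by expressed/not-expressed calls in two conditions into
four transition categories (both, only_before, only_after, neither). Per-gene
accessibility is summarised as fragment-midpoint density in a fixed window
centred on the TSS, and categories are compared with the two-sided
Mann-Whitney U test (exact distribution for small tie-free groups, otherwise
the tie-corrected normal approximation), with Benjamini-Hochberg adjustment
across requested category pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import FragmentSet, GeneModel, PeakSet

__all__ = [
    "CATEGORIES",
    "ExpressionTable",
    "TSSProfile",
    "GroupComparison",
    "classify_expression",
    "tss_mean_coverage",
    "mann_whitney",
    "compare_categories",
    "fraction_pre_opened",
    "resistant_comparison",
]

CATEGORIES = ("both", "only_before", "only_after", "neither")


def _category(before: bool, after: bool) -> str:
    if before and after:
        return "both"
    if before:
        return "only_before"
    if after:
        return "only_after"
    return "neither"


@dataclass
class ExpressionTable:
    """Per-gene expressed/not calls in two conditions plus the derived category."""

    df: pd.DataFrame  # gene_id, expressed_before, expressed_after, category

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in expression table")
        if "category" not in df.columns:
            df["category"] = [
                _category(b, a)
                for b, a in zip(df["expressed_before"], df["expressed_after"])
            ]
        self.df = df

    @classmethod
    def from_calls(
        cls, calls: Mapping[str, tuple[bool, bool]]
    ) -> "ExpressionTable":
        rows = [(g, bool(b), bool(a)) for g, (b, a) in calls.items()]
        return cls(
            pd.DataFrame(rows, columns=["gene_id", "expressed_before", "expressed_after"])
        )

    def genes_in(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return self.df.loc[self.df["category"] == category, "gene_id"].tolist()

    def category_counts(self) -> dict[str, int]:
        counts = self.df["category"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CATEGORIES}


def classify_expression(
    abundance_before: Mapping[str, float],
    abundance_after: Mapping[str, float],
    threshold: float = 1.0,
) -> ExpressionTable:
    """Call a gene expressed iff abundance > threshold, in each condition."""
    missing = set(abundance_before) ^ set(abundance_after)
    if missing:
        raise ValueError(
            f"genes present in only one condition: {sorted(missing)[:10]}"
        )
    rows = [
        (g, abundance_before[g] > threshold, abundance_after[g] > threshold)
        for g in abundance_before
    ]
    return ExpressionTable(
        pd.DataFrame(rows, columns=["gene_id", "expressed_before", "expressed_after"])
    )


@dataclass
class TSSProfile:
    """Per-gene mean coverage (fragment midpoints per bp) around the TSS."""

    sample_label: str
    window: int
    coverage: pd.Series  # index gene_id, value fragments per bp

    def values_for(self, gene_ids: Sequence[str]) -> np.ndarray:
        return self.coverage.loc[list(gene_ids)].to_numpy()


def tss_mean_coverage(
    fragments: FragmentSet,
    genes: Sequence[GeneModel],
    genome_lengths: Mapping[str, int],
    window: int = 1000,
) -> TSSProfile:
    """Fragment-midpoint density in ``[tss - window/2, tss + window/2)`` per gene.

    Genes at chromosome edges use the clipped window width as denominator, so
    the value stays a rate.
    """
    if window <= 0 or window % 2 != 0:
        raise ValueError("window must be positive and even")
    half = window // 2
    mids = fragments.midpoints_by_chrom()
    values = {}
    for g in genes:
        lo = max(0, g.tss - half)
        hi = min(genome_lengths[g.chrom], g.tss + half)
        m = mids.get(g.chrom)
        n = 0 if m is None else int(np.searchsorted(m, hi) - np.searchsorted(m, lo))
        values[g.gene_id] = n / (hi - lo)
    return TSSProfile(fragments.label, window, pd.Series(values, dtype=float))


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_statistic: float  # U for group A
    p_value: float
    median_a: float
    median_b: float
    adjusted_p: float | None = None
    all_identical: bool = False

    @property
    def higher_group(self) -> str:
        if self.median_a == self.median_b:
            return "tie"
        return self.label_a if self.median_a > self.median_b else self.label_b


def mann_whitney(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two samples.

    The exact null distribution is used when both groups have <= 20
    observations and there are no ties; otherwise the tie-corrected normal
    approximation (with continuity correction). Two identical constant
    samples give p = 1 by convention, flagged via ``all_identical``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return GroupComparison(
            label_a, label_b, len(a), len(b),
            u_statistic=len(a) * len(b) / 2.0, p_value=1.0,
            median_a=float(np.median(a)), median_b=float(np.median(b)),
            all_identical=True,
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        label_a, label_b, len(a), len(b),
        u_statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
    )


DEFAULT_PAIRS = (
    ("only_after", "neither"),
    ("both", "neither"),
    ("only_before", "neither"),
    ("only_after", "only_before"),
)


def compare_categories(
    profile: TSSProfile,
    table: ExpressionTable,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
) -> list[GroupComparison]:
    """Mann-Whitney comparisons of TSS coverage between expression categories.

    Raw p-values are always kept; ``adjusted_p`` carries the
    Benjamini-Hochberg adjustment across the requested pairs. Pairs with an
    empty category are skipped with a warning.
    """
    missing = set(table.df["gene_id"]) - set(profile.coverage.index)
    if missing:
        raise ValueError(f"genes without coverage values: {sorted(missing)[:10]}")
    comparisons = []
    for cat_a, cat_b in pairs:
        genes_a = table.genes_in(cat_a)
        genes_b = table.genes_in(cat_b)
        if not genes_a or not genes_b:
            warnings.warn(
                f"skipping {cat_a} vs {cat_b}: empty category", stacklevel=2
            )
            continue
        comparisons.append(
            mann_whitney(
                profile.values_for(genes_a), profile.values_for(genes_b), cat_a, cat_b
            )
        )
    if comparisons:
        adj = multipletests([c.p_value for c in comparisons], method="fdr_bh")[1]
        comparisons = [
            GroupComparison(
                c.label_a, c.label_b, c.n_a, c.n_b, c.u_statistic, c.p_value,
                c.median_a, c.median_b, adjusted_p=float(p), all_identical=c.all_identical,
            )
            for c, p in zip(comparisons, adj)
        ]
    return comparisons


def fraction_pre_opened(
    activated_gene_ids: Sequence[str],
    donor_peaks: PeakSet,
    genes: Sequence[GeneModel],
    window: int = 1000,
) -> float:
    """Fraction of activated genes whose TSS +/- window overlaps a donor peak."""
    if not activated_gene_ids:
        raise ValueError("empty activated gene list")
    by_id = {g.gene_id: g for g in genes}
    unknown = [g for g in activated_gene_ids if g not in by_id]
    if unknown:
        raise ValueError(f"activated genes outside gene universe: {unknown[:10]}")
    peak_by_chrom = donor_peaks.by_chrom()
    lengths = donor_peaks.genome.lengths
    n_hit = 0
    for gid in activated_gene_ids:
        g = by_id[gid]
        lo = max(0, g.tss - window)
        hi = min(lengths[g.chrom], g.tss + window + 1)
        if g.chrom not in peak_by_chrom:
            continue
        ts, te = peak_by_chrom[g.chrom]
        idx = np.searchsorted(ts, hi, side="left")
        if idx > 0 and bool(np.max(te[:idx]) > lo):
            n_hit += 1
    return n_hit / len(activated_gene_ids)


def resistant_comparison(
    resistant_gene_ids: Sequence[str],
    activated_gene_ids: Sequence[str],
    donor_profile: TSSProfile,
) -> GroupComparison:
    """Donor TSS coverage of reprogramming-resistant vs successfully activated
    genes (Mann-Whitney, direction readable from the medians)."""
    if not resistant_gene_ids or not activated_gene_ids:
        raise ValueError("both gene lists must be nonempty")
    overlap = set(resistant_gene_ids) & set(activated_gene_ids)
    if overlap:
        raise ValueError(f"gene lists overlap: {sorted(overlap)[:10]}")
    return mann_whitney(
        donor_profile.values_for(resistant_gene_ids),
        donor_profile.values_for(activated_gene_ids),
        "resistant",
        "activated",
    )
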