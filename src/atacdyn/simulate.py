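"""Seeded generator of a miniature two-condition accessibility dataset.

The generator emulates the statistical structure the analysis assumes, with a
ground-truth record for every planted feature:

* before-condition peaks placed as a mixture (with probability ``p_tss``
  inside a TSS window of an "accessible" gene subset, else uniformly) so the
  realised TSS-window fold enrichment matches ``tss_enrichment_fold`` in
  expectation;
* after-condition peaks = a jittered retained subset of the before peaks plus
  planted new peaks, each verified at least ``min_new_dist`` bp from every
  before peak (rejection sampling with a loud attempt cap), a configured
  fraction of them additionally intergenic and TSS-distal;
* expression calls coupled to donor TSS openness, with the activated
  (only-after) gene set subsampled so its pre-opened fraction equals ``q``
  exactly;
* fragments as background + peak-centred + TSS-window components, the open
  TSS rate multiplied by ``coverage_effect``;
* motif consensus sequences written into peak centres with set-specific
  probabilities.

One master seed fixes every output byte; per-stage streams are spawned from
it so stages can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .genome_io import (
    FragmentSet,
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    write_bed,
    write_chrom_sizes,
    write_fragments_bed,
    write_gene_table,
    write_narrowpeak,
)
from .motifs import PWM, write_fasta
from .region_enrichment import build_tss_windows
from .genome_io import merge_intervals

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_genome",
    "generate_annotation",
    "generate_peaks",
    "generate_expression",
    "generate_fragments",
    "plant_motifs",
    "generate_dataset",
    "write_dataset",
]

_STREAMS = ("genome", "annotation", "peaks", "expression", "fragments", "motifs")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset (all randomness seeded)."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    # annotation
    n_genes: int = 500
    n_enhancers: int = 100
    gene_width_min: int = 2_000
    gene_width_max: int = 20_000
    enhancer_width_min: int = 500
    enhancer_width_max: int = 1_500
    enhancer_tss_min_dist: int = 5_000
    # peaks
    n_peaks_before: int = 2_000
    n_peaks_after: int = 2_000
    peak_width_min: int = 200
    peak_width_max: int = 800
    tss_enrichment_fold: float = 15.0
    tss_window_half: int = 500  # 1-kb planted/measured TSS class
    frac_accessible_genes: float = 0.4
    frac_new_peaks: float = 0.15
    frac_distal_new: float = 0.4
    min_new_dist: int = 5_000
    retain_jitter: int = 300
    # expression
    pre_opened_fraction: float | None = 0.56  # None: no exact-q subsampling
    n_activated_max: int | None = None  # cap on the activated (only-after) set
    pre_open_window: int = 1_000
    expr_before_open: float = 0.8
    expr_before_closed: float = 0.2
    expr_after_open: float = 0.7
    expr_after_closed: float = 0.15
    n_resistant: int = 50
    # fragments
    coverage_effect: float = 3.0
    coverage_window: int = 1_000
    fragment_depth: float = 200.0  # background fragments per Mb
    tss_fragments_mean: float = 20.0  # closed-gene TSS-window mean count
    peak_fragments_mean: float = 10.0
    # motifs
    planted_motif: str = "GATA3_SYN"
    motif_prob_before: float = 0.05
    motif_prob_after: float = 0.4
    # plumbing
    max_attempts: int = 10_000

    def __post_init__(self):
        for name in (
            "frac_accessible_genes",
            "frac_new_peaks",
            "frac_distal_new",
            "pre_opened_fraction",
            "expr_before_open",
            "expr_before_closed",
            "expr_after_open",
            "expr_after_closed",
            "motif_prob_before",
            "motif_prob_after",
        ):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tss_enrichment_fold < 1.0:
            raise ValueError("tss_enrichment_fold must be >= 1")
        if self.chrom_length < 50_000:
            raise ValueError("chrom_length must be >= 50 kb")
        if self.retain_jitter >= self.min_new_dist:
            raise ValueError("retain_jitter must be < min_new_dist")

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass
class GroundTruth:
    """Per-entity planted labels; one record per generated entity."""

    p_tss: float = float("nan")
    before_tss_planted: list[bool] = field(default_factory=list)
    after_status: list[str] = field(default_factory=list)  # retained|new|new_distal
    accessible_gene_ids: list[str] = field(default_factory=list)
    donor_open_gene_ids: list[str] = field(default_factory=list)
    activated_gene_ids: list[str] = field(default_factory=list)
    resistant_gene_ids: list[str] = field(default_factory=list)
    pre_opened_fraction: float = float("nan")
    motif_id: str | None = None
    motif_loci_a: list[tuple[str, int]] = field(default_factory=list)
    motif_loci_b: list[tuple[str, int]] = field(default_factory=list)
    motif_skipped: list[tuple[str, int]] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeLayout
    sequences: dict[str, str] | None
    genes: list[GeneModel]
    enhancers: list[GenomicInterval]
    peaks_before: PeakSet
    peaks_after: PeakSet
    expression: ExpressionTable
    fragments_before: FragmentSet
    fragments_after: FragmentSet
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def generate_genome(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    with_sequence: bool = True,
) -> tuple[GenomeLayout, dict[str, str] | None]:
    """Uniform-composition i.i.d. sequence per chromosome (deterministic)."""
    rng = rng or config.streams()["genome"]
    names = tuple(f"chr{i + 1}" for i in range(config.n_chroms))
    lengths = tuple(config.chrom_length for _ in names)
    layout = GenomeLayout(names, lengths)
    if not with_sequence:
        return layout, None
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for name, length in zip(names, lengths):
        draw = rng.integers(0, 4, size=length)
        seqs[name] = bases[draw].tobytes().decode("ascii")
    return layout, seqs


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _pack_intervals(
    rng: np.random.Generator, length: int, widths: np.ndarray
) -> np.ndarray:
    """Non-overlapping starts for the given widths on [0, length), placed by
    drawing the gaps between features from a flat Dirichlet."""
    free = length - int(widths.sum())
    if free < 0:
        raise ValueError(
            "infeasible feature density: total feature width exceeds the "
            "chromosome; use a larger genome"
        )
    n = len(widths)
    gaps = np.floor(rng.dirichlet(np.ones(n + 1)) * free).astype(np.int64)
    starts = np.cumsum(gaps[:n]) + np.concatenate([[0], np.cumsum(widths[:-1])])
    return starts


def generate_annotation(
    config: SyntheticConfig,
    genome: GenomeLayout,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneModel], list[GenomicInterval]]:
    """Non-overlapping gene bodies with random strands, plus enhancers at
    least ``enhancer_tss_min_dist`` bp from every TSS."""
    rng = rng or config.streams()["annotation"]
    n_chroms = len(genome.chrom_names)
    per_chrom = [
        config.n_genes // n_chroms + (1 if i < config.n_genes % n_chroms else 0)
        for i in range(n_chroms)
    ]
    genes: list[GeneModel] = []
    gid = 0
    for chrom, length, count in zip(genome.chrom_names, genome.chrom_lengths, per_chrom):
        if count == 0:
            continue
        widths = rng.integers(config.gene_width_min, config.gene_width_max + 1, count)
        starts = _pack_intervals(rng, int(length), widths)
        strands = rng.choice(np.array(["+", "-"]), size=count)
        for s, w, strand in zip(starts, widths, strands):
            gid += 1
            genes.append(
                GeneModel(
                    f"g{gid:05d}",
                    GenomicInterval(chrom, int(s), int(s + w)),
                    str(strand),
                )
            )
    tss_by_chrom = {
        c: np.sort(np.asarray([g.tss for g in genes if g.chrom == c]))
        for c in genome.chrom_names
    }
    enhancers: list[GenomicInterval] = []
    lengths = genome.lengths
    for i in range(config.n_enhancers):
        placed = False
        for _ in range(config.max_attempts):
            chrom = str(rng.choice(np.asarray(genome.chrom_names)))
            w = int(rng.integers(config.enhancer_width_min, config.enhancer_width_max + 1))
            s = int(rng.integers(0, lengths[chrom] - w))
            tss = tss_by_chrom[chrom]
            if len(tss):
                idx = np.searchsorted(tss, s)
                near = []
                if idx > 0:
                    near.append(s - tss[idx - 1])
                if idx < len(tss):
                    near.append(max(tss[idx] - (s + w), 0) if tss[idx] >= s + w else 0)
                if near and min(near) < config.enhancer_tss_min_dist:
                    continue
            enhancers.append(GenomicInterval(chrom, s, s + w))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place enhancer {i} after {config.max_attempts} attempts; "
                "use a larger genome or fewer features"
            )
    return genes, enhancers


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


def _solve_p_tss(
    config: SyntheticConfig, genome: GenomeLayout, genes: Sequence[GeneModel]
) -> float:
    """Mixture weight for TSS-window placement giving the target fold.

    E[in-class fraction] = p + (1 - p) * u where u is the chance a uniformly
    placed peak of mean width overlaps the merged class.
    """
    windows = build_tss_windows(genes, genome, config.tss_window_half)
    merged = merge_intervals(windows)
    class_bp = sum(iv.width for iv in merged)
    total = genome.total_bp
    mean_w = (config.peak_width_min + config.peak_width_max) / 2
    u = min(sum(iv.width + mean_w - 1 for iv in merged) / total, 1.0)
    target = config.tss_enrichment_fold * class_bp / total
    if target >= 0.98:
        raise ValueError(
            f"tss_enrichment_fold {config.tss_enrichment_fold} infeasible: the TSS "
            f"class covers {class_bp / total:.1%} of the genome "
            f"(ceiling fold {total / class_bp:.1f})"
        )
    return float(np.clip((target - u) / (1 - u), 0.0, 1.0))


def _sample_uniform_position(
    rng: np.random.Generator, genome: GenomeLayout, width: int
) -> tuple[str, int]:
    lengths = np.asarray(genome.chrom_lengths, dtype=float)
    ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
    chrom = genome.chrom_names[ci]
    start = int(rng.integers(0, genome.chrom_lengths[ci] - width))
    return chrom, start


def _min_gap_single(
    chrom: str,
    s: int,
    e: int,
    arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> float:
    """Gap from one interval to a per-chrom (starts, ends, prefix-max-end) set."""
    if chrom not in arrays:
        return np.inf
    ts, _te, pme = arrays[chrom]
    idx = int(np.searchsorted(ts, e, side="left"))
    if idx > 0 and pme[idx - 1] > s:
        return 0.0
    left = s - pme[idx - 1] if idx > 0 else np.inf
    right = ts[idx] - e if idx < len(ts) else np.inf
    return float(max(min(left, right), 0.0))


def _indexed(by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]):
    return {
        c: (s, e, np.maximum.accumulate(e)) for c, (s, e) in by_chrom.items()
    }


def generate_peaks(
    config: SyntheticConfig,
    genome: GenomeLayout,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
) -> tuple[PeakSet, PeakSet, GroundTruth]:
    """Before/after peak sets with planted TSS enrichment and new peaks."""
    rng = rng or config.streams()["peaks"]
    truth = truth or GroundTruth()
    lengths = genome.lengths

    n_acc = int(round(config.frac_accessible_genes * len(genes)))
    acc_idx = np.sort(rng.choice(len(genes), size=n_acc, replace=False))
    accessible = [genes[i] for i in acc_idx]
    truth.accessible_gene_ids = [g.gene_id for g in accessible]

    p_tss = _solve_p_tss(config, genome, genes)
    truth.p_tss = p_tss

    n_b = config.n_peaks_before
    half = config.tss_window_half
    widths = rng.integers(config.peak_width_min, config.peak_width_max + 1, n_b)
    at_tss = (rng.random(n_b) < p_tss) & (n_acc > 0)
    gene_pick = rng.integers(0, max(n_acc, 1), n_b)
    offsets = rng.integers(-half, half + 1, n_b)
    # uniform fallback positions, chromosome weighted by length
    lens = np.asarray(genome.chrom_lengths, dtype=np.int64)
    ci = rng.choice(len(lens), size=n_b, p=lens / lens.sum())
    upos = rng.integers(0, lens[ci] - widths)
    chroms_arr = np.asarray(genome.chrom_names)[ci].astype(object)
    starts = upos.copy()
    if n_acc:
        acc_tss = np.asarray([g.tss for g in accessible])
        acc_chrom = np.asarray([g.chrom for g in accessible], dtype=object)
        acc_len = np.asarray([lengths[g.chrom] for g in accessible])
        sel = np.flatnonzero(at_tss)
        mids = acc_tss[gene_pick[sel]] + offsets[sel]
        s = np.clip(mids - widths[sel] // 2, 0, acc_len[gene_pick[sel]] - widths[sel])
        starts[sel] = s
        chroms_arr[sel] = acc_chrom[gene_pick[sel]]
    rows = [
        (c, int(s), int(s + w), f"b{i:05d}", 0.0, float(w // 2))
        for i, (c, s, w) in enumerate(zip(chroms_arr, starts, widths))
    ]
    planted_flags = [bool(x) for x in at_tss]
    before = PeakSet(
        "before",
        genome,
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "summit"]),
    )
    truth.before_tss_planted = planted_flags

    before_idx = _indexed(before.by_chrom())
    n_new = int(round(config.frac_new_peaks * config.n_peaks_after))
    n_retained = config.n_peaks_after - n_new
    if n_retained > config.n_peaks_before:
        raise ValueError("retained subset larger than the before peak set")
    n_distal = int(round(config.frac_distal_new * n_new))

    keep = np.sort(rng.choice(config.n_peaks_before, size=n_retained, replace=False))
    sub = before.df.iloc[keep]
    r_chrom = sub["chrom"].to_numpy(dtype=object)
    r_w = (sub["end"] - sub["start"]).to_numpy()
    shifts = rng.integers(-config.retain_jitter, config.retain_jitter + 1, n_retained)
    r_len = np.asarray([lengths[c] for c in r_chrom], dtype=np.int64)
    r_start = np.clip(sub["start"].to_numpy() + shifts, 0, r_len - r_w)
    rows_after = [
        (c, int(s), int(s + w), f"a{j:05d}", 0.0, float(w // 2))
        for j, (c, s, w) in enumerate(zip(r_chrom, r_start, r_w))
    ]
    status = ["retained"] * n_retained

    gene_idx = _indexed(
        PeakSet(
            "bodies",
            genome,
            pd.DataFrame(
                {
                    "chrom": [g.chrom for g in genes],
                    "start": [g.body.start for g in genes],
                    "end": [g.body.end for g in genes],
                }
            ),
        ).by_chrom()
    )
    tss_sorted = {
        c: np.sort(np.asarray([g.tss for g in genes if g.chrom == c]))
        for c in genome.chrom_names
    }

    def _tss_dist(chrom: str, s: int, e: int) -> float:
        pts = tss_sorted.get(chrom)
        if pts is None or len(pts) == 0:
            return np.inf
        idx = int(np.searchsorted(pts, s, side="left"))
        left = s - pts[idx - 1] if idx > 0 else np.inf
        if idx == len(pts):
            return float(left)
        if pts[idx] < e:  # a TSS inside the interval
            return 0.0
        return float(min(left, pts[idx] - e))

    for j in range(n_new):
        distal = j < n_distal
        placed = False
        for _ in range(config.max_attempts):
            w = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
            chrom, start = _sample_uniform_position(rng, genome, w)
            end = start + w
            if _min_gap_single(chrom, start, end, before_idx) < config.min_new_dist:
                continue
            if distal:
                if _min_gap_single(chrom, start, end, gene_idx) == 0.0:
                    continue
                if _tss_dist(chrom, start, end) < config.min_new_dist:
                    continue
            rows_after.append(
                (chrom, start, end, f"a{n_retained + j:05d}", 0.0, float(w // 2))
            )
            status.append("new_distal" if distal else "new")
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place new peak {j} after {config.max_attempts} attempts; "
                "relax the density or enlarge the genome"
            )

    after = PeakSet(
        "after",
        genome,
        pd.DataFrame(
            rows_after, columns=["chrom", "start", "end", "name", "score", "summit"]
        ),
    )
    truth.after_status = status
    return before, after, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def donor_open_mask(
    genes: Sequence[GeneModel], peaks: PeakSet, window: int
) -> np.ndarray:
    """True where the gene's TSS +/- window overlaps >=1 peak."""
    arrays = _indexed(peaks.by_chrom())
    lengths = peaks.genome.lengths
    out = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        if g.chrom not in arrays:
            continue
        lo = max(0, g.tss - window)
        hi = min(lengths[g.chrom], g.tss + window + 1)
        ts, _te, pme = arrays[g.chrom]
        idx = int(np.searchsorted(ts, hi, side="left"))
        out[i] = idx > 0 and bool(pme[idx - 1] > lo)
    return out


def generate_expression(
    config: SyntheticConfig,
    genes: Sequence[GeneModel],
    peaks_before: PeakSet,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionTable, GroundTruth]:
    """Expression calls coupled to donor openness; activated set subsampled so
    that its pre-opened fraction equals ``pre_opened_fraction`` exactly."""
    rng = rng or config.streams()["expression"]
    truth = truth or GroundTruth()
    is_open = donor_open_mask(genes, peaks_before, config.pre_open_window)
    truth.donor_open_gene_ids = [g.gene_id for g, o in zip(genes, is_open) if o]

    p_before = np.where(is_open, config.expr_before_open, config.expr_before_closed)
    p_after = np.where(is_open, config.expr_after_open, config.expr_after_closed)
    expressed_before = rng.random(len(genes)) < p_before
    expressed_after = rng.random(len(genes)) < p_after

    only_after = ~expressed_before & expressed_after
    avail_open = np.flatnonzero(only_after & is_open)
    avail_closed = np.flatnonzero(only_after & ~is_open)

    if config.pre_opened_fraction is None:
        activated = np.flatnonzero(only_after)
        truth.activated_gene_ids = [genes[int(i)].gene_id for i in activated]
        truth.pre_opened_fraction = (
            float(is_open[activated].mean()) if len(activated) else float("nan")
        )
        resist_pool = np.flatnonzero(~is_open & ~expressed_before & ~expressed_after)
        n_res = min(config.n_resistant, len(resist_pool))
        resistant = (
            np.sort(rng.choice(resist_pool, size=n_res, replace=False))
            if n_res
            else np.empty(0, int)
        )
        truth.resistant_gene_ids = [genes[int(i)].gene_id for i in resistant]
        table = ExpressionTable(
            pd.DataFrame(
                {
                    "gene_id": [g.gene_id for g in genes],
                    "expressed_before": expressed_before,
                    "expressed_after": expressed_after,
                }
            )
        )
        return table, truth

    q = Fraction(config.pre_opened_fraction).limit_denominator(1000)
    num, den = q.numerator, q.denominator
    if num == 0:
        k = len(avail_closed) // den
    elif num == den:
        k = len(avail_open) // den
    else:
        k = min(len(avail_open) // num, len(avail_closed) // (den - num))
    if config.n_activated_max is not None:
        k = min(k, config.n_activated_max // den)
    if k == 0:
        feasible_lo = 0 if len(avail_closed) else 1
        feasible_hi = 1 if len(avail_open) else 0
        raise ValueError(
            f"pre_opened_fraction {config.pre_opened_fraction} infeasible with "
            f"{len(avail_open)} open and {len(avail_closed)} closed candidate "
            f"genes; feasible range needs enough of both (attainable extremes "
            f"{feasible_lo}..{feasible_hi}); increase n_genes or adjust couplings"
        )
    pick_open = rng.choice(avail_open, size=k * num, replace=False) if num else np.empty(0, int)
    pick_closed = (
        rng.choice(avail_closed, size=k * (den - num), replace=False)
        if den - num
        else np.empty(0, int)
    )
    activated = np.sort(np.concatenate([pick_open, pick_closed]).astype(int))
    demoted = np.setdiff1d(np.concatenate([avail_open, avail_closed]).astype(int), activated)
    expressed_after[demoted] = False

    truth.activated_gene_ids = [genes[i].gene_id for i in activated]
    truth.pre_opened_fraction = float(Fraction(num, den)) if den else float("nan")

    resist_pool = np.flatnonzero(~is_open & ~expressed_before & ~expressed_after)
    n_res = min(config.n_resistant, len(resist_pool))
    resistant = np.sort(rng.choice(resist_pool, size=n_res, replace=False)) if n_res else np.empty(0, int)
    truth.resistant_gene_ids = [genes[int(i)].gene_id for i in resistant]

    table = ExpressionTable(
        pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "expressed_before": expressed_before,
                "expressed_after": expressed_after,
            }
        )
    )
    return table, truth


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------


def _fragment_widths(rng: np.random.Generator, n: int) -> np.ndarray:
    """Two-component fragment-length mixture (sub- vs mono-nucleosomal)."""
    sub = rng.random(n) < 0.5
    w = np.where(
        sub,
        rng.normal(80, 10, n),
        rng.normal(200, 20, n),
    )
    return np.maximum(np.round(w).astype(np.int64), 20)


def generate_fragments(
    config: SyntheticConfig,
    genome: GenomeLayout,
    genes: Sequence[GeneModel],
    peaks: PeakSet,
    open_mask: np.ndarray,
    rng: np.random.Generator,
    label: str,
) -> FragmentSet:
    """Fragments = uniform background + peak-centred + TSS-window components.

    The TSS-window fragment rate of open genes is ``coverage_effect`` times
    the closed rate; peaks overlapping any TSS coverage window contribute no
    separate fragments, so that ratio is the realised coverage contrast.
    """
    lengths = genome.lengths
    half = config.coverage_window // 2
    chrom_parts: list[np.ndarray] = []
    mid_parts: list[np.ndarray] = []

    # TSS windows
    g_chrom = np.asarray([g.chrom for g in genes], dtype=object)
    g_len = np.asarray([lengths[g.chrom] for g in genes], dtype=np.int64)
    tss = np.asarray([g.tss for g in genes], dtype=np.int64)
    lo = np.maximum(0, tss - half)
    hi = np.minimum(g_len, tss + half)
    lam = config.tss_fragments_mean * (hi - lo) / config.coverage_window
    lam = np.where(np.asarray(open_mask, bool), lam * config.coverage_effect, lam)
    ns = rng.poisson(lam)
    rep = np.repeat(np.arange(len(genes)), ns)
    pos = lo[rep] + rng.integers(0, (hi - lo)[rep])
    chrom_parts.append(g_chrom[rep])
    mid_parts.append(pos)

    # peaks away from TSS windows
    window_ivs = [
        GenomicInterval(c, int(a), int(b)) for c, a, b in zip(g_chrom, lo, hi)
    ]
    windows_idx = _indexed(
        PeakSet(
            "w",
            genome,
            pd.DataFrame(
                {
                    "chrom": [iv.chrom for iv in window_ivs],
                    "start": [iv.start for iv in window_ivs],
                    "end": [iv.end for iv in window_ivs],
                }
            ),
        ).by_chrom()
    )
    p_chrom = peaks.df["chrom"].to_numpy(dtype=object)
    p_start = peaks.df["start"].to_numpy()
    p_end = peaks.df["end"].to_numpy()
    away = np.ones(len(p_chrom), dtype=bool)
    for chrom, (ts, _te, pme) in windows_idx.items():
        sel = p_chrom == chrom
        if not sel.any():
            continue
        idx = np.searchsorted(ts, p_end[sel], side="left")
        overlap = (idx > 0) & (pme[np.maximum(idx - 1, 0)] > p_start[sel])
        away[np.flatnonzero(sel)[overlap]] = False
    ns_p = np.where(away, rng.poisson(config.peak_fragments_mean, len(p_chrom)), 0)
    rep_p = np.repeat(np.arange(len(p_chrom)), ns_p)
    if len(rep_p):
        centers = (p_start[rep_p] + p_end[rep_p]) / 2
        sds = (p_end[rep_p] - p_start[rep_p]) / 4
        p_len = np.asarray([lengths[c] for c in p_chrom], dtype=np.int64)
        pos_p = np.clip(
            np.round(rng.normal(centers, sds)), 0, p_len[rep_p] - 1
        ).astype(np.int64)
        chrom_parts.append(p_chrom[rep_p])
        mid_parts.append(pos_p)

    # uniform background
    n_bg = int(rng.poisson(config.fragment_depth * genome.total_bp / 1e6))
    if n_bg:
        lens = np.asarray(genome.chrom_lengths, dtype=np.int64)
        ci = rng.choice(len(lens), size=n_bg, p=lens / lens.sum())
        pos_bg = rng.integers(0, lens[ci])
        chrom_parts.append(np.asarray(genome.chrom_names, dtype=object)[ci])
        mid_parts.append(pos_bg)

    chroms = np.concatenate(chrom_parts) if chrom_parts else np.empty(0, object)
    mids_arr = (
        np.concatenate(mid_parts).astype(np.int64) if mid_parts else np.empty(0, np.int64)
    )
    widths = _fragment_widths(rng, len(mids_arr))
    starts = mids_arr - widths // 2
    ends = starts + widths
    # shift fragments at chromosome edges inside bounds, preserving width
    chrom_len = np.asarray([lengths[c] for c in chroms], dtype=np.int64)
    shift_left = np.maximum(-starts, 0)
    starts = starts + shift_left
    ends = ends + shift_left
    shift_right = np.maximum(ends - chrom_len, 0)
    starts = starts - shift_right
    ends = ends - shift_right
    starts = np.maximum(starts, 0)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return FragmentSet(label, df)


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------


def plant_motifs(
    config: SyntheticConfig,
    sequences: dict[str, str],
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    pwm: PWM,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Write the motif consensus at peak centres with set-specific probability.

    Set A uses ``motif_prob_after``, set B ``motif_prob_before``. A planting
    whose footprint overlaps an already-planted locus is skipped and recorded.
    Returns modified sequences (the input mapping is not mutated).
    """
    rng = rng or config.streams()["motifs"]
    truth = truth or GroundTruth()
    truth.motif_id = pwm.motif_id
    consensus = pwm.consensus
    L = len(consensus)
    buf = {c: bytearray(s, "ascii") for c, s in sequences.items()}
    planted: dict[str, list[tuple[int, int]]] = {c: [] for c in sequences}

    def _plant(peaks: PeakSet, prob: float, record: list[tuple[str, int]]):
        for row in peaks.df.itertuples():
            if rng.random() >= prob:
                continue
            width = int(row.end - row.start)
            if L >= width:
                raise ValueError(
                    f"motif ({L} bp) not shorter than peak of width {width}"
                )
            center = int(row.start) + (
                int(row.summit) if not np.isnan(row.summit) else width // 2
            )
            start = center - L // 2
            start = int(np.clip(start, 0, len(buf[row.chrom]) - L))
            if any(s < start + L and start < e for s, e in planted[row.chrom]):
                truth.motif_skipped.append((str(row.chrom), start))
                continue
            buf[row.chrom][start : start + L] = consensus.encode("ascii")
            planted[row.chrom].append((start, start + L))
            record.append((str(row.chrom), start))

    _plant(peaks_a, config.motif_prob_after, truth.motif_loci_a)
    _plant(peaks_b, config.motif_prob_before, truth.motif_loci_b)
    return {c: b.decode("ascii") for c, b in buf.items()}, truth


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def generate_dataset(
    config: SyntheticConfig,
    with_sequence: bool = False,
    pwm: PWM | None = None,
) -> SyntheticDataset:
    """Generate the full dataset; sequence and motif planting are opt-in."""
    streams = config.streams()
    genome, sequences = generate_genome(config, streams["genome"], with_sequence)
    genes, enhancers = generate_annotation(config, genome, streams["annotation"])
    truth = GroundTruth()
    before, after, truth = generate_peaks(config, genome, genes, streams["peaks"], truth)
    expression, truth = generate_expression(
        config, genes, before, streams["expression"], truth
    )
    frag_rng = streams["fragments"]
    open_before = donor_open_mask(genes, before, config.pre_open_window)
    open_after = donor_open_mask(genes, after, config.pre_open_window)
    fragments_before = generate_fragments(
        config, genome, genes, before, open_before, frag_rng, "fragments_before"
    )
    fragments_after = generate_fragments(
        config, genome, genes, after, open_after, frag_rng, "fragments_after"
    )
    if sequences is not None and pwm is not None:
        new_mask = np.asarray([s != "retained" for s in truth.after_status])
        new_after = after.subset(new_mask)
        sequences, truth = plant_motifs(
            config, sequences, new_after, before, pwm, streams["motifs"], truth
        )
    return SyntheticDataset(
        config=config,
        genome=genome,
        sequences=sequences,
        genes=genes,
        enhancers=enhancers,
        peaks_before=before,
        peaks_after=after,
        expression=expression,
        fragments_before=fragments_before,
        fragments_after=fragments_after,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Emit the dataset in the standard formats the readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(dataset.genome, out / "genome.chrom.sizes")
    if dataset.sequences is not None:
        write_fasta(dataset.sequences, out / "genome.fa")
    write_gene_table(dataset.genes, out / "genes.tsv")
    with open(out / "enhancers.bed", "w") as fh:
        for i, iv in enumerate(dataset.enhancers):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tenh{i:04d}\t0\n")
    write_narrowpeak(dataset.peaks_before, out / "peaks_before.narrowPeak")
    write_narrowpeak(dataset.peaks_after, out / "peaks_after.narrowPeak")
    write_bed(dataset.peaks_before, out / "peaks_before.bed")
    write_bed(dataset.peaks_after, out / "peaks_after.bed")
    write_fragments_bed(dataset.fragments_before, out / "fragments_before.bed")
    write_fragments_bed(dataset.fragments_after, out / "fragments_after.bed")
    dataset.expression.df[["gene_id", "expressed_before", "expressed_after"]].to_csv(
        out / "expression.tsv", sep="\t", index=False
    )
    with open(out / "truth.json", "w") as fh:
        fh.write(dataset.truth.to_json())
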