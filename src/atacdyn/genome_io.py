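"""Genomic coordinate types, interval arithmetic and flat-file readers/writers.

Everything downstream works in 0-based, half-open coordinates (the BED
convention): an interval ``[start, end)`` covers ``end - start`` bases.
Abutting intervals do not overlap and are at distance 0; distances between
features on different chromosomes are *absent* (``None``), never a sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "GenomeLayout",
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneModel",
    "FragmentSet",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "read_narrowpeak",
    "write_bed",
    "write_narrowpeak",
    "read_gene_table",
    "write_gene_table",
    "read_fragments_bed",
    "write_bedgraph",
    "overlaps",
    "interval_distance",
    "nearest_distance",
    "merge_intervals",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending path and line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; the coordinate universe."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chrom_names) == 0:
            raise ValueError("genome layout must contain at least one chromosome")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, (int(x) for x in self.chrom_lengths)))

    def length_of(self, chrom: str) -> int:
        try:
            return int(self.chrom_lengths[self.chrom_names.index(chrom)])
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """An accessibility peak: an interval plus optional summit and score."""

    interval: GenomicInterval
    summit: int | None = None  # offset within the interval
    score: float = 0.0

    def __post_init__(self):
        if self.summit is not None and not (0 <= self.summit < self.interval.width):
            raise ValueError(
                f"summit offset {self.summit} outside peak of width {self.interval.width}"
            )
        if self.score < 0:
            raise ValueError("peak score must be nonnegative")


@dataclass(frozen=True)
class GeneModel:
    """Gene body plus strand; the TSS is derived, never stored."""

    gene_id: str
    body: GenomicInterval
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        # last covered base for minus-strand genes under half-open coordinates
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def chrom(self) -> str:
        return self.body.chrom


def _empty_peak_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=str),
            "score": pd.Series(dtype=float),
            "summit": pd.Series(dtype=float),  # NaN = absent
        }
    )


@dataclass
class PeakSet:
    """A labelled collection of peaks tied to a genome layout.

    Stored columnar (a DataFrame with chrom/start/end/name/score/summit) so
    whole-set operations vectorise; `peaks()` materialises `Peak` objects.
    """

    label: str
    genome: GenomeLayout
    df: pd.DataFrame = field(default_factory=_empty_peak_frame)

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        for col, default in (("name", ""), ("score", 0.0), ("summit", np.nan)):
            if col not in df.columns:
                df[col] = default
        df = df[["chrom", "start", "end", "name", "score", "summit"]]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        lengths = self.genome.lengths
        if len(df):
            unknown = ~df["chrom"].isin(lengths)
            if unknown.any():
                bad = df.loc[unknown, "chrom"].iloc[0]
                raise ValueError(f"peak on unknown chromosome {bad!r}")
            chrom_len = df["chrom"].map(lengths).to_numpy()
            starts = df["start"].to_numpy()
            ends = df["end"].to_numpy()
            bad = (starts < 0) | (starts >= ends) | (ends > chrom_len)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"peak {df['chrom'].iat[i]}:{starts[i]}-{ends[i]} out of bounds "
                    f"(chromosome length {chrom_len[i]})"
                )
            summits = df["summit"].to_numpy(dtype=float)
            with_summit = ~np.isnan(summits)
            bad = with_summit & (
                (summits < 0) | (summits >= (ends - starts).astype(float))
            )
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"peak {df['chrom'].iat[i]}:{starts[i]}-{ends[i]}: summit offset "
                    f"{int(summits[i])} outside peak"
                )
        self.df = df

    @classmethod
    def from_peaks(cls, label: str, genome: GenomeLayout, peaks: Iterable[Peak]) -> "PeakSet":
        rows = [
            (
                p.interval.chrom,
                p.interval.start,
                p.interval.end,
                "",
                p.score,
                np.nan if p.summit is None else float(p.summit),
            )
            for p in peaks
        ]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "summit"])
        if not rows:
            df = _empty_peak_frame()
        return cls(label, genome, df)

    def count(self) -> int:
        return len(self.df)

    def peaks(self) -> Iterator[Peak]:
        for row in self.df.itertuples():
            yield Peak(
                GenomicInterval(row.chrom, int(row.start), int(row.end)),
                None if np.isnan(row.summit) else int(row.summit),
                float(row.score),
            )

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in self.df.itertuples()
        ]

    def midpoints(self) -> pd.DataFrame:
        mids = (self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2
        return pd.DataFrame({"chrom": self.df["chrom"], "mid": mids})

    def subset(self, mask) -> "PeakSet":
        return PeakSet(self.label, self.genome, self.df.loc[mask].reset_index(drop=True))

    def relabel(self, label: str) -> "PeakSet":
        return PeakSet(label, self.genome, self.df)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            order = np.argsort(sub["start"].to_numpy(), kind="stable")
            out[str(chrom)] = (
                sub["start"].to_numpy()[order],
                sub["end"].to_numpy()[order],
            )
        return out


@dataclass
class FragmentSet:
    """Sequenced fragments (intervals) from one sample."""

    label: str
    df: pd.DataFrame  # chrom, start, end

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and not (df["end"] > df["start"]).all():
            raise ValueError("fragments must have positive width")
        self.df = df

    def count(self) -> int:
        return len(self.df)

    def midpoints_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted fragment midpoints per chromosome."""
        out = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            out[str(chrom)] = np.sort(mids)
        return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _iter_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column ``name<TAB>length`` chrom-sizes file."""
    names: list[str] = []
    lengths: list[int] = []
    for lineno, line in _iter_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer length {fields[1]!r}") from None
        if name in names:
            raise ParseError(path, lineno, f"duplicate chromosome {name!r}")
        if length <= 0:
            raise ParseError(path, lineno, f"non-positive length {length} for {name!r}")
        names.append(name)
        lengths.append(length)
    if not names:
        raise ParseError(path, 0, "empty chrom-sizes file")
    return GenomeLayout(tuple(names), tuple(lengths))


def write_chrom_sizes(genome: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


def _parse_bed_like(path, genome: GenomeLayout, n_required: int):
    lengths = genome.lengths
    for lineno, line in _iter_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < n_required:
            raise ParseError(
                path, lineno, f"expected >= {n_required} columns, got {len(fields)}"
            )
        chrom = fields[0]
        if chrom not in lengths:
            raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates") from None
        if start >= end:
            raise ParseError(path, lineno, f"start {start} >= end {end}")
        if start < 0 or end > lengths[chrom]:
            raise ParseError(
                path,
                lineno,
                f"record {chrom}:{start}-{end} outside chromosome (length {lengths[chrom]})",
            )
        yield lineno, fields, chrom, start, end


def read_bed(path, genome: GenomeLayout, label: str | None = None) -> PeakSet:
    """Read BED3+ into a PeakSet (column 4 = name, column 5 = score)."""
    rows = []
    for lineno, fields, chrom, start, end in _parse_bed_like(path, genome, 3):
        name = fields[3] if len(fields) > 3 else ""
        try:
            score = float(fields[4]) if len(fields) > 4 else 0.0
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
        rows.append((chrom, start, end, name, score, np.nan))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "summit"])
    if not rows:
        df = _empty_peak_frame()
    return PeakSet(label or Path(path).stem, genome, df)


def read_narrowpeak(path, genome: GenomeLayout, label: str | None = None) -> PeakSet:
    """Read ENCODE narrowPeak (10 columns; column 10 = summit offset, -1 = absent)."""
    rows = []
    for lineno, fields, chrom, start, end in _parse_bed_like(path, genome, 10):
        name = fields[3]
        try:
            score = float(fields[4])
            summit = int(fields[9])
        except ValueError:
            raise ParseError(path, lineno, "non-numeric score/summit") from None
        if summit >= end - start:
            raise ParseError(
                path, lineno, f"summit offset {summit} >= width {end - start}"
            )
        rows.append((chrom, start, end, name, score, np.nan if summit < 0 else float(summit)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "summit"])
    if not rows:
        df = _empty_peak_frame()
    return PeakSet(label or Path(path).stem, genome, df)


def write_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.df.itertuples()):
            name = row.name or f"{peaks.label}_{i}"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{_fmt_score(row.score)}\n")


def write_narrowpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.df.itertuples()):
            name = row.name or f"{peaks.label}_{i}"
            summit = -1 if np.isnan(row.summit) else int(row.summit)
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{_fmt_score(row.score)}"
                f"\t.\t0\t-1\t-1\t{summit}\n"
            )


def _fmt_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(float(score))


def read_gene_table(path, genome: GenomeLayout) -> list[GeneModel]:
    """Read a TSV gene table: gene_id, chrom, start, end, strand (header row)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParseError(path, 0, f"duplicate gene ids: {dups[:5]}")
    lengths = genome.lengths
    genes = []
    for row in df.itertuples():
        if row.strand not in ("+", "-"):
            raise ParseError(path, 0, f"gene {row.gene_id}: bad strand {row.strand!r}")
        if row.chrom not in lengths:
            raise ParseError(path, 0, f"gene {row.gene_id}: unknown chromosome {row.chrom!r}")
        if not (0 <= row.start < row.end <= lengths[row.chrom]):
            raise ParseError(path, 0, f"gene {row.gene_id}: body out of bounds")
        genes.append(
            GeneModel(row.gene_id, GenomicInterval(row.chrom, int(row.start), int(row.end)), row.strand)
        )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.body.start}\t{g.body.end}\t{g.strand}\n")


def read_fragments_bed(path, genome: GenomeLayout, label: str | None = None) -> FragmentSet:
    rows = []
    for _lineno, _fields, chrom, start, end in _parse_bed_like(path, genome, 3):
        rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return FragmentSet(label or Path(path).stem, df)


def write_fragments_bed(fragments: FragmentSet, path) -> None:
    fragments.df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(genome: GenomeLayout, bin_width: int, values: np.ndarray, path) -> None:
    """Write a concatenated per-bin track (as produced by binned_coverage)."""
    with open(path, "w") as fh:
        offset = 0
        for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
            n_bins = -(-int(length) // bin_width)
            for i in range(n_bins):
                v = values[offset + i]
                if v != 0:
                    start = i * bin_width
                    end = min((i + 1) * bin_width, int(length))
                    fh.write(f"{chrom}\t{start}\t{end}\t{_fmt_score(float(v))}\n")
            offset += n_bins


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Edge-to-edge gap in bp; 0 if overlapping or abutting; None across chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    return max(b.start - a.end, a.start - b.end, 0)


def point_interval_distance(point: int, interval_start: int, interval_end: int) -> int:
    """Distance from a bp point to a half-open interval (0 if inside)."""
    if point < interval_start:
        return interval_start - point
    if point < interval_end:
        return 0
    return point - interval_end


def nearest_distance(
    query: GenomicInterval, anchors: Mapping[str, int] | Sequence[tuple[str, int]]
) -> tuple[int, str] | None:
    """Nearest anchor point to an interval.

    ``anchors`` maps anchor id -> bp coordinate; only anchors implicitly on the
    query's chromosome should be passed (use :func:`nearest_anchor_distances`
    for the genome-wide, chromosome-aware batch form). Returns
    ``(distance, anchor_id)`` or None if there are no anchors. Ties break
    toward the smaller coordinate, then the lexicographically smaller id.
    """
    items = anchors.items() if isinstance(anchors, Mapping) else anchors
    best: tuple[int, int, str] | None = None
    for anchor_id, pos in items:
        d = point_interval_distance(pos, query.start, query.end)
        key = (d, pos, anchor_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[0], best[2]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal disjoint cover of the same bases (adjacent intervals coalesce)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    chrom_order: list[str] = []
    for iv in intervals:
        if iv.chrom not in by_chrom:
            by_chrom[iv.chrom] = []
            chrom_order.append(iv.chrom)
        by_chrom[iv.chrom].append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(chrom_order):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


# ---------------------------------------------------------------------------
# Vectorised batch queries on sorted interval/point collections
# ---------------------------------------------------------------------------


def min_gap_to_intervals(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    t_starts: np.ndarray,
    t_ends: np.ndarray,
) -> np.ndarray:
    """Minimum edge gap from each query interval to a set of target intervals.

    Targets must be on the same chromosome, sorted by start. Overlap or
    abutment gives 0. Returns +inf where the target set is empty.
    """
    n = len(q_starts)
    if len(t_starts) == 0:
        return np.full(n, np.inf)
    order = np.argsort(t_starts, kind="stable")
    ts, te = np.asarray(t_starts)[order], np.asarray(t_ends)[order]
    prefix_max_end = np.maximum.accumulate(te)
    idx = np.searchsorted(ts, q_ends, side="left")  # targets [0, idx) start before q end
    gap = np.full(n, np.inf)
    has_left = idx > 0
    left_end = np.where(has_left, prefix_max_end[np.maximum(idx - 1, 0)], -np.inf)
    overlap = has_left & (left_end > q_starts)
    left_gap = np.where(has_left, q_starts - left_end, np.inf)
    has_right = idx < len(ts)
    right_gap = np.where(has_right, ts[np.minimum(idx, len(ts) - 1)] - q_ends, np.inf)
    gap = np.minimum(np.maximum(left_gap, 0), np.maximum(right_gap, 0))
    gap[overlap] = 0
    return gap


def min_dist_points_to_intervals(
    points: np.ndarray, t_starts: np.ndarray, t_ends: np.ndarray
) -> np.ndarray:
    """Distance from each point to the nearest target interval (same chromosome)."""
    return min_gap_to_intervals(points, points + 1, t_starts, t_ends)


def min_dist_intervals_to_points(
    q_starts: np.ndarray, q_ends: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Distance from each query interval to the nearest anchor point.

    Points inside the interval give 0; outside, the left gap is
    ``start - point`` and the right gap ``point - end`` (abutment = 0).
    """
    n = len(q_starts)
    if len(points) == 0:
        return np.full(n, np.inf)
    pts = np.sort(np.asarray(points))
    idx = np.searchsorted(pts, q_starts, side="left")
    left = np.where(idx > 0, q_starts - pts[np.maximum(idx - 1, 0)], np.inf)
    # first point >= start: 0 if it falls inside [start, end), else point - end
    has_right = idx < len(pts)
    first_ge = pts[np.minimum(idx, len(pts) - 1)]
    inside = has_right & (first_ge < q_ends)
    right = np.where(has_right, np.maximum(first_ge - q_ends, 0), np.inf)
    res = np.minimum(left, right)
    res[inside] = 0
    return res
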