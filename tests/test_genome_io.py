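"""Coordinate types, file IO and interval arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atacdyn.genome_io import (
    GenomeLayout,
    GenomicInterval,
    ParseError,
    PeakSet,
    interval_distance,
    merge_intervals,
    nearest_distance,
    overlaps,
    read_bed,
    read_chrom_sizes,
    read_gene_table,
    read_narrowpeak,
    write_bed,
    write_narrowpeak,
)

from conftest import make_peaks


# ---------------------------------------------------------------------------
# chrom sizes
# ---------------------------------------------------------------------------


def test_read_chrom_sizes_totals(tmp_path):
    p = tmp_path / "g.chrom.sizes"
    p.write_text("chr1\t1000\nchr2\t500\n")
    layout = read_chrom_sizes(p)
    assert layout.total_bp == 1500
    assert layout.chrom_names == ("chr1", "chr2")


@pytest.mark.parametrize(
    "content,match",
    [
        ("", "empty"),
        ("chr1\t0\n", "non-positive"),
        ("chr1\t100\nchr1\t200\n", "duplicate"),
        ("chr1\n", "columns"),
        ("chr1\tabc\n", "non-integer"),
    ],
)
def test_read_chrom_sizes_errors(tmp_path, content, match):
    p = tmp_path / "bad.sizes"
    p.write_text(content)
    with pytest.raises(ParseError, match=match):
        read_chrom_sizes(p)


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------


def test_read_bed_fields(tmp_path, genome):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\nchr1\t300\t450\tp1\t57\n")
    ps = read_bed(p, genome)
    assert ps.count() == 2
    first = next(ps.peaks())
    assert first.interval.width == 100
    assert ps.df.loc[1, "score"] == 57.0


@pytest.mark.parametrize(
    "record,match",
    [
        ("chrZ\t10\t20", "unknown chromosome"),
        ("chr1\t200\t100", "start"),
        ("chr1\t10\t999999", "outside"),
    ],
)
def test_read_bed_errors(tmp_path, genome, record, match):
    p = tmp_path / "bad.bed"
    p.write_text(record + "\n")
    with pytest.raises(ParseError, match=match):
        read_bed(p, genome)


def test_read_narrowpeak_summits(tmp_path, genome):
    p = tmp_path / "a.narrowPeak"
    p.write_text(
        "chr1\t100\t200\tp1\t5\t.\t0\t-1\t-1\t50\n"
        "chr1\t300\t400\tp2\t5\t.\t0\t-1\t-1\t-1\n"
    )
    ps = read_narrowpeak(p, genome)
    peaks = list(ps.peaks())
    assert peaks[0].summit == 50
    assert peaks[1].summit is None


def test_read_narrowpeak_summit_beyond_width(tmp_path, genome):
    p = tmp_path / "bad.narrowPeak"
    p.write_text("chr1\t100\t200\tp1\t5\t.\t0\t-1\t-1\t100\n")
    with pytest.raises(ParseError, match="summit"):
        read_narrowpeak(p, genome)


def test_peakset_roundtrip_bit_exact(tmp_path, genome, rng):
    starts = rng.integers(0, 90_000, 50)
    widths = rng.integers(50, 500, 50)
    import pandas as pd

    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + widths,
            "name": [f"p{i}" for i in range(50)],
            "score": rng.integers(0, 1000, 50).astype(float),
            "summit": (widths // 3).astype(float),
        }
    )
    ps = PeakSet("orig", genome, df)
    path = tmp_path / "rt.narrowPeak"
    write_narrowpeak(ps, path)
    back = read_narrowpeak(path, genome, "orig")
    pd.testing.assert_frame_equal(ps.df, back.df)

    path2 = tmp_path / "rt.bed"
    write_bed(ps, path2)
    back2 = read_bed(path2, genome)
    assert (back2.df[["chrom", "start", "end", "score"]].values == ps.df[
        ["chrom", "start", "end", "score"]
    ].values).all()


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------


def test_gene_table_tss_strand_rules(tmp_path, genome):
    p = tmp_path / "genes.tsv"
    p.write_text(
        "gene_id\tchrom\tstart\tend\tstrand\n"
        "g1\tchr1\t100\t500\t+\n"
        "g2\tchr1\t100\t500\t-\n"
    )
    genes = read_gene_table(p, genome)
    assert genes[0].tss == 100
    assert genes[1].tss == 499  # last covered base, half-open


def test_gene_table_duplicate_id(tmp_path, genome):
    p = tmp_path / "genes.tsv"
    p.write_text(
        "gene_id\tchrom\tstart\tend\tstrand\ng1\tchr1\t0\t10\t+\ng1\tchr1\t20\t30\t+\n"
    )
    with pytest.raises(ParseError, match="duplicate"):
        read_gene_table(p, genome)


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------


def test_overlaps_convention():
    a = GenomicInterval("chr1", 100, 200)
    assert overlaps(a, GenomicInterval("chr1", 150, 250))
    assert not overlaps(a, GenomicInterval("chr1", 200, 300))  # abutting
    assert not overlaps(a, GenomicInterval("chr2", 100, 200))


def test_interval_distance_convention():
    a = GenomicInterval("chr1", 100, 200)
    assert interval_distance(a, GenomicInterval("chr1", 700, 800)) == 500
    assert interval_distance(a, GenomicInterval("chr1", 150, 250)) == 0
    assert interval_distance(GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)) == 0
    assert interval_distance(a, GenomicInterval("chr2", 0, 10)) is None


_iv = st.tuples(st.integers(0, 10_000), st.integers(1, 200)).map(
    lambda t: GenomicInterval("chr1", t[0], t[0] + t[1])
)


@settings(derandomize=True, max_examples=200)
@given(_iv, _iv)
def test_overlap_and_distance_symmetry(a, b):
    assert overlaps(a, b) == overlaps(b, a)
    assert interval_distance(a, b) == interval_distance(b, a)
    if overlaps(a, b):
        assert interval_distance(a, b) == 0


@settings(derandomize=True, max_examples=100)
@given(_iv, _iv)
def test_interval_distance_matches_per_bp_scan(a, b):
    """Edge gap equals the minimum point distance over all covered bases."""
    best = min(
        abs(pa - pb) for pa in range(a.start, a.end) for pb in range(b.start, b.end)
    )
    expected = max(best - 1, 0)  # adjacent bases are at gap 0
    assert interval_distance(a, b) == expected


def test_nearest_distance_tie_breaks():
    q = GenomicInterval("chr1", 100, 200)
    assert nearest_distance(q, {"x": 50, "y": 500}) == (50, "x")
    assert nearest_distance(q, {"x": 150}) == (0, "x")
    # equidistant: 50 to the left edge, 50 beyond the right edge
    assert nearest_distance(q, {"far": 250, "near": 50}) == (50, "near")
    assert nearest_distance(q, {}) is None


def test_merge_intervals_examples():
    merged = merge_intervals(
        [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 20)]
    )
    assert merged == [GenomicInterval("chr1", 0, 20)]
    disjoint = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 30, 40)]
    assert merge_intervals(disjoint) == disjoint


@settings(derandomize=True, max_examples=100)
@given(st.lists(_iv, min_size=1, max_size=20), st.randoms())
def test_merge_is_canonical_and_conserves_bases(ivs, rnd):
    """Merging is order-invariant, idempotent, and covers the same bases."""
    merged = merge_intervals(ivs)
    shuffled = list(ivs)
    rnd.shuffle(shuffled)
    assert merge_intervals(shuffled) == merged
    assert merge_intervals(merged) == merged
    covered = set()
    for iv in ivs:
        covered.update(range(iv.start, iv.end))
    merged_covered = set()
    for iv in merged:
        assert iv.width > 0
        merged_covered.update(range(iv.start, iv.end))
    assert merged_covered == covered
    # disjoint and sorted
    for x, y in zip(merged, merged[1:]):
        assert x.end < y.start


def test_layout_and_interval_invariants():
    with pytest.raises(ValueError):
        GenomeLayout(("chr1", "chr1"), (10, 10))
    with pytest.raises(ValueError):
        GenomeLayout(("chr1",), (0,))
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)


def test_peakset_rejects_out_of_bounds(genome):
    with pytest.raises(ValueError, match="out of bounds"):
        make_peaks(genome, [("chr2", 40_000, 60_000)])
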