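"""Region-class enrichment, coverage tracks and sample clustering."""

import numpy as np
import pandas as pd
import pytest

from atacdyn.genome_io import (
    FragmentSet,
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    merge_intervals,
    overlaps,
)
from atacdyn.region_enrichment import (
    RegionCatalog,
    binned_coverage,
    build_tss_windows,
    classify_peaks,
    cluster_samples,
    fold_enrichment,
    fraction_regions_with_peak,
    spearman_tracks,
    tss_matrix,
)

from conftest import make_peaks


def _gene(gid, chrom, start, end, strand="+"):
    return GeneModel(gid, GenomicInterval(chrom, start, end), strand)


# ---------------------------------------------------------------------------
# TSS windows
# ---------------------------------------------------------------------------


def test_tss_window_width_and_clipping(genome):
    genes = [_gene("g1", "chr1", 5000, 20_000), _gene("g2", "chr1", 300, 5000)]
    win = build_tss_windows(genes, genome, half_width=1000)
    assert win[0].start == 4000 and win[0].end == 6001 and win[0].width == 2001
    assert win[1].start == 0 and win[1].end == 1301  # clipped at the chromosome edge


def test_tss_window_merged_bp_matches_merge_oracle(genome):
    genes = [_gene("g1", "chr1", 4000, 10_000), _gene("g2", "chr1", 4500, 10_500)]
    win = build_tss_windows(genes, genome, half_width=1000)
    cat = RegionCatalog.from_intervals(genome, {"tss": win})
    merged = merge_intervals(win)
    assert cat.class_bp("tss") == sum(iv.width for iv in merged) == 2501


# ---------------------------------------------------------------------------
# fold enrichment
# ---------------------------------------------------------------------------


def test_fold_formula_half_in_ten_percent_class():
    genome = GenomeLayout(("chr1",), (100_000,))
    cat = RegionCatalog.from_intervals(
        genome, {"c": [GenomicInterval("chr1", 0, 10_000)]}
    )
    inside = [("chr1", i * 100, i * 100 + 50) for i in range(50)]
    outside = [("chr1", 20_000 + i * 100, 20_000 + i * 100 + 50) for i in range(50)]
    ps = make_peaks(genome, inside + outside)
    res = fold_enrichment(ps, "c", cat)
    assert res.n_peaks_in_class == 50
    assert res.fold == pytest.approx(5.0)


def test_fold_ceiling_all_peaks_inside():
    genome = GenomeLayout(("chr1",), (100_000,))
    cat = RegionCatalog.from_intervals(
        genome, {"c": [GenomicInterval("chr1", 0, 10_000)]}
    )
    ps = make_peaks(genome, [("chr1", i * 100, i * 100 + 50) for i in range(20)])
    res = fold_enrichment(ps, "c", cat)
    assert res.fold == pytest.approx(genome.total_bp / cat.class_bp("c"))


def test_fold_whole_genome_class_is_one(genome):
    cat = RegionCatalog.from_intervals(
        genome,
        {"genome": [GenomicInterval("chr1", 0, 100_000), GenomicInterval("chr2", 0, 50_000)]},
    )
    ps = make_peaks(genome, [("chr1", 10, 60), ("chr2", 100, 200)])
    assert fold_enrichment(ps, "genome", cat).fold == pytest.approx(1.0)


def test_fold_errors_on_empty_inputs(genome):
    cat = RegionCatalog.from_intervals(genome, {"c": [GenomicInterval("chr1", 0, 10)]})
    with pytest.raises(ValueError, match="empty peak set"):
        fold_enrichment(PeakSet("e", genome), "c", cat)


def test_hypergeometric_type_one_error_under_uniform_null():
    """Uniformly placed peaks reject at alpha=0.05 at the nominal rate."""
    genome = GenomeLayout(("chr1",), (100_000,))
    cat = RegionCatalog.from_intervals(
        genome, {"c": [GenomicInterval("chr1", 0, 10_000)]}
    )
    rng = np.random.default_rng(0)
    n_sims, rejections = 1000, 0
    for _ in range(n_sims):
        pos = rng.integers(0, 99_999, 500)
        ps = PeakSet("u", genome, pd.DataFrame({"chrom": "chr1", "start": pos, "end": pos + 1}))
        rejections += fold_enrichment(ps, "c", cat, bin_width=1).p_value < 0.05
    assert 0.03 <= rejections / n_sims <= 0.07


def test_planted_fold_recovered_within_ten_percent():
    from atacdyn.simulate import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(seed=11)
    ds = generate_dataset(cfg)
    win = build_tss_windows(ds.genes, ds.genome, cfg.tss_window_half)
    cat = RegionCatalog.from_intervals(ds.genome, {"tss": win})
    res = fold_enrichment(ds.peaks_before, "tss", cat)
    assert res.fold == pytest.approx(cfg.tss_enrichment_fold, rel=0.10)


# ---------------------------------------------------------------------------
# per-region fractions and classification
# ---------------------------------------------------------------------------


def test_fraction_regions_with_peak(genome):
    regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(5)]
    ps = make_peaks(genome, [("chr1", 100, 200), ("chr1", 1100, 1200)])
    assert fraction_regions_with_peak(regions, ps) == pytest.approx(0.4)
    assert fraction_regions_with_peak(regions, PeakSet("e", genome)) == 0.0
    hit_all = make_peaks(genome, [("chr1", 0, 4600)])
    assert fraction_regions_with_peak(regions, hit_all) == 1.0


def test_classify_peaks_precedence_and_fallback(genome):
    cat = RegionCatalog.from_intervals(
        genome,
        {
            "tss": [GenomicInterval("chr1", 1000, 2000)],
            "gene_body": [GenomicInterval("chr1", 1500, 5000)],
        },
    )
    ps = make_peaks(
        genome, [("chr1", 1400, 1600), ("chr1", 3000, 3100), ("chr1", 90_000, 90_100)]
    )
    labels = classify_peaks(ps, cat, ["tss", "gene_body"])
    assert list(labels) == ["tss", "gene_body", "intergenic"]


def test_classify_peaks_matches_brute_force_and_order_invariance(genome, rng):
    class_ivs = {
        "a": [GenomicInterval("chr1", int(s), int(s) + 300) for s in rng.integers(0, 90_000, 10)],
        "b": [GenomicInterval("chr1", int(s), int(s) + 500) for s in rng.integers(0, 90_000, 10)],
    }
    cat = RegionCatalog.from_intervals(genome, class_ivs)
    spans = [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 90_000, 200)]
    ps = make_peaks(genome, spans)
    labels = classify_peaks(ps, cat, ["a", "b"])

    def brute(span):
        iv = GenomicInterval(*span)
        for cls in ("a", "b"):
            if any(overlaps(iv, r) for r in class_ivs[cls]):
                return cls
        return "intergenic"

    assert list(labels) == [brute(s) for s in spans]
    # label counts are invariant to peak order
    perm = rng.permutation(len(spans))
    labels_perm = classify_peaks(make_peaks(genome, [spans[i] for i in perm]), cat, ["a", "b"])
    assert labels.value_counts().to_dict() == labels_perm.value_counts().to_dict()


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------


def test_binned_coverage_midpoint_rule(genome):
    frags = FragmentSet("f", pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [300]}))
    track = binned_coverage(frags, genome, 1000)
    assert track[0] == 1 and track.sum() == 1
    # midpoint exactly on a boundary goes right
    frags2 = FragmentSet("f", pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1100]}))
    track2 = binned_coverage(frags2, genome, 1000)
    assert track2[1] == 1 and track2[0] == 0


def test_binned_coverage_conserves_fragments(genome, rng):
    n = 500
    starts = rng.integers(0, 40_000, n)
    frags = FragmentSet(
        "f",
        pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], n), "start": starts, "end": starts + 100}),
    )
    assert binned_coverage(frags, genome, 777).sum() == n


def test_spearman_tracks_oracle():
    a = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.0, 6.0, 5.0, 3.5, 7.0])
    assert spearman_tracks(a, a) == pytest.approx(1.0)
    assert spearman_tracks(a, -a) == pytest.approx(-1.0)
    b = np.array([2.0, 8.0, 1.0, 6.0, 3.0, 9.0, 4.0, 7.0, 5.0, 0.5])
    # direct rank-formula oracle (no ties): 1 - 6*sum(d^2)/(n(n^2-1))
    ra = a.argsort().argsort()
    rb = b.argsort().argsort()
    d2 = ((ra - rb) ** 2).sum()
    expected = 1 - 6 * d2 / (10 * 99)
    assert spearman_tracks(a, b) == pytest.approx(expected)
    with pytest.raises(ValueError, match="zero-variance"):
        spearman_tracks(np.ones(5), a[:5])


def test_tss_matrix_orientation_and_conservation(genome):
    genes = [
        _gene("plus", "chr1", 10_000, 20_000, "+"),
        _gene("minus", "chr1", 30_000, 40_000, "-"),
    ]
    # one fragment midpoint exactly at each TSS, one 100 bp downstream in genome coords
    frags = FragmentSet(
        "f",
        pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "start": [9_990, 10_090, 39_989, 40_089],
                "end": [10_010, 10_110, 40_009, 40_109],
            }
        ),
    )
    mat, ids = tss_matrix(frags, genes, window=1000, bin_width=100)
    assert ids == ["plus", "minus"]
    assert mat[0, 5] == 1 and mat[0, 6] == 1  # TSS bin and +100 bin
    # minus strand rows are reversed: the TSS bin 5 maps to 4, and a fragment
    # 100 bp downstream in genome coordinates appears one bin upstream (3)
    assert mat[1, 4] == 1 and mat[1, 3] == 1
    assert mat.sum() == 4


def test_cluster_samples_identical_pair_joins_first(rng):
    base = rng.random((20, 10))
    noise = base + rng.normal(0, 1e-3, base.shape)
    anti = -base
    Z, labels = cluster_samples({"s1": base, "s2": noise, "s3": anti})
    assert labels == ["s1", "s2", "s3"]
    # first merge joins s1 (0) and s2 (1) at near-zero height
    assert set(Z[0, :2].astype(int)) == {0, 1}
    assert Z[0, 2] < 0.01
    Zdup, _ = cluster_samples({"a": base, "b": base.copy(), "c": anti})
    assert Zdup[0, 2] == pytest.approx(0.0)


def test_cluster_three_samples_matches_exhaustive_oracle(rng):
    """With three samples the first merge must be the closest pair by
    1 - Spearman, and the final height the average of the remaining distances."""
    from scipy.stats import spearmanr

    profiles = {k: rng.random(30) for k in ("s1", "s2", "s3")}
    Z, labels = cluster_samples(profiles)
    d = {}
    for i in range(3):
        for j in range(i + 1, 3):
            d[(i, j)] = 1 - spearmanr(profiles[labels[i]], profiles[labels[j]]).statistic
    closest = min(d, key=d.get)
    assert set(Z[0, :2].astype(int)) == set(closest)
    assert Z[0, 2] == pytest.approx(d[closest])
    other = [k for k in d if k != closest]
    assert Z[1, 2] == pytest.approx(np.mean([d[k] for k in other]))
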