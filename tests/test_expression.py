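"""Expression transitions, TSS coverage and Mann-Whitney comparisons."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from atacdyn.expression import (
    ExpressionTable,
    TSSProfile,
    classify_expression,
    compare_categories,
    fraction_pre_opened,
    mann_whitney,
    resistant_comparison,
    tss_mean_coverage,
)
from atacdyn.genome_io import FragmentSet, GeneModel, GenomicInterval
from atacdyn.region_enrichment import tss_matrix

from conftest import make_peaks


def _gene(gid, chrom, start, end, strand="+"):
    return GeneModel(gid, GenomicInterval(chrom, start, end), strand)


# ---------------------------------------------------------------------------
# expression categories
# ---------------------------------------------------------------------------


def test_classify_expression_four_way():
    table = classify_expression(
        {"a": 0.0, "b": 5.0, "c": 0.5, "d": 3.0},
        {"a": 5.0, "b": 5.0, "c": 0.5, "d": 0.2},
        threshold=1.0,
    )
    cats = dict(zip(table.df["gene_id"], table.df["category"]))
    assert cats == {"a": "only_after", "b": "both", "c": "neither", "d": "only_before"}
    assert sum(table.category_counts().values()) == 4


def test_classify_expression_universe_mismatch():
    with pytest.raises(ValueError, match="one condition"):
        classify_expression({"a": 1.0}, {"b": 1.0})


# ---------------------------------------------------------------------------
# TSS coverage
# ---------------------------------------------------------------------------


def test_tss_mean_coverage_density(genome):
    genes = [_gene("g1", "chr1", 10_000, 20_000)]
    mids = np.linspace(9_550, 10_450, 10).astype(int)
    frags = FragmentSet(
        "f", pd.DataFrame({"chrom": "chr1", "start": mids - 10, "end": mids + 10})
    )
    prof = tss_mean_coverage(frags, genes, genome.lengths, window=1000)
    assert prof.coverage["g1"] == pytest.approx(0.01)
    empty = FragmentSet("f", pd.DataFrame({"chrom": [], "start": [], "end": []}))
    assert tss_mean_coverage(empty, genes, genome.lengths).coverage["g1"] == 0.0


def test_tss_mean_coverage_clipped_window_denominator(genome):
    genes = [_gene("edge", "chr1", 200, 5_000)]  # window clipped to [0, 700)
    frags = FragmentSet(
        "f", pd.DataFrame({"chrom": ["chr1"], "start": [90], "end": [110]})
    )
    prof = tss_mean_coverage(frags, genes, genome.lengths, window=1000)
    assert prof.coverage["edge"] == pytest.approx(1 / 700)


def test_tss_mean_coverage_translation_equivariance(genome, rng):
    delta = 7_000
    starts = rng.integers(5_000, 40_000, 300)
    genes = [_gene("g1", "chr1", 20_000, 30_000)]
    genes_shift = [_gene("g1", "chr1", 20_000 + delta, 30_000 + delta)]
    f1 = FragmentSet("f", pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 80}))
    f2 = FragmentSet(
        "f", pd.DataFrame({"chrom": "chr1", "start": starts + delta, "end": starts + 80 + delta})
    )
    p1 = tss_mean_coverage(f1, genes, genome.lengths)
    p2 = tss_mean_coverage(f2, genes_shift, genome.lengths)
    assert p1.coverage["g1"] == p2.coverage["g1"]


def test_tss_mean_coverage_consistent_with_tss_matrix(genome, rng):
    genes = [
        _gene(f"g{i}", "chr1", int(s), int(s) + 3_000, strand=str(st))
        for i, (s, st) in enumerate(
            zip(rng.integers(5_000, 90_000, 20), rng.choice(["+", "-"], 20))
        )
    ]
    starts = rng.integers(0, 99_000, 2_000)
    frags = FragmentSet(
        "f", pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 60})
    )
    prof = tss_mean_coverage(frags, genes, genome.lengths, window=1000)
    mat, ids = tss_matrix(frags, genes, window=1000, bin_width=100)
    for i, gid in enumerate(ids):
        assert prof.coverage[gid] == pytest.approx(mat[i].sum() / 1000)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def test_mann_whitney_exact_enumeration_oracle():
    """For {1,2,3} vs {4,5,6}, enumerate all 20 rank assignments: only the
    two extreme arrangements are as separated, so two-sided p = 2/20."""
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    pooled = a + b
    observed_u = sum(x < y for x in a for y in b)  # 9 = n1*n2, U for A = 0
    count_extreme = 0
    for idx in combinations(range(6), 3):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(6) if i not in idx]
        u = sum(x > y for x in ga for y in gb)
        if min(u, 9 - u) <= min(0, 9 - 0):
            count_extreme += 1
    expected_p = count_extreme / 20
    assert expected_p == pytest.approx(0.1)
    res = mann_whitney(a, b)
    assert res.u_statistic == 0
    assert res.p_value == pytest.approx(0.1)


def test_mann_whitney_symmetry_and_identical():
    a = [1.0, 5.0, 3.0, 8.0]
    b = [2.0, 9.0, 4.0]
    r1 = mann_whitney(a, b)
    r2 = mann_whitney(b, a)
    assert r1.p_value == pytest.approx(r2.p_value)
    assert r1.u_statistic + r2.u_statistic == len(a) * len(b)
    same = mann_whitney([2.0, 2.0], [2.0, 2.0])
    assert same.p_value == 1.0 and same.all_identical


def test_mann_whitney_null_rejection_rate(rng):
    n_sims, rej = 1000, 0
    for _ in range(n_sims):
        res = mann_whitney(rng.normal(size=30), rng.normal(size=30))
        rej += res.p_value < 0.05
    assert 0.03 <= rej / n_sims <= 0.07


# ---------------------------------------------------------------------------
# category comparisons
# ---------------------------------------------------------------------------


def _make_profile_and_table(rng, effect, n=200):
    gene_ids = [f"g{i}" for i in range(4 * n)]
    cats = ["only_after"] * n + ["neither"] * n + ["both"] * n + ["only_before"] * n
    cov = rng.poisson(20, 4 * n).astype(float)
    cov[:n] = rng.poisson(20 * effect, n)
    table = ExpressionTable(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "expressed_before": [c in ("both", "only_before") for c in cats],
                "expressed_after": [c in ("both", "only_after") for c in cats],
            }
        )
    )
    profile = TSSProfile("donor", 1000, pd.Series(cov / 1000, index=gene_ids))
    return profile, table


def test_compare_categories_planted_effect_detected(rng):
    profile, table = _make_profile_and_table(rng, effect=3.0)
    comps = compare_categories(profile, table, pairs=[("only_after", "neither")])
    assert comps[0].adjusted_p < 0.05
    assert comps[0].higher_group == "only_after"


def test_compare_categories_null_mostly_nonsignificant():
    flips = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        profile, table = _make_profile_and_table(rng, effect=1.0)
        comps = compare_categories(profile, table, pairs=[("only_after", "neither")])
        flips += comps[0].p_value < 0.05
    assert flips <= 2  # >=90% of seeds nonsignificant


def test_compare_categories_label_swap_symmetric(rng):
    profile, table = _make_profile_and_table(rng, effect=2.0)
    c1 = compare_categories(profile, table, pairs=[("only_after", "neither")])[0]
    c2 = compare_categories(profile, table, pairs=[("neither", "only_after")])[0]
    assert c1.p_value == pytest.approx(c2.p_value)


def test_compare_categories_skips_empty_with_warning(rng):
    profile, table = _make_profile_and_table(rng, effect=1.0)
    table.df.loc[table.df["category"] == "neither", "category"] = "both"
    with pytest.warns(UserWarning, match="empty category"):
        comps = compare_categories(profile, table, pairs=[("only_after", "neither")])
    assert comps == []


# ---------------------------------------------------------------------------
# pre-opened fraction and resistant genes
# ---------------------------------------------------------------------------


def test_fraction_pre_opened_arithmetic(genome):
    genes = [_gene(f"g{i}", "chr1", 1000 + 3000 * i, 3000 + 3000 * i) for i in range(25)]
    # donor peaks at the TSSs of the first 14 genes -> 14/25 = 56%
    donor = make_peaks(
        genome, [("chr1", 1000 + 3000 * i, 1200 + 3000 * i) for i in range(14)], "donor"
    )
    frac = fraction_pre_opened([g.gene_id for g in genes], donor, genes, window=1000)
    assert frac == pytest.approx(0.56)
    from atacdyn.genome_io import PeakSet

    assert fraction_pre_opened(["g0"], PeakSet("e", genome), genes) == 0.0
    with pytest.raises(ValueError):
        fraction_pre_opened([], donor, genes)


def test_resistant_comparison_direction_and_errors(rng):
    gene_ids = [f"g{i}" for i in range(200)]
    cov = pd.Series(
        np.concatenate([rng.poisson(4, 100), rng.poisson(20, 100)]) / 1000.0,
        index=gene_ids,
    )
    profile = TSSProfile("donor", 1000, cov)
    res = resistant_comparison(gene_ids[:100], gene_ids[100:], profile)
    assert res.p_value < 0.01
    assert res.higher_group == "activated"
    with pytest.raises(ValueError, match="overlap"):
        resistant_comparison(gene_ids[:10], gene_ids[5:20], profile)
    single = resistant_comparison(["g0"], ["g150"], profile)
    assert 0 < single.p_value <= 1.0
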