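"""Nucleotide diversity, Weir–Cockerham Fst, windows, fits, outliers."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tuberscan.core import GeneModel, VariantTable
from tuberscan.popgen import (
    OutlierSet,
    common_regions,
    enrichment_test,
    fit_fst_distribution,
    intersect_outliers_with_genes,
    outlier_cutoff,
    pairwise_fst,
    select_outlier_windows,
    site_pi,
    wc_fst_sites,
    windowed_fst,
)


def make_table(genotypes, positions=None, chrom="chr1", samples=None):
    gt = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples, _ = gt.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return VariantTable(
        seqnames=np.array([chrom] * n_sites, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alts=[("T",)] * n_sites,
        qual=np.full(n_sites, 99.0),
        genotypes=gt,
        depth=np.full((n_sites, n_samples), 30, dtype=np.int32),
        samples=list(samples),
    )


# ------------------------------------------------------------------- π
def test_site_pi_closed_form():
    # 2 diploids, counts 2 ref / 2 alt -> pi = 4/6
    vt = make_table([[[0, 0], [1, 1]]])
    assert site_pi(vt)["pi"].iloc[0] == pytest.approx(4 / 6)


def test_monomorphic_site_pi_zero():
    vt = make_table([[[0, 0], [0, 0]]])
    assert site_pi(vt)["pi"].iloc[0] == 0.0


def test_pi_matches_pairwise_mismatch_oracle():
    """π equals the O(n²) average pairwise-difference count per site."""
    rng = np.random.default_rng(3)
    gt = rng.integers(0, 2, size=(100, 12, 2)).astype(np.int8)
    gt[rng.random((100, 12)) < 0.1] = -1
    vt = make_table(gt)
    df = site_pi(vt)
    for _, row in df.iterrows():
        i = int(np.flatnonzero(vt.pos == row["pos"])[0])
        alleles = [a for pair in gt[i] for a in pair if pair[0] >= 0 and pair[1] >= 0]
        n = len(alleles)
        diff = sum(
            alleles[x] != alleles[y] for x in range(n) for y in range(x + 1, n)
        )
        assert row["pi"] == pytest.approx(diff / (n * (n - 1) / 2), abs=1e-12)


# ------------------------------------------------------------- WC 1984
def wc_oracle(pop1, pop2):
    """Direct scalar evaluation of the 1984 two-population formulas.

    Written independently of the vectorised implementation: takes two
    lists of diploid genotype tuples (allele pairs, None for missing).
    """
    def summarise(pop):
        called = [g for g in pop if g is not None]
        n = len(called)
        p = sum(a + b for a, b in called) / (2 * n)
        h = sum(1 for a, b in called if a != b) / n
        return n, p, h

    n1, p1, h1 = summarise(pop1)
    n2, p2, h2 = summarise(pop2)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c, a / (a + b + c)


def test_fixed_difference_gives_theta_one():
    gt = [[[1, 1]] * 10 + [[0, 0]] * 10]
    vt = make_table(gt)
    df = wc_fst_sites(vt, [f"s{i}" for i in range(10)], [f"s{i}" for i in range(10, 20)])
    assert df["theta"].iloc[0] == pytest.approx(1.0)


def test_two_pop_example_matches_oracle():
    # pop1 {0/0, 0/1}, pop2 {0/1, 1/1}
    gt = [[[0, 0], [0, 1], [0, 1], [1, 1]]]
    vt = make_table(gt)
    df = wc_fst_sites(vt, ["s0", "s1"], ["s2", "s3"])
    _, _, _, theta = wc_oracle([(0, 0), (0, 1)], [(0, 1), (1, 1)])
    assert df["theta"].iloc[0] == pytest.approx(theta, abs=1e-14)


def test_cluster_label_swap_symmetry():
    rng = np.random.default_rng(9)
    gt = rng.integers(0, 2, size=(40, 16, 2)).astype(np.int8)
    vt = make_table(gt)
    a = [f"s{i}" for i in range(8)]
    b = [f"s{i}" for i in range(8, 16)]
    d1 = wc_fst_sites(vt, a, b)
    d2 = wc_fst_sites(vt, b, a)
    assert np.allclose(d1["theta"], d2["theta"])


def test_permutation_null_centres_on_zero():
    rng = np.random.default_rng(21)
    gt = rng.integers(0, 2, size=(40, 20, 2)).astype(np.int8)
    vt = make_table(gt)
    samples = np.array(vt.samples)
    means = []
    for _ in range(300):
        perm = rng.permutation(20)
        df = wc_fst_sites(vt, samples[perm[:10]], samples[perm[10:]])
        means.append(df["theta"].mean())
    assert abs(np.mean(means)) < 0.02  # Monte-Carlo error band


def test_monomorphic_and_underpowered_sites_excluded():
    gt = [
        [[0, 0], [0, 0], [0, 0], [0, 0]],       # monomorphic: excluded
        [[0, 1], [-1, -1], [0, 1], [1, 1]],     # pop1 has 1 call: excluded
        [[0, 1], [0, 0], [1, 1], [0, 1]],       # kept
    ]
    vt = make_table(gt)
    df = wc_fst_sites(vt, ["s0", "s1"], ["s2", "s3"])
    assert df["pos"].tolist() == [300]


def test_pairwise_requires_two_clusters():
    vt = make_table([[[0, 1], [0, 0]]])
    with pytest.raises(ValueError, match="at least two clusters"):
        pairwise_fst(vt, {"A": ["s0", "s1"]})


# ------------------------------------------------------------- windows
def test_window_tiling_70kb_chromosome():
    comp = pd.DataFrame(
        {"seqname": ["chr1"] * 3, "pos": [100, 30000, 69000],
         "a": [0.1] * 3, "b": [0.2] * 3, "c": [0.1] * 3}
    )
    win = windowed_fst(comp, {"chr1": 70_000})
    assert list(zip(win["start"], win["end"])) == [
        (1, 50_000), (10_001, 60_000), (20_001, 70_000)
    ]


def test_single_site_window_equals_site_theta():
    comp = pd.DataFrame(
        {"seqname": ["chr1"], "pos": [100], "a": [0.3], "b": [0.1], "c": [0.2]}
    )
    win = windowed_fst(comp, {"chr1": 40_000})
    assert win["weighted_fst"].iloc[0] == pytest.approx(0.3 / 0.6)


def test_short_chromosome_gives_truncated_window():
    comp = pd.DataFrame(
        {"seqname": ["chr1"], "pos": [100], "a": [0.3], "b": [0.1], "c": [0.2]}
    )
    win = windowed_fst(comp, {"chr1": 20_000})
    assert len(win) == 1 and bool(win["truncated"].iloc[0])
    assert (win["start"].iloc[0], win["end"].iloc[0]) == (1, 20_000)


def test_windowed_fst_matches_brute_force_sum():
    rng = np.random.default_rng(13)
    pos = np.sort(rng.choice(np.arange(1, 70_001), size=12, replace=False))
    a = rng.uniform(0, 0.3, 12)
    b = rng.uniform(0, 0.3, 12)
    c = rng.uniform(0, 0.3, 12)
    comp = pd.DataFrame({"seqname": ["chr1"] * 12, "pos": pos, "a": a, "b": b, "c": c})
    win = windowed_fst(comp, {"chr1": 70_000})
    for _, row in win.iterrows():
        inside = (pos >= row["start"]) & (pos <= row["end"])
        expect = a[inside].sum() / (a[inside] + b[inside] + c[inside]).sum()
        assert row["weighted_fst"] == pytest.approx(expect, abs=1e-12)
        assert row["n_variants"] == int(inside.sum())


def test_window_value_invariant_to_site_order():
    comp = pd.DataFrame(
        {"seqname": ["chr1"] * 4, "pos": [100, 200, 300, 400],
         "a": [0.1, 0.2, 0.05, 0.3], "b": [0.1] * 4, "c": [0.05] * 4}
    )
    shuffled = comp.sample(frac=1, random_state=1)
    w1 = windowed_fst(comp, {"chr1": 50_000})
    w2 = windowed_fst(shuffled, {"chr1": 50_000})
    assert np.allclose(w1["weighted_fst"], w2["weighted_fst"])


# ---------------------------------------------------- distribution fit
def test_normal_loglik_matches_closed_form():
    rng = np.random.default_rng(4)
    x = rng.normal(0.3, 0.05, 2000)
    x = x[x > 0]
    fits, _ = fit_fst_distribution(x)
    norm_fit = next(f for f in fits if f.family == "normal")
    mu, sigma = np.mean(x), np.std(x)
    closed = -len(x) / 2 * math.log(2 * math.pi * sigma**2) - np.sum(
        (x - mu) ** 2
    ) / (2 * sigma**2)
    assert norm_fit.loglik == pytest.approx(closed, abs=1e-9)
    assert norm_fit.aic == pytest.approx(4 - 2 * closed, abs=1e-9)


def test_too_few_values_raises_with_fallback_advice():
    with pytest.raises(ValueError, match="empirical quantile"):
        fit_fst_distribution(np.full(10, 0.2))


def test_weibull_quantiles_analytic():
    fit_shape1 = fit_fst_distribution(
        stats.weibull_min.rvs(1.0, scale=0.2, size=500, random_state=1)
    )[1]
    # analytic checks use constructed fits, not the estimated ones
    from tuberscan.popgen import DistributionFit

    lam = 0.37
    f1 = DistributionFit("weibull", (1.0, lam), 0.0, 0.0, 1)
    assert outlier_cutoff(f1, 0.95) == pytest.approx(lam * math.log(20), abs=1e-9)
    f2 = DistributionFit("weibull", (2.0, lam), 0.0, 0.0, 1)
    assert outlier_cutoff(f2, 0.95) == pytest.approx(
        lam * math.sqrt(math.log(20)), abs=1e-9
    )
    with pytest.raises(ValueError):
        outlier_cutoff(f1, 1.5)
    assert fit_shape1.family in {"weibull", "gamma", "lognormal", "normal"}


def test_empirical_quantile_converges_to_analytic_cutoff():
    lam, shape = 0.1, 1.5
    from tuberscan.popgen import DistributionFit

    fit = DistributionFit("weibull", (shape, lam), 0.0, 0.0, 1)
    analytic = outlier_cutoff(fit, 0.95)
    rng = np.random.default_rng(8)
    errs = []
    for n in (1_000, 100_000):
        draws = stats.weibull_min.rvs(shape, scale=lam, size=n, random_state=rng)
        errs.append(abs(np.quantile(draws, 0.95) - analytic))
    assert errs[1] < errs[0] < 0.02


# ----------------------------------------------------- gene intersect
def _win(rows):
    return pd.DataFrame(rows, columns=["seqname", "start", "end"]).assign(
        n_variants=1, weighted_fst=0.5, pair="A_vs_B", truncated=False
    )


def test_one_bp_overlap_is_reported():
    oset = OutlierSet("A_vs_B", 0.1, _win([("chr1", 10_001, 60_000)]))
    gene = GeneModel("g1", "chr1", "+", [(60_000, 61_000)], [])
    assert intersect_outliers_with_genes(oset, [gene]) == ["g1"]
    gene2 = GeneModel("g2", "chr1", "+", [(60_001, 61_000)], [])
    oset2 = OutlierSet("A_vs_B", 0.1, _win([("chr1", 10_001, 60_000)]))
    assert intersect_outliers_with_genes(oset2, [gene2]) == []


def test_seqname_mismatch_raises():
    oset = OutlierSet("A_vs_B", 0.1, _win([("chrX", 1, 100)]))
    gene = GeneModel("g1", "chr1", "+", [(10, 20)], [])
    with pytest.raises(ValueError, match="chrX"):
        intersect_outliers_with_genes(oset, [gene])


def test_intersection_matches_brute_force_oracle():
    rng = np.random.default_rng(17)
    windows = [
        ("chr1", int(s), int(s) + 4999)
        for s in rng.integers(1, 100_000, size=15)
    ]
    genes = [
        GeneModel(f"g{i}", "chr1", "+", [(int(s), int(s) + 999)], [])
        for i, s in enumerate(rng.integers(1, 105_000, size=40))
    ]
    oset = OutlierSet("A_vs_B", 0.1, _win(windows))
    got = set(intersect_outliers_with_genes(oset, genes))
    expect = {
        g.gene_id
        for g in genes
        if any(g.start <= e and g.end >= s for _, s, e in windows)
    }
    assert got == expect


def test_common_regions_three_way():
    sets = [
        OutlierSet("A_vs_B", 0, _win([("chr1", 1, 100), ("chr1", 500, 600)])),
        OutlierSet("A_vs_C", 0, _win([("chr1", 50, 120)])),
        OutlierSet("B_vs_C", 0, _win([("chr1", 80, 200), ("chr2", 1, 50)])),
    ]
    assert common_regions(sets) == [("chr1", 80, 100)]


def test_common_regions_merges_overlaps():
    sets = [
        OutlierSet("p1", 0, _win([("chr1", 1, 100), ("chr1", 90, 300)])),
        OutlierSet("p2", 0, _win([("chr1", 1, 300)])),
    ]
    assert common_regions(sets) == [("chr1", 1, 300)]


# ----------------------------------------------------------- enrichment
def test_hypergeometric_tail_matches_enumeration():
    background = [f"g{i}" for i in range(100)]
    term = {"T": background[:10]}
    selection = background[:5] + background[20:25]  # 5 of 10 annotated
    df = enrichment_test(selection, background, term)
    expect = sum(
        math.comb(10, k) * math.comb(90, 10 - k) for k in range(5, 11)
    ) / math.comb(100, 10)
    assert df["p"].iloc[0] == pytest.approx(expect, rel=1e-12)


def test_enrichment_degenerate_cases():
    background = [f"g{i}" for i in range(50)]
    term = {"T": background[:10]}
    assert enrichment_test(background, background, term)["p"].iloc[0] == pytest.approx(1.0)
    none_annotated = background[10:20]
    assert enrichment_test(none_annotated, background, term)["p"].iloc[0] == pytest.approx(1.0)


def test_enrichment_rejects_non_subset_and_skips_absent_terms():
    with pytest.raises(ValueError):
        enrichment_test(["x"], ["a", "b"], {})
    with pytest.warns(UserWarning, match="absent"):
        df = enrichment_test(["a"], ["a", "b"], {"T": ["zzz"]})
    assert df.empty
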