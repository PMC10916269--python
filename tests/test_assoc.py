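"""Association filters, GLM, allele effects, expression-by-allele."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tuberscan.assoc import (
    allele_effect,
    assoc_snp_filter,
    cross_reference_selection,
    expression_by_allele,
    glm_association,
    qtn_name,
    AssociationHit,
)
from tuberscan.core import VariantTable


def make_table(genotypes, samples=None, positions=None):
    gt = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples, _ = gt.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    return VariantTable(
        seqnames=np.array(["chr10"] * n_sites, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(["G"] * n_sites, dtype=object),
        alts=[("T",)] * n_sites,
        qual=np.full(n_sites, 99.0),
        genotypes=gt,
        depth=np.full((n_sites, n_samples), 30, dtype=np.int32),
        samples=list(samples),
    )


def phen_frame(values, samples, trait="starch_content", location="Godet"):
    return pd.DataFrame(
        {
            "sample": samples,
            "trait": trait,
            "location": location,
            "replicate": 1,
            "value": values,
        }
    )


# ------------------------------------------------------------- filters
def test_maf_boundary_inclusive_and_missing_strict():
    n = 20  # MAF 0.05 == 2 alt alleles of 40
    gt_maf = [[1, 1]] + [[0, 0]] * 19
    gt_low = [[0, 1]] + [[0, 0]] * 19        # MAF 0.025
    gt_miss = [[-1, -1]] * 4 + [[0, 1]] * 16  # missing rate 0.20 exactly
    vt = make_table([gt_maf, gt_low, gt_miss])
    out = assoc_snp_filter(vt, vt.samples)
    assert out.pos.tolist() == [100]


def test_filter_requires_sample_overlap():
    vt = make_table([[[0, 1], [0, 0], [1, 1], [0, 1]]])
    with pytest.raises(ValueError, match="no phenotyped sample"):
        assoc_snp_filter(vt, ["other1", "other2"])


def test_hand_enumerated_panel_of_20_snps():
    rng = np.random.default_rng(0)
    n = 25
    sites = []
    for i in range(20):
        p = 0.02 + 0.03 * i  # MAF sweeps through the 0.05 gate
        alleles = rng.binomial(1, p, size=(n, 2))
        sites.append(alleles)
    gt = np.array(sites, dtype=np.int8)
    vt = make_table(gt)
    out = assoc_snp_filter(vt, vt.samples)
    maf = vt.maf()
    expected = [int(p) for p, m in zip(vt.pos, maf) if m >= 0.05]
    assert out.pos.tolist() == expected


# ----------------------------------------------------------------- GLM
def test_noise_free_signal_has_vanishing_p():
    rng = np.random.default_rng(1)
    n = 30
    d = rng.binomial(1, 0.5, size=(n, 2)).astype(np.int8)
    vt = make_table([d])
    y = vt.dosage()[0] * 2.0 + 5.0
    hits = glm_association(vt, phen_frame(y, vt.samples), "starch_content", "Godet")
    assert len(hits) == 1 and hits[0].p_value < 1e-10
    assert hits[0].qtn == "qSC10.1"


def test_constant_phenotype_not_retained():
    rng = np.random.default_rng(2)
    d = rng.binomial(1, 0.5, size=(30, 2)).astype(np.int8)
    vt = make_table([d])
    y = np.full(30, 7.0)
    # constant phenotype would fail the "3 distinct values" gate: perturb
    with pytest.raises(ValueError, match="distinct"):
        glm_association(vt, phen_frame(y, vt.samples), "starch_content", "Godet")
    y2 = np.full(30, 7.0)
    y2[:3] = [7.0, 7.1, 6.9]
    hits = glm_association(vt, phen_frame(y2, vt.samples), "starch_content", "Godet")
    assert all(h.p_value > 0.001 for h in hits) or not hits


def test_factor_glm_matches_statsmodels_ols():
    """The F-test equals a statsmodels OLS genotype-factor fit."""
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(3)
    n = 40
    d = rng.binomial(1, 0.4, size=(n, 2)).astype(np.int8)
    vt = make_table([d])
    y = 1.5 * vt.dosage()[0] + rng.normal(0, 2, n)
    hits = glm_association(
        vt, phen_frame(y, vt.samples), "starch_content", "Godet", p_max=1.0
    )
    df = pd.DataFrame({"y": y, "g": vt.dosage()[0].astype(int).astype(str)})
    ols = smf.ols("y ~ C(g)", df).fit()
    assert hits[0].p_value == pytest.approx(ols.f_pvalue, rel=1e-9)


def test_replicates_are_averaged_per_sample():
    rng = np.random.default_rng(4)
    n = 20
    d = rng.binomial(1, 0.5, size=(n, 2)).astype(np.int8)
    vt = make_table([d])
    base = vt.dosage()[0] * 3.0
    frames = []
    for rep, shift in [(1, -1.0), (2, 0.0), (3, 1.0)]:
        f = phen_frame(base + shift, vt.samples)
        f["replicate"] = rep
        frames.append(f)
    phen = pd.concat(frames)
    hits = glm_association(vt, phen, "starch_content", "Godet", p_max=1.0)
    # replicate shifts cancel in the mean: perfect signal again
    assert hits[0].p_value < 1e-10


def test_null_markers_retained_at_nominal_rate():
    """1,000 null markers: P<=0.001 retention within the 99% binomial CI."""
    rng = np.random.default_rng(5)
    n_sites, n = 1000, 60
    p = rng.uniform(0.1, 0.9, n_sites)
    gt = (rng.random((n_sites, n, 2)) < p[:, None, None]).astype(np.int8)
    vt = make_table(gt, positions=np.arange(1, n_sites + 1) * 50)
    y = rng.normal(0, 1, n)
    hits = glm_association(vt, phen_frame(y, vt.samples), "starch_content", "Godet")
    k = len(hits)
    lo = stats.binom.ppf(0.005, n_sites, 0.001)
    hi = stats.binom.ppf(0.995, n_sites, 0.001)
    assert lo <= k <= hi


# -------------------------------------------------------- allele effect
def test_identical_groups_give_zero_effect():
    gt = [[[0, 0]] * 5 + [[1, 1]] * 5]
    vt = make_table(gt)
    y = pd.Series(np.full(10, 4.0), index=vt.samples)
    eff = allele_effect(vt, y, vt.site_ids()[0])
    assert eff.t_stat == 0.0 and eff.p_value == 1.0 and eff.effect_pct == 0.0


def test_fifty_percent_effect_arithmetic():
    gt = [[[0, 0]] * 5 + [[1, 1]] * 5]
    vt = make_table(gt)
    y = pd.Series([2.0] * 5 + [3.0] * 5, index=vt.samples)
    eff = allele_effect(vt, y, vt.site_ids()[0])
    assert eff.effect_pct == pytest.approx(50.0)


def test_t_statistic_matches_direct_formula_oracle():
    rng = np.random.default_rng(6)
    for _ in range(30):
        n1, n2 = int(rng.integers(3, 12)), int(rng.integers(3, 12))
        gt = [[[0, 0]] * n1 + [[1, 1]] * n2]
        vt = make_table(gt)
        y1, y2 = rng.normal(0, 1, n1), rng.normal(0.5, 1, n2)
        y = pd.Series(np.concatenate([y1, y2]), index=vt.samples)
        eff = allele_effect(vt, y, vt.site_ids()[0])
        # pooled-variance two-sample t computed from scratch; the minor
        # group is the alt homozygotes when the alt allele is rarer
        g_minor, g_major = (y2, y1) if n2 <= n1 else (y1, y2)
        sp2 = ((n1 - 1) * y1.var(ddof=1) + (n2 - 1) * y2.var(ddof=1)) / (n1 + n2 - 2)
        nmi, nma = len(g_minor), len(g_major)
        t = (g_minor.mean() - g_major.mean()) / np.sqrt(sp2 * (1 / nmi + 1 / nma))
        p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        assert eff.t_stat == pytest.approx(t, abs=1e-10)
        assert eff.p_value == pytest.approx(p, abs=1e-10)


def test_allele_effect_antisymmetric_under_label_swap():
    # balanced design: relabelling ref<->alt exchanges the two groups
    rng = np.random.default_rng(7)
    gt = np.array([[[0, 0]] * 7 + [[1, 1]] * 7], dtype=np.int8)
    vt = make_table(gt)
    y = pd.Series(rng.normal(0, 1, 14), index=vt.samples)
    eff = allele_effect(vt, y, vt.site_ids()[0])
    swapped = make_table(1 - gt)  # relabel ref<->alt alleles
    eff2 = allele_effect(swapped, y, swapped.site_ids()[0])
    assert eff2.p_value == pytest.approx(eff.p_value, abs=1e-12)
    assert np.sign(eff2.mean_minor - eff2.mean_major) == -np.sign(
        eff.mean_minor - eff.mean_major
    )


def test_small_group_raises():
    gt = [[[0, 0]] * 9 + [[1, 1]]]
    vt = make_table(gt)
    y = pd.Series(np.arange(10.0), index=vt.samples)
    with pytest.raises(ValueError, match="<2 samples"):
        allele_effect(vt, y, vt.site_ids()[0])


# ------------------------------------------------- expression-by-allele
def _expr_frame(gene, samples, tpms):
    rows = []
    for s, tpm in zip(samples, tpms):
        for rep, v in enumerate(tpm, 1):
            rows.append({"gene": gene, "sample": s, "replicate": rep, "tpm": v})
    return pd.DataFrame(rows)


def test_log2_transform_arithmetic():
    gt = [[[0, 0]] * 3 + [[1, 1]] * 3]
    vt = make_table(gt)
    expr = _expr_frame("gX", vt.samples, [(4, 4, 4)] * 6)
    out = expression_by_allele(expr, vt, vt.site_ids()[0], "gX")
    for g in out["groups"].values():
        assert g["mean_tpm"] == pytest.approx(4.0)
        assert g["log2_mean_plus1"] == pytest.approx(np.log2(5), abs=1e-12)
    assert out["fold_change"] == pytest.approx(1.0) and not out["flagged"]


def test_planted_fold_change_flagged():
    gt = [[[0, 0]] * 3 + [[1, 1]] * 3]
    vt = make_table(gt)
    expr = _expr_frame("gX", vt.samples, [(2, 2, 2)] * 3 + [(8, 8, 8)] * 3)
    out = expression_by_allele(expr, vt, vt.site_ids()[0], "gX")
    assert out["fold_change"] == pytest.approx(4.0) and out["flagged"]


def test_missing_replicates_warn_but_average():
    gt = [[[0, 0]] * 2 + [[1, 1]] * 2]
    vt = make_table(gt)
    expr = _expr_frame("gX", vt.samples, [(2, 2, 2), (2, 2), (8, 8, 8), (8, 8, 8)])
    with pytest.warns(UserWarning, match="missing replicates"):
        out = expression_by_allele(expr, vt, vt.site_ids()[0], "gX")
    assert out["fold_change"] == pytest.approx(4.0)


def test_absent_gene_raises():
    vt = make_table([[[0, 0], [1, 1], [0, 1], [0, 1]]])
    with pytest.raises(KeyError):
        expression_by_allele(
            _expr_frame("gY", vt.samples, [(1,)] * 4), vt, vt.site_ids()[0], "gX"
        )


# ------------------------------------------------------ cross-reference
def _hit(gene, trait="hardness"):
    return AssociationHit(
        snp_id="S1_1", trait=trait, location="Godet", seqname="chr1", pos=1,
        major="G", minor="T", p_value=1e-5, gene_id=gene,
    )


def test_cross_reference_intersection():
    hits = [_hit("gA"), _hit("gB", "gumminess"), _hit(None)]
    outliers = {"A_vs_B": ["gA", "gC"], "B_vs_C": ["gA"]}
    df = cross_reference_selection(hits, outliers)
    assert df["gene_id"].tolist() == ["gA"]
    assert df["pairs"].iloc[0] == "A_vs_B,B_vs_C"


def test_cross_reference_empty_outliers():
    assert cross_reference_selection([_hit("gA")], {}).empty


def test_cross_reference_matches_set_oracle():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(30)]
    hits = [_hit(g) for g in rng.choice(genes, 12, replace=False)]
    outliers = {"p": rng.choice(genes, 10, replace=False).tolist()}
    df = cross_reference_selection(hits, outliers)
    expect = {h.gene_id for h in hits} & set(outliers["p"])
    assert set(df["gene_id"]) == expect


def test_qtn_naming():
    assert qtn_name("starch_content", "chr10", 1) == "qSC10.1"
    assert qtn_name("springiness", "chr1", 2) == "qSp1.2"
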