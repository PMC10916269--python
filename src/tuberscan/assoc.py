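"""Candidate-gene association: GLM marker tests, allele effects and
expression-by-allele comparison.

The association model is a fixed-effect one-way GLM: per-location trait
values (replicates averaged per sample) regressed on the genotype class
factor (2–3 classes), with an F-test p-value; variants are gated at
MAF ≥ 0.05 and missing rate < 20 % and retained at P ≤ 0.001.  Allele
effects compare the major-allele-homozygote group against minor-allele
carriers with a two-tailed t-test, and the effect size is expressed as a
percentage of the major-group mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import VariantTable

__all__ = [
    "AssociationHit",
    "AlleleEffect",
    "assoc_snp_filter",
    "phenotype_means",
    "glm_association",
    "allele_effect",
    "expression_by_allele",
    "cross_reference_selection",
    "qtn_name",
]

TRAIT_ABBREV = {
    "hardness": "H",
    "gumminess": "G",
    "springiness": "Sp",
    "cohesiveness": "C",
    "total_area": "Ta",
    "starch_content": "SC",
    "brown_index": "BI",
    "hue_index": "HI",
    "whiteness_index": "WI",
    "yellow_index": "YI",
}


@dataclass
class AssociationHit:
    """One retained SNP × trait association."""

    snp_id: str
    trait: str
    location: str
    seqname: str
    pos: int
    major: str
    minor: str
    p_value: float
    effect_pct: float | None = None
    gene_id: str | None = None
    category: str | None = None
    pathway: str | None = None
    qtn: str | None = None


@dataclass
class AlleleEffect:
    """Major-vs-minor allele-group comparison for one SNP and trait."""

    snp_id: str
    trait: str
    mean_major: float
    mean_minor: float
    t_stat: float
    p_value: float
    effect_pct: float
    n_major: int
    n_minor: int


def qtn_name(trait: str, seqname: str, rank: int) -> str:
    """QTN label q⟨TraitAbbrev⟩⟨chrom⟩.⟨rank⟩, e.g. qSC10.1."""
    import re

    m = re.search(r"(\d+)", seqname)
    chrom = str(int(m.group(1))) if m else seqname
    abbrev = TRAIT_ABBREV.get(trait, trait[:2].upper())
    return f"q{abbrev}{chrom}.{rank}"


# ------------------------------------------------------------- filters
def assoc_snp_filter(
    vt: VariantTable,
    phenotyped_samples: Sequence[str],
    maf: float = 0.05,
    max_missing_rate: float = 0.20,
) -> VariantTable:
    """Gate SNPs on MAF ≥ ``maf`` (inclusive) and missing rate < 20 %.

    Both statistics are computed among the phenotyped samples only.
    """
    shared = [s for s in phenotyped_samples if s in set(vt.samples)]
    if not shared:
        raise ValueError("no phenotyped sample intersects the genotyped panel")
    sub = vt.subset_samples(shared)
    site_maf = sub.maf()
    # direct fraction (not 1 - call_rate) so the strict boundary is exact
    missing = np.any(sub.genotypes < 0, axis=2).mean(axis=1)
    keep = (~np.isnan(site_maf)) & (site_maf >= maf) & (missing < max_missing_rate)
    return vt.subset_sites(keep)


def phenotype_means(
    phenotypes: pd.DataFrame, trait: str, location: str
) -> pd.Series:
    """Per-sample trait mean at one location (replicates averaged)."""
    sub = phenotypes[
        (phenotypes["trait"] == trait) & (phenotypes["location"] == location)
    ]
    return sub.groupby("sample")["value"].mean()


# ----------------------------------------------------------------- GLM
def _anova_p(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effect F-test; constant response gives F=0, p=1."""
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):
        return 0.0, 1.0
    return float(f), float(p)


def glm_association(
    vt: VariantTable,
    phenotypes: pd.DataFrame,
    trait: str,
    location: str,
    p_max: float = 0.001,
    encoding: str = "factor",
    annotation: Mapping[str, Mapping] | None = None,
) -> list[AssociationHit]:
    """Per-SNP GLM of one trait at one location; retain P ≤ ``p_max``.

    With the default factor encoding each genotype class (hom-ref, het,
    hom-alt) is a level and empty classes are dropped; ``encoding=
    "dosage"`` instead fits a linear regression on allele count.  An
    optional ``annotation`` map (snp_id → dict with gene_id/category/
    pathway) decorates retained hits, and QTN names are assigned per
    (trait, chromosome) in p-value order.
    """
    y_by_sample = phenotype_means(phenotypes, trait, location)
    if y_by_sample.nunique() < 3:
        raise ValueError(
            f"fewer than 3 distinct phenotype values for {trait}@{location}"
        )
    shared = [s for s in vt.samples if s in y_by_sample.index]
    sub = vt.subset_samples(shared)
    y = y_by_sample.loc[shared].to_numpy(dtype=float)
    dosage = sub.dosage()

    hits: list[AssociationHit] = []
    ids = sub.site_ids()
    for i in range(sub.n_sites):
        d = dosage[i]
        ok = ~np.isnan(d)
        if ok.sum() < 3:
            continue
        di, yi = d[ok], y[ok]
        if encoding == "factor":
            groups = [yi[di == lvl] for lvl in np.unique(di)]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2:
                continue
            _, p = _anova_p(groups)
        elif encoding == "dosage":
            if np.ptp(di) == 0:
                continue
            res = stats.linregress(di, yi)
            p = float(res.pvalue)
        else:
            raise ValueError(f"unknown encoding {encoding!r}")
        if p <= p_max:
            n, alt = sub.subset_sites([i]).allele_counts()
            alt_freq = alt[0] / n[0] if n[0] else np.nan
            major, minor = (
                (sub.ref[i], sub.alts[i][0])
                if alt_freq <= 0.5
                else (sub.alts[i][0], sub.ref[i])
            )
            hit = AssociationHit(
                snp_id=ids[i],
                trait=trait,
                location=location,
                seqname=str(sub.seqnames[i]),
                pos=int(sub.pos[i]),
                major=str(major),
                minor=str(minor),
                p_value=p,
            )
            try:
                # single-site view keeps the effect computation O(n)
                eff = allele_effect(sub.subset_sites([i]), y_by_sample, ids[i], trait)
                hit.effect_pct = eff.effect_pct
            except ValueError:
                pass
            if annotation and ids[i] in annotation:
                ann = annotation[ids[i]]
                hit.gene_id = ann.get("gene_id")
                hit.category = ann.get("category")
                hit.pathway = ann.get("pathway")
            hits.append(hit)

    # QTN naming per (trait, chromosome), ranked by p-value
    by_chrom: dict[str, list[AssociationHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.seqname, []).append(h)
    for chrom, group in by_chrom.items():
        for rank, h in enumerate(sorted(group, key=lambda h: h.p_value), 1):
            h.qtn = qtn_name(trait, chrom, rank)
    return hits


# -------------------------------------------------------- allele effect
def allele_effect(
    vt: VariantTable,
    phenotype_by_sample: pd.Series | Mapping[str, float],
    snp: str,
    trait: str = "",
) -> AlleleEffect:
    """Two-tailed t-test between major-homozygote and minor-carrier groups.

    effect % = 100 × (mean(minor group) − mean(major group)) /
    |mean(major group)|, sign preserved.
    """
    ids = vt.site_ids()
    try:
        i = ids.index(snp)
    except ValueError:
        raise KeyError(f"SNP {snp} not in table") from None
    y = pd.Series(phenotype_by_sample)
    shared = [s for s in vt.samples if s in y.index]
    cols = [vt.samples.index(s) for s in shared]
    d = vt.dosage()[i, cols]
    vals = y.loc[shared].to_numpy(dtype=float)
    ok = ~np.isnan(d) & ~np.isnan(vals)
    d, vals = d[ok], vals[ok]
    n, alt = vt.allele_counts()
    alt_freq = alt[i] / n[i]
    minor_is_alt = alt_freq <= 0.5
    major_mask = (d == 0) if minor_is_alt else (d == 2)
    g_major, g_minor = vals[major_mask], vals[~major_mask]
    if len(g_major) < 2 or len(g_minor) < 2:
        raise ValueError(
            f"allele group with <2 samples at {snp} "
            f"(major n={len(g_major)}, minor n={len(g_minor)})"
        )
    if np.ptp(g_major) == 0 and np.ptp(g_minor) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(g_minor, g_major)
    mean_major, mean_minor = float(g_major.mean()), float(g_minor.mean())
    if mean_major == 0:
        effect = np.nan
    else:
        effect = 100.0 * (mean_minor - mean_major) / abs(mean_major)
    return AlleleEffect(
        snp_id=snp,
        trait=trait,
        mean_major=mean_major,
        mean_minor=mean_minor,
        t_stat=float(t),
        p_value=float(p),
        effect_pct=float(effect),
        n_major=len(g_major),
        n_minor=len(g_minor),
    )


# ------------------------------------------------- expression-by-allele
def expression_by_allele(
    expression: pd.DataFrame,
    vt: VariantTable,
    snp: str,
    gene: str,
    fold_threshold: float = 2.0,
) -> dict:
    """Compare a gene's expression between allele classes at one SNP.

    Per sample the TPM replicates are averaged and transformed as
    log2(mean + 1); the fold change is the ratio of allele-group means
    of the untransformed per-sample means (larger over smaller), and the
    gene is flagged when it reaches ``fold_threshold``.
    """
    sub = expression[expression["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene} absent from expression table")
    counts = sub.groupby("sample")["tpm"].count()
    expected = counts.max()
    if (counts < expected).any():
        warnings.warn(
            f"missing replicates for {gene}; averaging over available"
        )
    means = sub.groupby("sample")["tpm"].mean()
    ids = vt.site_ids()
    i = ids.index(snp)
    d = vt.dosage()[i]
    groups: dict[str, list[float]] = {}
    for j, s in enumerate(vt.samples):
        if s not in means.index or np.isnan(d[j]):
            continue
        ref, alt = str(vt.ref[i]), str(vt.alts[i][0])
        dos = int(d[j])
        label = {0: f"{ref}/{ref}", 1: f"{ref}/{alt}", 2: f"{alt}/{alt}"}[dos]
        groups.setdefault(label, []).append(float(means[s]))
    summary = {
        label: {
            "n": len(v),
            "mean_tpm": float(np.mean(v)),
            "log2_mean_plus1": float(np.log2(np.mean(v) + 1.0)),
        }
        for label, v in groups.items()
    }
    group_means = [g["mean_tpm"] for g in summary.values()]
    if len(group_means) >= 2 and min(group_means) > 0:
        fold = max(group_means) / min(group_means)
    elif len(group_means) >= 2:
        fold = np.inf if max(group_means) > 0 else 1.0
    else:
        fold = 1.0
    return {
        "gene": gene,
        "snp_id": snp,
        "groups": summary,
        "fold_change": float(fold),
        "flagged": bool(fold >= fold_threshold),
    }


# ------------------------------------------------------ cross-reference
def cross_reference_selection(
    hits: Iterable[AssociationHit],
    outlier_genes_by_pair: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Genes found by BOTH the association and the Fst-outlier scans.

    Each row lists the gene, the traits it was associated with, and the
    cluster pairs whose outlier windows contain it.
    """
    gene_pairs: dict[str, set[str]] = {}
    for pair, genes in outlier_genes_by_pair.items():
        for g in genes:
            gene_pairs.setdefault(g, set()).add(pair)
    rows: dict[str, dict] = {}
    for h in hits:
        if h.gene_id and h.gene_id in gene_pairs:
            row = rows.setdefault(
                h.gene_id,
                {"gene_id": h.gene_id, "traits": set(), "pairs": gene_pairs[h.gene_id]},
            )
            row["traits"].add(h.trait)
    out = [
        {
            "gene_id": r["gene_id"],
            "traits": ",".join(sorted(r["traits"])),
            "pairs": ",".join(sorted(r["pairs"])),
        }
        for r in rows.values()
    ]
    return pd.DataFrame(out, columns=["gene_id", "traits", "pairs"])
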