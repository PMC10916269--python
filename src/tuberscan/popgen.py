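"""Nucleotide diversity, pairwise windowed Weir–Cockerham Fst, and the
distribution-fit quantile outlier scan.

The site-level estimator is the Weir & Cockerham (1984) two-level
analysis of variance with variance components ``a`` (among populations),
``b`` (among individuals within populations) and ``c`` (within
individuals); the per-site estimate is ``a/(a+b+c)`` and the windowed
estimate is the ratio of sums over all sites in a window, which is the
standard "weighted" form.

Window values are then fitted by maximum likelihood with four candidate
families (Weibull, normal, lognormal, gamma), the family with the lowest
AIC is retained, and windows at or above the fitted distribution's
``q``-quantile (default 0.95, i.e. the top 5 %) are declared outliers.
Genes overlapping outlier windows are the selection candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, VariantTable

__all__ = [
    "FstComponents",
    "DistributionFit",
    "OutlierSet",
    "site_pi",
    "wc_fst_sites",
    "pairwise_fst",
    "windowed_fst",
    "fit_fst_distribution",
    "outlier_cutoff",
    "select_outlier_windows",
    "intersect_outliers_with_genes",
    "common_regions",
    "enrichment_test",
]


# ------------------------------------------------------------------- π
def site_pi(vt: VariantTable) -> pd.DataFrame:
    """Per-site nucleotide diversity π = c_ref·c_alt / C(n, 2).

    ``n`` counts non-missing alleles at the site.  Sites with fewer than
    two called alleles are skipped with a warning.  The returned frame
    has columns seqname, pos, n_alleles, pi; the mean over sites is
    ``df["pi"].mean()`` and a per-bp mean is that sum divided by any
    stated denominator.
    """
    n, alt = vt.allele_counts()
    ref = n - alt
    usable = n >= 2
    if np.any(~usable):
        warnings.warn(f"{int((~usable).sum())} sites with <2 called alleles skipped")
    pairs = n * (n - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = (ref * alt) / pairs
    return pd.DataFrame(
        {
            "seqname": vt.seqnames[usable],
            "pos": vt.pos[usable],
            "n_alleles": n[usable],
            "pi": pi[usable],
        }
    )


# ------------------------------------------------------- WC 1984 theta
def _pop_stats(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_i, p_i, h_i) per site for one population's genotype block.

    ``n_i`` is the number of fully called diploids, ``p_i`` the alt
    allele frequency, ``h_i`` the observed heterozygote frequency.
    """
    called = np.all(gt >= 0, axis=2)
    n = called.sum(axis=1).astype(float)
    alt = np.where(called[:, :, None], gt, 0).sum(axis=(1, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
    het = (called & (gt[:, :, 0] != gt[:, :, 1])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = het / n
    return n, p, h


def wc_fst_sites(
    vt: VariantTable,
    cluster_a: Sequence[str],
    cluster_b: Sequence[str],
) -> pd.DataFrame:
    """Weir–Cockerham (1984) variance components per site for one pair.

    Returns a frame with columns seqname, pos, a, b, c, theta.  Sites
    where either cluster has fewer than two called genotypes, or that
    are monomorphic across both clusters, are excluded.
    """
    a_set, b_set = set(cluster_a), set(cluster_b)
    if not a_set or not b_set:
        raise ValueError("both clusters must be non-empty")
    if a_set & b_set:
        raise ValueError(f"clusters overlap: {sorted(a_set & b_set)}")
    idx = {s: j for j, s in enumerate(vt.samples)}
    ga = vt.genotypes[:, [idx[s] for s in cluster_a], :]
    gb = vt.genotypes[:, [idx[s] for s in cluster_b], :]

    r = 2.0
    n1, p1, h1 = _pop_stats(ga)
    n2, p2, h2 = _pop_stats(gb)
    usable = (n1 >= 2) & (n2 >= 2)
    total_alt = np.where(usable, 2 * n1 * p1 + 2 * n2 * p2, 0.0)
    total_n = 2 * (n1 + n2)
    polymorphic = usable & (total_alt > 0) & (total_alt < total_n)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)

    keep = polymorphic & (denom != 0)
    return pd.DataFrame(
        {
            "seqname": vt.seqnames[keep],
            "pos": vt.pos[keep],
            "a": a[keep],
            "b": b[keep],
            "c": c[keep],
            "theta": theta[keep],
        }
    )


def pairwise_fst(
    vt: VariantTable, clusters: Mapping[str, Sequence[str]]
) -> dict[str, pd.DataFrame]:
    """Site components for every unordered cluster pair (label "A_vs_B")."""
    labels = sorted(clusters)
    if len(labels) < 2:
        raise ValueError(
            f"need at least two clusters for pairwise Fst, got {len(labels)}"
        )
    out = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            out[f"{la}_vs_{lb}"] = wc_fst_sites(vt, clusters[la], clusters[lb])
    return out


# ------------------------------------------------------------- windows
def windowed_fst(
    components: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = 50_000,
    step: int = 10_000,
    min_variants: int = 1,
    pair: str = "",
) -> pd.DataFrame:
    """Weighted Fst = Σa/Σ(a+b+c) in sliding windows anchored at 1.

    Windows advance by ``step`` and are emitted only when they contain at
    least ``min_variants`` sites.  A chromosome shorter than the window
    yields a single truncated window flagged in the ``truncated`` column.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = components[components["seqname"] == chrom]
        pos = np.sort(sub["pos"].to_numpy())
        order = np.argsort(sub["pos"].to_numpy())
        a = sub["a"].to_numpy()[order]
        abc = (sub["a"] + sub["b"] + sub["c"]).to_numpy()[order]
        if length < window:
            starts = [1]
            truncated = True
        else:
            starts = range(1, length - window + 2, step)
            truncated = False
        for start in starts:
            end = min(start + window - 1, length)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            nv = hi - lo
            if nv < min_variants or nv == 0:
                continue
            denom = abc[lo:hi].sum()
            rows.append(
                {
                    "seqname": chrom,
                    "start": start,
                    "end": end,
                    "n_variants": int(nv),
                    "weighted_fst": a[lo:hi].sum() / denom if denom else np.nan,
                    "pair": pair,
                    "truncated": truncated,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "seqname", "start", "end", "n_variants", "weighted_fst", "pair",
            "truncated",
        ],
    )


# -------------------------------------------------- distribution fits
@dataclass(frozen=True)
class DistributionFit:
    """A maximum-likelihood fit of one candidate family (k = 2 params)."""

    family: str
    params: tuple[float, ...]
    loglik: float
    aic: float
    n_obs: int

    def frozen(self):
        """The scipy frozen distribution for quantile evaluation."""
        if self.family == "weibull":
            return stats.weibull_min(self.params[0], loc=0, scale=self.params[1])
        if self.family == "normal":
            return stats.norm(self.params[0], self.params[1])
        if self.family == "lognormal":
            return stats.lognorm(self.params[0], loc=0, scale=self.params[1])
        if self.family == "gamma":
            return stats.gamma(self.params[0], loc=0, scale=self.params[1])
        raise ValueError(self.family)


FAMILIES = ("weibull", "normal", "lognormal", "gamma")


def fit_fst_distribution(
    values: Iterable[float], min_n: int = 30
) -> tuple[list[DistributionFit], DistributionFit]:
    """Fit all four families by MLE and pick the lowest-AIC one.

    Non-positive values are excluded before fitting the positive-support
    families (Weibull, lognormal, gamma); the normal fit uses every
    value.  AIC = 2k − 2·logL with k = 2 for each family (no location
    parameter is fitted).  Raises when fewer than ``min_n`` positive
    values remain — fall back to an empirical quantile in that case.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    pos = x[x > 0]
    if len(pos) < min_n:
        raise ValueError(
            f"only {len(pos)} positive values (< {min_n}); "
            "use an empirical quantile instead of a parametric fit"
        )
    fits: list[DistributionFit] = []

    shape, _, scale = stats.weibull_min.fit(pos, floc=0)
    ll = stats.weibull_min.logpdf(pos, shape, loc=0, scale=scale).sum()
    fits.append(DistributionFit("weibull", (shape, scale), ll, 4 - 2 * ll, len(pos)))

    mu, sigma = float(np.mean(x)), float(np.std(x))
    ll = stats.norm.logpdf(x, mu, sigma).sum()
    fits.append(DistributionFit("normal", (mu, sigma), ll, 4 - 2 * ll, len(x)))

    logs = np.log(pos)
    mu_l, s_l = float(np.mean(logs)), float(np.std(logs))
    ll = stats.lognorm.logpdf(pos, s_l, loc=0, scale=np.exp(mu_l)).sum()
    fits.append(
        DistributionFit("lognormal", (s_l, float(np.exp(mu_l))), ll, 4 - 2 * ll, len(pos))
    )

    shape, _, scale = stats.gamma.fit(pos, floc=0)
    ll = stats.gamma.logpdf(pos, shape, loc=0, scale=scale).sum()
    fits.append(DistributionFit("gamma", (shape, scale), ll, 4 - 2 * ll, len(pos)))

    best = min(fits, key=lambda f: f.aic)
    return fits, best


def outlier_cutoff(fit: DistributionFit, q: float = 0.95) -> float:
    """Inverse-CDF cutoff at quantile ``q`` of the fitted family."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    return float(fit.frozen().ppf(q))


def select_outlier_windows(windows: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Windows with weighted Fst at or above the cutoff (inclusive)."""
    return windows[windows["weighted_fst"] >= cutoff].reset_index(drop=True)


@dataclass
class OutlierSet:
    """Outlier windows for one cluster pair plus overlapping genes."""

    pair: str
    cutoff: float
    windows: pd.DataFrame
    genes: list[str] = field(default_factory=list)


# --------------------------------------------------- gene intersection
def intersect_outliers_with_genes(
    outliers: OutlierSet, genes: Sequence[GeneModel]
) -> list[str]:
    """Deduplicated genes with ≥1 bp overlap with any outlier window."""
    win = outliers.windows
    win_chroms = set(win["seqname"])
    gene_chroms = {g.seqname for g in genes}
    if win_chroms and gene_chroms and not (win_chroms & gene_chroms):
        raise ValueError(
            "no shared sequence names between windows and genes: "
            f"windows on {sorted(win_chroms)}, genes on {sorted(gene_chroms)}"
        )
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, row in win.iterrows():
        by_chrom.setdefault(row["seqname"], []).append((row["start"], row["end"]))
    hits = []
    seen = set()
    for g in genes:
        for s, e in by_chrom.get(g.seqname, ()):
            if g.start <= e and g.end >= s and g.gene_id not in seen:
                hits.append(g.gene_id)
                seen.add(g.gene_id)
                break
    outliers.genes = hits
    return hits


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def common_regions(
    outlier_sets: Sequence[OutlierSet],
) -> list[tuple[str, int, int]]:
    """Maximal intervals covered by ≥1 outlier window from EVERY pair.

    Each pair's windows are first merged into a union of intervals per
    sequence; the unions are then intersected across pairs, and any
    touching or overlapping results are merged and counted once.
    """
    if not outlier_sets:
        return []
    unions: list[dict[str, list[tuple[int, int]]]] = []
    for oset in outlier_sets:
        per: dict[str, list[tuple[int, int]]] = {}
        for _, row in oset.windows.iterrows():
            per.setdefault(row["seqname"], []).append((row["start"], row["end"]))
        unions.append({c: _merge(ivs) for c, ivs in per.items()})
    chroms = set(unions[0])
    for u in unions[1:]:
        chroms &= set(u)
    out = []
    for chrom in sorted(chroms):
        acc = unions[0][chrom]
        for u in unions[1:]:
            acc = _intersect(acc, u[chrom])
        for s, e in _merge(acc):
            out.append((chrom, s, e))
    return out


# ---------------------------------------------------------- enrichment
def enrichment_test(
    gene_set: Iterable[str],
    background: Iterable[str],
    term_annotation: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment per term with BH adjustment.

    For a background of ``M`` genes of which ``K`` carry the term, and a
    selection of ``N`` genes of which ``k`` carry it, the p-value is
    P(X ≥ k) for X ~ Hypergeom(M, K, N).  Terms with no annotated gene
    in the background are skipped with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    sel = set(gene_set)
    bg = set(background)
    if not sel <= bg:
        raise ValueError("gene set must be a subset of the background")
    rows = []
    for term, genes in term_annotation.items():
        annotated = set(genes) & bg
        if not annotated:
            warnings.warn(f"term {term!r} absent from background; skipped")
            continue
        k = len(annotated & sel)
        p = float(stats.hypergeom.sf(k - 1, len(bg), len(annotated), len(sel)))
        rows.append({"term": term, "k": k, "K": len(annotated), "p": p})
    df = pd.DataFrame(rows, columns=["term", "k", "K", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    return df
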