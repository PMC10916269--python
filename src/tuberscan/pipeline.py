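"""End-to-end orchestration: simulate → QC → Fst scan → pathways →
association → expression → cross-reference.

``run_pipeline`` wires the module operations together on a synthetic
dataset and returns every intermediate product, so the same code path
serves the command-line interface, the end-to-end tests and the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import pathways as pathways_mod
from . import popgen, synthdata, variants
from .core import VariantTable, snp_id
from .synthdata import AnnotationBundle, QtnSpec, SimConfig, TruthSet

__all__ = ["PipelineResult", "simulate_all", "run_pipeline"]


@dataclass
class PipelineResult:
    config: SimConfig
    vt_raw: VariantTable
    vt_qc: VariantTable
    vt_popgen: VariantTable
    clusters: dict
    truth: TruthSet
    bundle: AnnotationBundle
    phenotypes: pd.DataFrame
    expression: pd.DataFrame
    pi: pd.DataFrame
    fst_components: dict
    fst_windows: dict
    fits: dict
    cutoffs: dict
    outlier_sets: dict
    outlier_genes: dict
    common: list
    pathway_genes: dict
    candidate_snps: pd.DataFrame
    hits: list
    cross_ref: pd.DataFrame
    expression_report: dict | None


def _harmonise_refs(
    vt: VariantTable, genome: Mapping[str, str], seed: int
) -> VariantTable:
    """Re-label ref/alt bases so refs agree with the generated genome.

    Allele indices in the genotype matrix are positional, so renaming
    the bases never changes any statistic downstream.
    """
    rng = np.random.default_rng((seed, 3))
    ref = vt.ref.copy()
    alts = list(vt.alts)
    pick = rng.integers(0, 3, size=vt.n_sites)
    for i in range(vt.n_sites):
        base = genome[vt.seqnames[i]][vt.pos[i] - 1].upper()
        if ref[i] != base:
            ref[i] = base
        if alts[i][0] == base:
            others = [b for b in "ACGT" if b != base]
            alts[i] = (others[pick[i]],)
    return VariantTable(
        seqnames=vt.seqnames, pos=vt.pos, ref=ref, alts=alts, qual=vt.qual,
        genotypes=vt.genotypes, depth=vt.depth, samples=list(vt.samples),
    )


def simulate_all(config: SimConfig):
    """Generate a fully coordinated synthetic dataset.

    Runs the population simulation, anchors the annotation on the
    planted selected loci, resolves any QTN whose site index is None to
    the anchor gene's splice-donor site, harmonises reference alleles
    with the genome, and simulates phenotypes and expression.
    """
    vt, clusters, truth = synthdata.simulate_population(config)
    bundle = synthdata.simulate_annotation_and_orthogroups(
        config, truth=truth, variant_sites=(vt.seqnames, vt.pos)
    )
    vt = _harmonise_refs(vt, bundle.genome, config.seed)

    if truth.anchor_gene_id is not None:
        anchor = next(
            g for g in bundle.genes if g.gene_id == truth.anchor_gene_id
        )
        donor_pos = anchor.start + synthdata.DONOR_OFFSET
        anchor_sid = snp_id(anchor.seqname, donor_pos)
        for q in config.qtn_spec:
            if q.site_index is None:
                truth.qtn_effects[anchor_sid] = (q.trait, q.effect)

    gene_ids = sorted(
        {g.gene_id for g in bundle.genes if g.attributes.get("ec_number")}
        | truth.orthology_only_gene_ids
    )
    phenotypes, expression = synthdata.simulate_phenotypes_and_expression(
        vt, truth, config, gene_ids=gene_ids
    )
    return vt, clusters, truth, bundle, phenotypes, expression


def run_pipeline(
    config: SimConfig | None = None,
    seed: int = 0,
    q: float = 0.95,
    p_max: float = 0.001,
) -> PipelineResult:
    """Run the whole analysis chain on a synthetic dataset."""
    if config is None:
        config = SimConfig(
            seed=seed,
            qtn_spec=[QtnSpec(None, "starch_content", 3.0)],
        )
    vt, clusters, truth, bundle, phenotypes, expression = simulate_all(config)

    vt_qc = variants.filter_variants(vt)
    vt_pg = variants.popgen_site_filter(vt_qc)
    pi = popgen.site_pi(vt_pg)

    components = popgen.pairwise_fst(vt_pg, clusters)
    windows, fits, cutoffs, outlier_sets, outlier_genes = {}, {}, {}, {}, {}
    for pair, comp in components.items():
        win = popgen.windowed_fst(comp, config.chrom_lengths, pair=pair)
        windows[pair] = win
        all_fits, best = popgen.fit_fst_distribution(win["weighted_fst"])
        fits[pair] = best
        cut = popgen.outlier_cutoff(best, q)
        cutoffs[pair] = cut
        oset = popgen.OutlierSet(
            pair=pair, cutoff=cut,
            windows=popgen.select_outlier_windows(win, cut),
        )
        outlier_sets[pair] = oset
        outlier_genes[pair] = popgen.intersect_outliers_with_genes(
            oset, bundle.genes
        )
    common = popgen.common_regions(list(outlier_sets.values()))

    pathway_genes = {}
    for pw in bundle.catalog:
        seeds = pathways_mod.keyword_retrieval(bundle.genes, bundle.catalog, pw)
        pathway_genes[pw] = pathways_mod.orthogroup_expansion(
            seeds, bundle.og_table, synthdata.FOCAL_SPECIES
        )

    pathway_gene_ids = {
        g.gene_id for genes in pathway_genes.values() for g in genes
    }
    in_pathway = [
        g for g in bundle.genes if g.gene_id in pathway_gene_ids
    ]
    span_mask = np.zeros(vt_qc.n_sites, dtype=bool)
    for g in in_pathway:
        span_mask |= (
            (vt_qc.seqnames == g.seqname)
            & (vt_qc.pos >= g.start)
            & (vt_qc.pos <= g.end)
        )
    consequences = variants.classify_variants(
        vt_qc.subset_sites(span_mask), in_pathway, bundle.genome
    )
    candidate_snps = pathways_mod.candidate_snp_extraction(
        consequences, pathway_genes
    )

    hits = []
    if len(candidate_snps):
        cand_ids = set(candidate_snps["snp_id"])
        cand_mask = np.array([sid in cand_ids for sid in vt_qc.site_ids()])
        vt_cand = vt_qc.subset_sites(cand_mask)
        phen_samples = phenotypes["sample"].unique().tolist()
        vt_tested = assoc_mod.assoc_snp_filter(vt_cand, phen_samples)
        annotation = {
            row.snp_id: {
                "gene_id": row.gene_id,
                "category": row.category,
                "pathway": row.pathway,
            }
            for row in candidate_snps.itertuples(index=False)
        }
        if vt_tested.n_sites:
            for trait in phenotypes["trait"].unique():
                for loc in config.locations:
                    hits.extend(
                        assoc_mod.glm_association(
                            vt_tested, phenotypes, trait, loc,
                            p_max=p_max, annotation=annotation,
                        )
                    )

    cross_ref = assoc_mod.cross_reference_selection(hits, outlier_genes)

    expression_report = None
    if truth.expression_allele_gene and truth.expression_allele_snp:
        sid_index = {s: i for i, s in enumerate(vt.site_ids())}
        if truth.expression_allele_snp in sid_index:
            expression_report = assoc_mod.expression_by_allele(
                expression, vt, truth.expression_allele_snp,
                truth.expression_allele_gene,
            )

    return PipelineResult(
        config=config, vt_raw=vt, vt_qc=vt_qc, vt_popgen=vt_pg,
        clusters=clusters, truth=truth, bundle=bundle,
        phenotypes=phenotypes, expression=expression, pi=pi,
        fst_components=components, fst_windows=windows, fits=fits,
        cutoffs=cutoffs, outlier_sets=outlier_sets,
        outlier_genes=outlier_genes, common=common,
        pathway_genes=pathway_genes, candidate_snps=candidate_snps,
        hits=hits, cross_ref=cross_ref, expression_report=expression_report,
    )
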