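"""Pathway gene retrieval by EC keyword and orthogroup expansion.

A pathway is a set of Enzyme Commission (EC) codes.  Retrieval first
collects the focal-species genes whose annotation carries one of those
codes (the "keyword" route), then expands the set with every
focal-species gene sharing an orthogroup with a retrieved gene (the
"orthology" route) — this is how unannotated paralogs are pulled into a
pathway.  Presence/absence tallies across species reproduce UpSet-style
intersection counts over orthogroups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import Consequence, GeneModel

__all__ = [
    "PathwayGene",
    "keyword_retrieval",
    "orthogroup_expansion",
    "presence_absence",
    "candidate_snp_extraction",
]

_EC_GRAMMAR = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")

#: Genomic locations counted as the transcribed unit of a gene.
TRANSCRIBED = {"stop_gained", "stop_lost", "start_lost",
               "splice_acceptor_variant", "splice_donor_variant",
               "missense", "synonymous", "intron", "5'UTR", "3'UTR"}


@dataclass
class PathwayGene:
    """A retrieved gene with its provenance and inherited EC labels."""

    gene_id: str
    pathway: str
    provenance: str  # "keyword" or "orthology"
    ecs: set[str] = field(default_factory=set)


def _ec_matches(gene_ec: str, catalog_ec: str) -> bool:
    """Exact match on full codes; prefix match for dash-terminated ones."""
    if "-" in catalog_ec:
        prefix = catalog_ec.split("-")[0]
        return gene_ec.startswith(prefix)
    return gene_ec == catalog_ec


def keyword_retrieval(
    genes: Sequence[GeneModel],
    catalog: Mapping[str, set[str]],
    pathway: str,
) -> list[PathwayGene]:
    """Genes whose EC annotation intersects the pathway's EC set."""
    if pathway not in catalog:
        raise KeyError(
            f"unknown pathway {pathway!r}; available: {sorted(catalog)}"
        )
    wanted = catalog[pathway]
    for ec in wanted:
        if not _EC_GRAMMAR.match(ec):
            raise ValueError(f"malformed EC code {ec!r} in pathway {pathway}")
    out = []
    for g in genes:
        hit = {
            gec
            for gec in g.ec_numbers()
            for cec in wanted
            if _ec_matches(gec, cec)
        }
        if hit:
            out.append(PathwayGene(g.gene_id, pathway, "keyword", hit))
    return out


def orthogroup_expansion(
    seeds: Sequence[PathwayGene],
    og_table: Mapping[str, Mapping[str, Sequence[str]]],
    focal_species: str,
) -> list[PathwayGene]:
    """Union of seeds and focal-species co-members of their orthogroups.

    Added genes inherit the union of the EC labels of the seed genes in
    their orthogroup and are labelled provenance "orthology"; a gene
    retrieved by both routes keeps the "keyword" label.  Seeds missing
    from the table are kept as singletons.
    """
    gene_to_og: dict[str, str] = {}
    for og, species in og_table.items():
        for gid in species.get(focal_species, ()):
            gene_to_og[gid] = og
    by_id: dict[str, PathwayGene] = {s.gene_id: s for s in seeds}
    for seed in seeds:
        og = gene_to_og.get(seed.gene_id)
        if og is None:
            continue  # singleton: not in any orthogroup
        for gid in og_table[og].get(focal_species, ()):
            if gid in by_id:
                by_id[gid].ecs |= seed.ecs
            else:
                by_id[gid] = PathwayGene(
                    gid, seed.pathway, "orthology", set(seed.ecs)
                )
    return list(by_id.values())


def presence_absence(
    og_table: Mapping[str, Mapping[str, Sequence[str]]],
    species: Sequence[str],
) -> tuple[pd.DataFrame, dict[frozenset, int], int]:
    """Binary OG×species matrix plus UpSet-style intersection tallies.

    Returns the matrix, a map from each species combination to the count
    of orthogroups present in *exactly* that combination, and the count
    shared by all species.  Orthogroups absent from every listed species
    are dropped.
    """
    if len(species) < 1:
        raise ValueError("at least one species required")
    known = {sp for og in og_table.values() for sp in og}
    missing = [sp for sp in species if sp not in known]
    if missing:
        raise ValueError(f"species absent from orthogroup table: {missing}")
    rows = {}
    for og, members in og_table.items():
        row = [1 if members.get(sp) else 0 for sp in species]
        if any(row):
            rows[og] = row
    matrix = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(species)
    ).sort_index()
    tallies: dict[frozenset, int] = {}
    for og, row in matrix.iterrows():
        combo = frozenset(sp for sp in species if row[sp])
        tallies[combo] = tallies.get(combo, 0) + 1
    shared_all = tallies.get(frozenset(species), 0)
    return matrix, tallies, shared_all


def candidate_snp_extraction(
    consequences: Iterable[Consequence],
    pathway_genes: Mapping[str, Sequence[PathwayGene]],
    impact_set: set[str] | frozenset[str] | None = None,
) -> pd.DataFrame:
    """Per-pathway tables of high-impact SNPs inside pathway genes.

    A SNP qualifies when its host gene belongs to the pathway set, its
    location is within the transcribed unit (CDS, intron, 5'/3' UTR —
    up/downstream SNPs are excluded) and its category passes the
    high-impact selection.  Provenance labels travel with each row.
    """
    from .variants import select_high_impact
    from .core import HIGH_IMPACT_DEFAULT

    impact_set = set(impact_set) if impact_set is not None else set(HIGH_IMPACT_DEFAULT)
    gene_lookup: dict[str, PathwayGene] = {}
    for pw, genes in pathway_genes.items():
        for g in genes:
            gene_lookup[g.gene_id] = g
    kept = select_high_impact(
        [c for c in consequences if c.category in TRANSCRIBED], impact_set
    )
    rows = []
    for c in kept:
        pg = gene_lookup.get(c.gene_id or "")
        if pg is None:
            continue
        rows.append(
            {
                "snp_id": c.snp_id,
                "seqname": c.seqname,
                "pos": c.pos,
                "gene_id": c.gene_id,
                "pathway": pg.pathway,
                "provenance": pg.provenance,
                "category": c.category,
                "impact": c.impact,
                "protein_notation": c.protein_notation,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "seqname", "pos", "gene_id", "pathway", "provenance",
            "category", "impact", "protein_notation",
        ],
    )
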