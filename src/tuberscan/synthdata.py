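"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates a structured diploid panel in the Balding–Nichols
sense: each site has an ancestral allele frequency drawn from
Uniform(0.05, 0.95) and each cluster draws its own frequency from a Beta
distribution with that mean and a dispersion set by the divergence
parameter F, so that the expected Weir–Cockerham Fst between clusters
tracks F.  Selected loci are planted as contiguous blocks of consecutive
sites simulated at an elevated F, so that sliding windows actually carry
the divergence signal instead of diluting isolated sites.

On top of the genotypes the generator lays down a toy genome with gene
models (two exons, a spliceable intron, UTRs and a translatable ORF),
EC-number annotation for a configurable number of pathway genes, an
orthogroup table in which unannotated paralogs share groups with
annotated ones, quantitative phenotypes with additive QTN effects scaled
to a target narrow-sense heritability, and a TPM expression table with
one gene showing a planted allele-linked fold change.  Everything is a
pure function of the integer seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, VariantTable, snp_id

__all__ = [
    "SimConfig",
    "QtnSpec",
    "TruthSet",
    "AnnotationBundle",
    "simulate_population",
    "simulate_annotation_and_orthogroups",
    "simulate_phenotypes_and_expression",
]

BASES = np.array(list("ACGT"))
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

#: Baseline trait means in their natural units (texture in N or ratios,
#: starch in % dry matter, colour indices dimensionless).
TRAIT_BASELINES = {
    "hardness": 20.0,
    "cohesiveness": 0.55,
    "gumminess": 10.0,
    "springiness": 0.80,
    "total_area": 150.0,
    "starch_content": 77.9,
    "brown_index": 60.0,
    "hue_index": 40.0,
}

SPECIES = ("dalata", "drotundata", "ddumetorum", "dzingiberensis", "tzeylanicus")
FOCAL_SPECIES = "dalata"

# gene template geometry (offsets from the gene start)
_EXON1 = (0, 399)
_EXON2 = (600, 1101)
_CDS1 = (100, 399)
_CDS2 = (600, 1001)
GENE_SPAN = 1102
#: offset of the splice-donor dinucleotide of a plus-strand template gene
DONOR_OFFSET = 400


@dataclass(frozen=True)
class QtnSpec:
    """One planted quantitative trait nucleotide.

    ``site_index`` may be None, meaning "anchor on a selected locus" —
    the pipeline resolves it to the site whose host gene also carries
    planted divergence.
    """

    site_index: int | None
    trait: str
    effect: float
    model: str = "additive"


@dataclass
class SimConfig:
    """Knobs of the generator; defaults mirror the study conditions.

    Three clusters of 36 diploids approximate the 107-diploid panel; the
    background/selected divergence contrast (0.05 vs 0.4) and the
    100 + 48 pathway-gene split reproduce the situations the downstream
    stages are meant to detect.
    """

    n_samples_per_cluster: int = 36
    n_clusters: int = 3
    n_sites: int = 2400
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 600_000}
    )
    background_F: float = 0.05
    selected_F: float = 0.4
    n_selected_loci: int = 90
    n_selected_blocks: int = 3
    qtn_spec: list[QtnSpec] = field(default_factory=list)
    h2: float = 0.7
    seed: int = 0
    n_pathway_genes_annotated: int = 100
    n_pathway_genes_orthology_only: int = 48
    n_background_genes: int = 52
    missing_rate: float = 0.05
    low_qual_rate: float = 0.05
    mean_depth: float = 37.0
    depth_dispersion: float = 10.0
    expression_fold_change: float = 4.0
    n_replicates: int = 3
    locations: tuple[str, ...] = ("Godet", "Roujol", "Duclos")

    def __post_init__(self) -> None:
        for name in (
            "n_samples_per_cluster", "n_clusters", "n_sites",
            "n_selected_blocks", "n_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for fname in ("background_F", "selected_F"):
            f = getattr(self, fname)
            if not 0.0 < f < 1.0:
                raise ValueError(f"{fname} must be in the open interval (0, 1)")
        if self.selected_F <= self.background_F:
            raise ValueError("selected_F must exceed background_F")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must be in (0, 1]")
        if self.n_selected_loci > self.n_sites:
            raise ValueError("n_selected_loci cannot exceed n_sites")
        for q in self.qtn_spec:
            if q.site_index is not None and not 0 <= q.site_index < self.n_sites:
                raise ValueError(f"QTN site index {q.site_index} out of range")


@dataclass
class TruthSet:
    """Ground truth planted by the generator, JSON round-trippable."""

    selected_site_ids: set[str] = field(default_factory=set)
    qtn_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    orthology_only_gene_ids: set[str] = field(default_factory=set)
    expression_allele_gene: str | None = None
    expression_allele_snp: str | None = None
    anchor_gene_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "selected_site_ids": sorted(self.selected_site_ids),
            "qtn_effects": {k: list(v) for k, v in self.qtn_effects.items()},
            "orthology_only_gene_ids": sorted(self.orthology_only_gene_ids),
            "expression_allele_gene": self.expression_allele_gene,
            "expression_allele_snp": self.expression_allele_snp,
            "anchor_gene_id": self.anchor_gene_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TruthSet":
        return cls(
            selected_site_ids=set(d["selected_site_ids"]),
            qtn_effects={k: (v[0], float(v[1])) for k, v in d["qtn_effects"].items()},
            orthology_only_gene_ids=set(d["orthology_only_gene_ids"]),
            expression_allele_gene=d.get("expression_allele_gene"),
            expression_allele_snp=d.get("expression_allele_snp"),
            anchor_gene_id=d.get("anchor_gene_id"),
        )


# ======================================================================
# population
# ======================================================================
def _site_positions(config: SimConfig, rng: np.random.Generator):
    """Sorted 1-based positions per chromosome, proportional to length."""
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    share = lengths / lengths.sum()
    counts = np.floor(share * config.n_sites).astype(int)
    counts[0] += config.n_sites - counts.sum()
    seqnames, positions = [], []
    for chrom, k in zip(chroms, counts):
        pos = np.sort(
            rng.choice(config.chrom_lengths[chrom], size=k, replace=False) + 1
        )
        seqnames.extend([chrom] * k)
        positions.extend(pos.tolist())
    return np.array(seqnames, dtype=object), np.array(positions, dtype=np.int64)


def _selected_blocks(
    config: SimConfig, seqnames: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Site indices of the planted selected loci (contiguous blocks)."""
    n_blocks = min(config.n_selected_blocks, config.n_selected_loci)
    sizes = np.full(n_blocks, config.n_selected_loci // n_blocks)
    sizes[: config.n_selected_loci % n_blocks] += 1
    chroms = list(dict.fromkeys(seqnames))
    per_chrom = {c: np.flatnonzero(seqnames == c) for c in chroms}
    chosen: list[int] = []
    taken: list[tuple[int, int]] = []
    for bi, size in enumerate(sizes):
        chrom = chroms[bi % len(chroms)]
        sites = per_chrom[chrom]
        if len(sites) < size:
            raise ValueError(f"chromosome {chrom} has too few sites for a block")
        for _ in range(200):
            start = int(rng.integers(0, len(sites) - size + 1))
            lo, hi = sites[start], sites[start + size - 1]
            if all(hi < s or lo > e for s, e in taken):
                taken.append((lo, hi))
                chosen.extend(sites[start : start + size].tolist())
                break
        else:  # pragma: no cover - pathological configs only
            raise ValueError("could not place non-overlapping selected blocks")
    return np.array(sorted(chosen), dtype=int)


def simulate_population(
    config: SimConfig, genome: Mapping[str, str] | None = None
) -> tuple[VariantTable, dict[str, list[str]], TruthSet]:
    """Draw a structured diploid panel with planted divergent loci.

    Returns the variant table, the cluster assignment (label → sample
    names) and the truth set.  When a ``genome`` is supplied the
    reference alleles are read from it so that consequence
    classification against the FASTA is consistent.
    """
    rng = np.random.default_rng((config.seed, 0))
    seqnames, positions = _site_positions(config, rng)
    selected = _selected_blocks(config, seqnames, rng)

    F = np.full(config.n_sites, config.background_F)
    F[selected] = config.selected_F

    p_anc = rng.uniform(0.05, 0.95, size=config.n_sites)
    alpha = p_anc * (1.0 - F) / F
    beta = (1.0 - p_anc) * (1.0 - F) / F

    n_per = config.n_samples_per_cluster
    labels = [chr(ord("A") + k) for k in range(config.n_clusters)]
    samples = [f"{lab}{i + 1:02d}" for lab in labels for i in range(n_per)]
    clusters = {
        lab: samples[k * n_per : (k + 1) * n_per] for k, lab in enumerate(labels)
    }

    genotypes = np.empty((config.n_sites, len(samples), 2), dtype=np.int8)
    for k in range(config.n_clusters):
        p_k = rng.beta(alpha, beta)
        draws = rng.random((config.n_sites, n_per, 2)) < p_k[:, None, None]
        genotypes[:, k * n_per : (k + 1) * n_per, :] = draws.astype(np.int8)

    missing = rng.random((config.n_sites, len(samples))) < config.missing_rate
    genotypes[missing] = -1

    r = config.depth_dispersion
    depth = rng.negative_binomial(
        r, r / (r + config.mean_depth), size=(config.n_sites, len(samples))
    ).astype(np.int32)

    qual = rng.gamma(4.0, 150.0, size=config.n_sites)
    low = rng.random(config.n_sites) < config.low_qual_rate
    qual[low] = rng.uniform(10.0, 29.9, size=int(low.sum()))

    ref = np.empty(config.n_sites, dtype=object)
    alts: list[tuple[str, ...]] = []
    alt_choice = rng.integers(0, 3, size=config.n_sites)
    ref_choice = rng.integers(0, 4, size=config.n_sites)
    for i in range(config.n_sites):
        if genome is not None:
            ref[i] = genome[seqnames[i]][positions[i] - 1].upper()
        else:
            ref[i] = BASES[ref_choice[i]]
        others = [b for b in "ACGT" if b != ref[i]]
        alts.append((others[alt_choice[i]],))

    vt = VariantTable(
        seqnames=seqnames,
        pos=positions,
        ref=ref,
        alts=alts,
        qual=qual,
        genotypes=genotypes,
        depth=depth,
        samples=samples,
    )
    truth = TruthSet(
        selected_site_ids={
            snp_id(seqnames[i], positions[i]) for i in selected
        }
    )
    for q in config.qtn_spec:
        if q.site_index is not None:
            sid = snp_id(seqnames[q.site_index], positions[q.site_index])
            truth.qtn_effects[sid] = (q.trait, q.effect)
    return vt, clusters, truth


# ======================================================================
# annotation, orthogroups, pathways
# ======================================================================
@dataclass
class AnnotationBundle:
    genes: list[GeneModel]
    genome: dict[str, str]
    og_table: dict[str, dict[str, list[str]]]
    catalog: dict[str, set[str]]


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _make_gene(gene_id: str, chrom: str, start: int, strand: str) -> GeneModel:
    exons = [
        (start + _EXON1[0], start + _EXON1[1]),
        (start + _EXON2[0], start + _EXON2[1]),
    ]
    cds = [
        (start + _CDS1[0], start + _CDS1[1]),
        (start + _CDS2[0], start + _CDS2[1]),
    ]
    return GeneModel(gene_id, chrom, strand, exons, cds)


def _write_orf(genome: dict[str, list[str]], gene: GeneModel, rng) -> None:
    n_codons = gene.cds_length // 3
    coding = _random_orf(n_codons, rng)
    genomic = coding if gene.strand == "+" else _revcomp(coding)
    off = 0
    seq = genome[gene.seqname]
    for s, e in gene.cds:
        seq[s - 1 : e] = list(genomic[off : off + e - s + 1])
        off += e - s + 1


def simulate_annotation_and_orthogroups(
    config: SimConfig,
    truth: TruthSet | None = None,
    variant_sites: tuple[np.ndarray, np.ndarray] | None = None,
) -> AnnotationBundle:
    """Build the toy genome, gene models, EC catalog and orthogroups.

    Pathway genes are two-exon models with a translatable ORF;
    ``n_pathway_genes_annotated`` carry an ``ec_number`` attribute drawn
    from the pathway catalog, ``n_pathway_genes_orthology_only`` carry
    no EC but share an orthogroup with an annotated gene (and are
    recorded in the truth set).  When ``truth`` and ``variant_sites``
    are given, one annotated gene is anchored so that its splice-donor
    dinucleotide covers a planted selected site, and another annotated
    gene containing a variant site is marked as the allele-linked
    expression gene.
    """
    rng = np.random.default_rng((config.seed, 1))
    genome = {
        chrom: rng.choice(BASES, size=length).tolist()
        for chrom, length in config.chrom_lengths.items()
    }

    n_ann = config.n_pathway_genes_annotated
    n_orth = config.n_pathway_genes_orthology_only
    n_total = n_ann + n_orth + config.n_background_genes

    pitch = GENE_SPAN + 1898  # 3 kb per gene slot
    slots = [
        (chrom, start)
        for chrom, length in config.chrom_lengths.items()
        for start in range(500, length - GENE_SPAN - 500, pitch)
    ]
    genes: list[GeneModel] = []
    counter = itertools.count(1)

    anchor: GeneModel | None = None
    if truth is not None and variant_sites is not None and truth.selected_site_ids:
        seqnames, positions = variant_sites
        ids = [snp_id(c, p) for c, p in zip(seqnames, positions)]
        sel_idx = sorted(
            i for i, sid in enumerate(ids) if sid in truth.selected_site_ids
        )
        mid = sel_idx[len(sel_idx) // 2]
        a_chrom, a_pos = str(seqnames[mid]), int(positions[mid])
        start = a_pos - DONOR_OFFSET
        if start < 1 or start + GENE_SPAN > config.chrom_lengths[a_chrom]:
            raise ValueError("anchor site too close to a chromosome end")
        anchor = _make_gene(
            f"Dal{_chrom_num(a_chrom)}G{next(counter):04d}", a_chrom, start, "+"
        )
        genes.append(anchor)
        truth.anchor_gene_id = anchor.gene_id
        slots = [
            (c, s)
            for c, s in slots
            if c != a_chrom or s + GENE_SPAN < start or s > start + GENE_SPAN
        ]

    if len(slots) < n_total - len(genes):
        raise ValueError(
            f"cannot place {n_total} genes on the configured chromosomes "
            f"({len(slots)} slots available)"
        )
    slot_idx = rng.choice(len(slots), size=n_total - len(genes), replace=False)
    strands = rng.random(n_total) < 0.5
    for j, si in enumerate(np.sort(slot_idx)):
        chrom, start = slots[si]
        genes.append(
            _make_gene(
                f"Dal{_chrom_num(chrom)}G{next(counter):04d}",
                chrom,
                start,
                "+" if strands[j] else "-",
            )
        )
    for g in genes:
        _write_orf(genome, g, rng)

    annotated = genes[:n_ann]
    orthology_only = genes[n_ann : n_ann + n_orth]
    background = genes[n_ann + n_orth :]

    # EC catalog: one synthetic dotted code per annotated gene, pathways
    # assigned round-robin across the three target maps
    pathway_ids = ["map00040", "map00500", "map00941"]
    catalog: dict[str, set[str]] = {pw: set() for pw in pathway_ids}
    for i, g in enumerate(annotated):
        ec = f"{i % 6 + 1}.{i % 9 + 1}.{i % 13 + 1}.{i + 1}"
        pw = pathway_ids[i % 3]
        catalog[pw].add(ec)
        g.attributes["ec_number"] = ec
        g.attributes["pathway"] = pw

    og_table: dict[str, dict[str, list[str]]] = {}
    other_present = rng.random((n_ann + len(background), len(SPECIES) - 1)) < 0.7
    for i, g in enumerate(annotated):
        og = f"OG{i + 1:07d}"
        og_table[og] = {FOCAL_SPECIES: [g.gene_id]}
        for j, sp in enumerate(SPECIES[1:]):
            if other_present[i, j]:
                og_table[og][sp] = [f"{sp}_g{i + 1:04d}"]
    for j, g in enumerate(orthology_only):
        og = f"OG{(j % n_ann) + 1:07d}"
        og_table[og][FOCAL_SPECIES].append(g.gene_id)
        if truth is not None:
            truth.orthology_only_gene_ids.add(g.gene_id)
    for i, g in enumerate(background):
        og = f"OGB{i + 1:06d}"
        og_table[og] = {FOCAL_SPECIES: [g.gene_id]}
        for j, sp in enumerate(SPECIES[1:]):
            if other_present[n_ann + i, j]:
                og_table[og][sp] = [f"{sp}_bg{i + 1:04d}"]

    if truth is not None and variant_sites is not None:
        seqnames, positions = variant_sites
        for g in annotated:
            if anchor is not None and g.gene_id == anchor.gene_id:
                continue
            inside = np.flatnonzero(
                (seqnames == g.seqname) & (positions >= g.start) & (positions <= g.end)
            )
            if len(inside):
                truth.expression_allele_gene = g.gene_id
                truth.expression_allele_snp = snp_id(
                    g.seqname, int(positions[inside[0]])
                )
                break

    return AnnotationBundle(
        genes=genes,
        genome={c: "".join(s) for c, s in genome.items()},
        og_table=og_table,
        catalog=catalog,
    )


def _chrom_num(chrom: str) -> str:
    import re

    m = re.search(r"(\d+)", chrom)
    return f"{int(m.group(1)):02d}" if m else chrom


# ======================================================================
# phenotypes and expression
# ======================================================================
def simulate_phenotypes_and_expression(
    vt: VariantTable,
    truth: TruthSet,
    config: SimConfig,
    gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additive-QTN phenotypes at a target h² plus a TPM table.

    Each trait value is Σ(effect × alt dosage) + baseline + N(0, σ²_e)
    with σ²_e chosen so that genetic variance / total variance equals
    the configured h² per observation; three replicates are drawn per
    sample and location.  The expression table carries replicate TPMs
    for the pathway genes, with the planted gene's minor-allele carriers
    shifted by the configured fold change.
    """
    if not 0.0 < config.h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    rng = np.random.default_rng((config.seed, 2))
    ids = vt.site_ids()
    index_of = {sid: i for i, sid in enumerate(ids)}
    dosage = vt.dosage()

    rows = []
    for trait, baseline in TRAIT_BASELINES.items():
        g = np.zeros(vt.n_samples)
        for sid, (qt_trait, effect) in truth.qtn_effects.items():
            if qt_trait != trait:
                continue
            if sid not in index_of:
                raise ValueError(f"QTN site {sid} absent from genotypes")
            d = dosage[index_of[sid]]
            d = np.where(np.isnan(d), np.nanmean(d), d)
            g = g + effect * d
        var_g = float(np.var(g))
        if var_g > 0:
            sigma_e = float(np.sqrt(var_g * (1.0 - config.h2) / config.h2))
        else:
            sigma_e = 0.05 * abs(baseline)  # null trait: pure noise
        for loc in config.locations:
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(0.0, sigma_e, size=vt.n_samples) if sigma_e else 0.0
                values = baseline + g + noise
                for s, v in zip(vt.samples, np.atleast_1d(values) + np.zeros(vt.n_samples)):
                    rows.append(
                        {
                            "sample": s,
                            "trait": trait,
                            "location": loc,
                            "replicate": rep,
                            "value": float(v),
                        }
                    )
    phenotypes = pd.DataFrame(rows)

    if gene_ids is None:
        gene_ids = sorted(truth.orthology_only_gene_ids)
        if truth.expression_allele_gene:
            gene_ids = sorted(set(gene_ids) | {truth.expression_allele_gene})
    carrier = np.zeros(vt.n_samples, dtype=bool)
    if truth.expression_allele_snp and truth.expression_allele_snp in index_of:
        d = dosage[index_of[truth.expression_allele_snp]]
        carrier = np.nan_to_num(d) >= 1
    expr_rows = []
    for gid in gene_ids:
        base = float(rng.lognormal(3.0, 1.0))
        planted = gid == truth.expression_allele_gene
        for j, s in enumerate(vt.samples):
            level = base * (
                config.expression_fold_change if planted and carrier[j] else 1.0
            )
            for rep in range(1, config.n_replicates + 1):
                expr_rows.append(
                    {
                        "gene": gid,
                        "sample": s,
                        "replicate": rep,
                        "tpm": float(level * rng.lognormal(0.0, 0.1)),
                    }
                )
    expression = pd.DataFrame(expr_rows, columns=["gene", "sample", "replicate", "tpm"])
    return phenotypes, expression
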