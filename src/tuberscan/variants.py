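"""Variant QC filters and SNP consequence classification.

The filters mirror the standard VCFtools-style gates used to clean a
resequencing panel: per-call depth masking (minDP/maxDP), site quality
(minQ), call rate (max-missing), then, for population-genetic work,
restriction to biallelic SNPs, a minor-allele-frequency floor and greedy
positional thinning.

Consequence classification re-implements the usual annotation classes
(stop gained/lost, start lost, splice donor/acceptor, missense,
synonymous, intron, UTRs, up/downstream, intergenic) directly on gene
models and a reference genome, strand-aware, using the standard nuclear
genetic code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .core import (
    HIGH_IMPACT_DEFAULT,
    IMPACT_OF_CATEGORY,
    Consequence,
    GeneModel,
    VariantTable,
    snp_id,
)

__all__ = [
    "FilterThresholds",
    "filter_variants",
    "popgen_site_filter",
    "classify_consequence",
    "classify_variants",
    "select_high_impact",
    "ld_prune",
]

#: Flank size (bp) for the upstream/downstream categories.
FLANK_BP = 5000

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FilterThresholds:
    """Hard QC gates; defaults are the conventional resequencing values."""

    min_qual: float = 30.0
    min_dp: int = 10
    max_dp: int = 200
    max_missing: float = 0.5  # minimum retained call rate (inclusive)


def filter_variants(
    vt: VariantTable, thresholds: FilterThresholds | None = None
) -> VariantTable:
    """Apply depth masking, site-quality and call-rate filters.

    Per-call depths outside ``[min_dp, max_dp]`` set the genotype to
    missing *before* the call rate is computed; sites with
    ``QUAL < min_qual`` or call rate below ``max_missing`` are dropped.
    Site order is preserved and the operation is idempotent.
    """
    th = thresholds or FilterThresholds()
    vt.validate()
    if vt.n_sites == 0:
        return vt
    bad_dp = (vt.depth < th.min_dp) | (vt.depth > th.max_dp)
    genotypes = vt.genotypes.copy()
    genotypes[bad_dp] = -1
    masked = VariantTable(
        seqnames=vt.seqnames,
        pos=vt.pos,
        ref=vt.ref,
        alts=list(vt.alts),
        qual=vt.qual,
        genotypes=genotypes,
        depth=vt.depth,
        samples=list(vt.samples),
    )
    keep = (masked.qual >= th.min_qual) & (masked.call_rate() >= th.max_missing)
    return masked.subset_sites(keep)


def popgen_site_filter(
    vt: VariantTable, maf: float = 0.01, thin_bp: int = 10
) -> VariantTable:
    """Biallelic-SNP restriction, MAF floor and greedy positional thinning.

    A site survives when it is a biallelic SNP, its minor allele frequency
    over non-missing alleles is at least ``maf``, and it lies at least
    ``thin_bp`` base pairs from the previously kept site on the same
    sequence (left-to-right greedy rule).
    """
    keep = vt.is_biallelic_snp()
    site_maf = vt.maf()
    keep &= ~np.isnan(site_maf) & (site_maf >= maf)
    # greedy thinning, per seqname in position order
    order = np.lexsort((vt.pos, vt.seqnames.astype(str)))
    last_kept: dict[str, int] = {}
    thin_keep = np.zeros(vt.n_sites, dtype=bool)
    for i in order:
        if not keep[i]:
            continue
        chrom = vt.seqnames[i]
        prev = last_kept.get(chrom)
        if prev is None or vt.pos[i] - prev >= thin_bp:
            thin_keep[i] = True
            last_kept[chrom] = int(vt.pos[i])
    return vt.subset_sites(keep & thin_keep)


def ld_prune(
    vt: VariantTable, window_sites: int = 50, max_r2: float = 0.1
) -> VariantTable:
    """Greedy r²-based pruning (disabled by default in the pipeline).

    Scans sites in order; a site is dropped when its squared genotype
    correlation with any kept site among the previous ``window_sites``
    kept sites on the same sequence exceeds ``max_r2``.
    """
    dosage = vt.dosage()
    kept: list[int] = []
    recent: dict[str, list[int]] = {}
    for i in range(vt.n_sites):
        chrom = vt.seqnames[i]
        window = recent.get(chrom, [])[-window_sites:]
        drop = False
        for j in window:
            x, y = dosage[i], dosage[j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 3:
                continue
            sx, sy = np.std(x[ok]), np.std(y[ok])
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            if r * r > max_r2:
                drop = True
                break
        if not drop:
            kept.append(i)
            recent.setdefault(chrom, []).append(i)
    return vt.subset_sites(np.array(kept, dtype=int))


# ======================================================================
# consequence classification
# ======================================================================
def _gene_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.seqname, IntervalTree()).addi(
            g.start - FLANK_BP, g.end + FLANK_BP + 1, g
        )
    return trees


def _splice_sites(gene: GeneModel) -> dict[int, str]:
    """Map intronic positions to splice categories, strand-aware.

    The two intronic bases adjacent to each exon boundary are splice
    sites: the pair at the transcription-direction start of the intron is
    the donor, the pair at its end the acceptor.
    """
    sites: dict[int, str] = {}
    for s, e in gene.introns():
        if e - s + 1 < 2:
            continue
        if gene.strand == "+":
            donor, acceptor = (s, s + 1), (e - 1, e)
        else:
            donor, acceptor = (e - 1, e), (s, s + 1)
        for p in donor:
            sites[p] = "splice_donor_variant"
        for p in acceptor:
            sites[p] = "splice_acceptor_variant"
    return sites


def _cds_sequence(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Coding-strand CDS sequence in translation order."""
    chrom = genome[gene.seqname]
    parts = [chrom[s - 1 : e] for s, e in gene.cds]
    seq = "".join(parts)
    return _revcomp(seq) if gene.strand == "-" else seq


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of ``pos`` within the coding sequence, or None."""
    off = 0
    for s, e in gene.cds:
        if s <= pos <= e:
            genomic = off + (pos - s)
            if gene.strand == "+":
                return genomic
            return gene.cds_length - 1 - genomic
        off += e - s + 1
    return None


def _coding_consequence(
    gene: GeneModel, genome: Mapping[str, str], pos: int, ref: str, alt: str
) -> tuple[str, str | None]:
    cds_seq = _cds_sequence(gene, genome).upper()
    offset = _cds_offset(gene, pos)
    assert offset is not None
    if len(cds_seq) % 3 != 0:
        warnings.warn(
            f"CDS length of {gene.gene_id} not divisible by 3; "
            "classifying by local codon"
        )
    ref_c = ref.upper() if gene.strand == "+" else _revcomp(ref.upper())
    alt_c = alt.upper() if gene.strand == "+" else _revcomp(alt.upper())
    if cds_seq[offset] != ref_c:
        raise ValueError(
            f"reference base mismatch inside CDS of {gene.gene_id} at "
            f"{gene.seqname}:{pos} (CDS has {cds_seq[offset]}, VCF ref {ref_c})"
        )
    codon_idx = offset // 3
    within = offset % 3
    codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:
        return "missense", None  # trailing partial codon of a broken model
    mutated = codon[:within] + alt_c + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    n = codon_idx + 1
    if codon_idx == 0 and ref_aa == "M" and alt_aa != "M":
        return "start_lost", "p.Met1?"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost", f"p.Ter{n}{AA3[alt_aa]}ext*?"
    if alt_aa == "*" and ref_aa != "*":
        return "stop_gained", f"p.{AA3[ref_aa]}{n}>STOP"
    if ref_aa == alt_aa:
        return "synonymous", f"p.{AA3[ref_aa]}{n}="
    return "missense", f"p.{AA3[ref_aa]}{n}>{AA3[alt_aa]}"


def _classify_in_gene(
    gene: GeneModel, genome: Mapping[str, str], pos: int, ref: str, alt: str
) -> tuple[str, str | None]:
    if gene.contains(pos):
        splice = _splice_sites(gene)
        if pos in splice:
            return splice[pos], None
        if any(s <= pos <= e for s, e in gene.cds):
            return _coding_consequence(gene, genome, pos, ref, alt)
        for side, ivs in gene.utrs().items():
            if any(s <= pos <= e for s, e in ivs):
                return (f"{side}'UTR", None)
        return "intron", None
    before = pos < gene.start
    if (before and gene.strand == "+") or (not before and gene.strand == "-"):
        return "upstream", None
    return "downstream", None


def classify_consequence(
    seqname: str,
    pos: int,
    ref: str,
    alt: str,
    genes: Sequence[GeneModel] | Mapping[str, IntervalTree],
    genome: Mapping[str, str],
) -> list[Consequence]:
    """Classify one SNP against every overlapping gene model.

    Returns one :class:`Consequence` per gene whose span (±5 kb flanks)
    covers the position, or a single intergenic record if none does.
    Raises if the VCF reference base disagrees with the genome FASTA.
    """
    if genome[seqname][pos - 1].upper() != ref.upper():
        raise ValueError(
            f"reference mismatch at {seqname}:{pos}: genome has "
            f"{genome[seqname][pos - 1]}, VCF ref {ref}"
        )
    trees = genes if isinstance(genes, dict) else _gene_trees(genes)
    sid = snp_id(seqname, pos)
    hits = sorted(
        (iv.data for iv in trees.get(seqname, IntervalTree()).at(pos)),
        key=lambda g: g.gene_id,
    )
    out: list[Consequence] = []
    for gene in hits:
        category, notation = _classify_in_gene(gene, genome, pos, ref, alt)
        out.append(
            Consequence(
                snp_id=sid,
                seqname=seqname,
                pos=pos,
                ref=ref,
                alt=alt,
                gene_id=gene.gene_id,
                category=category,
                impact=IMPACT_OF_CATEGORY[category],
                protein_notation=notation,
            )
        )
    if not out:
        out.append(
            Consequence(
                snp_id=sid,
                seqname=seqname,
                pos=pos,
                ref=ref,
                alt=alt,
                gene_id=None,
                category="intergenic",
                impact="MODIFIER",
            )
        )
    return out


def classify_variants(
    vt: VariantTable,
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> list[Consequence]:
    """Classify every (site, alt allele) pair of a variant table."""
    trees = _gene_trees(genes)
    out: list[Consequence] = []
    for i in range(vt.n_sites):
        for alt in vt.alts[i]:
            out.extend(
                classify_consequence(
                    str(vt.seqnames[i]), int(vt.pos[i]), str(vt.ref[i]), alt,
                    trees, genome,
                )
            )
    return out


def select_high_impact(
    consequences: Iterable[Consequence],
    impact_set: frozenset[str] | set[str] = HIGH_IMPACT_DEFAULT,
) -> list[Consequence]:
    """Keep consequences whose category is in ``impact_set``.

    The default set is the protein-disrupting tier (premature stop,
    lost start/stop, broken splice site); pass a set including
    ``"missense"`` to also keep amino-acid substitutions.
    """
    impact_set = set(impact_set)
    if not impact_set:
        raise ValueError("impact_set must not be empty")
    unknown = impact_set - set(IMPACT_OF_CATEGORY)
    if unknown:
        raise ValueError(f"unknown categories in impact_set: {sorted(unknown)}")
    return [c for c in consequences if c.category in impact_set]
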