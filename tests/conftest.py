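"""Shared fixtures: a hand-built two-exon toy gene with planted SNPs of
every consequence class, and a 10-site hand-enumerated variant table for
the filter tests."""

from __future__ import annotations

import numpy as np
import pytest

from tuberscan.core import GeneModel, VariantTable

TOY_CHROM = "chr7"
TOY_LEN = 9000

# toy gene geometry: exon1 2001-2101 (5'UTR 2001-2050, CDS 2051-2101),
# intron 2102-2301, exon2 2302-2501 (CDS 2302-2451, 3'UTR 2452-2501)
TOY_EXONS = [(2001, 2101), (2302, 2501)]
TOY_CDS = [(2051, 2101), (2302, 2451)]
N_CODONS = 67  # (51 + 150) / 3

# coding sequence: ATG | TGG | CTT | GAA | 62 x GCT | TAA
TOY_CODING = "ATG" + "TGG" + "CTT" + "GAA" + "GCT" * 62 + "TAA"
assert len(TOY_CODING) == 3 * N_CODONS


def _build_toy_genome() -> str:
    base = ("ACGT" * (TOY_LEN // 4 + 1))[:TOY_LEN]
    seq = list(base)
    off = 0
    for s, e in TOY_CDS:
        seq[s - 1 : e] = list(TOY_CODING[off : off + e - s + 1])
        off += e - s + 1
    return "".join(seq)


@pytest.fixture(scope="session")
def toy_gene() -> GeneModel:
    return GeneModel("gTOY", TOY_CHROM, "+", TOY_EXONS, TOY_CDS)


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, str]:
    return {TOY_CHROM: _build_toy_genome()}


def cds_genomic_pos(offset: int) -> int:
    """Genomic position of a 0-based coding-sequence offset (plus strand)."""
    if offset < 51:
        return 2051 + offset
    return 2302 + (offset - 51)


#: (pos, alt, expected category) for every consequence class; refs are
#: read from the toy genome.
PLANTED_SNPS = [
    (cds_genomic_pos(1), "C", "start_lost"),        # ATG -> ACG
    (cds_genomic_pos(5), "A", "stop_gained"),       # TGG -> TGA (p.Trp2>STOP)
    (cds_genomic_pos(8), "C", "synonymous"),        # CTT -> CTC (Leu)
    (cds_genomic_pos(10), "T", "missense"),         # GAA -> GTA (Glu>Val)
    (cds_genomic_pos(198), "C", "stop_lost"),       # TAA -> CAA
    (2102, None, "splice_donor_variant"),           # first intron base
    (2103, None, "splice_donor_variant"),
    (2300, None, "splice_acceptor_variant"),        # 2 bp before exon2
    (2301, None, "splice_acceptor_variant"),
    (2150, None, "intron"),
    (2010, None, "5'UTR"),
    (2460, None, "3'UTR"),
    (1500, None, "upstream"),
    (2600, None, "downstream"),
    (8500, None, "intergenic"),
]


def flip_coord(pos: int, length: int = TOY_LEN) -> int:
    return length - pos + 1


COMP = str.maketrans("ACGT", "TGCA")


def reverse_toy(genome: dict[str, str], gene: GeneModel):
    """Reverse-complement the toy world (genome, gene, coordinates)."""
    seq = genome[TOY_CHROM].translate(COMP)[::-1]
    flip = lambda iv: (flip_coord(iv[1]), flip_coord(iv[0]))
    flipped = GeneModel(
        gene.gene_id,
        gene.seqname,
        "-" if gene.strand == "+" else "+",
        [flip(e) for e in gene.exons],
        [flip(c) for c in gene.cds],
        dict(gene.attributes),
    )
    return {TOY_CHROM: seq}, flipped


# ----------------------------------------------------------------------
# 10-site hand-enumerated table (6 samples).  Per-site expectations:
#   pos 100: clean               -> QC keep, popgen keep
#   pos 105: QUAL 29.9           -> QC drop (quality)
#   pos 112: 3 calls DP 5 masked -> call rate 0.5, boundary keep; popgen keep
#   pos 120: 4 calls DP 5 masked -> call rate 1/3, drop
#   pos 130: 2 calls DP 250 masked -> call rate 2/3 keep; popgen keep
#   pos 200: triallelic          -> QC keep, popgen drop (not biallelic)
#   pos 205: monomorphic ref     -> QC keep, popgen drop (MAF 0 < 0.01)
#   pos 209: clean               -> QC keep, popgen keep
#   pos 215: 6 bp from 209       -> QC keep, popgen drop (thinning)
#   pos 230: clean               -> QC keep, popgen keep
QC_SURVIVORS = [100, 112, 130, 200, 205, 209, 215, 230]
POPGEN_SURVIVORS = [100, 112, 130, 209, 230]


@pytest.fixture()
def ten_site_table() -> VariantTable:
    n = 6
    het = [[0, 1]] * 3 + [[0, 0]] * 3
    hom_mix = [[1, 1]] * 2 + [[0, 0]] * 4
    all_ref = [[0, 0]] * 6
    gt = np.array(
        [
            het,                                   # 100
            het,                                   # 105
            het,                                   # 112
            het,                                   # 120
            hom_mix,                               # 130
            [[0, 1], [0, 2], [1, 2]] + [[0, 0]] * 3,  # 200 triallelic
            all_ref,                               # 205
            hom_mix,                               # 209
            het,                                   # 215
            het,                                   # 230
        ],
        dtype=np.int8,
    )
    dp = np.full((10, n), 30, dtype=np.int32)
    dp[2, 3:] = 5       # masks 3 hom-ref calls at 112 (hets remain)
    dp[3, :4] = 5       # masks 4 calls at 120
    dp[4, 4:] = 250     # masks 2 hom-ref calls at 130 (alt homs remain)
    qual = np.array([50, 29.9, 80, 80, 35, 90, 90, 90, 90, 90], dtype=float)
    alts = [("T",)] * 10
    alts[5] = ("C", "T")
    return VariantTable(
        seqnames=np.array(["chr1"] * 10, dtype=object),
        pos=np.array([100, 105, 112, 120, 130, 200, 205, 209, 215, 230]),
        ref=np.array(["A"] * 5 + ["G"] + ["A"] * 4, dtype=object),
        alts=alts,
        qual=qual,
        genotypes=gt,
        depth=dp,
        samples=[f"s{i}" for i in range(n)],
    )
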