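"""Core in-memory containers shared by every pipeline stage.

``VariantTable`` holds biallelic-or-multiallelic SNP sites with unphased
diploid genotype calls, per-call depth and site quality — the minimal
information the QC filters, the Weir–Cockerham estimator and the
association stage all operate on.  ``GeneModel`` is a stranded exon/CDS
structure on a named sequence with free-form attributes (optionally an
``ec_number``).  ``Consequence`` records what a SNP does to a gene model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VariantTable",
    "GeneModel",
    "Consequence",
    "IMPACT_OF_CATEGORY",
    "HIGH_IMPACT_DEFAULT",
    "snp_id",
]

#: Conventional category -> impact tier mapping (fixed table).
IMPACT_OF_CATEGORY = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "missense": "MODERATE",
    "synonymous": "LOW",
    "intron": "MODIFIER",
    "5'UTR": "MODIFIER",
    "3'UTR": "MODIFIER",
    "upstream": "MODIFIER",
    "downstream": "MODIFIER",
    "intergenic": "MODIFIER",
}

#: Categories kept by default when selecting protein-disrupting SNPs.
HIGH_IMPACT_DEFAULT = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

_DIGITS = re.compile(r"(\d+)")


def snp_id(seqname: str, pos: int) -> str:
    """Render the ``S{chrom-number}_{pos}`` identifier (e.g. ``S4_20715506``).

    The chromosome number is the first run of digits in the sequence name
    with leading zeros dropped; a name without digits is used verbatim.
    """
    m = _DIGITS.search(seqname)
    chrom = str(int(m.group(1))) if m else seqname
    return f"S{chrom}_{int(pos)}"


@dataclass
class VariantTable:
    """Column-oriented table of SNP sites with diploid genotype calls.

    Genotypes are stored as an ``(n_sites, n_samples, 2)`` int8 array of
    allele indices into ``{ref} ∪ alts`` with ``-1`` marking a missing
    allele.  Depth is ``(n_sites, n_samples)`` int32.  Positions are
    1-based, per VCF.
    """

    seqnames: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alts: list[tuple[str, ...]]
    qual: np.ndarray
    genotypes: np.ndarray
    depth: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.seqnames = np.asarray(self.seqnames, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.qual = np.asarray(self.qual, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n_sites, n_samples, 2)")
        if len(self.alts) != self.n_sites:
            raise ValueError("alts length must equal number of sites")

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_ids(self) -> list[str]:
        return [snp_id(c, p) for c, p in zip(self.seqnames, self.pos)]

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise naming the offending site."""
        if np.any(self.pos < 1):
            i = int(np.argmax(self.pos < 1))
            raise ValueError(f"position < 1 at {self.seqnames[i]}:{self.pos[i]}")
        n_alleles = np.array([1 + len(a) for a in self.alts])
        too_big = self.genotypes >= n_alleles[:, None, None]
        if np.any(too_big):
            i = int(np.argwhere(too_big)[0, 0])
            raise ValueError(
                "genotype allele index out of range at "
                f"{self.seqnames[i]}:{self.pos[i]}"
            )
        for i, (r, alts) in enumerate(zip(self.ref, self.alts)):
            if r in alts:
                raise ValueError(
                    f"ref == alt at {self.seqnames[i]}:{self.pos[i]}"
                )

    # ------------------------------------------------------------------
    def subset_sites(self, mask_or_index) -> "VariantTable":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantTable(
            seqnames=self.seqnames[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alts=[self.alts[i] for i in idx],
            qual=self.qual[idx],
            genotypes=self.genotypes[idx],
            depth=self.depth[idx],
            samples=list(self.samples),
        )

    def subset_samples(self, names: Sequence[str]) -> "VariantTable":
        lookup = {s: j for j, s in enumerate(self.samples)}
        cols = [lookup[n] for n in names]
        return VariantTable(
            seqnames=self.seqnames,
            pos=self.pos,
            ref=self.ref,
            alts=list(self.alts),
            qual=self.qual,
            genotypes=self.genotypes[:, cols, :],
            depth=self.depth[:, cols],
            samples=list(names),
        )

    # ------------------------------------------------------------------
    def is_biallelic_snp(self) -> np.ndarray:
        """True where the site is a biallelic single-nucleotide variant."""
        return np.array(
            [
                len(a) == 1 and len(a[0]) == 1 and len(r) == 1
                for r, a in zip(self.ref, self.alts)
            ]
        )

    def call_rate(self) -> np.ndarray:
        """Fraction of samples with a fully called genotype, per site."""
        called = np.all(self.genotypes >= 0, axis=2)
        return called.mean(axis=1)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (non-missing allele count, alt allele count) per site.

        Only meaningful for biallelic sites; alt count sums indices > 0.
        """
        g = self.genotypes
        known = g >= 0
        n = known.sum(axis=(1, 2))
        alt = np.where(known, g, 0).sum(axis=(1, 2))
        return n, alt

    def maf(self) -> np.ndarray:
        """Minor allele frequency over non-missing alleles (NaN if none)."""
        n, alt = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / n
        return np.where(np.isnan(p), np.nan, np.minimum(p, 1.0 - p))

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage matrix (n_sites, n_samples), NaN where missing."""
        g = self.genotypes.astype(float)
        miss = np.any(self.genotypes < 0, axis=2)
        d = g.sum(axis=2)
        d[miss] = np.nan
        return d


@dataclass
class GeneModel:
    """A stranded gene with sorted, non-overlapping exons and a CDS.

    Intervals are 1-based closed ``(start, end)`` tuples in genomic
    coordinates.  UTRs are derived (exonic minus CDS, 5'/3' by strand).
    """

    gene_id: str
    seqname: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted(tuple(map(int, e)) for e in self.exons)
        self.cds = sorted(tuple(map(int, c)) for c in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]

    def utrs(self) -> dict[str, list[tuple[int, int]]]:
        """Exonic intervals outside the CDS, split into 5' and 3' sides."""
        if not self.cds:
            return {"5": [], "3": []}
        cs, ce = self.cds[0][0], self.cds[-1][1]
        left, right = [], []
        for s, e in self.exons:
            if s < cs:
                left.append((s, min(e, cs - 1)))
            if e > ce:
                right.append((max(s, ce + 1), e))
        if self.strand == "+":
            return {"5": left, "3": right}
        return {"5": right, "3": left}

    def ec_numbers(self) -> tuple[str, ...]:
        raw = self.attributes.get("ec_number", "")
        if not raw:
            return ()
        return tuple(x.strip() for x in raw.split(",") if x.strip())

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class Consequence:
    """Effect of one SNP on one gene model (or intergenic)."""

    snp_id: str
    seqname: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    category: str
    impact: str
    protein_notation: str | None = None

    def __post_init__(self) -> None:
        if self.category not in IMPACT_OF_CATEGORY:
            raise ValueError(f"unknown consequence category {self.category!r}")
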