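"""Readers and writers for the standard interchange formats.

Reading goes through the established parsers (cyvcf2 for VCF, gffutils
for GFF3, pyfaidx for FASTA); writing VCF v4.2 / GFF3 is a direct text
emitter so that a fixed simulation seed produces byte-identical files.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import GeneModel, VariantTable

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_gff3",
    "read_gff3",
    "write_fasta",
    "read_fasta",
    "write_orthogroups",
    "read_orthogroups",
    "write_pathways",
    "read_pathways",
    "write_json",
    "read_json",
]


# ----------------------------------------------------------------- VCF
def write_vcf(vt: VariantTable, path: str, contigs: Mapping[str, int] | None = None) -> None:
    """Write a VCF v4.2 file with GT:DP per sample and QUAL per site."""
    lines = ["##fileformat=VCFv4.2", "##source=tuberscan"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    lines.append(header + "\t" + "\t".join(vt.samples))
    ids = vt.site_ids()
    for i in range(vt.n_sites):
        alt = ",".join(vt.alts[i]) if vt.alts[i] else "."
        qual = f"{vt.qual[i]:.1f}"
        calls = []
        for j in range(vt.n_samples):
            a, b = vt.genotypes[i, j]
            gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
            calls.append(f"{gt}:{vt.depth[i, j]}")
        lines.append(
            "\t".join(
                [
                    str(vt.seqnames[i]),
                    str(vt.pos[i]),
                    ids[i],
                    str(vt.ref[i]),
                    alt,
                    qual,
                    "PASS",
                    ".",
                    "GT:DP",
                ]
                + calls
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> VariantTable:
    """Load a VCF into a :class:`VariantTable` via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    seqnames, pos, ref, alts, qual, gts, dps = [], [], [], [], [], [], []
    for v in vcf:
        seqnames.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alts.append(tuple(v.ALT))
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        g = np.array(v.genotypes, dtype=np.int16)[:, :2]
        gts.append(g.astype(np.int8))
        dp = v.format("DP")
        if dp is None:
            dps.append(np.zeros(len(samples), dtype=np.int32))
        else:
            dps.append(dp.reshape(-1).astype(np.int32))
    n = len(pos)
    return VariantTable(
        seqnames=np.array(seqnames, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alts=alts,
        qual=np.array(qual, dtype=float),
        genotypes=(
            np.stack(gts) if n else np.zeros((0, len(samples), 2), dtype=np.int8)
        ),
        depth=(
            np.stack(dps) if n else np.zeros((0, len(samples)), dtype=np.int32)
        ),
        samples=samples,
    )


# ---------------------------------------------------------------- GFF3
def write_gff3(genes: Iterable[GeneModel], path: str) -> None:
    """Emit gene/mRNA/exon/CDS records; EC tags go on the gene line."""
    out = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id}"
        ec = g.attributes.get("ec_number")
        if ec:
            attrs += f";ec_number={ec}"
        for k, v in g.attributes.items():
            if k != "ec_number":
                attrs += f";{k}={v}"
        base = [g.seqname, "tuberscan"]
        out.append(
            "\t".join(base + ["gene", str(g.start), str(g.end), ".", g.strand, ".", attrs])
        )
        mrna = f"{g.gene_id}.1"
        out.append(
            "\t".join(
                base
                + ["mRNA", str(g.start), str(g.end), ".", g.strand, ".",
                   f"ID={mrna};Parent={g.gene_id}"]
            )
        )
        for s, e in g.exons:
            out.append(
                "\t".join(base + ["exon", str(s), str(e), ".", g.strand, ".", f"Parent={mrna}"])
            )
        for s, e in g.cds:
            out.append(
                "\t".join(base + ["CDS", str(s), str(e), ".", g.strand, "0", f"Parent={mrna}"])
            )
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def read_gff3(path: str) -> list[GeneModel]:
    """Parse gene models back out of a GFF3 file using gffutils."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons, cds = [], []
        for child in db.children(g, level=2):
            if child.featuretype == "exon":
                exons.append((child.start, child.end))
            elif child.featuretype == "CDS":
                cds.append((child.start, child.end))
        attrs = {
            k: ",".join(v)
            for k, v in g.attributes.items()
            if k not in ("ID", "Parent")
        }
        genes.append(
            GeneModel(
                gene_id=g.id,
                seqname=g.seqid,
                strand=g.strand,
                exons=exons,
                cds=cds,
                attributes=attrs,
            )
        )
    return genes


# --------------------------------------------------------------- FASTA
def write_fasta(genome: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(path)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


# ----------------------------------------------------------- flat TSVs
def write_orthogroups(og_table: Mapping[str, Mapping[str, list[str]]], path: str) -> None:
    """One row per (OG, species): OG_ID <tab> species <tab> comma-joined genes."""
    rows = []
    for og in og_table:
        for sp, genes in og_table[og].items():
            rows.append((og, sp, ",".join(genes)))
    pd.DataFrame(rows, columns=["orthogroup", "species", "genes"]).to_csv(
        path, sep="\t", index=False
    )


def read_orthogroups(path: str) -> dict[str, dict[str, list[str]]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    table: dict[str, dict[str, list[str]]] = {}
    for og, sp, genes in df.itertuples(index=False):
        table.setdefault(og, {})[sp] = genes.split(",") if isinstance(genes, str) else []
    return table


def write_pathways(catalog: Mapping[str, set[str]], path: str) -> None:
    rows = [(pw, ec) for pw in catalog for ec in sorted(catalog[pw])]
    pd.DataFrame(rows, columns=["pathway_id", "ec"]).to_csv(path, sep="\t", index=False)


def read_pathways(path: str) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    catalog: dict[str, set[str]] = {}
    for pw, ec in df.itertuples(index=False):
        catalog.setdefault(pw, set()).add(ec)
    return catalog


# ---------------------------------------------------------------- JSON
def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def read_json(path: str):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
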