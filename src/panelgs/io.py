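"""Readers and writers for the standard interchange formats.

Genotypes travel as plain-text VCF (GT field, ``./.`` for missing calls),
gene models as GFF3 (1-based inclusive gene features), gene -> GO maps as
two-column TSV and phenotypes as long-format CSV.  Reading VCF uses cyvcf2
and GFF3 uses gffutils; only biallelic SNP records are accepted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dosage import HOM_ALT, HOM_REF, HET, MISSING, DosageMatrix
from .synthetic import GeneAnnotation

_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(g: DosageMatrix, path: str) -> None:
    """Write a raw/imputed-coded matrix as an uncompressed VCF."""
    if g.coding_state == "final":
        raise ValueError("final -1/+1 coding has no VCF representation")
    chroms = list(dict.fromkeys(g.markers["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelgs\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.lines) + "\n")
        mk = g.markers
        for j in range(g.n_markers):
            gts = "\t".join(_GT_STRING[int(v)] for v in g.values[:, j])
            fh.write(f"{mk['chrom'].iat[j]}\t{mk['pos'].iat[j]}\t{mk['id'].iat[j]}"
                     f"\t{mk['ref'].iat[j]}\t{mk['alt'].iat[j]}\t.\tPASS\t.\tGT\t"
                     f"{gts}\n")


def read_vcf(path: str) -> DosageMatrix:
    """Read biallelic SNPs from a VCF into a raw-coded DosageMatrix.

    Multi-allelic or non-SNP records are rejected; the error reports how many
    were found.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    lines = list(vcf.samples)
    chroms, pos, ids, ref, alt, rows = [], [], [], [], [], []
    n_rejected = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_rejected += 1
            continue
        chroms.append(var.CHROM)
        pos.append(var.POS)
        ids.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
        ref.append(var.REF)
        alt.append(var.ALT[0])
        # gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        gt = var.gt_types
        col = np.full(len(lines), MISSING, dtype=np.int8)
        col[gt == 0] = HOM_REF
        col[gt == 1] = HET
        col[gt == 3] = HOM_ALT
        rows.append(col)
    if n_rejected:
        raise ValueError(f"{n_rejected} multi-allelic/non-SNP records rejected")
    values = np.column_stack(rows)
    markers = pd.DataFrame({"id": ids, "chrom": chroms,
                            "pos": np.array(pos, dtype=np.int64),
                            "ref": ref, "alt": alt})
    return DosageMatrix(values, markers, lines=lines, coding_state="raw")


def write_gff3(annotation: GeneAnnotation, path: str) -> None:
    """Write gene features as GFF3 with GO terms in the Ontology_term tag."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in annotation.genes.iterrows():
            terms = sorted(annotation.gene_to_go.get(row["id"], set()))
            attrs = f"ID={row['id']}"
            if terms:
                attrs += ";Ontology_term=" + ",".join(terms)
            fh.write(f"{row['chrom']}\tpanelgs\tgene\t{row['start']}\t{row['end']}"
                     f"\t.\t{row['strand']}\t.\t{attrs}\n")


def read_gff3(path: str, go_map_path: str = None) -> GeneAnnotation:
    """Read gene features (and optionally a separate gene -> GO TSV)."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes, gene_to_go = [], {}
    for feat in db.features_of_type("gene"):
        gid = feat.id
        genes.append((gid, feat.seqid, feat.start, feat.end, feat.strand))
        terms = feat.attributes.get("Ontology_term", [])
        if terms:
            gene_to_go[gid] = set(terms)
    df = pd.DataFrame(genes, columns=["id", "chrom", "start", "end", "strand"])
    if go_map_path is not None:
        gene_to_go = read_go_map(go_map_path)
    return GeneAnnotation(genes=df, gene_to_go=gene_to_go)


def write_go_map(annotation: GeneAnnotation, path: str) -> None:
    """Two-column TSV: gene id, GO term id (one row per pair)."""
    with open(path, "w") as fh:
        for gene in annotation.genes["id"]:
            for term in sorted(annotation.gene_to_go.get(gene, set())):
                fh.write(f"{gene}\t{term}\n")


def read_go_map(path: str) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    out = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
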