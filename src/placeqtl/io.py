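"""Readers and writers for the plain-text exchange formats.

Genotypes travel either as a minimal VCF v4.2 (GT field only, ``./.`` for
missing) or as a sample x SNP dosage TSV with ``NA`` missing codes.  Gene
coordinates are BED (0-based half-open on disk, converted to the package's
1-based inclusive convention on read).  All tables round-trip losslessly
through these functions.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import CovariateTable, ExpressionMatrix, GenotypeMatrix

_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    meta = g.snp_meta
    samples = g.sample_ids
    dosage = g.dosage.to_numpy(dtype=float)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=placeqtl\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, snp in enumerate(meta.itertuples()):
            calls = [_GT_CODES.get(dosage[i, j], "./.") for i in range(len(samples))]
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.Index}\t{snp.ref}\t{snp.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a GT-only VCF into a dosage matrix (ALT-allele counts)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    ids, chroms, poss, refs, alts = [], [], [], [], []
    for var in vcf:
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
        ids.append(var.ID)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
    vcf.close()
    dosage = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=samples,
        columns=ids,
    )
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="snp"),
    )
    return GenotypeMatrix(dosage, meta)


def write_dosage_tsv(g: GenotypeMatrix, path: str) -> None:
    g.dosage.to_csv(path, sep="\t", na_rep="NA", index_label="sample")


def read_dosage_tsv(path: str, snp_meta: pd.DataFrame) -> GenotypeMatrix:
    dosage = pd.read_csv(path, sep="\t", index_col="sample", na_values="NA")
    dosage.columns = pd.Index(dosage.columns, name=snp_meta.index.name)
    return GenotypeMatrix(dosage, snp_meta.loc[dosage.columns].copy())


def write_snp_meta(g: GenotypeMatrix, path: str) -> None:
    g.snp_meta.to_csv(path, sep="\t", index_label="snp")


def read_snp_meta(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="snp")


def write_expression_tsv(e: ExpressionMatrix, path: str) -> None:
    e.values.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def write_gene_bed(e: ExpressionMatrix, path: str) -> None:
    """BED is 0-based half-open: start-1, end for a 1-based inclusive gene."""
    bed = pd.DataFrame(
        {
            "chrom": e.gene_meta["chrom"],
            "start": e.gene_meta["start"] - 1,
            "end": e.gene_meta["end"],
            "name": e.gene_meta.index,
            "score": 0,
            "strand": e.gene_meta.get("strand", "+"),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_expression(expr_path: str, bed_path: str) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col="gene", na_values="NA")
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    meta = pd.DataFrame(
        {
            "chrom": bed["chrom"].to_numpy(),
            "start": bed["start"].to_numpy() + 1,  # back to 1-based inclusive
            "end": bed["end"].to_numpy(),
            "strand": bed["strand"].to_numpy(),
        },
        index=pd.Index(bed["name"], name="gene"),
    )
    return ExpressionMatrix(values, meta.loc[values.index])


def write_covariates(c: CovariateTable, path: str) -> None:
    c.data.to_csv(path, sep="\t", na_rep="NA", index_label="sample")
    import json

    with open(path + ".encodings.json", "w") as fh:
        json.dump({k: {str(a): int(b) for a, b in v.items()} for k, v in c.encodings.items()}, fh, indent=1)


def read_covariates(path: str) -> CovariateTable:
    import json

    data = pd.read_csv(path, sep="\t", index_col="sample", na_values="NA")
    enc_path = path + ".encodings.json"
    encodings = {}
    if os.path.exists(enc_path):
        with open(enc_path) as fh:
            encodings = json.load(fh)
    return CovariateTable(data, encodings)
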