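"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive internally (VCF/GFF convention); BED output
is converted to 0-based half-open at the file boundary.  Genotypes are additive
ALT-allele dosages in {0, 1, 2}, stored as float with NaN for missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

#: columns expected in a clinical covariate table, in priority order
CLINICAL_COLUMNS = [
    "Batch",
    "Cohort",
    "Group",
    "Delivery",
    "MaternalAge",
    "Ethnicity",
    "GestationalAge",
    "Sex",
    "Parity",
]

GROUP_LABELS = ["CTRL", "PE", "IUGR", "PE+IUGR"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix plus SNP metadata.

    Parameters
    ----------
    dosage : DataFrame
        ``samples x snps``; values in {0, 1, 2} or NaN.
    snp_meta : DataFrame
        Indexed by SNP id with columns ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt``.  Positions must be strictly positive.
    """

    dosage: pd.DataFrame
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosage.columns) != list(self.snp_meta.index):
            raise ValueError("dosage columns and snp_meta index differ")
        if not self.snp_meta.index.is_unique:
            raise ValueError("SNP ids are not unique")
        if not self.dosage.index.is_unique:
            raise ValueError("sample ids are not unique")
        if len(self.snp_meta) and (self.snp_meta["pos"] < 1).any():
            raise ValueError("SNP positions must be >= 1 (1-based)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        d = self.dosage
        if samples is not None:
            d = d.loc[samples]
        if snps is not None:
            d = d[snps]
        return GenotypeMatrix(d.copy(), self.snp_meta.loc[d.columns].copy())


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensity matrix plus gene coordinates.

    ``gene_meta`` is indexed by gene id with ``chrom``, ``start``, ``end``
    (1-based inclusive) and ``strand``.
    """

    values: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.gene_meta.index):
            raise ValueError("expression rows and gene_meta index differ")
        if not self.gene_meta.index.is_unique:
            raise ValueError("gene ids are not unique")
        if len(self.gene_meta) and (self.gene_meta["start"] > self.gene_meta["end"]).any():
            raise ValueError("gene start must be <= end")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes].copy(), self.gene_meta.loc[genes].copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[samples].copy(), self.gene_meta.copy())


@dataclass
class CovariateTable:
    """Per-sample covariates, numeric-encoded one column per variable.

    ``encodings`` records, for every categorical column, the label -> integer
    code mapping used; numeric columns are absent from it.
    """

    data: pd.DataFrame
    encodings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("sample ids are not unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def columns(self) -> list[str]:
        return list(self.data.columns)

    def design(self, columns) -> np.ndarray:
        """Numeric design block (no intercept) for the requested columns."""
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise KeyError(f"covariate columns absent from table: {missing}")
        return self.data[list(columns)].to_numpy(dtype=float)

    def with_columns(self, frame: pd.DataFrame) -> "CovariateTable":
        merged = self.data.join(frame, how="left")
        return CovariateTable(merged, dict(self.encodings))


def align_samples(*objs):
    """Intersect sample ids across containers, preserving the first one's order."""
    common = None
    for o in objs:
        ids = o.sample_ids
        common = ids if common is None else [s for s in common if s in set(ids)]
    out = []
    for o in objs:
        if isinstance(o, GenotypeMatrix):
            out.append(o.subset(samples=common))
        elif isinstance(o, ExpressionMatrix):
            out.append(o.subset_samples(common))
        elif isinstance(o, CovariateTable):
            out.append(CovariateTable(o.data.loc[common].copy(), dict(o.encodings)))
        else:  # pragma: no cover
            raise TypeError(type(o))
    return out
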