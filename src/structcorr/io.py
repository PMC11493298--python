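"""Readers and writers for the tabular formats the package exchanges.

Genotypes travel as TSV (rows = individuals, header = locus ids, values
0/1/2) or VCF (biallelic diploid GT); covariance matrices as labelled CSV;
expression as TSV with species rows, gene columns and empty cells for
missing; pedigrees as three-column TSV (individual, sire, dam; ``0``,
``NA``, ``.`` or empty mark founders).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariance import CovarianceMatrix, GenotypeMatrix, Pedigree

__all__ = [
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "read_covariance_csv",
    "write_covariance_csv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_pedigree_tsv",
    "read_pairs_tsv",
]

_FOUNDER_MARKS = {"0", "NA", ".", "", "nan", "None"}


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        df.to_numpy(dtype=np.int8), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    pd.DataFrame(geno.dosages, index=geno.labels, columns=geno.loci).to_csv(path, sep="\t")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read diploid GT dosages from a VCF; biallelic sites only."""
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    labels = list(vcf.samples)
    cols, loci = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = np.array([g[0] + g[1] for g in var.genotypes], dtype=np.int8)
        cols.append(gts)
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    dosages = np.column_stack(cols) if cols else np.zeros((len(labels), 0), np.int8)
    return GenotypeMatrix(dosages, labels, loci)


def read_covariance_csv(path) -> CovarianceMatrix:
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy(dtype=float)
    vals = (vals + vals.T) / 2.0  # text round-trip may break exact symmetry
    return CovarianceMatrix(vals, [str(i) for i in df.index])


def write_covariance_csv(sigma: CovarianceMatrix, path) -> None:
    pd.DataFrame(sigma.values, index=sigma.labels, columns=sigma.labels).to_csv(path)


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")


def read_pedigree_tsv(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    for required in ("individual", "sire", "dam"):
        if required not in cols:
            raise ValueError(f"pedigree TSV needs a {required!r} column")
    records = [
        (
            row["individual"],
            None if row["sire"] in _FOUNDER_MARKS else row["sire"],
            None if row["dam"] in _FOUNDER_MARKS else row["dam"],
        )
        for _, row in df.iterrows()
    ]
    return Pedigree(records)


def read_pairs_tsv(path) -> set:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return {frozenset((a, b)) for a, b in zip(df[0], df[1])}
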