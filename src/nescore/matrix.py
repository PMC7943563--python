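"""Expression-matrix container and TSV/GCT readers and writers.

The matrix is genes x samples with a scale tag (``linear`` vs ``log2``) that
downstream scoring uses to decide whether a log transform is still needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SCALES = ("linear", "log2")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. Entries are
        finite floats or NaN.
    scale
        ``"linear"`` or ``"log2"``; an attestation by whoever built the
        matrix, not something inferred from the data.
    provenance
        Free-text note on where the matrix came from.
    """

    values: pd.DataFrame
    scale: str = "log2"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy(dtype=float, copy=False)
        if np.isinf(arr).any():
            raise ValidationError("expression matrix contains infinite values")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        """Return a copy carrying new values (same provenance)."""
        return ExpressionMatrix(values, scale or self.scale, self.provenance)


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        n = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by mean", n)
        df = df.groupby(level=0, sort=False).mean()
    return df


def read_expression(path, format: str | None = None, scale: str = "log2") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT 1.2.

    TSV: header row of sample ids, first column gene ids. GCT: ``#1.2``
    version line, dimensions line, then Name/Description columns before the
    samples. Duplicate gene rows are collapsed by mean with a warning.
    """
    path = str(path)
    if format is None:
        format = "gct" if path.endswith(".gct") else "tsv"
    if format == "tsv":
        df = _read_tsv(path)
    elif format == "gct":
        df = _read_gct(path)
    else:
        raise FormatError(f"unknown expression format {format!r}")
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df, scale=scale, provenance=path)


def _read_tsv(path: str) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows, index = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise FormatError(
                    f"{path}:{lineno}: expected {ncol} fields, found {len(fields)}"
                )
            index.append(fields[0])
            rows.append(fields[1:])
    try:
        data = np.array(rows, dtype=float) if rows else np.empty((0, ncol - 1))
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    return pd.DataFrame(data, index=index, columns=header[1:])


def _read_gct(path: str) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != n_samples + 2:
            raise FormatError(
                f"{path}: header names {len(header) - 2} samples, dims line says {n_samples}"
            )
        index, rows = [], []
        for lineno, line in enumerate(fh, start=4):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_samples + 2:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_samples + 2} fields, found {len(fields)}"
                )
            index.append(fields[0])
            rows.append(fields[2:])
    if len(index) != n_genes:
        raise FormatError(f"{path}: body has {len(index)} genes, dims line says {n_genes}")
    try:
        data = np.array(rows, dtype=float) if rows else np.empty((0, n_samples))
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    return pd.DataFrame(data, index=index, columns=header[2:])


def write_expression(expr: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write a matrix to TSV (default) or GCT 1.2."""
    path = str(path)
    if format is None:
        format = "gct" if path.endswith(".gct") else "tsv"
    if format == "tsv":
        expr.values.to_csv(path, sep="\t", index_label="gene")
    elif format == "gct":
        n_genes, n_samples = expr.shape
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_genes}\t{n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, expr.sample_ids)) + "\n")
            for gene, row in expr.values.iterrows():
                vals = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{gene}\tna\t{vals}\n")
    else:
        raise FormatError(f"unknown expression format {format!r}")
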