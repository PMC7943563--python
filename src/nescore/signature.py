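"""Two-centroid neuroendocrine (NE) signature scoring.

A 50-gene signature carries two expression prototypes: one averaged from
neuroendocrine SCLC cell lines (the NE centroid) and one from
non-neuroendocrine lines (the non-NE centroid). A sample's NE score is

    score = (r_NE - r_nonNE) / 2

where ``r_NE`` (``r_nonNE``) is the Pearson correlation between the
sample's log2 expression of the signature genes and the NE (non-NE)
centroid. The score lies in [-1, +1]; positive predicts a neuroendocrine
phenotype, negative a non-neuroendocrine (variant) phenotype, and the
magnitude reflects confidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    EmptyResultError,
    FormatError,
    InsufficientOverlapError,
    UndefinedCorrelationError,
    ValidationError,
)
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 40

SCORE_COLUMNS = ["sample", "correl_ne", "correl_non_ne", "ne_score", "n_genes_used", "call"]


@dataclass(frozen=True)
class GeneSignature:
    """Ordered gene list with NE and non-NE centroid expression (log2)."""

    gene_ids: tuple[str, ...]
    ne_centroid: np.ndarray
    non_ne_centroid: np.ndarray
    name: str = "NE signature"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ne_centroid", np.asarray(self.ne_centroid, dtype=float))
        object.__setattr__(self, "non_ne_centroid", np.asarray(self.non_ne_centroid, dtype=float))
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValidationError("duplicate gene ids in signature")
        if self.ne_centroid.shape != (n,) or self.non_ne_centroid.shape != (n,):
            raise ValidationError("centroid lengths do not match gene list")
        if not (np.isfinite(self.ne_centroid).all() and np.isfinite(self.non_ne_centroid).all()):
            raise ValidationError("centroid values must be finite")
        for label, c in (("ne_centroid", self.ne_centroid), ("non_ne_centroid", self.non_ne_centroid)):
            if np.ptp(c) == 0:
                raise ValidationError(f"constant centroid: {label}")
        if np.array_equal(self.ne_centroid, self.non_ne_centroid):
            raise ValidationError("NE and non-NE centroids are identical; every score would be 0")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def swapped(self) -> "GeneSignature":
        """Signature with the two centroids exchanged (negates every score)."""
        return GeneSignature(self.gene_ids, self.non_ne_centroid, self.ne_centroid,
                             name=f"{self.name} (swapped)")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.gene_ids, "ne_centroid": self.ne_centroid,
             "non_ne_centroid": self.non_ne_centroid}
        )


@dataclass(frozen=True)
class NEScore:
    """Per-sample NE score with its two component correlations."""

    sample_id: str
    correl_ne: float
    correl_non_ne: float
    score: float
    n_genes_used: int
    call: str  # "NE" | "non-NE" | "indeterminate"


def load_signature(path, format: str = "tsv") -> GeneSignature:
    """Load a signature TSV with columns gene, ne_centroid, non_ne_centroid."""
    if format != "tsv":
        raise FormatError(f"unsupported signature format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"gene", "ne_centroid", "non_ne_centroid"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) < 3:
        raise FormatError(f"{path}: signature needs at least 3 genes, found {len(df)}")
    for col in ("ne_centroid", "non_ne_centroid"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "gene"].iloc[0]
            raise ValidationError(f"{path}: non-numeric {col} entry for gene {bad!r}")
        df[col] = vals
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    return GeneSignature(
        tuple(df["gene"]),
        df["ne_centroid"].to_numpy(),
        df["non_ne_centroid"].to_numpy(),
        name=str(path),
    )


def write_signature(signature: GeneSignature, path) -> None:
    signature.as_frame().to_csv(path, sep="\t", index=False)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    if denom == 0:
        raise UndefinedCorrelationError("zero-variance vector in correlation")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _call(score: float) -> str:
    if score > 0:
        return "NE"
    if score < 0:
        return "non-NE"
    return "indeterminate"


def compute_ne_score(
    profile: Mapping[str, float] | pd.Series,
    signature: GeneSignature,
    min_genes: int = DEFAULT_MIN_GENES,
    sample_id: str = "sample",
) -> NEScore:
    """Score one log2-scale expression profile against the signature.

    Correlations run over the intersection of profile and signature genes;
    NaN profile values drop the gene pairwise and decrement
    ``n_genes_used``. Fewer than ``min_genes`` usable genes raises
    :class:`InsufficientOverlapError`; a zero-variance restricted profile
    (or restricted centroid) raises :class:`UndefinedCorrelationError`.
    """
    if not isinstance(profile, pd.Series):
        profile = pd.Series(profile, dtype=float)
    present = profile.reindex(signature.gene_ids)
    mask = present.notna().to_numpy()
    n_used = int(mask.sum())
    if n_used < min_genes:
        raise InsufficientOverlapError(n_used, min_genes, sample_id=sample_id)
    x = present.to_numpy(dtype=float)[mask]
    if np.ptp(x) == 0:
        raise UndefinedCorrelationError(
            f"sample {sample_id!r}: profile constant over the {n_used} signature genes used"
        )
    r_ne = _pearson(x, signature.ne_centroid[mask])
    r_non = _pearson(x, signature.non_ne_centroid[mask])
    score = (r_ne - r_non) / 2.0
    return NEScore(sample_id, r_ne, r_non, score, n_used, _call(score))


def score_matrix(
    expr: ExpressionMatrix,
    signature: GeneSignature,
    min_genes: int = DEFAULT_MIN_GENES,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Score every sample of a matrix; report per-sample failures.

    Returns ``(scores, failures)``: a DataFrame with one row per scored
    sample (columns sample, correl_ne, correl_non_ne, ne_score,
    n_genes_used, call, in input sample order) and a mapping from failed
    sample id to the reason. Raises :class:`EmptyResultError` if no sample
    is scoreable.
    """
    values = expr.values
    if expr.scale == "linear":
        logger.warning("linear-scale matrix: applying log2(x + 1) before scoring")
        values = np.log2(values + 1.0)
    rows: list[NEScore] = []
    failures: dict[str, str] = {}
    for sample in values.columns:
        try:
            rows.append(compute_ne_score(values[sample], signature, min_genes, sample_id=sample))
        except (InsufficientOverlapError, UndefinedCorrelationError) as exc:
            failures[sample] = str(exc)
            logger.warning("sample %r not scored: %s", sample, exc)
    if not rows:
        raise EmptyResultError(
            f"no sample scoreable against signature {signature.name!r} "
            f"({len(failures)} failures)"
        )
    scores = pd.DataFrame(
        [
            (r.sample_id, r.correl_ne, r.correl_non_ne, r.score, r.n_genes_used, r.call)
            for r in rows
        ],
        columns=SCORE_COLUMNS,
    )
    return scores, failures


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing score columns {sorted(missing)}")
    return df
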