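"""Normalization and standardization steps for expression matrices.

Covers the preprocessing applied to bulk and single-cell data before
signature scoring: quantile normalization, log2 transformation, library-size
normalization, per-sample/per-gene z-scoring, and cluster pseudobulk
averaging with min-max scaling.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so every sample shares one distribution.

    The reference distribution is the vector of row means after sorting each
    column; each column's values are replaced by the reference values at
    their ranks. Tied values within a column receive the mean of the
    reference values at their tied ranks.
    """
    X = expr.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("quantile_normalize does not support NaN values")
    if X.shape[1] < 1:
        raise ValidationError("need at least one column")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = reference.copy()
        col_sorted = col[order]
        # average reference values over runs of tied input values
        start = 0
        for i in range(1, len(col_sorted) + 1):
            if i == len(col_sorted) or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    assigned[start:i] = reference[start:i].mean()
                start = i
        out[order, j] = assigned
    values = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return expr.with_values(values)


def log2_transform(expr: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Apply ``log2(x + offset)`` to a linear-scale matrix and retag it."""
    if expr.scale == "log2":
        raise ValidationError("matrix already on log2 scale; refusing a double transform")
    if offset < 0:
        raise ValidationError("offset must be nonnegative")
    X = expr.values.to_numpy(dtype=float)
    if np.nanmin(X) < 0:
        raise ValidationError("negative values cannot be log2-transformed")
    values = pd.DataFrame(
        np.log2(X + offset), index=expr.values.index, columns=expr.values.columns
    )
    return expr.with_values(values, scale="log2")


def library_size_normalize(counts: ExpressionMatrix, target: float | None = None) -> ExpressionMatrix:
    """Scale each column so its total equals the median of the column totals.

    ``target`` overrides the median with a fixed library size.
    """
    X = counts.values.to_numpy(dtype=float)
    if np.nanmin(X) < 0:
        raise ValidationError("library-size normalization requires nonnegative values")
    totals = np.nansum(X, axis=0)
    zero = totals <= 0
    if zero.any():
        bad = [s for s, z in zip(counts.sample_ids, zero) if z]
        raise ValidationError(f"zero-total columns: {', '.join(map(str, bad))}")
    if target is None:
        target = float(np.median(totals))
    values = pd.DataFrame(
        X * (target / totals), index=counts.values.index, columns=counts.values.columns
    )
    return counts.with_values(values)


def zscore_standardize(expr: ExpressionMatrix, axis: str = "per_sample") -> ExpressionMatrix:
    """Standardize to mean 0, sample sd 1 along the chosen axis.

    ``per_sample`` standardizes each column across genes (as used for
    heatmap display); ``per_gene`` standardizes each row across samples.
    Constant vectors map to all-zeros with a logged warning.
    """
    if axis not in ("per_sample", "per_gene"):
        raise ValidationError(f"unknown axis {axis!r}")
    X = expr.values.to_numpy(dtype=float)
    np_axis = 0 if axis == "per_sample" else 1
    if X.shape[np_axis] < 2:
        raise ValidationError(f"axis of length {X.shape[np_axis]} cannot be standardized")
    mean = np.nanmean(X, axis=np_axis, keepdims=True)
    sd = np.nanstd(X, axis=np_axis, ddof=1, keepdims=True)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant %s vector(s) standardized to zeros",
            int(constant.sum()),
            "sample" if axis == "per_sample" else "gene",
        )
    sd = np.where(constant, 1.0, sd)
    Z = (X - mean) / sd
    Z = np.where(np.broadcast_to(constant, Z.shape), 0.0, Z)
    values = pd.DataFrame(Z, index=expr.values.index, columns=expr.values.columns)
    return expr.with_values(values)


def cluster_average_minmax(
    expr: ExpressionMatrix,
    cell_to_cluster: Mapping[str, str],
    min_cluster_size: int = 10,
) -> ExpressionMatrix:
    """Average cells per cluster, then min-max scale each gene to [0, 1].

    Clusters with fewer than ``min_cluster_size`` members are dropped (and
    logged); genes constant across retained clusters map to all-zeros with a
    warning. Used to summarize scRNA-seq expression by cell type.
    """
    mapping = pd.Series(
        {s: cell_to_cluster[s] for s in expr.sample_ids if s in cell_to_cluster}
    )
    sizes = mapping.value_counts()
    keep = sizes[sizes >= min_cluster_size].index
    dropped = sizes[sizes < min_cluster_size]
    for name, n in dropped.items():
        logger.info("dropping cluster %r with %d < %d cells", name, int(n), min_cluster_size)
    if len(keep) < 2:
        raise ValidationError(
            f"only {len(keep)} cluster(s) of size >= {min_cluster_size}; need at least 2"
        )
    mapping = mapping[mapping.isin(keep)]
    means = expr.values[mapping.index].T.groupby(mapping).mean().T
    means = means[sorted(means.columns, key=str)]
    lo = means.min(axis=1)
    hi = means.max(axis=1)
    span = hi - lo
    constant = span == 0
    if constant.any():
        logger.warning("%d gene(s) constant across clusters scaled to zeros", int(constant.sum()))
    scaled = means.sub(lo, axis=0).div(span.where(~constant, 1.0), axis=0)
    scaled.loc[constant] = 0.0
    return ExpressionMatrix(scaled, scale=expr.scale, provenance=f"{expr.provenance} (pseudobulk)")
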