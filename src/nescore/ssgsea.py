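"""Single-sample GSEA (ssGSEA) scores.

Each sample is scored for each gene set from its own expression ranking:
the score is the sum, over all ranking positions, of the difference between
the weighted empirical CDF of in-set genes (weights ``rank**alpha``,
normalized within the set) and the unweighted ECDF of out-of-set genes.
High scores mean the set's genes sit coordinately near the top of the
sample's expression ranking — used here for MHC class I and immune-cell
infiltration signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .genesets import GeneSetCollection
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SSGSEAScores:
    """Sample x set ssGSEA score matrix with the parameters that made it."""

    scores: pd.DataFrame  # samples x sets
    alpha: float
    normalized: bool


def ssgsea(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> SSGSEAScores:
    """Compute ssGSEA scores for every (sample, gene set) pair.

    Genes are ranked within each sample by decreasing expression (average
    ranks on ties, so the top gene has rank N). With ``normalize`` the whole
    output matrix is divided by its global range, as the GSVA convention
    does. Sets with empty or full intersection with the matrix genes are
    skipped with a diagnostic.
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    values = expr.values
    n_genes = values.shape[0]
    if n_genes < 2:
        raise ValidationError("need at least 2 genes for ssGSEA")
    genes = np.asarray(values.index, dtype=object)
    X = values.to_numpy(dtype=float)
    # rank 1 = lowest expression, N = highest; average ties
    ranks = np.apply_along_axis(lambda c: rankdata(c, method="average"), 0, X)
    # descending order of expression per sample; stable so ties keep row order
    order = np.argsort(-ranks, axis=0, kind="stable")

    columns: dict[str, np.ndarray] = {}
    for name, members in sets:
        in_set = np.isin(genes, list(members))
        k = int(in_set.sum())
        if k == 0:
            logger.warning("set %r shares no genes with the matrix; skipped", name)
            continue
        if k == n_genes:
            logger.warning("set %r covers every matrix gene; skipped", name)
            continue
        out = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            idx = order[:, j]
            hit = in_set[idx]
            w = np.where(hit, ranks[idx, j] ** alpha, 0.0)
            total = w.sum()
            cdf_in = np.cumsum(w) / (total if total > 0 else 1.0)
            cdf_out = np.cumsum(~hit) / (n_genes - k)
            out[j] = float(np.sum(cdf_in - cdf_out))
        columns[name] = out
    scores = pd.DataFrame(columns, index=list(values.columns))
    if normalize and not scores.empty:
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        if span > 0:
            scores = scores / span
        else:
            logger.warning("ssGSEA scores have zero spread; normalization skipped")
    return SSGSEAScores(scores, alpha=alpha, normalized=normalize)
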