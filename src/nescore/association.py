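"""Association statistics around the NE score.

Gene-level Pearson correlation screens (with exact t-based p-values and
Benjamini-Hochberg adjustment), two-group t-tests, pairwise correlation
panels, and the sign-proportion chi-squared test that asks whether a gene
category (e.g. innate-immunity genes) is negatively associated with the NE
score more often than the background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignProportionTest:
    """2x2 sign-enrichment result: set vs background by negative-r status."""

    set_name: str
    n_neg_in_set: int
    n_nonneg_in_set: int
    n_neg_background: int
    n_nonneg_background: int
    chi2: float
    pvalue: float


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must be finite and in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pearson_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, np.finfo(float).tiny, np.minimum(p, 1.0))


def correlate_genes_with_score(
    expr: ExpressionMatrix, scores: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Pearson correlation of every gene with the NE score.

    Pairwise-complete observations per gene (NaNs drop that sample for that
    gene, with the per-gene n recorded); constant genes and genes with
    fewer than 3 complete pairs are excluded with a logged count. Returns a
    DataFrame with columns gene, r, n, pvalue, padj (BH over tested genes).
    """
    values = expr.values
    if isinstance(scores, pd.Series):
        scores = scores.reindex(values.columns).to_numpy(dtype=float)
    else:
        scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != values.shape[1]:
        raise ValidationError("score vector length does not match sample count")
    if values.shape[1] < 3:
        raise ValidationError("need >= 3 samples")
    X = values.to_numpy(dtype=float)
    rows = []
    n_excluded = 0
    for gene, x in zip(values.index, X):
        mask = np.isfinite(x) & np.isfinite(scores)
        n = int(mask.sum())
        if n < 3:
            n_excluded += 1
            continue
        xv, sv = x[mask], scores[mask]
        if np.ptp(xv) == 0 or np.ptp(sv) == 0:
            n_excluded += 1
            continue
        r = float(np.corrcoef(xv, sv)[0, 1])
        rows.append((gene, np.clip(r, -1, 1), n))
    if n_excluded:
        logger.info("excluded %d gene(s) (constant or < 3 complete pairs)", n_excluded)
    if not rows:
        raise ValidationError("no testable genes")
    out = pd.DataFrame(rows, columns=["gene", "r", "n"])
    out["pvalue"] = _pearson_pvalue(out["r"].to_numpy(), out["n"].to_numpy())
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = False
) -> tuple[float, float, tuple[float, float]]:
    """Two-sided two-sample t-test (Welch by default).

    Returns ``(t, pvalue, (mean_a, mean_b))``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValidationError("both groups have zero variance; t undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue), (float(a.mean()), float(b.mean()))


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 table.

    Classic ``sum((O - E)^2 / E)`` with expected counts from the margins;
    two-sided p from the chi-squared distribution with 1 df. Any zero
    row or column margin is an error.
    """
    O = np.asarray(table, dtype=float)
    if O.shape != (2, 2) or (O < 0).any():
        raise ValidationError("need a 2x2 table of nonnegative counts")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    for name, margin in (("row", row), ("column", col)):
        if (margin == 0).any():
            raise ValidationError(f"zero {name} margin in 2x2 table")
    E = np.outer(row, col) / O.sum()
    chi2 = float(((O - E) ** 2 / E).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def sign_proportion_test(
    associations: pd.DataFrame,
    gene_set: Sequence[str],
    set_name: str = "set",
    significant_only: bool = False,
    alpha: float = 0.05,
) -> SignProportionTest:
    """Is a gene category negatively correlated with the score more often?

    Builds the 2x2 table (in-set vs background) x (negative r vs
    nonnegative r) from a ``correlate_genes_with_score`` result and applies
    the Pearson chi-squared test without continuity correction. With
    ``significant_only`` a gene counts as negative only when r < 0 and
    padj <= alpha.
    """
    members = set(gene_set)
    in_set = associations["gene"].isin(members).to_numpy()
    if not in_set.any():
        raise ValidationError("gene set shares no genes with the tested genes")
    if in_set.all():
        raise ValidationError("background is empty: every tested gene is in the set")
    neg = associations["r"].to_numpy() < 0
    if significant_only:
        neg &= associations["padj"].to_numpy() <= alpha
    table = np.array(
        [
            [int((neg & in_set).sum()), int((~neg & in_set).sum())],
            [int((neg & ~in_set).sum()), int((~neg & ~in_set).sum())],
        ]
    )
    chi2, pvalue = chi2_2x2(table)
    return SignProportionTest(
        set_name, int(table[0, 0]), int(table[0, 1]), int(table[1, 0]), int(table[1, 1]),
        chi2, pvalue,
    )


def pairwise_correlation_panel(
    variables: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r and p over named variables of equal length.

    Returns ``(r, p)`` DataFrames; r is symmetric with a unit diagonal, the
    diagonal of p is NaN (self-correlation is not a test).
    """
    names = list(variables)
    if len(names) < 2:
        raise ValidationError("need at least two variables")
    arrays = [np.asarray(variables[k], dtype=float) for k in names]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValidationError("variables differ in length")
    if n < 3:
        raise ValidationError("need vectors of length >= 3")
    R = np.corrcoef(np.vstack(arrays))
    np.fill_diagonal(R, 1.0)
    P = _pearson_pvalue(R, np.full_like(R, n))
    np.fill_diagonal(P, np.nan)
    return (
        pd.DataFrame(R, index=names, columns=names),
        pd.DataFrame(P, index=names, columns=names),
    )
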