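"""Deterministic arithmetic for IHC and qPCR quantifications.

H-score summarizes nuclear staining from the percentage of nuclei at each
intensity level (3+ strong, 2+ moderate, 1+ weak, remainder unstained):
``H = 3*%strong + 2*%moderate + 1*%weak``, range 0-300. Cell density is
cells per mm^2 of analyzed tissue. qPCR relative expression follows the
ddCt convention: per-sample median Ct of target and of the PPIA control
over replicates, ``2**(Ct_control - Ct_target)``, scaled by the median of
the parental samples' normalized values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class IntensityBreakdown:
    """Percent of nuclei at strong (3+), moderate (2+), weak (1+) intensity."""

    pct_strong: float
    pct_moderate: float
    pct_weak: float

    def __post_init__(self) -> None:
        for name, v in (("pct_strong", self.pct_strong), ("pct_moderate", self.pct_moderate),
                        ("pct_weak", self.pct_weak)):
            if not np.isfinite(v) or v < 0 or v > 100:
                raise ValidationError(f"{name}={v!r} outside [0, 100]")
        if self.pct_strong + self.pct_moderate + self.pct_weak > 100 + 1e-9:
            raise ValidationError("intensity percentages sum to more than 100")


def h_score(breakdown: IntensityBreakdown) -> float:
    """IHC H-score: 3*%strong + 2*%moderate + 1*%weak (0-300)."""
    return 3.0 * breakdown.pct_strong + 2.0 * breakdown.pct_moderate + 1.0 * breakdown.pct_weak


def h_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """H-scores for a TSV-style table (sample, pct_strong, pct_moderate, pct_weak)."""
    required = {"sample", "pct_strong", "pct_moderate", "pct_weak"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"missing columns {sorted(missing)}")
    out = table[["sample"]].copy()
    out["h_score"] = [
        h_score(IntensityBreakdown(row.pct_strong, row.pct_moderate, row.pct_weak))
        for row in table.itertuples()
    ]
    return out


def cell_density(count: float, area_mm2: float) -> float:
    """Cells per mm^2 of analyzed tissue."""
    if count < 0:
        raise ValidationError("cell count must be nonnegative")
    if area_mm2 <= 0:
        raise ValidationError("area must be positive")
    return count / area_mm2


def qpcr_normalized_value(
    ct_target: Sequence[float],
    ct_control: Sequence[float],
    mode: str = "ct_median",
) -> float:
    """Control-normalized expression from replicate Ct values.

    ``ct_median`` (default) takes the median Ct of target and control
    separately, then ``2**(median_control - median_target)``;
    ``delta_ct_median`` takes the median of per-replicate
    (control - target) differences before exponentiating (requires paired
    replicates).
    """
    t = np.asarray(ct_target, dtype=float)
    c = np.asarray(ct_control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValidationError("need at least one replicate of target and control")
    if not (np.isfinite(t).all() and np.isfinite(c).all()) or (t <= 0).any() or (c <= 0).any():
        raise ValidationError("Ct values must be finite and positive")
    if mode == "ct_median":
        return float(2.0 ** (np.median(c) - np.median(t)))
    if mode == "delta_ct_median":
        if t.size != c.size:
            raise ValidationError("delta_ct_median needs paired replicates")
        return float(2.0 ** np.median(c - t))
    raise ValidationError(f"unknown mode {mode!r}")


def qpcr_relative_expression(
    normalized: Mapping[str, float], parental_samples: Sequence[str]
) -> dict[str, float]:
    """Fold change per sample: normalized value / median of parental values."""
    parents = [s for s in parental_samples if s in normalized]
    if not parents:
        raise ValidationError("parental group is empty")
    ref = float(np.median([normalized[s] for s in parents]))
    if ref <= 0:
        raise ValidationError("parental median is not positive")
    return {s: v / ref for s, v in normalized.items()}


def qpcr_fold_changes(
    table: pd.DataFrame,
    parental_samples: Sequence[str],
    mode: str = "ct_median",
) -> pd.DataFrame:
    """Per-sample fold change from a replicate-level Ct table.

    ``table`` columns: sample, replicate, ct_target, ct_control (one row
    per replicate).
    """
    required = {"sample", "ct_target", "ct_control"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"missing columns {sorted(missing)}")
    normalized = {
        str(sample): qpcr_normalized_value(grp["ct_target"], grp["ct_control"], mode=mode)
        for sample, grp in table.groupby("sample", sort=False)
    }
    folds = qpcr_relative_expression(normalized, [str(s) for s in parental_samples])
    return pd.DataFrame(
        {"sample": list(folds), "normalized": [normalized[s] for s in folds],
         "fold": list(folds.values())}
    )
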