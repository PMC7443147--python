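"""Differential-expression filtering and gene-set overlap arithmetic.

Genes pass the filter at linear fold change >= ``fc_threshold`` (up) or
<= ``1/fc_threshold`` (down) with p below ``p_threshold``; fold changes are
treated/control ratios.  When replicate columns are supplied instead of a p
column, a two-sided unequal-variance t test produces the p values.  Overlap
of two gene sets is summarized as a percentage of the first set plus an
optional upper-tail hypergeometric enrichment probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class DEGResult:
    """Up/down partition of a differential-expression filter."""

    up_genes: set[str]
    down_genes: set[str]

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValidationError("up and down gene sets overlap")

    @property
    def n_total_regulated(self) -> int:
        return len(self.up_genes) + len(self.down_genes)

    @property
    def regulated(self) -> set[str]:
        return self.up_genes | self.down_genes


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe_size: int
    percent_of_a: float
    hypergeometric_p: float


def compute_p_values(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.Series:
    """Row-wise two-sided Welch t-test p values between two column groups."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each replicate group needs at least 2 columns")
    a = expr[list(group_a)].to_numpy(dtype=float)
    b = expr[list(group_b)].to_numpy(dtype=float)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return pd.Series(res.pvalue, index=expr.index, name="p_value")


def filter_deg(
    expr: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.01,
    group_a: Optional[Sequence[str]] = None,
    group_b: Optional[Sequence[str]] = None,
) -> DEGResult:
    """Partition genes into up/down-regulated sets.

    ``expr`` must carry ``gene`` and ``fold_change`` columns plus either a
    ``p_value`` column or two replicate column groups from which p values
    are computed.  Boundary rule: the fold-change threshold is inclusive
    (>= fc for up, <= 1/fc for down); the p threshold is strict.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    for col in ("gene", "fold_change"):
        if col not in expr.columns:
            raise ValidationError(f"expression table missing column {col!r}")
    fc = expr["fold_change"].astype(float)
    if (fc <= 0).any():
        raise ValidationError("fold_change values must be positive")
    if "p_value" in expr.columns:
        p = expr["p_value"].astype(float)
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("p_value outside [0, 1]")
    elif group_a and group_b:
        p = compute_p_values(expr, group_a, group_b)
    else:
        raise ValidationError(
            "expression table needs a p_value column or replicate groups"
        )
    sig = p < p_threshold
    up = set(expr.loc[sig & (fc >= fc_threshold), "gene"])
    down = set(expr.loc[sig & (fc <= 1.0 / fc_threshold), "gene"])
    return DEGResult(up_genes=up, down_genes=down)


def overlap_sets(
    a: Collection[str],
    b: Collection[str],
    universe_size: int,
) -> OverlapResult:
    """Overlap of two gene sets within a universe of ``universe_size`` genes.

    ``percent_of_a`` is ``100 * |a & b| / |a|`` (unrounded; round only at
    presentation).  ``hypergeometric_p`` is the probability of drawing at
    least the observed overlap when ``|b|`` genes are sampled without
    replacement from the universe — an optional enrichment annotation.
    """
    a, b = set(a), set(b)
    if not a:
        raise ValidationError("set a is empty")
    union = a | b
    if universe_size < len(union):
        raise ValidationError(
            f"universe size {universe_size} smaller than union {len(union)}"
        )
    n_overlap = len(a & b)
    p = float(
        stats.hypergeom.sf(n_overlap - 1, universe_size, len(a), len(b))
    )
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_overlap=n_overlap,
        universe_size=universe_size,
        percent_of_a=100.0 * n_overlap / len(a),
        hypergeometric_p=p,
    )


def overlap_percent(n_overlap: int, n_a: int) -> float:
    """Plain percentage ``100 * n_overlap / n_a`` for printed-count checks."""
    if n_a <= 0:
        raise ValueError("n_a must be positive")
    if n_overlap < 0 or n_overlap > n_a:
        raise ValueError("n_overlap must lie in [0, n_a]")
    return 100.0 * n_overlap / n_a
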