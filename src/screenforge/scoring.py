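"""Guide scoring and concordance-based hit calling.

A guide's score is its median-corrected log2 fold change: mean log2
abundance over treated samples minus mean over control samples, centered by
subtracting the median raw score over all guides.  A gene's score is the
mean of its guides' corrected scores, and a gene is called a hit when at
least ``min_concordant`` of its guides move past ``+tau`` (up) or ``-tau``
(down) in the same direction.  Ties at exactly ``tau`` are neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .library import LibraryReference
from .normalization import SCALE_LOG2, NormalizedMatrix

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"


def guide_scores(
    log_matrix: NormalizedMatrix,
    treated_samples: Sequence[str],
    control_samples: Sequence[str],
    median_correct: bool = True,
) -> pd.DataFrame:
    """Per-guide log2 fold changes, treated minus control.

    Returns a DataFrame indexed by guide_id with columns ``lfc_raw`` and
    ``lfc_corrected``.  ``lfc_raw`` is the mean of the treated columns'
    log2 values minus the mean of the control columns'; ``lfc_corrected``
    subtracts the median ``lfc_raw`` over all guides (identity when
    ``median_correct`` is false).
    """
    if log_matrix.scale != SCALE_LOG2:
        raise ValueError("guide_scores expects a log2-scale matrix")
    treated = list(treated_samples)
    control = list(control_samples)
    if not treated or not control:
        raise ValidationError("treated and control sample lists must be non-empty")
    overlap = set(treated) & set(control)
    if overlap:
        raise ValidationError(
            f"sample(s) {sorted(overlap)} appear in both treated and control"
        )
    missing = (set(treated) | set(control)) - set(log_matrix.data.columns)
    if missing:
        raise ValidationError(f"unknown sample id(s) {sorted(missing)}")

    lfc_raw = (
        log_matrix.data[treated].mean(axis=1)
        - log_matrix.data[control].mean(axis=1)
    )
    shift = float(np.median(lfc_raw.values)) if median_correct else 0.0
    out = pd.DataFrame(
        {"lfc_raw": lfc_raw, "lfc_corrected": lfc_raw - shift}
    )
    out.index.name = "guide_id"
    return out


def gene_scores(
    gscores: pd.DataFrame,
    lib: LibraryReference,
    tau: float = 0.0,
    min_concordant: int = 3,
) -> pd.DataFrame:
    """Aggregate guide scores to genes and call concordance hits.

    Returns a DataFrame indexed by gene with columns ``score`` (mean of the
    gene's ``lfc_corrected``), ``n_guides``, ``n_up`` (guides strictly above
    ``+tau``), ``n_down`` (strictly below ``-tau``), ``hit`` and
    ``direction``.  Genes with fewer guides than ``min_concordant`` are not
    callable (hit false, direction none) and trigger a warning.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if min_concordant < 1:
        raise ValueError("min_concordant must be positive")
    unknown = [g for g in gscores.index if g not in lib]
    if unknown:
        raise ValidationError(
            f"guide(s) {unknown[:5]} absent from the library"
        )

    genes = gscores.assign(gene=[lib.gene_of(g) for g in gscores.index])
    rows = []
    small_genes = []
    for gene, sub in genes.groupby("gene", sort=False):
        vals = sub["lfc_corrected"].values
        n_up = int((vals > tau).sum())
        n_down = int((vals < -tau).sum())
        n = len(vals)
        up_ok = n_up >= min_concordant
        down_ok = n_down >= min_concordant
        if n < min_concordant:
            small_genes.append(gene)
            hit, direction = False, DIRECTION_NONE
        elif up_ok and down_ok:
            # both sides qualify only when min_concordant <= n/2: larger wins
            if n_up > n_down:
                hit, direction = True, DIRECTION_UP
            elif n_down > n_up:
                hit, direction = True, DIRECTION_DOWN
            else:
                hit, direction = False, DIRECTION_NONE
        elif up_ok:
            hit, direction = True, DIRECTION_UP
        elif down_ok:
            hit, direction = True, DIRECTION_DOWN
        else:
            hit, direction = False, DIRECTION_NONE
        rows.append(
            {
                "gene": gene,
                "score": float(vals.mean()),
                "n_guides": n,
                "n_up": n_up,
                "n_down": n_down,
                "hit": hit,
                "direction": direction,
            }
        )
    if small_genes:
        warnings.warn(
            f"{len(small_genes)} gene(s) have fewer than {min_concordant} "
            f"guides and are not callable (e.g. {small_genes[:3]})"
        )
    out = pd.DataFrame(rows).set_index("gene")
    return out


def rank_genes(genes: pd.DataFrame, direction: str) -> list[str]:
    """Order genes for one direction: hits first by |score| descending.

    Ties break lexicographically by gene symbol.  Non-hit genes follow,
    ordered by score in the requested direction then symbol, so the result
    is a deterministic total ordering of the input genes.
    """
    if direction not in (DIRECTION_UP, DIRECTION_DOWN):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if genes.empty:
        raise ValidationError("gene table is empty")
    sign = 1.0 if direction == DIRECTION_UP else -1.0
    hits = genes[genes["hit"] & (genes["direction"] == direction)]
    rest = genes.drop(hits.index)
    hits_order = sorted(
        hits.index, key=lambda g: (-abs(hits.at[g, "score"]), g)
    )
    rest_order = sorted(
        rest.index, key=lambda g: (-sign * rest.at[g, "score"], g)
    )
    return hits_order + rest_order


def write_guide_scores(
    gscores: pd.DataFrame, lib: LibraryReference, path: str | Path
) -> None:
    """Write the guide-score TSV: guide_id, gene, lfc_raw, lfc_corrected."""
    out = gscores.assign(gene=[lib.gene_of(g) for g in gscores.index])
    out[["gene", "lfc_raw", "lfc_corrected"]].to_csv(
        path, sep="\t", index_label="guide_id"
    )


def write_gene_scores(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index_label="gene")
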