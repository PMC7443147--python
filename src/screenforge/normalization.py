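"""Count normalization: reads-per-million per sample, then log2(x + 1).

Each sequenced sample is one condition in the plate layout, so "per
condition" totals are per-column totals; replicate averaging happens later
in scoring.  The +1 pseudocount makes guides with zero reads loggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

SCALE_RPM = "rpm"
SCALE_LOG2 = "log2"


@dataclass
class NormalizedMatrix:
    """Guide x sample matrix tagged with its scale (``rpm`` or ``log2``)."""

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_RPM, SCALE_LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")

    def write(self, path: str | Path, decimals: int = 4) -> None:
        """Write as TSV with a ``# scale:`` header comment line.

        Values are rounded to ``decimals`` places on disk only; in-memory
        values keep full floating precision.
        """
        with open(path, "w") as fh:
            fh.write(f"# scale: {self.scale}\n")
            self.data.round(decimals).to_csv(fh, sep="\t", index_label="guide_id")


def read_normalized(path: str | Path) -> NormalizedMatrix:
    """Read a normalized TSV written by :meth:`NormalizedMatrix.write`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# scale:"):
            raise FormatError(f"{path}: missing '# scale:' header line")
        scale = header.split(":", 1)[1].strip()
        df = pd.read_csv(fh, sep="\t", index_col="guide_id")
    return NormalizedMatrix(df, scale)


def rpm_normalize(counts: pd.DataFrame, allow_empty: bool = False) -> NormalizedMatrix:
    """Scale each sample column to reads per million.

    ``value[g, s] = counts[g, s] / column_total(s) * 1e6``.  A column with
    zero total is an error unless ``allow_empty``, in which case it is set
    to all zeros with a warning.
    """
    if (counts.values < 0).any():
        raise ValidationError("count matrix contains negative values")
    totals = counts.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty and not allow_empty:
        raise ValidationError(
            f"sample(s) {empty} have zero total reads; pass allow_empty to "
            "emit zero columns instead"
        )
    if empty:
        warnings.warn(f"sample(s) {empty} have zero total reads; emitting zeros")
    safe_totals = totals.replace(0, 1)
    rpm = counts.div(safe_totals, axis=1) * 1e6
    return NormalizedMatrix(rpm.astype(float), SCALE_RPM)


def log2_transform(rpm: NormalizedMatrix) -> NormalizedMatrix:
    """Elementwise ``log2(value + 1)`` of an RPM matrix."""
    if rpm.scale != SCALE_RPM:
        raise ValueError(
            f"log2_transform expects an rpm-scale matrix, got {rpm.scale!r}"
        )
    return NormalizedMatrix(np.log2(rpm.data + 1.0), SCALE_LOG2)


def normalize(counts: pd.DataFrame, log2: bool = True, allow_empty: bool = False) -> NormalizedMatrix:
    """RPM-normalize and optionally log2-transform in one call."""
    rpm = rpm_normalize(counts, allow_empty=allow_empty)
    return log2_transform(rpm) if log2 else rpm
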