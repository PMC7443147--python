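"""Protein half-life from cycloheximide-chase time courses.

Band intensities are modeled as first-order decay; ordinary least squares
of ln(intensity) on time gives the decay rate k = -slope and half-life
ln(2)/k.  Non-decaying series (k <= 0) are flagged instead of yielding a
negative half-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class DecaySeries:
    """Paired (hours, relative intensity) observations for one condition."""

    times: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensities):
            raise ValidationError("times and intensities differ in length")
        if len(self.times) < 3:
            raise ValidationError("a decay series needs at least 3 points")
        if len(set(self.times)) < 3:
            raise ValidationError("a decay series needs >= 3 distinct times")
        if any(t < 0 for t in self.times):
            raise ValidationError("times must be nonnegative")
        if any(x <= 0 for x in self.intensities):
            raise ValidationError(
                "intensities must be strictly positive (log undefined at 0); "
                "floor zeros explicitly before fitting if appropriate"
            )


@dataclass(frozen=True)
class HalfLifeEstimate:
    k: float  # first-order decay rate, per hour
    half_life: float  # ln(2)/k hours; inf when not decaying
    r_squared: float
    n_points: int

    @property
    def decaying(self) -> bool:
        return self.k > 0


def fit_half_life(series: DecaySeries) -> HalfLifeEstimate:
    """Log-linear OLS fit of a decay series.

    Returns the decay rate, half-life (``inf`` with ``decaying`` false when
    the slope is nonnegative), the r-squared of the log-linear fit, and the
    number of points used.
    """
    t = np.asarray(series.times, dtype=float)
    y = np.log(np.asarray(series.intensities, dtype=float))
    res = stats.linregress(t, y)
    k = -float(res.slope)
    half_life = math.log(2) / k if k > 0 else math.inf
    return HalfLifeEstimate(
        k=k,
        half_life=half_life,
        r_squared=float(res.rvalue) ** 2,
        n_points=len(t),
    )


def load_decay_table(path: str | Path) -> dict[str, DecaySeries]:
    """Read a CSV ``time_h,intensity[,condition]``; one series per condition."""
    df = pd.read_csv(path)
    missing = {"time_h", "intensity"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if "condition" not in df.columns:
        df = df.assign(condition="all")
    out = {}
    for cond, sub in df.groupby("condition", sort=False):
        out[str(cond)] = DecaySeries(
            times=tuple(float(x) for x in sub["time_h"]),
            intensities=tuple(float(x) for x in sub["intensity"]),
        )
    return out


def fit_half_life_table(series_by_condition: dict[str, DecaySeries]) -> pd.DataFrame:
    rows = []
    for cond, series in series_by_condition.items():
        est = fit_half_life(series)
        rows.append(
            {
                "condition": cond,
                "k_per_h": est.k,
                "half_life_h": est.half_life,
                "r_squared": est.r_squared,
                "n_points": est.n_points,
                "decaying": est.decaying,
            }
        )
    return pd.DataFrame(rows)
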