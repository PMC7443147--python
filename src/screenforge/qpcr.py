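"""Relative quantification from threshold cycles.

qRT-PCR expression uses the 2^-ddCT method: normalize a target's mean CT by
a reference gene within each sample, difference against the control sample,
and exponentiate.  ChIP enrichment uses dCT against the input chromatin,
reported as 2^-dCT fold of input.  Amplification efficiency is fixed at 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate threshold cycles for one (sample, target) pair."""

    sample_id: str
    target: str
    replicate_cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.replicate_cts:
            raise ValidationError(
                f"{self.sample_id}/{self.target}: no CT replicates"
            )
        for ct in self.replicate_cts:
            if not math.isfinite(ct) or ct <= 0:
                raise ValidationError(
                    f"{self.sample_id}/{self.target}: invalid CT {ct}"
                )

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.replicate_cts))

    @property
    def sem_ct(self) -> Optional[float]:
        """Standard error of the mean; None for a single replicate."""
        n = len(self.replicate_cts)
        if n < 2:
            return None
        return float(np.std(self.replicate_cts, ddof=1) / math.sqrt(n))


@dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    target: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    sem_ddct: Optional[float] = None


@dataclass(frozen=True)
class ChipEnrichment:
    target: str
    delta_ct: float
    enrichment: float  # 2^-dCT, fold of input


def ddct(
    target_ct: CtMeasurement,
    reference_ct: CtMeasurement,
    control_target_ct: CtMeasurement,
    control_reference_ct: CtMeasurement,
) -> RelativeExpression:
    """2^-ddCT relative expression of a target against a control sample.

    dCT = mean CT(target) - mean CT(reference) within each sample;
    ddCT = dCT(sample) - dCT(control); fold change = 2^-ddCT.  The sem of
    ddCT is propagated in quadrature when all four sems exist.
    """
    if target_ct.target != control_target_ct.target:
        raise ValidationError(
            f"target mismatch: {target_ct.target!r} vs "
            f"{control_target_ct.target!r}"
        )
    if reference_ct.target != control_reference_ct.target:
        raise ValidationError(
            f"reference mismatch: {reference_ct.target!r} vs "
            f"{control_reference_ct.target!r}"
        )
    d_sample = target_ct.mean_ct - reference_ct.mean_ct
    d_control = control_target_ct.mean_ct - control_reference_ct.mean_ct
    dd = d_sample - d_control
    sems = [
        m.sem_ct
        for m in (target_ct, reference_ct, control_target_ct, control_reference_ct)
    ]
    sem_ddct = (
        math.sqrt(sum(s**2 for s in sems)) if all(s is not None for s in sems) else None
    )
    return RelativeExpression(
        sample_id=target_ct.sample_id,
        target=target_ct.target,
        delta_ct=d_sample,
        delta_delta_ct=dd,
        fold_change=2.0 ** (-dd),
        sem_ddct=sem_ddct,
    )


def chip_enrichment(ip_ct: CtMeasurement, input_ct: CtMeasurement) -> ChipEnrichment:
    """ChIP signal normalized to input: dCT = CT(ip) - CT(input), 2^-dCT."""
    if ip_ct.target != input_ct.target:
        raise ValidationError(
            f"amplicon mismatch: {ip_ct.target!r} vs {input_ct.target!r}"
        )
    d = ip_ct.mean_ct - input_ct.mean_ct
    return ChipEnrichment(target=ip_ct.target, delta_ct=d, enrichment=2.0 ** (-d))


# -- long-format CT table IO ----------------------------------------------


def load_ct_table(path: str | Path) -> dict[tuple[str, str], CtMeasurement]:
    """Read a long-format CT CSV (``sample_id,target,ct``, one replicate/row)."""
    df = pd.read_csv(path)
    missing = {"sample_id", "target", "ct"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[tuple[str, str], CtMeasurement] = {}
    for (sample, target), sub in df.groupby(["sample_id", "target"], sort=False):
        out[(str(sample), str(target))] = CtMeasurement(
            sample_id=str(sample),
            target=str(target),
            replicate_cts=tuple(float(x) for x in sub["ct"]),
        )
    return out


def ddct_table(
    measurements: dict[tuple[str, str], CtMeasurement],
    reference: str,
    control_sample: str,
) -> pd.DataFrame:
    """Apply :func:`ddct` to every (sample, target) pair in a CT table."""
    samples = sorted({s for s, _ in measurements}, key=str)
    targets = sorted({t for _, t in measurements if t != reference})
    rows = []
    for sample in samples:
        for target in targets:
            key, ref_key = (sample, target), (sample, reference)
            ctl_key, ctl_ref = (control_sample, target), (control_sample, reference)
            for k in (key, ref_key, ctl_key, ctl_ref):
                if k not in measurements:
                    raise ValidationError(f"missing CT measurement for {k}")
            rel = ddct(
                measurements[key],
                measurements[ref_key],
                measurements[ctl_key],
                measurements[ctl_ref],
            )
            rows.append(
                {
                    "sample_id": sample,
                    "target": target,
                    "delta_ct": rel.delta_ct,
                    "delta_delta_ct": rel.delta_delta_ct,
                    "fold_change": rel.fold_change,
                    "sem_ddct": rel.sem_ddct,
                }
            )
    return pd.DataFrame(rows)


def chip_table(
    measurements: dict[tuple[str, str], CtMeasurement],
    input_label: str = "input",
) -> pd.DataFrame:
    """Apply :func:`chip_enrichment` per target, IP samples against input."""
    rows = []
    for (sample, target), m in measurements.items():
        if sample == input_label:
            continue
        input_key = (input_label, target)
        if input_key not in measurements:
            raise ValidationError(f"no input CTs for amplicon {target!r}")
        enr = chip_enrichment(m, measurements[input_key])
        rows.append(
            {
                "sample_id": sample,
                "target": target,
                "delta_ct": enr.delta_ct,
                "enrichment": enr.enrichment,
            }
        )
    return pd.DataFrame(rows)
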