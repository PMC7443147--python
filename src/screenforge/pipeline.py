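"""End-to-end screen runs: count -> normalize -> score -> call -> rank.

Configuration lives in a plain ``key = value`` text file; CLI flags
override file values, which override defaults.  Every run writes its stage
TSVs plus a JSON report that echoes the effective configuration, so a run
is reproducible from its report alone.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .errors import FormatError, ValidationError
from .extraction import process_fastq, write_counts
from .library import load_library, load_sample_sheet
from .normalization import log2_transform, read_normalized, rpm_normalize
from .scoring import (
    gene_scores,
    guide_scores,
    rank_genes,
    write_gene_scores,
    write_guide_scores,
)

logger = logging.getLogger("screenforge")

_DEFAULTS = {
    "mode": "per_file",
    "anchor": "CACCG",
    "spacer_length": 20,
    "max_mismatch": 0,
    "tau": 0.0,
    "min_concordant": 3,
}

_INT_KEYS = {"spacer_length", "max_mismatch", "min_concordant", "seed"}
_FLOAT_KEYS = {"tau"}


@dataclass
class RunConfig:
    library: str
    samples: str
    out_dir: str
    fastq: Optional[str] = None  # inline-mode FASTQ path; per_file uses the sheet
    mode: str = "per_file"
    anchor: str = "CACCG"
    spacer_length: int = 20
    max_mismatch: int = 0
    tau: float = 0.0
    min_concordant: int = 3
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, overrides: Optional[dict] = None) -> "RunConfig":
        """Parse a ``key = value`` config file; overrides win over file values."""
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            if key in _INT_KEYS:
                values[key] = int(val)
            elif key in _FLOAT_KEYS:
                values[key] = float(val)
            else:
                values[key] = val
        if overrides:
            for k, v in overrides.items():
                if v is not None:
                    values[k] = v
        try:
            return cls(**values)
        except TypeError as exc:
            raise FormatError(f"{path}: {exc}") from exc

    def validate(self) -> None:
        for name in ("library", "samples"):
            if not Path(getattr(self, name)).is_file():
                raise ValidationError(f"{name} file not found: {getattr(self, name)}")
        if self.mode not in ("per_file", "inline_prefix"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "inline_prefix" and not self.fastq:
            raise ValidationError("inline_prefix mode requires a fastq path")
        if self.max_mismatch not in (0, 1):
            raise ValidationError("max_mismatch must be 0 or 1")
        if self.tau < 0 or self.min_concordant < 1:
            raise ValidationError("tau must be >= 0 and min_concordant >= 1")


@dataclass
class RunReport:
    version: str
    config: dict
    extraction: dict
    normalization: dict
    scoring: dict
    started: str
    finished: str = ""
    warnings: list[str] = field(default_factory=list)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_screen_pipeline(config: RunConfig) -> RunReport:
    """Run the full screen pipeline and write all stage outputs.

    Validation failures abort before any output is written.
    """
    config.validate()
    lib = load_library(config.library, spacer_length=config.spacer_length)
    sheet = load_sample_sheet(config.samples)
    sheet.require_both_arms()

    if config.mode == "per_file":
        fastq_inputs = {}
        for rec in sheet.rows:
            if not rec.fastq_path:
                raise ValidationError(f"sample {rec.sample_id} has no fastq_path")
            if not Path(rec.fastq_path).is_file():
                raise ValidationError(
                    f"fastq for sample {rec.sample_id} not found: {rec.fastq_path}"
                )
            fastq_inputs[rec.sample_id] = rec.fastq_path
    else:
        fastq_inputs = [config.fastq]

    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("counting reads from %d input(s)", len(fastq_inputs))
    counts, stats = process_fastq(
        fastq_inputs,
        lib,
        sheet,
        mode=config.mode,
        anchor=config.anchor,
        spacer_length=config.spacer_length,
        max_mismatch=config.max_mismatch,
    )
    write_counts(counts, out_dir / "counts.tsv")
    stats.write_json(out_dir / "extraction_stats.json")

    rpm = rpm_normalize(counts)
    logm = log2_transform(rpm)
    rpm.write(out_dir / "rpm.tsv")
    logm.write(out_dir / "norm.tsv")
    # score from the written matrix so a pipeline run is byte-identical to
    # invoking the stages one by one on each other's outputs
    logm = read_normalized(out_dir / "norm.tsv")

    treated = sheet.samples_by_condition("treated")
    control = sheet.samples_by_condition("control")
    gsc = guide_scores(logm, treated, control)
    gene_tab = gene_scores(gsc, lib, tau=config.tau, min_concordant=config.min_concordant)
    write_guide_scores(gsc, lib, out_dir / "guide_scores.tsv")
    write_gene_scores(gene_tab, out_dir / "gene_scores.tsv")

    for direction in ("up", "down"):
        ranked = rank_genes(gene_tab, direction)
        (out_dir / f"ranked_{direction}.txt").write_text("\n".join(ranked) + "\n")

    n_hits = int(gene_tab["hit"].sum())
    report = RunReport(
        version=__version__,
        config=asdict(config),
        extraction=stats.to_dict(),
        normalization={
            "column_totals": counts.sum(axis=0).to_dict(),
            "n_guides": int(counts.shape[0]),
        },
        scoring={
            "n_genes": int(gene_tab.shape[0]),
            "n_hits": n_hits,
            "n_up_hits": int((gene_tab["direction"] == "up").sum()),
            "n_down_hits": int((gene_tab["direction"] == "down").sum()),
            "treated_samples": treated,
            "control_samples": control,
        },
        started=started,
    )
    report.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    report.write_json(out_dir / "report.json")
    logger.info("pipeline complete: %d genes, %d hits", gene_tab.shape[0], n_hits)
    return report
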