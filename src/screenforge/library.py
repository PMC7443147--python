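"""sgRNA library reference and sample sheet models.

The library is a 3-column CSV (``guide_id,gene,spacer``) mapping each guide
to its gene and 20-nt spacer.  The sample sheet is a CSV
(``sample_id,barcode,condition,replicate,fastq_path``) describing the
sequenced samples; barcodes are 8-nt and must be unique.  Both files anchor
every downstream stage: extraction maps spacers through the library,
scoring aggregates guides by gene, and demultiplexing resolves barcodes
through the sheet.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import FormatError, ValidationError

SPACER_LENGTH = 20
BARCODE_LENGTH = 8
DNA_ALPHABET = frozenset("ACGT")
CONDITIONS = ("control", "treated")

#: Default screening coverage floor, cells per guide.
DEFAULT_COVERAGE_FLOOR = 300.0


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: identifier, target gene symbol and 20-nt spacer."""

    guide_id: str
    gene: str
    spacer: str


@dataclass
class LibraryReference:
    """Validated, ordered collection of guides with per-gene grouping.

    Guide ids and spacers are unique; ``genes`` maps each gene symbol to the
    guide ids targeting it, in input order.  Spacer lookup is injective.
    """

    guides: list[GuideRecord]
    spacer_length: int = SPACER_LENGTH
    genes: dict[str, list[str]] = field(init=False, repr=False)
    _by_spacer: dict[str, str] = field(init=False, repr=False)
    _by_guide: dict[str, GuideRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        genes: dict[str, list[str]] = {}
        by_spacer: dict[str, str] = {}
        by_guide: dict[str, GuideRecord] = {}
        for row, g in enumerate(self.guides, start=1):
            if g.guide_id in by_guide:
                raise ValidationError(
                    f"duplicate guide_id {g.guide_id!r} at row {row}"
                )
            if len(g.spacer) != self.spacer_length:
                raise ValidationError(
                    f"row {row} ({g.guide_id}): spacer length "
                    f"{len(g.spacer)} != {self.spacer_length}"
                )
            if not set(g.spacer) <= DNA_ALPHABET:
                bad = sorted(set(g.spacer) - DNA_ALPHABET)
                raise ValidationError(
                    f"row {row} ({g.guide_id}): spacer contains non-ACGT "
                    f"characters {bad}"
                )
            if g.spacer in by_spacer:
                raise ValidationError(
                    f"duplicate spacer shared by guide_ids "
                    f"{by_spacer[g.spacer]!r} and {g.guide_id!r}"
                )
            by_guide[g.guide_id] = g
            by_spacer[g.spacer] = g.guide_id
            genes.setdefault(g.gene, []).append(g.guide_id)
        if not by_guide:
            raise ValidationError("library contains no guides")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "_by_spacer", by_spacer)
        object.__setattr__(self, "_by_guide", by_guide)

    # -- lookups -----------------------------------------------------------

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    @property
    def n_guides(self) -> int:
        return len(self.guides)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def spacer_to_guide(self) -> Mapping[str, str]:
        """Injective spacer -> guide_id mapping (read-only view)."""
        return dict(self._by_spacer)

    def guide(self, guide_id: str) -> GuideRecord:
        return self._by_guide[guide_id]

    def gene_of(self, guide_id: str) -> str:
        return self._by_guide[guide_id].gene

    def __contains__(self, guide_id: str) -> bool:
        return guide_id in self._by_guide

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["guide_id", "gene", "spacer"])
            for g in self.guides:
                w.writerow([g.guide_id, g.gene, g.spacer])


def load_library(path: str | Path, spacer_length: int = SPACER_LENGTH) -> LibraryReference:
    """Read and validate a library CSV with header ``guide_id,gene,spacer``.

    Spacers are uppercased on load.  Row order is preserved.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty library file")
        missing = {"guide_id", "gene", "spacer"} - set(reader.fieldnames)
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {sorted(missing)}"
            )
        guides = [
            GuideRecord(
                guide_id=row["guide_id"].strip(),
                gene=row["gene"].strip(),
                spacer=row["spacer"].strip().upper(),
            )
            for row in reader
        ]
    return LibraryReference(guides, spacer_length=spacer_length)


def write_library(lib: LibraryReference, path: str | Path) -> None:
    lib.write(path)


# -- sample sheet ----------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    barcode: str
    condition: str
    replicate: int
    fastq_path: Optional[str] = None


@dataclass
class SampleSheet:
    """Samples with their demultiplexing barcodes and conditions."""

    rows: list[SampleRecord]

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_bc: set[str] = set()
        for i, r in enumerate(self.rows, start=1):
            if r.sample_id in seen_ids:
                raise ValidationError(f"duplicate sample_id {r.sample_id!r}")
            seen_ids.add(r.sample_id)
            if len(r.barcode) != BARCODE_LENGTH:
                raise ValidationError(
                    f"row {i} ({r.sample_id}): barcode length "
                    f"{len(r.barcode)} != {BARCODE_LENGTH}"
                )
            if not set(r.barcode) <= DNA_ALPHABET:
                raise ValidationError(
                    f"row {i} ({r.sample_id}): barcode contains non-ACGT characters"
                )
            if r.barcode in seen_bc:
                raise ValidationError(f"duplicate barcode {r.barcode!r}")
            seen_bc.add(r.barcode)
            if r.condition not in CONDITIONS:
                raise ValidationError(
                    f"row {i} ({r.sample_id}): condition {r.condition!r} "
                    f"not one of {CONDITIONS}"
                )
            if r.replicate < 1:
                raise ValidationError(
                    f"row {i} ({r.sample_id}): replicate must be >= 1"
                )
        if not self.rows:
            raise ValidationError("sample sheet contains no samples")

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]

    def barcode_to_sample(self) -> dict[str, str]:
        return {r.barcode: r.sample_id for r in self.rows}

    def samples_by_condition(self, condition: str) -> list[str]:
        return [r.sample_id for r in self.rows if r.condition == condition]

    def require_both_arms(self) -> None:
        """Scoring precondition: at least one control and one treated sample."""
        for cond in CONDITIONS:
            if not self.samples_by_condition(cond):
                raise ValidationError(f"sample sheet has no {cond} sample")

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", "barcode", "condition", "replicate", "fastq_path"])
            for r in self.rows:
                w.writerow(
                    [r.sample_id, r.barcode, r.condition, r.replicate, r.fastq_path or ""]
                )


def load_sample_sheet(path: str | Path) -> SampleSheet:
    """Read and validate a sample sheet CSV."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty sample sheet")
        required = {"sample_id", "barcode", "condition", "replicate"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {sorted(missing)}"
            )
        rows = []
        for row in reader:
            try:
                rep = int(row["replicate"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-integer replicate {row['replicate']!r}"
                ) from exc
            rows.append(
                SampleRecord(
                    sample_id=row["sample_id"].strip(),
                    barcode=row["barcode"].strip().upper(),
                    condition=row["condition"].strip().lower(),
                    replicate=rep,
                    fastq_path=(row.get("fastq_path") or "").strip() or None,
                )
            )
    return SampleSheet(rows)


# -- design and coverage reports ------------------------------------------


@dataclass
class DesignReport:
    """Per-gene guide counts checked against an expected design."""

    expected_guides_per_gene: int
    per_gene: list[tuple[str, int, bool]]  # (gene, n_guides, matches)

    @property
    def passed(self) -> bool:
        return all(ok for _, _, ok in self.per_gene)

    @property
    def deviating_genes(self) -> list[str]:
        return [g for g, _, ok in self.per_gene if not ok]

    def guide_counts(self) -> dict[str, int]:
        return {g: n for g, n, _ in self.per_gene}

    def to_dict(self) -> dict:
        return {
            "expected_guides_per_gene": self.expected_guides_per_gene,
            "passed": self.passed,
            "genes": [
                {"gene": g, "n_guides": n, "matches_expected": ok}
                for g, n, ok in self.per_gene
            ],
        }

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tn_guides\tmatches_expected\n")
            for g, n, ok in self.per_gene:
                fh.write(f"{g}\t{n}\t{str(ok).lower()}\n")

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def validate_design(lib: LibraryReference, expected_guides_per_gene: int = 4) -> DesignReport:
    """Check each gene's guide count against the expected per-gene design."""
    if expected_guides_per_gene < 1:
        raise ValueError("expected_guides_per_gene must be positive")
    per_gene = [
        (gene, len(gids), len(gids) == expected_guides_per_gene)
        for gene, gids in lib.genes.items()
    ]
    return DesignReport(expected_guides_per_gene, per_gene)


@dataclass(frozen=True)
class CoverageReport:
    n_cells: float
    n_guides: int
    cells_per_guide: float
    floor: float
    meets_floor: bool


def cells_per_guide(n_cells: float, n_guides: int) -> float:
    """Screening coverage: infected cells divided by library size."""
    if n_guides <= 0:
        raise ValueError("library must contain at least one guide")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    return n_cells / n_guides


def coverage_report(
    n_cells: float,
    lib: LibraryReference | int,
    floor: float = DEFAULT_COVERAGE_FLOOR,
) -> CoverageReport:
    """Coverage of a library by ``n_cells`` cells, checked against a floor.

    ``lib`` may be a :class:`LibraryReference` or a plain guide count.
    """
    n_guides = lib if isinstance(lib, int) else lib.n_guides
    cpg = cells_per_guide(n_cells, n_guides)
    return CoverageReport(
        n_cells=float(n_cells),
        n_guides=n_guides,
        cells_per_guide=cpg,
        floor=floor,
        meets_floor=cpg >= floor,
    )
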