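"""Read-level spacer extraction, demultiplexing, and guide counting.

Each read is resolved in a fixed precedence order so that failure statuses
are reproducible: ``unknown_barcode`` -> ``no_anchor`` ->
``insufficient_length`` -> ``unmapped_spacer`` -> ``ok``.  Extraction takes
the ``spacer_length`` characters immediately after the leftmost exact
occurrence of the vector anchor (default ``CACCG``); the anchor precedes
every insert in the vector, so the first hit is the vector copy.  Quality
scores are ignored throughout.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError, ValidationError
from .library import BARCODE_LENGTH, LibraryReference, SampleSheet

DEFAULT_ANCHOR = "CACCG"

STATUS_OK = "ok"
STATUS_NO_ANCHOR = "no_anchor"
STATUS_INSUFFICIENT = "insufficient_length"
STATUS_UNMAPPED = "unmapped_spacer"
STATUS_UNKNOWN_BARCODE = "unknown_barcode"
STATUSES = (
    STATUS_OK,
    STATUS_NO_ANCHOR,
    STATUS_INSUFFICIENT,
    STATUS_UNMAPPED,
    STATUS_UNKNOWN_BARCODE,
)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ReadAssignment:
    """Resolution of a single read: sample, guide, and failure status."""

    read_id: str
    sample_id: str
    guide_id: Optional[str]
    status: str


@dataclass
class ExtractionStats:
    """Per-sample and total tallies of each read status."""

    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)

    def tally(self, sample_id: str, status: str) -> None:
        bucket = self.per_sample.setdefault(
            sample_id, {s: 0 for s in STATUSES}
        )
        bucket[status] += 1

    def totals(self) -> dict[str, int]:
        out = {s: 0 for s in STATUSES}
        for bucket in self.per_sample.values():
            for s, n in bucket.items():
                out[s] += n
        return out

    @property
    def total_reads(self) -> int:
        return sum(self.totals().values())

    @property
    def fraction_ok(self) -> float:
        total = self.total_reads
        return self.totals()[STATUS_OK] / total if total else 0.0

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "fraction_ok": self.fraction_ok,
            "totals": self.totals(),
            "per_sample": self.per_sample,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def extract_spacer(
    read_sequence: str,
    anchor: str = DEFAULT_ANCHOR,
    spacer_length: int = 20,
) -> tuple[Optional[str], str]:
    """Return ``(spacer, status)`` for one read sequence.

    The spacer is the ``spacer_length`` characters immediately following the
    leftmost exact occurrence of ``anchor``; ``(None, "no_anchor")`` when
    the anchor is absent and ``(None, "insufficient_length")`` when fewer
    than ``spacer_length`` characters follow it.
    """
    if not read_sequence:
        raise ValueError("empty read sequence")
    pos = read_sequence.find(anchor)
    if pos < 0:
        return None, STATUS_NO_ANCHOR
    start = pos + len(anchor)
    spacer = read_sequence[start : start + spacer_length]
    if len(spacer) < spacer_length:
        return None, STATUS_INSUFFICIENT
    return spacer, STATUS_OK


def demultiplex(
    sequence: str,
    barcode_to_sample: Mapping[str, str],
    mode: str = "per_file",
    file_sample: Optional[str] = None,
) -> tuple[str, str]:
    """Resolve a read to a sample; returns ``(sample_id, remaining_sequence)``.

    ``per_file`` mode assigns every read of a file to that file's sample.
    ``inline_prefix`` mode treats the first 8 characters as the barcode and
    returns the remainder for extraction; unknown or truncated barcodes
    yield :data:`UNASSIGNED`.
    """
    if mode == "per_file":
        if file_sample is None:
            raise ValueError("per_file mode requires a file sample")
        return file_sample, sequence
    if mode == "inline_prefix":
        if len(sequence) < BARCODE_LENGTH:
            return UNASSIGNED, ""
        sample = barcode_to_sample.get(sequence[:BARCODE_LENGTH], UNASSIGNED)
        return sample, sequence[BARCODE_LENGTH:]
    raise ValueError(f"unknown demultiplex mode {mode!r}")


def _mismatch_neighbors(spacer: str) -> Iterable[str]:
    for i, base in enumerate(spacer):
        for sub in "ACGT":
            if sub != base:
                yield spacer[:i] + sub + spacer[i + 1 :]


def map_spacer(
    spacer: str,
    lib: LibraryReference,
    max_mismatch: int = 0,
    _lookup: Optional[Mapping[str, str]] = None,
) -> Optional[str]:
    """Map a spacer to its guide_id, or ``None`` when unmapped.

    With ``max_mismatch=1`` an inexact spacer maps to the unique library
    spacer at Hamming distance 1; two candidates at that distance are
    ambiguous and yield ``None``.  Exact matches always win.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    lookup = _lookup if _lookup is not None else lib.spacer_to_guide()
    hit = lookup.get(spacer)
    if hit is not None or max_mismatch == 0:
        return hit
    candidates = {
        lookup[n] for n in _mismatch_neighbors(spacer) if n in lookup
    }
    if len(candidates) == 1:
        return candidates.pop()
    return None


def _open_fastq(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path: str | Path):
    """Yield (index, title, sequence); re-raise parse errors with context."""
    with _open_fastq(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(
                    f"{path}: malformed FASTQ record at index {index}: {exc}"
                ) from exc
            yield index, title, seq
            index += 1


def process_fastq(
    fastq_inputs: Mapping[str, str | Path] | Sequence[str | Path],
    lib: LibraryReference,
    sheet: SampleSheet,
    mode: str = "per_file",
    anchor: str = DEFAULT_ANCHOR,
    spacer_length: Optional[int] = None,
    max_mismatch: int = 0,
) -> tuple[pd.DataFrame, ExtractionStats]:
    """Count guide-assigned reads per sample across FASTQ inputs.

    In ``per_file`` mode ``fastq_inputs`` maps sample_id -> FASTQ path (or
    is omitted in favour of the sheet's ``fastq_path`` column); in
    ``inline_prefix`` mode it is a sequence of FASTQ paths whose reads
    carry an 8-nt barcode prefix.

    Returns the guide x sample count matrix (all library guides present,
    zero-filled; columns in sample-sheet order) and extraction statistics.
    """
    if spacer_length is None:
        spacer_length = lib.spacer_length
    barcode_map = sheet.barcode_to_sample()
    sample_ids = sheet.sample_ids
    lookup = lib.spacer_to_guide()
    anchor_len = len(anchor)

    counts: dict[str, dict[str, int]] = {s: {} for s in sample_ids}
    stats = ExtractionStats()

    if mode == "per_file":
        if not isinstance(fastq_inputs, Mapping):
            raise ValueError(
                "per_file mode requires a mapping of sample_id -> fastq path"
            )
        unknown = set(fastq_inputs) - set(sample_ids)
        if unknown:
            raise ValidationError(
                f"fastq inputs name unknown sample(s) {sorted(unknown)}"
            )
        work = [(sample, path) for sample, path in fastq_inputs.items()]
    elif mode == "inline_prefix":
        if isinstance(fastq_inputs, Mapping):
            paths: Sequence[str | Path] = list(fastq_inputs.values())
        else:
            paths = list(fastq_inputs)
        work = [(None, path) for path in paths]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for file_sample, path in work:
        for _idx, _title, seq in _iter_fastq(path):
            if file_sample is None:
                if len(seq) < BARCODE_LENGTH:
                    stats.tally(UNASSIGNED, STATUS_UNKNOWN_BARCODE)
                    continue
                sample = barcode_map.get(seq[:BARCODE_LENGTH])
                if sample is None:
                    stats.tally(UNASSIGNED, STATUS_UNKNOWN_BARCODE)
                    continue
                body = seq[BARCODE_LENGTH:]
            else:
                sample = file_sample
                body = seq
            pos = body.find(anchor)
            if pos < 0:
                stats.tally(sample, STATUS_NO_ANCHOR)
                continue
            start = pos + anchor_len
            spacer = body[start : start + spacer_length]
            if len(spacer) < spacer_length:
                stats.tally(sample, STATUS_INSUFFICIENT)
                continue
            guide = lookup.get(spacer)
            if guide is None and max_mismatch == 1:
                guide = map_spacer(spacer, lib, max_mismatch=1, _lookup=lookup)
            if guide is None:
                stats.tally(sample, STATUS_UNMAPPED)
                continue
            bucket = counts[sample]
            bucket[guide] = bucket.get(guide, 0) + 1
            stats.tally(sample, STATUS_OK)

    matrix = pd.DataFrame(
        0, index=pd.Index(lib.guide_ids, name="guide_id"), columns=sample_ids,
        dtype="int64",
    )
    for sample, bucket in counts.items():
        if bucket:
            col = pd.Series(bucket)
            matrix.loc[col.index, sample] = col.astype("int64")
    return matrix, stats


def write_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a guide x sample count matrix as TSV (first column guide_id)."""
    matrix.to_csv(path, sep="\t", index_label="guide_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV written by :func:`write_counts`."""
    df = pd.read_csv(path, sep="\t", index_col="guide_id")
    return df
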