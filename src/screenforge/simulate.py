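"""Synthetic inputs with known ground truth for every pipeline stage.

The screen generator draws per-guide baseline abundances log-normally,
multiplies the treated arm's weights by ``2**effect`` for enriched genes,
samples per-sample counts multinomially at fixed depth, and emits
structured reads::

    [8-nt barcode (inline mode only)][0..stagger_max random nt]
    [vector tail ending in CACCG][20-nt spacer][scaffold suffix]

Vector tail and scaffold suffix are fixed constants so reads regenerate
bit-exactly for a given seed.  Companion generators invert the qPCR and
decay models so the estimators can be checked by round trip.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .decay import DecaySeries
from .errors import ValidationError
from .library import (
    BARCODE_LENGTH,
    SPACER_LENGTH,
    GuideRecord,
    LibraryReference,
    SampleRecord,
    SampleSheet,
)

#: Last 26 nt of the U6-promoter side of the expression vector; the final
#: five bases are the extraction anchor, and the spacer follows directly.
VECTOR_TAIL = "TATCTTGTGGAAAGGACGAAACACCG"

#: First 20 nt of the constant guide scaffold, appended after the spacer.
SCAFFOLD_SUFFIX = "GTTTTAGAGCTAGAAATAGC"

QUALITY_CHAR = "I"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, k))
    return [b"".join(_BASES[row]).decode() for row in codes]


def generate_library(
    n_genes: int,
    guides_per_gene: int = 4,
    seed: int = 0,
    spacer_length: int = SPACER_LENGTH,
) -> LibraryReference:
    """Random library: genes ``G0001``..., unique uniform-random spacers.

    Spacers are rejection-sampled to uniqueness; deterministic per seed.
    """
    if n_genes < 1 or guides_per_gene < 1:
        raise ValueError("n_genes and guides_per_gene must be positive")
    n_guides = n_genes * guides_per_gene
    if n_guides > 4**spacer_length // 2:
        raise ValueError("requested guide count infeasible for spacer length")
    rng = np.random.default_rng(seed)
    spacers: list[str] = []
    seen: set[str] = set()
    while len(spacers) < n_guides:
        for s in _random_kmers(rng, n_guides - len(spacers), spacer_length):
            if s not in seen:
                seen.add(s)
                spacers.append(s)
    width = max(4, len(str(n_genes)))
    guides = []
    i = 0
    for g in range(1, n_genes + 1):
        gene = f"G{g:0{width}d}"
        for j in range(1, guides_per_gene + 1):
            guides.append(
                GuideRecord(guide_id=f"{gene}_{j}", gene=gene, spacer=spacers[i])
            )
            i += 1
    return LibraryReference(guides, spacer_length=spacer_length)


@dataclass
class ScreenSimConfig:
    """Parameters of the two-arm screen simulation."""

    enriched_genes: Union[int, Sequence[str]] = 0
    effect_log2: float = 2.0
    depth: int = 100_000
    abundance_sigma: float = 1.0
    stagger_max: int = 7
    barcode_mode: str = "per_file"  # or "inline_prefix"
    base_error_rate: float = 0.0
    seed: int = 0
    gzip_fastq: bool = False
    #: optional per-guide log2 effects overriding the gene-level effect
    guide_effects: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must lie in [0, 1]")
        if self.stagger_max < 0:
            raise ValueError("stagger_max must be nonnegative")
        if self.barcode_mode not in ("per_file", "inline_prefix"):
            raise ValueError(f"unknown barcode_mode {self.barcode_mode!r}")


@dataclass
class ScreenTruth:
    """Ground truth of one simulated screen."""

    library_guide_ids: list[str]
    baseline_abundance: dict[str, float]
    counts: pd.DataFrame  # guide x sample true read counts
    enriched_effects: dict[str, float]  # gene -> log2 effect
    guide_log2_effect: dict[str, float]  # per-guide effect actually applied
    treated_samples: list[str]
    control_samples: list[str]
    seed: int
    config: dict = field(default_factory=dict)

    def expected_guide_lfc(self) -> pd.Series:
        """Analytic expected raw lfc per guide: effect minus the shift from
        renormalizing the treated arm's weights to the same depth."""
        base = pd.Series(self.baseline_abundance)
        eff = pd.Series(self.guide_log2_effect).reindex(base.index, fill_value=0.0)
        shift = math.log2((base * 2.0**eff).sum() / base.sum())
        return eff - shift

    def write_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "enriched_effects": self.enriched_effects,
            "guide_log2_effect": self.guide_log2_effect,
            "treated_samples": self.treated_samples,
            "control_samples": self.control_samples,
            "baseline_abundance": self.baseline_abundance,
            "counts": {s: self.counts[s].to_dict() for s in self.counts.columns},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")


def _resolve_enriched(
    lib: LibraryReference, config: ScreenSimConfig, rng: np.random.Generator
) -> dict[str, float]:
    genes = list(lib.genes)
    if isinstance(config.enriched_genes, int):
        if config.enriched_genes > len(genes):
            raise ValidationError("more enriched genes requested than simulated")
        chosen = [str(g) for g in rng.choice(genes, size=config.enriched_genes, replace=False)]
    else:
        chosen = list(config.enriched_genes)
        missing = set(chosen) - set(genes)
        if missing:
            raise ValidationError(f"enriched gene(s) {sorted(missing)} not in library")
    return {g: float(config.effect_log2) for g in chosen}


def simulate_counts(
    lib: LibraryReference, config: ScreenSimConfig
) -> tuple[ScreenTruth, SampleSheet]:
    """Draw true per-sample counts without emitting reads."""
    rng = np.random.default_rng(config.seed)
    guide_ids = lib.guide_ids
    n = len(guide_ids)

    baseline = np.exp(rng.normal(0.0, config.abundance_sigma, size=n))
    enriched = _resolve_enriched(lib, config, rng)
    effects = np.zeros(n)
    for i, gid in enumerate(guide_ids):
        if config.guide_effects and gid in config.guide_effects:
            effects[i] = config.guide_effects[gid]
        elif lib.gene_of(gid) in enriched:
            effects[i] = enriched[lib.gene_of(gid)]
    treated_w = baseline * np.exp2(effects)

    samples = ["NaOH_ctrl", "hemin_CD235A"]
    sheet = SampleSheet(
        [
            SampleRecord("NaOH_ctrl", _sample_barcode(0), "control", 1),
            SampleRecord("hemin_CD235A", _sample_barcode(1), "treated", 1),
        ]
    )
    counts = pd.DataFrame(
        {
            "NaOH_ctrl": rng.multinomial(config.depth, baseline / baseline.sum()),
            "hemin_CD235A": rng.multinomial(config.depth, treated_w / treated_w.sum()),
        },
        index=pd.Index(guide_ids, name="guide_id"),
    )
    truth = ScreenTruth(
        library_guide_ids=guide_ids,
        baseline_abundance=dict(zip(guide_ids, baseline.tolist())),
        counts=counts,
        enriched_effects=enriched,
        guide_log2_effect={
            gid: float(e) for gid, e in zip(guide_ids, effects) if e != 0.0
        },
        treated_samples=["hemin_CD235A"],
        control_samples=["NaOH_ctrl"],
        seed=config.seed,
        config={
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in asdict(config).items()
            if k != "guide_effects"
        },
    )
    return truth, sheet


def _sample_barcode(index: int) -> str:
    # deterministic, well-separated 8-mers
    pool = ["ACGTACGT", "TGCATGCA", "GGAACCTT", "CCTTGGAA", "ATATCGCG", "GCGCATAT"]
    if index < len(pool):
        return pool[index]
    raise ValueError("barcode pool exhausted")


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != bytes(arr[i])]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _emit_sample_fastq(
    path: Path,
    sample_id: str,
    barcode: Optional[str],
    guide_counts: np.ndarray,
    spacers: Sequence[str],
    config: ScreenSimConfig,
    rng: np.random.Generator,
    gzip_out: bool,
    append: bool = False,
) -> None:
    n_reads = int(guide_counts.sum())
    guide_idx = np.repeat(np.arange(len(spacers)), guide_counts)
    rng.shuffle(guide_idx)
    stag_lens = rng.integers(0, config.stagger_max + 1, size=n_reads)
    stag_codes = rng.integers(0, 4, size=int(stag_lens.sum()))
    stag_bases = b"".join(_BASES[stag_codes]).decode()
    offsets = np.concatenate(([0], np.cumsum(stag_lens)))
    anchor = VECTOR_TAIL[-5:]

    prefix = barcode or ""
    mode = ("at" if append else "wt")
    opener = gzip.open if gzip_out else open
    with opener(path, mode) as fh:
        buf: list[str] = []
        for i in range(n_reads):
            stag = stag_bases[offsets[i] : offsets[i + 1]]
            # real staggers are fixed primer sequences that never contain the
            # anchor; resample the rare random stagger that does, so the
            # vector copy stays the leftmost occurrence
            while anchor in stag:
                stag = b"".join(_BASES[rng.integers(0, 4, len(stag))]).decode()
            seq = f"{prefix}{stag}{VECTOR_TAIL}{spacers[guide_idx[i]]}{SCAFFOLD_SUFFIX}"
            if config.base_error_rate > 0:
                seq = _apply_errors(seq, config.base_error_rate, rng)
            buf.append(
                f"@{sample_id}.{i}\n{seq}\n+\n{QUALITY_CHAR * len(seq)}\n"
            )
            if len(buf) >= 20_000:
                fh.write("".join(buf))
                buf.clear()
        fh.write("".join(buf))


def simulate_screen(
    lib: LibraryReference,
    config: ScreenSimConfig,
    out_dir: Optional[str | Path] = None,
) -> tuple[ScreenTruth, dict[str, Path]]:
    """Simulate the two-arm screen; optionally write FASTQ + metadata files.

    Returns the truth record and, when ``out_dir`` is given, the emitted
    file paths (``library``, ``samples``, ``truth`` plus one FASTQ per
    sample in per_file mode or a single ``reads`` FASTQ in inline mode).
    """
    truth, sheet = simulate_counts(lib, config)
    paths: dict[str, Path] = {}
    if out_dir is None:
        return truth, paths

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)  # read emission stream
    spacers = [lib.guide(g).spacer for g in lib.guide_ids]
    ext = ".fastq.gz" if config.gzip_fastq else ".fastq"
    barcodes = sheet.barcode_to_sample()
    bc_of = {v: k for k, v in barcodes.items()}

    rows = []
    if config.barcode_mode == "per_file":
        for rec in sheet.rows:
            fq = out_dir / f"{rec.sample_id}{ext}"
            _emit_sample_fastq(
                fq,
                rec.sample_id,
                None,
                truth.counts[rec.sample_id].to_numpy(),
                spacers,
                config,
                rng,
                config.gzip_fastq,
            )
            paths[rec.sample_id] = fq
            rows.append(
                SampleRecord(rec.sample_id, rec.barcode, rec.condition, rec.replicate, str(fq))
            )
    else:
        fq = out_dir / f"reads{ext}"
        for i, rec in enumerate(sheet.rows):
            _emit_sample_fastq(
                fq,
                rec.sample_id,
                bc_of[rec.sample_id],
                truth.counts[rec.sample_id].to_numpy(),
                spacers,
                config,
                rng,
                config.gzip_fastq,
                append=(i > 0),
            )
            rows.append(
                SampleRecord(rec.sample_id, rec.barcode, rec.condition, rec.replicate, str(fq))
            )
        paths["reads"] = fq

    sheet = SampleSheet(rows)
    lib_path = out_dir / "library.csv"
    lib.write(lib_path)
    sheet_path = out_dir / "samples.csv"
    sheet.write(sheet_path)
    truth_path = out_dir / "truth.json"
    truth.write_json(truth_path)
    paths.update(library=lib_path, samples=sheet_path, truth=truth_path)
    return truth, paths


# -- qPCR and decay generators --------------------------------------------

CONTROL_TARGET_CT = 25.0
REFERENCE_CT = 20.0


def simulate_qpcr(
    true_fold_changes: Mapping[str, float],
    reference_gene: str = "ACTB",
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    control_sample: str = "control",
    sample_id: str = "treated",
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Long-format CT table encoding known fold changes.

    Control-sample target CT is fixed at 25 and the treated sample's at
    ``25 - log2(fold)``; the reference gene sits at CT 20 everywhere, so
    the 2^-ddCT read-out recovers the input folds exactly at zero noise.
    """
    for gene, fold in true_fold_changes.items():
        if fold <= 0:
            raise ValidationError(f"fold change for {gene!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []

    def emit(sample: str, target: str, ct: float) -> None:
        for _ in range(n_replicates):
            rows.append(
                {
                    "sample_id": sample,
                    "target": target,
                    "ct": ct + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0),
                }
            )

    for sample in (control_sample, sample_id):
        emit(sample, reference_gene, REFERENCE_CT)
    for gene, fold in true_fold_changes.items():
        emit(control_sample, gene, CONTROL_TARGET_CT)
        emit(sample_id, gene, CONTROL_TARGET_CT - math.log2(fold))
    return pd.DataFrame(rows)


def simulate_decay(
    half_life_h: float,
    times: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0),
    noise_cv: float = 0.0,
    seed: int = 0,
) -> DecaySeries:
    """First-order decay series with multiplicative log-normal noise.

    Noise is median-unbiased (log-mean 0) with log-sd chosen so the
    multiplicative factor has coefficient of variation ``noise_cv``.
    """
    if half_life_h <= 0:
        raise ValueError("half_life_h must be positive")
    rng = np.random.default_rng(seed)
    k = math.log(2) / half_life_h
    t = np.asarray(times, dtype=float)
    clean = np.exp(-k * t)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        clean = clean * np.exp(rng.normal(0.0, sigma, size=len(t)))
    return DecaySeries(times=tuple(t.tolist()), intensities=tuple(clean.tolist()))
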