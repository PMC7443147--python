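# screenforge

Analysis toolkit for pooled CRISPR-knockout differentiation screens, with
the downstream quantifications that usually accompany them, and a
synthetic-data generator with full ground truth so every stage is testable
offline.

## What it does

**Screen pipeline** (`count -> normalize -> score -> call -> rank`):

- **Library / sample models** — validated sgRNA library CSV
  (`guide_id,gene,spacer`, 20-nt spacers, default 4 guides/gene) and sample
  sheet (`sample_id,barcode,condition,replicate,fastq_path`, 8-nt barcodes);
  design and coverage (cells-per-guide) reports.
- **Read extraction** — spacer = the 20 nt after the leftmost `CACCG`
  vector anchor in each read; demultiplexing either one FASTQ per sample
  (`per_file`) or by an inline 8-nt barcode prefix (`inline_prefix`); exact
  spacer lookup with optional unique-best Hamming-1 rescue. Every read gets
  exactly one status (`ok`, `no_anchor`, `insufficient_length`,
  `unmapped_spacer`, `unknown_barcode`); nothing is silently dropped.
- **Normalization** — reads per million per sample, then `log2(x + 1)`.
- **Scoring** — per-guide log2 fold change (mean treated minus mean control,
  log2 scale), median-corrected over all guides; gene score = mean of its
  guides' corrected scores; a gene is a hit when >= `min_concordant`
  (default 3) of its guides move past `+/-tau` in the same direction;
  deterministic ranking with documented tie-breaks.

**Companion quantifications:**

- `qpcr` / `chip` — 2^-ddCT relative expression against a reference gene
  and control sample; ChIP dCT against input (reported as 2^-dCT fold of
  input).
- `halflife` — first-order (log-linear OLS) half-life from
  cycloheximide-chase intensity series.
- `deg` / `overlap` — fold-change/p filtering of expression tables
  (FC >= 1.5 inclusive, p < 0.01 strict, Welch t from replicates when no p
  column), and gene-set overlap with percentage and optional
  hypergeometric enrichment p.

**Simulator** (`screenforge simulate ...`) — random libraries, two-arm
screens (log-normal baseline abundance, `2^effect` enrichment of designated
genes in the treated arm, multinomial sampling at fixed depth, structured
reads with stagger/anchor/spacer/scaffold and optional substitution noise),
qPCR CT tables and decay series — all seeded and bit-reproducible, with a
`truth.json` ground-truth record.

## CLI

```sh
# simulate a screen, then run the full pipeline on it
screenforge simulate screen --n-genes 1000 --enriched 20 --effect 2.0 \
    --depth 1000000 --seed 42 --out simdir/
printf 'library = simdir/library.csv\nsamples = simdir/samples.csv\nout_dir = out\ntau = 0.5\n' > run.cfg
screenforge run --config run.cfg

# or stage by stage
screenforge count simdir/NaOH_ctrl.fastq simdir/hemin_CD235A.fastq \
    --library simdir/library.csv --samples simdir/samples.csv --out counts.tsv
screenforge normalize counts.tsv --out norm.tsv
screenforge score norm.tsv --library simdir/library.csv \
    --treated hemin_CD235A --control NaOH_ctrl --tau 0.5

# companions
screenforge qpcr ct.csv --reference ACTB --control-sample control
screenforge chip ct.csv --input-label input
screenforge halflife chx.csv
screenforge deg expr.csv --fc 1.5 --p 0.01
screenforge overlap setA.txt setB.txt --universe 20000
screenforge coverage --n-cells 2.5e7 --n-guides 76441
```

Config precedence is CLI flags > config file > defaults. A pipeline run
writes all stage TSVs plus `report.json`; reruns on identical inputs are
byte-identical, and a `run` equals the stage-by-stage CLI invocations
byte-for-byte.

Note on real libraries: the bundled format is the 3-column CSV above;
commercial library distributions ship extra columns and must be converted
to `guide_id,gene,spacer` first (any spreadsheet/`pandas` one-liner works —
no converter is bundled).

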