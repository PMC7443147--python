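import math
from collections import Counter

import numpy as np
import pytest

from screenforge.decay import fit_half_life
from screenforge.errors import ValidationError
from screenforge.extraction import process_fastq
from screenforge.library import load_library, load_sample_sheet
from screenforge.normalization import normalize
from screenforge.qpcr import ddct_table, load_ct_table
from screenforge.scoring import gene_scores, guide_scores
from screenforge.simulate import (
    SCAFFOLD_SUFFIX,
    VECTOR_TAIL,
    ScreenSimConfig,
    generate_library,
    simulate_counts,
    simulate_decay,
    simulate_qpcr,
    simulate_screen,
)


class TestGenerateLibrary:
    def test_construction_counts(self):
        lib = generate_library(1000, 4, seed=7)
        assert lib.n_guides == 4000
        assert lib.n_genes == 1000
        assert all(len(v) == 4 for v in lib.genes.values())
        assert len(set(g.spacer for g in lib.guides)) == 4000

    def test_determinism_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_library(30, 4, seed=11).write(p1)
        generate_library(30, 4, seed=11).write(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_minimal_case(self):
        assert generate_library(2, 1, seed=0).n_guides == 2

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            generate_library(0, 4)


class TestSimulateScreen:
    def test_vector_constants(self):
        assert VECTOR_TAIL.endswith("CACCG")
        assert len(SCAFFOLD_SUFFIX) == 20

    def test_truth_counts_sum_to_depth(self):
        lib = generate_library(20, 4, seed=1)
        truth, _ = simulate_counts(lib, ScreenSimConfig(depth=5000, seed=2))
        assert (truth.counts.sum(axis=0) == 5000).all()

    def test_zero_noise_identity_with_extraction(self, tmp_path):
        lib = generate_library(25, 4, seed=3)
        config = ScreenSimConfig(enriched_genes=3, depth=20_000, seed=4)
        truth, paths = simulate_screen(lib, config, out_dir=tmp_path)
        sheet = load_sample_sheet(paths["samples"])
        counts, stats = process_fastq(
            {s: paths[s] for s in truth.counts.columns}, lib, sheet
        )
        assert stats.fraction_ok == 1.0
        assert counts.equals(truth.counts)

    def test_truth_matches_brute_force_spacer_tally(self, tmp_path):
        lib = generate_library(10, 4, seed=5)
        config = ScreenSimConfig(depth=3000, seed=6)
        truth, paths = simulate_screen(lib, config, out_dir=tmp_path)
        spacer_of = {g.guide_id: g.spacer for g in lib.guides}
        for sample in truth.counts.columns:
            tally = Counter()
            with open(paths[sample]) as fh:
                lines = fh.read().splitlines()
            seqs = lines[1::4]
            assert len(seqs) == config.depth
            for seq in seqs:
                for gid, spacer in spacer_of.items():
                    if VECTOR_TAIL + spacer in seq:
                        tally[gid] += 1
                        break
            for gid in lib.guide_ids:
                assert tally[gid] == truth.counts.loc[gid, sample]

    def test_fastq_determinism(self, tmp_path):
        lib = generate_library(5, 4, seed=8)
        config = ScreenSimConfig(depth=500, seed=9)
        _, p1 = simulate_screen(lib, config, out_dir=tmp_path / "a")
        _, p2 = simulate_screen(lib, config, out_dir=tmp_path / "b")
        for sample in ("NaOH_ctrl", "hemin_CD235A"):
            assert p1[sample].read_bytes() == p2[sample].read_bytes()

    def test_emitted_metadata_loadable(self, tmp_path):
        lib = generate_library(5, 4, seed=8)
        _, paths = simulate_screen(lib, ScreenSimConfig(depth=500, seed=9), out_dir=tmp_path)
        lib2 = load_library(paths["library"])
        assert lib2.guide_ids == lib.guide_ids
        sheet = load_sample_sheet(paths["samples"])
        sheet.require_both_arms()

    def test_base_errors_reduce_ok_fraction(self, tmp_path):
        lib = generate_library(10, 4, seed=10)
        config = ScreenSimConfig(depth=2000, seed=11, base_error_rate=0.05)
        truth, paths = simulate_screen(lib, config, out_dir=tmp_path)
        sheet = load_sample_sheet(paths["samples"])
        _, stats = process_fastq(
            {s: paths[s] for s in truth.counts.columns}, lib, sheet
        )
        assert stats.fraction_ok < 1.0

    def test_unknown_enriched_gene_errors(self):
        lib = generate_library(5, 4, seed=1)
        with pytest.raises(ValidationError, match="not in library"):
            simulate_counts(lib, ScreenSimConfig(enriched_genes=["NOPE"]))

    def test_expected_lfc_close_to_effect(self):
        lib = generate_library(100, 4, seed=12)
        truth, _ = simulate_counts(
            lib, ScreenSimConfig(enriched_genes=5, effect_log2=2.0, depth=10_000, seed=13)
        )
        expected = truth.expected_guide_lfc()
        enriched_guides = [
            g for g in lib.guide_ids if lib.gene_of(g) in truth.enriched_effects
        ]
        # enrichment renormalizes total mass, so expectation sits just below 2
        assert all(1.5 < expected[g] < 2.0 for g in enriched_guides)

    def test_effect_monotonicity_same_seed(self):
        lib = generate_library(50, 4, seed=14)
        gene = "G0007"
        scores = []
        for effect in (0.5, 1.0, 2.0, 3.0):
            config = ScreenSimConfig(
                enriched_genes=[gene], effect_log2=effect, depth=200_000, seed=15
            )
            truth, _ = simulate_counts(lib, config)
            gsc = guide_scores(
                normalize(truth.counts), truth.treated_samples, truth.control_samples
            )
            genes = gene_scores(gsc, lib)
            scores.append(genes.loc[gene, "score"])
        assert scores == sorted(scores)

    def test_partial_concordance_two_of_four_not_called(self):
        lib = generate_library(50, 4, seed=16)
        gene = "G0003"
        gids = lib.genes[gene]
        config = ScreenSimConfig(
            depth=500_000,
            seed=17,
            guide_effects={gids[0]: 3.0, gids[1]: 3.0},  # only 2 of 4 respond
        )
        truth, _ = simulate_counts(lib, config)
        gsc = guide_scores(
            normalize(truth.counts), truth.treated_samples, truth.control_samples
        )
        genes = gene_scores(gsc, lib, tau=0.5, min_concordant=3)
        assert not bool(genes.loc[gene, "hit"])

    def test_null_calibration(self):
        # no enriched genes: gene-level hit rate at the calibrated tau stays
        # below 5%, and gene scores are centered at zero
        lib = generate_library(200, 4, seed=0)
        hit_rates = []
        medians = []
        for seed in range(100):
            config = ScreenSimConfig(enriched_genes=0, depth=1_000_000, seed=seed)
            truth, _ = simulate_counts(lib, config)
            gsc = guide_scores(
                normalize(truth.counts), truth.treated_samples, truth.control_samples
            )
            genes = gene_scores(gsc, lib, tau=0.5, min_concordant=3)
            hit_rates.append(genes["hit"].mean())
            medians.append(float(np.median(genes["score"])))
        assert np.mean(hit_rates) < 0.05
        assert max(abs(m) for m in medians) < 0.05


class TestSimulateQpcr:
    def test_zero_noise_inverse_identity(self):
        table = simulate_qpcr({"GENE": 4.0}, ct_noise_sd=0.0, seed=0)
        mts = {
            (s, t): v
            for (s, t), v in table.groupby(["sample_id", "target"])["ct"].mean().items()
        }
        assert mts[("treated", "GENE")] == pytest.approx(23.0)
        import screenforge.qpcr as q

        cts = {
            key: q.CtMeasurement(key[0], key[1], tuple(sub["ct"]))
            for key, sub in table.groupby(["sample_id", "target"])
        }
        out = ddct_table(cts, "ACTB", "control")
        fold = out[(out.sample_id == "treated") & (out.target == "GENE")].fold_change
        assert fold.iloc[0] == pytest.approx(4.0)

    def test_fold_one_identity(self):
        table = simulate_qpcr({"GENE": 1.0}, ct_noise_sd=0.0, seed=0)
        cts = load_ct_table_from_frame(table)
        out = ddct_table(cts, "ACTB", "control")
        assert out[(out.sample_id == "treated")].fold_change.iloc[0] == pytest.approx(1.0)

    def test_noisy_recovery_median_within_5pct(self):
        recovered = []
        for seed in range(200):
            table = simulate_qpcr({"GENE": 2.5}, ct_noise_sd=0.05, seed=seed)
            out = ddct_table(load_ct_table_from_frame(table), "ACTB", "control")
            recovered.append(
                out[(out.sample_id == "treated")].fold_change.iloc[0]
            )
        med = float(np.median(recovered))
        assert abs(med - 2.5) / 2.5 < 0.05

    def test_invalid_fold_rejected(self):
        with pytest.raises(ValidationError):
            simulate_qpcr({"GENE": -1.0})


def load_ct_table_from_frame(df):
    from screenforge.qpcr import CtMeasurement

    return {
        (s, t): CtMeasurement(s, t, tuple(sub["ct"]))
        for (s, t), sub in df.groupby(["sample_id", "target"], sort=False)
    }


class TestSimulateDecay:
    def test_exact_halving(self):
        series = simulate_decay(4.0, times=(0, 4, 8), noise_cv=0.0)
        assert series.intensities == pytest.approx((1.0, 0.5, 0.25))

    def test_inverse_identity(self):
        series = simulate_decay(8.0, noise_cv=0.0)
        assert fit_half_life(series).half_life == pytest.approx(8.0, rel=1e-12)

    def test_noisy_recovery_median_in_band(self):
        recovered = [
            fit_half_life(simulate_decay(8.0, noise_cv=0.05, seed=s)).half_life
            for s in range(200)
        ]
        assert 7.2 <= float(np.median(recovered)) <= 8.8

    def test_determinism(self):
        a = simulate_decay(8.0, noise_cv=0.1, seed=5)
        b = simulate_decay(8.0, noise_cv=0.1, seed=5)
        assert a == b

    def test_invalid_half_life(self):
        with pytest.raises(ValueError):
            simulate_decay(0.0)
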