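"""Generator contracts: profile arithmetic, apportionment, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from l1scope import (
    CodingCategory,
    LengthModel,
    allocate_counts,
    build_toy_genome,
    paper_means_profile,
    simulate_library,
)
from l1scope.simulate import (
    ConfigurationError,
    FLANK_INTERGENIC,
    FLANK_INTRAGENIC,
    FLANK_NONE,
    FLANK_UNMAPPED,
    load_toy_genome,
)


class TestPaperMeansProfile:
    def test_noncoding_fraction_is_the_remainder(self):
        profile = paper_means_profile()
        f = profile.category_fractions
        assert f[CodingCategory.NONCODING] == pytest.approx(
            100 - 5.77 - 0.017 - 0.221 - 0.078 - 0.006, abs=1e-12
        )
        assert f[CodingCategory.NONCODING] == pytest.approx(93.908, abs=1e-9)

    def test_category_fractions_sum_to_100(self):
        assert sum(paper_means_profile().category_fractions.values()) == pytest.approx(100.0)

    def test_yy1_fraction_nested_inside_utr5_fraction(self):
        profile = paper_means_profile()
        assert profile.yy1_pct == 19.38 <= profile.utr5_pct == 45.28


class TestAllocateCounts:
    def test_paper_means_at_100k_is_exact(self):
        counts = allocate_counts(paper_means_profile().category_fractions, 100_000)
        assert counts[CodingCategory.ORF1_ONLY] == 5770
        assert counts[CodingCategory.ORF2_ONLY] == 17
        assert counts[CodingCategory.ORF2P_ONLY] == 221
        assert counts[CodingCategory.ORF1_ORF2P] == 78
        assert counts[CodingCategory.ORF1_ORF2] == 6
        assert counts[CodingCategory.NONCODING] == 93_908

    def test_single_read_goes_to_largest_fraction(self):
        counts = allocate_counts(paper_means_profile().category_fractions, 1)
        assert counts[CodingCategory.NONCODING] == 1
        assert sum(counts.values()) == 1

    @given(n=st.integers(min_value=1, max_value=100_000))
    @settings(max_examples=50, deadline=None)
    def test_counts_always_sum_to_n(self, n):
        counts = allocate_counts(paper_means_profile().category_fractions, n)
        assert sum(counts.values()) == n
        assert all(c >= 0 for c in counts.values())


class TestLengthModel:
    def test_default_model_mean_matches_calibration(self):
        lengths = LengthModel().draw(10_000, 7)
        assert np.mean(lengths) == pytest.approx(3541.0, rel=0.02)

    def test_long_read_tail_is_sparse(self):
        lengths = LengthModel().draw(50_000, 7)
        frac_ge_6kb = np.mean(lengths >= 6000)
        assert 0.001 < frac_ge_6kb < 0.03


class TestToyGenome:
    def test_gene_intervals_do_not_overlap(self, toy_genome):
        spans = sorted((g.start, g.end) for g in toy_genome.genes)
        assert all(prev[1] <= cur[0] for prev, cur in zip(spans, spans[1:]))

    def test_gff3_round_trip(self, toy_genome, tmp_path):
        fasta, gff = tmp_path / "genome.fasta", tmp_path / "genes.gff3"
        toy_genome.write_fasta(fasta)
        toy_genome.write_gff3(gff)
        reloaded = load_toy_genome(fasta, gff)
        assert reloaded.chroms == toy_genome.chroms
        assert [(g.chrom, g.start, g.end, g.gene_id) for g in reloaded.genes] == [
            (g.chrom, g.start, g.end, g.gene_id) for g in toy_genome.genes
        ]

    def test_bed_round_trip(self, toy_genome, tmp_path):
        fasta, bed = tmp_path / "genome.fasta", tmp_path / "genes.bed"
        toy_genome.write_fasta(fasta)
        toy_genome.write_bed(bed)
        reloaded = load_toy_genome(fasta, bed)
        assert [(g.start, g.end) for g in reloaded.genes] == [(g.start, g.end) for g in toy_genome.genes]

    def test_fixed_seed_reproduces_sequence(self):
        assert build_toy_genome(seed=9).chroms == build_toy_genome(seed=9).chroms


class TestSimulateLibrary:
    def test_category_counts_follow_apportionment(self, balanced_library, balanced_profile):
        counts = balanced_library.truth["true_category"].value_counts()
        expected = allocate_counts(balanced_profile.category_fractions, 400)
        for cat, n in expected.items():
            assert counts.get(cat.value, 0) == n

    def test_yy1_nested_in_utr5(self, balanced_library):
        truth = balanced_library.truth
        assert (truth.loc[truth["yy1_intact"], "has_utr5"]).all()

    def test_truncated_categories_never_carry_utr(self, balanced_library):
        truth = balanced_library.truth
        trunc = truth["true_category"].isin(["ORF2_ONLY", "ORF2P_ONLY"])
        assert not truth.loc[trunc, "has_utr5"].any()

    def test_marginals_recovered_exactly(self, balanced_library, balanced_profile):
        truth = balanced_library.truth
        n = len(truth)
        assert 100.0 * truth["sense"].mean() == pytest.approx(balanced_profile.sense_pct)
        assert 100.0 * truth["has_utr5"].mean() == pytest.approx(balanced_profile.utr5_pct)
        assert 100.0 * truth["yy1_intact"].mean() == pytest.approx(balanced_profile.yy1_pct)
        assert 100.0 * (truth["flank_class"] == FLANK_INTRAGENIC).mean() == pytest.approx(40.0)
        assert 100.0 * (truth["flank_class"] == FLANK_INTERGENIC).mean() == pytest.approx(10.0)
        none_unmapped = truth["flank_class"].isin([FLANK_NONE, FLANK_UNMAPPED])
        assert 100.0 * none_unmapped.mean() == pytest.approx(50.0)

    def test_each_read_has_exactly_one_truth_record(self, balanced_library):
        ids = [r for r, _ in balanced_library.reads]
        assert sorted(ids) == sorted(balanced_library.truth["read_id"])
        assert balanced_library.truth["read_id"].is_unique

    def test_fixed_seed_gives_byte_identical_fasta(self, toy_model, toy_genome, balanced_profile, tmp_path):
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        for path in (a, b):
            lib = simulate_library(toy_model, toy_genome, profile=balanced_profile, n=50, seed=11)
            lib.write_fasta(path)
        assert a.read_bytes() == b.read_bytes()

    def test_unsatisfiable_feature_combination_raises(self, toy_model, toy_genome, balanced_profile):
        from dataclasses import replace

        bad = replace(balanced_profile, utr5_pct=0.5, yy1_pct=0.4)
        # nearly all UTR quota is forced onto a tiny eligible pool; a profile
        # with yy1 demanded but no UTR at all must fail at construction
        with pytest.raises(ConfigurationError):
            replace(balanced_profile, utr5_pct=0.0, yy1_pct=10.0)

    def test_excessive_error_rate_rejected(self, toy_model, toy_genome):
        with pytest.raises(ConfigurationError):
            simulate_library(toy_model, toy_genome, n=10, seed=1, error_rate=0.05)

    def test_planted_orf2_savs_recorded_in_truth(self, toy_model, toy_genome, balanced_profile):
        lib = simulate_library(
            toy_model,
            toy_genome,
            profile=balanced_profile,
            n=100,
            seed=5,
            orf2_savs=[(5, "W")],
        )
        truth = lib.truth
        orf2_full = truth["true_category"].isin(["ORF2_ONLY", "ORF1_ORF2"])
        assert (truth.loc[orf2_full, "orf2_savs"] == "5W").all()
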