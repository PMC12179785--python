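"""Detection: seeding/chaining correctness, oracle equivalence, masking."""

import numpy as np
import pytest
from Bio import Align

from l1scope import (
    RepeatLibrary,
    annotate_corpus,
    annotate_subfamilies,
    find_l1_segments,
    mask_l1,
    merge_hits,
    toy_repeat_library,
)
from l1scope._seq import random_dna, revcomp
from l1scope.detect import AlignParams


def _sw_dna_aligner(p: AlignParams) -> Align.PairwiseAligner:
    """Full Smith-Waterman oracle at the package's DNA scoring scheme."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    aligner.open_gap_score = p.gap_open
    aligner.extend_gap_score = p.gap_extend
    return aligner


class TestFindSegments:
    def test_exact_substring_yields_identity_one_hit(self, toy_model):
        read = toy_model.nt_seq[100:600]
        hits = find_l1_segments(read, toy_model)
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "+"
        assert h.identity == 1.0
        assert h.read_interval == (0, 500)
        assert h.consensus_interval == (100, 600)

    def test_reverse_complement_flips_strand_not_coordinates(self, toy_model):
        read = toy_model.nt_seq[100:600]
        hits = find_l1_segments(revcomp(read), toy_model)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].consensus_interval == (100, 600)

    def test_random_read_has_no_hits_and_no_qualifying_alignment(self, toy_model, rng):
        # oracle: a 100 bp segment at >= 80% identity would score >= 80
        # under match 2 / mismatch -4, so an optimal SW score below 80
        # proves no qualifying local alignment exists for this read
        read = random_dna(500, rng)
        params = AlignParams()
        assert find_l1_segments(read, toy_model, params) == []
        oracle = _sw_dna_aligner(params)
        score = max(
            oracle.align(toy_model.nt_seq, read).score,
            oracle.align(toy_model.nt_seq, revcomp(read)).score,
        )
        assert score < 80

    def test_internal_deletion_is_chained_across(self, toy_model):
        # a transcript missing an internal consensus block still yields one
        # hit spanning the full consensus extent (splice-tolerant chaining)
        read = toy_model.nt_seq[50:400] + toy_model.nt_seq[900:1300]
        hits = find_l1_segments(read, toy_model)
        assert len(hits) == 1
        assert hits[0].consensus_interval == (50, 1300)
        assert hits[0].read_interval == (0, 750)
        assert hits[0].identity > 0.95

    @pytest.mark.parametrize("span,n_subs", [((100, 900), 0), ((200, 1400), 8), ((0, 1494), 4)])
    def test_agrees_with_smith_waterman_oracle(self, toy_model, rng, span, n_subs):
        """Seed-chain-extend matches full SW on reads <= 2 kb: interval
        within 5 bp, identity within 0.02."""
        s, e = span
        read = list(toy_model.nt_seq[s:e])
        for pos in rng.choice(len(read), size=n_subs, replace=False):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        read = "".join(read)
        params = AlignParams()
        hits = find_l1_segments(read, toy_model, params)
        assert len(hits) == 1
        aln = _sw_dna_aligner(params).align(toy_model.nt_seq, read)[0]
        t_blocks, q_blocks = aln.aligned
        assert abs(hits[0].consensus_interval[0] - t_blocks[0][0]) <= 5
        assert abs(hits[0].consensus_interval[1] - t_blocks[-1][1]) <= 5
        assert abs(hits[0].read_interval[0] - q_blocks[0][0]) <= 5
        assert abs(hits[0].read_interval[1] - q_blocks[-1][1]) <= 5
        counts = aln.counts()
        oracle_identity = counts.identities / (counts.identities + counts.mismatches + counts.gaps)
        assert hits[0].identity == pytest.approx(oracle_identity, abs=0.02)

    def test_strand_symmetry(self, toy_model, rng):
        for _ in range(3):
            s = int(rng.integers(0, 800))
            read = toy_model.nt_seq[s : s + 400]
            fwd = find_l1_segments(read, toy_model)
            rev = find_l1_segments(revcomp(read), toy_model)
            assert [h.consensus_interval for h in fwd] == [h.consensus_interval for h in rev]
            assert {h.strand for h in fwd} == {"+"} and {h.strand for h in rev} == {"-"}


class TestSubfamilyAnnotation:
    def test_pure_read_gets_single_best_annotation(self, toy_model):
        lib = toy_repeat_library(toy_model, divergence=0.30, seed=1)
        read = lib.entries["L1toyHS"][200:900]
        anns = annotate_subfamilies(read, lib)
        assert [a[0] for a in anns] == ["L1toyHS"]

    def test_chimeric_read_gets_two_annotations(self, toy_model):
        lib = toy_repeat_library(toy_model, divergence=0.30, seed=1)
        read = lib.entries["L1toyHS"][0:400] + lib.entries["L1toyPA"][800:1200]
        anns = annotate_subfamilies(read, lib)
        assert sorted(a[0] for a in anns) == ["L1toyHS", "L1toyPA"]

    def test_corpus_mean_annotations_per_read(self, toy_model):
        lib = toy_repeat_library(toy_model, divergence=0.30, seed=1)
        single = lib.entries["L1toyHS"][200:900]
        double = lib.entries["L1toyHS"][0:400] + lib.entries["L1toyPA"][800:1200]
        corpus = [(f"s{i}", single) for i in range(50)] + [(f"d{i}", double) for i in range(50)]
        result = annotate_corpus(corpus, lib)
        assert result["mean_annotations_per_read"] == pytest.approx(1.5)
        assert result["subfamily_pct"]["L1toyHS"] == pytest.approx(100.0)
        assert result["subfamily_pct"]["L1toyPA"] == pytest.approx(50.0)
        assert sum(result["subfamily_pct"].values()) > 100.0

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            RepeatLibrary({})


class TestMasking:
    def test_fully_covered_read_has_no_flanks(self, toy_model):
        read = toy_model.nt_seq[100:600]
        hits = find_l1_segments(read, toy_model)
        masked = mask_l1(read, hits, min_flank_len=100)
        assert masked.flank_segments == []
        assert set(masked.masked_seq) == {"N"}

    def test_two_flanks_survive_masking(self, toy_model, rng):
        left, right = random_dna(200, rng), random_dna(200, rng)
        core = toy_model.nt_seq[200:1200]
        read = left + core + right
        hits = find_l1_segments(read, toy_model)
        masked = mask_l1(read, hits, min_flank_len=100)
        assert len(masked.flank_segments) == 2
        (iv1, s1), (iv2, s2) = masked.flank_segments
        assert len(s1) == pytest.approx(200, abs=5) and len(s2) == pytest.approx(200, abs=5)

    def test_masking_preserves_length(self, toy_model, rng):
        for _ in range(5):
            read = random_dna(50, rng) + toy_model.nt_seq[300:800] + random_dna(30, rng)
            hits = find_l1_segments(read, toy_model)
            masked = mask_l1(read, hits, min_flank_len=40)
            assert len(masked.masked_seq) == len(read)

    def test_merge_keeps_higher_score_on_overlap(self, toy_model):
        from l1scope.detect import L1Hit

        a = L1Hit("r", (0, 300), (0, 300), "+", 1.0, 600)
        b = L1Hit("r", (200, 500), (200, 500), "+", 0.9, 400)
        merged = merge_hits([a, b])
        assert len(merged) == 1
        assert merged[0].read_interval == (0, 500)
        assert merged[0].score == 600
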