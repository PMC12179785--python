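"""Variant collapsing, support thresholds, SAVs, residue conservation."""

import pytest
from hypothesis import given, settings, strategies as st

from l1scope import (
    CodingCategory,
    Variant,
    call_variants,
    find_savs,
    private_variant_fraction,
    residue_conservation,
)
from l1scope.classify import Orientation, ReadClassification


def _read(read_id, protein, sample="S1", category=CodingCategory.ORF2_ONLY):
    return ReadClassification(
        read_id=read_id,
        sample_id=sample,
        category=category,
        orientation=Orientation.SENSE,
        orf2_protein=protein,
    )


class TestCallVariants:
    def test_three_identical_reads_make_one_variant(self):
        reads = [_read(f"r{i}", "MKLV" * 30) for i in range(3)]
        variants, unsupported = call_variants(reads, min_support=3)
        assert len(variants) == 1
        assert variants[0].support == 3
        assert unsupported == []

    def test_two_reads_fall_below_support_threshold(self):
        reads = [_read(f"r{i}", "MKLV" * 30) for i in range(2)]
        variants, unsupported = call_variants(reads, min_support=3)
        assert variants == []
        assert len(unsupported) == 1

    def test_seven_reads_split_four_three_give_two_variants(self):
        # brute-force oracle: group by exact protein with a Counter
        from collections import Counter

        proteins = ["MAAA" * 30] * 4 + ["MCCC" * 30] * 3
        oracle = Counter(proteins)
        reads = [_read(f"r{i}", p) for i, p in enumerate(proteins)]
        variants, _ = call_variants(reads, min_support=3)
        assert len(variants) == sum(1 for c in oracle.values() if c >= 3) == 2
        assert sorted(v.support for v in variants) == sorted(oracle.values())

    def test_noncoding_reads_are_ignored(self):
        reads = [_read(f"r{i}", None, category=CodingCategory.NONCODING) for i in range(5)]
        variants, unsupported = call_variants(reads)
        assert variants == [] and unsupported == []

    @given(seed=st.integers(min_value=0, max_value=1000))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance_and_read_conservation(self, seed):
        import random

        proteins = ["MAAA" * 30] * 4 + ["MCCC" * 30] * 3 + ["MDDD" * 30] * 2
        reads = [_read(f"r{i}", p) for i, p in enumerate(proteins)]
        shuffled = reads[:]
        random.Random(seed).shuffle(shuffled)
        v1, u1 = call_variants(reads)
        v2, u2 = call_variants(shuffled)
        assert [(v.key, v.support) for v in v1] == [(v.key, v.support) for v in v2]
        n_grouped = sum(v.support for v in v1) + sum(len(ids) for _, ids in u1)
        assert n_grouped == len(reads)


class TestPrivateVariantFraction:
    def _variant(self, vid, samples):
        return Variant(vid, CodingCategory.ORF2_ONLY, ("p",), {}, ["r"] * 3, set(samples))

    def test_all_private(self):
        variants = [self._variant(f"V{i}", [f"S{i}"]) for i in range(5)]
        assert private_variant_fraction(variants) == 1.0

    def test_none_private(self):
        variants = [self._variant(f"V{i}", ["S1", "S2"]) for i in range(5)]
        assert private_variant_fraction(variants) == 0.0

    def test_49_of_100_private(self):
        variants = [self._variant(f"V{i}", ["S1"] if i < 49 else ["S1", "S2"]) for i in range(100)]
        assert private_variant_fraction(variants) == pytest.approx(0.49)


class TestFindSavs:
    def test_identical_proteins_have_no_savs(self, toy_model):
        res = find_savs(toy_model.orf2_protein, toy_model.orf2_protein)
        assert res.savs == []
        assert res.covered_span == (0, len(toy_model.orf2_protein))
        assert res.truncation_spans == []

    def test_single_substitution_reported_at_position(self, toy_model):
        p = toy_model.orf2_protein
        alt = "W" if p[10] != "W" else "Y"
        res = find_savs(p[:10] + alt + p[11:], p)
        assert [(s.position, s.consensus_aa, s.variant_aa) for s in res.savs] == [(10, p[10], alt)]

    @pytest.mark.parametrize("n_subs", [1, 3, 8])
    def test_gap_free_sav_count_equals_hamming_distance(self, toy_model, rng, n_subs):
        p = toy_model.orf2_protein
        variant = list(p)
        positions = rng.choice(len(p), size=n_subs, replace=False)
        for pos in positions:
            variant[pos] = "W" if variant[pos] != "W" else "Y"
        variant = "".join(variant)
        hamming = sum(a != b for a, b in zip(variant, p))
        res = find_savs(variant, p)
        assert len(res.savs) == hamming == n_subs

    def test_truncation_reported_as_span_not_savs(self, toy_model):
        p = toy_model.orf2_protein
        res = find_savs(p[: int(0.8 * len(p))], p)
        assert res.savs == []
        assert res.truncation_spans == [(int(0.8 * len(p)), len(p))]

    def test_empty_protein_rejected(self, toy_model):
        with pytest.raises(ValueError):
            find_savs("", toy_model.orf2_protein)


class TestResidueConservation:
    def _variants_with_one_mutant(self, model, position, n=59):
        p = model.orf2_protein
        alt = "W" if p[position] != "W" else "Y"
        mutant = p[:position] + alt + p[position + 1 :]
        out = []
        for i in range(n):
            protein = mutant if i == 0 else p
            out.append(
                Variant(f"V{i}", CodingCategory.ORF2_ONLY, (protein,), {"ORF2": protein}, ["r"] * 3, {"S1"})
            )
        return out

    def test_fully_conserved_positions(self, toy_model):
        variants = self._variants_with_one_mutant(toy_model, 40)
        table = residue_conservation(variants, [10, 20], toy_model)
        assert (table["conserved_fraction"] == 1.0).all()

    def test_one_of_59_mutated_gives_1_69_pct(self, toy_model):
        variants = self._variants_with_one_mutant(toy_model, 40, n=59)
        table = residue_conservation(variants, [40], toy_model)
        row = table.iloc[0]
        assert row["conserved_fraction"] == pytest.approx(58 / 59)
        assert row["mutated_pct"] == pytest.approx(100 / 59, abs=0.005)
        assert row["mutated_pct"] == pytest.approx(1.69, abs=0.01)

    def test_position_beyond_truncation_flagged_absent(self, toy_model):
        p = toy_model.orf2_protein
        cut = int(0.8 * len(p))
        variants = [
            Variant("V0", CodingCategory.ORF2P_ONLY, (p[:cut],), {"ORF2": p[:cut]}, ["r"] * 3, {"S1"})
        ]
        table = residue_conservation(variants, [cut + 5], toy_model)
        assert table.iloc[0]["n_absent"] == 1
        assert table.iloc[0]["conserved_fraction"] == 0.0

    def test_position_outside_protein_rejected(self, toy_model):
        with pytest.raises(ValueError):
            residue_conservation([], [len(toy_model.orf2_protein)], toy_model)


class TestSavParameterRecovery:
    def test_generator_planted_savs_recovered_exactly(self, toy_model, toy_genome, balanced_profile):
        from l1scope import analyze_reads, simulate_library

        planted = [(5, "W"), (30, "P")]
        lib = simulate_library(
            toy_model, toy_genome, profile=balanced_profile, n=120, seed=9, orf2_savs=planted
        )
        result = analyze_reads(lib.reads, toy_model, toy_genome)
        orf2_variants = [v for v in result.variants if v.category is CodingCategory.ORF2_ONLY]
        assert orf2_variants, "expected at least one supported ORF2 variant"
        for v in orf2_variants:
            assert sorted((s.position, s.variant_aa) for s in v.savs) == sorted(planted)
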