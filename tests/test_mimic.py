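"""Mimic scanning, mutation application, synonymy, variant classification."""

import itertools

import pytest

from ripscan.mimic import (
    MutationSpec,
    apply_mutations,
    classify_variant,
    is_synonymous,
    scan_mimic,
)
from ripscan.synthetic import simulate_cds_with_mimic

from conftest import TOY_HAIRPIN

# Standard genetic code, written out independently of the implementation's
# translation machinery (oracle for the synonymy brute-force check).
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


class TestScanMimic:
    def test_recovers_planted_mimic_at_truth_position(self):
        cds, pos = simulate_cds_with_mimic(300, "GUG", insert_pos=150, stem_len=5, seed=1)
        hits = scan_mimic(cds, "GUG")
        assert len(hits) == 1
        assert hits[0].triplet_pos == pos
        assert hits[0].stem_len == 5

    def test_truth_position_invariant_to_flank_randomness(self):
        positions = set()
        for seed in (3, 4, 5, 6):
            cds, pos = simulate_cds_with_mimic(
                300, "GUG", insert_pos=120, stem_len=4, seed=seed
            )
            hits = scan_mimic(cds, "GUG")
            positions.update(h.triplet_pos for h in hits)
        assert positions == {120}

    def test_triplet_absent_gives_no_hits(self):
        assert scan_mimic("ACACAC" * 10, "GUG") == []

    def test_min_stem_filters_weak_hairpins(self):
        cds, pos = simulate_cds_with_mimic(200, "GUG", insert_pos=100, stem_len=3, seed=0)
        assert scan_mimic(cds, "GUG", min_stem=4) == []
        hits = scan_mimic(cds, "GUG", min_stem=3)
        assert [h.triplet_pos for h in hits] == [100]

    def test_cds_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            scan_mimic("ACGUACGU", "GUG", window_len=15)


class TestApplyMutations:
    def test_single_substitution(self):
        assert apply_mutations("GGT", [MutationSpec.parse("T3A")]) == "GGA"

    def test_reference_mismatch_reports_position(self):
        with pytest.raises(ValueError, match="position 2.*expected C.*found G"):
            apply_mutations("GGT", [MutationSpec.parse("C2A")])

    def test_order_independent(self):
        muts = [MutationSpec.parse(m) for m in ("T1098A", "C1104A", "C1107A")]
        cds = "A" * 1097 + "T" + "A" * 5 + "C" + "A" * 2 + "C" + "A" * 10
        results = {
            apply_mutations(cds, list(perm)) for perm in itertools.permutations(muts)
        }
        assert len(results) == 1

    def test_u_t_equivalence(self):
        assert apply_mutations("GGU", [MutationSpec.parse("T3A")]) == "GGA"

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError, match="cannot parse"):
            MutationSpec.parse("1101TA")
        with pytest.raises(ValueError, match="ref equals alt"):
            MutationSpec.parse("T5U")


class TestIsSynonymous:
    def test_wobble_ggu_to_gga_is_silent(self):
        assert is_synonymous("GGT", MutationSpec.parse("T3A"))

    def test_met_codon_never_silent(self):
        for alt_spec in ("A1C", "T2A", "G3A"):
            assert not is_synonymous("ATG", MutationSpec.parse(alt_spec))

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            is_synonymous("GGTA", MutationSpec.parse("T3A"))

    def test_all_576_single_substitutions_match_codon_table_oracle(self):
        bases = "TCAG"
        checked = 0
        for codon in CODON_TABLE:
            for pos in range(3):
                for alt in bases:
                    if alt == codon[pos]:
                        continue
                    mut = MutationSpec(position=pos + 1, ref=codon[pos], alt=alt)
                    mutant = codon[:pos] + alt + codon[pos + 1 :]
                    expected = CODON_TABLE[codon] == CODON_TABLE[mutant]
                    assert is_synonymous(codon, mut) == expected, (codon, mut)
                    checked += 1
        assert checked == 576


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "mutations, expected",
        [
            (["U7A"], "anticodon_lost"),  # loop GUG -> GAG
            (["C3A", "G11A"], "stem_disrupted"),  # stem pairs broken
            (["C3G", "G11C"], "stem_preserved"),  # compensatory swap
            ([], "stem_preserved"),
        ],
    )
    def test_toy_hairpin_classes(self, mutations, expected):
        result = classify_variant(
            TOY_HAIRPIN, [MutationSpec.parse(m) for m in mutations], "GUG"
        )
        assert result.label == expected

    def test_anticodon_loss_is_sequence_level(self):
        result = classify_variant(TOY_HAIRPIN, [MutationSpec.parse("U7A")], "GUG")
        assert not result.triplet_intact

    def test_diagnostics_populated(self):
        result = classify_variant(TOY_HAIRPIN, [MutationSpec.parse("C3G"), MutationSpec.parse("G11C")], "GUG")
        assert result.pairs_retained == 1.0
        assert result.triplet_in_loop

    def test_absolute_coordinates_via_window_start(self):
        # Window placed at CDS position 1094: mutation given in CDS coords.
        result = classify_variant(
            TOY_HAIRPIN,
            [MutationSpec(position=1100, ref="U", alt="A")],
            "GUG",
            window_start=1094,
        )
        assert result.label == "anticodon_lost"

    def test_mutation_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside the window"):
            classify_variant(
                TOY_HAIRPIN, [MutationSpec(position=50, ref="A", alt="G")], "GUG"
            )

    def test_window_without_mimic_rejected(self):
        with pytest.raises(ValueError, match="does not present"):
            classify_variant("ACACACACACACA", [], "GUG")
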