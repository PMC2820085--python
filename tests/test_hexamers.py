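import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirextra.hexamers import (
    alignment_to_mask,
    all_hexamers,
    build_count_matrix,
    count_nonoverlapping,
    hexamers_for_mirnas,
    mirna_to_hexamers,
    normalized_count,
    reverse_complement_dna,
)
from mirextra.io_model import MiRNARecord, UTRRecord

from conftest import MIR1, brute_force_max_disjoint, rna_rc_to_dna


class TestMiRNAToHexamers:
    @pytest.mark.parametrize(
        "sequence, expected",
        [
            # hsa-miR-1: seed match CATTCC is the canonical positive control
            ("UGGAAUGUAAAGAAGUAUGUAU", ("ATTCCA", "CATTCC", "ACATTC")),
            ("AAAAAAAA", ("TTTTTT", "TTTTTT", "TTTTTT")),
            ("ACGUACGU", ("GTACGT", "CGTACG", "ACGTAC")),
        ],
    )
    def test_known_hexamers(self, sequence, expected):
        hexes = mirna_to_hexamers(MiRNARecord("m", sequence))
        assert hexes.triple == expected
        # independent oracle: reverse-complement each RNA window directly
        assert expected == tuple(
            rna_rc_to_dna(sequence[i : i + 6]) for i in range(3)
        )

    @given(st.text(alphabet="ACGU", min_size=8, max_size=25))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_recovers_mirna_window(self, sequence):
        """RC of the mRNA hexamer (read back to RNA) is the miRNA window."""
        hexes = mirna_to_hexamers(MiRNARecord("m", sequence))
        for i, h in enumerate(hexes.triple):
            back = reverse_complement_dna(h).replace("T", "U")
            assert back == sequence[i : i + 6]

    def test_short_mirna_named_in_error(self):
        mir = MiRNARecord.__new__(MiRNARecord)  # bypass its own validation
        mir.mirna_id, mir.sequence = "mir-short", "ACGUACG"
        with pytest.raises(ValueError, match="mir-short"):
            mirna_to_hexamers(mir)


class TestCountNonOverlapping:
    @pytest.mark.parametrize(
        "sequence, hexamer, mask, expected",
        [
            ("AAAAAAAAAAAA", "AAAAAA", None, 2),
            ("ACGTACGTACGT", "ACGTAC", None, 1),  # offsets 0 and 4 overlap
            ("AAAAAAAAAAAA", "AAAAAA", "111111000000", 1),
            ("GGGGGG", "AAAAAA", None, 0),
            ("AAANAAAAAA", "AAAAAA", None, 1),  # N window never matches
            ("", "AAAAAA", None, 0),
        ],
    )
    def test_examples(self, sequence, hexamer, mask, expected):
        assert count_nonoverlapping(sequence, hexamer, mask) == expected

    def test_invalid_hexamer_rejected(self):
        for bad in ("AAAAA", "AAAAAAA", "AAAAAN", "aaaaaa"):
            with pytest.raises(ValueError):
                count_nonoverlapping("ACGT", bad)

    @given(
        st.text(alphabet="AC", min_size=0, max_size=30),
        st.text(alphabet="AC", min_size=6, max_size=6),
    )
    @settings(max_examples=200, deadline=None)
    def test_greedy_equals_max_disjoint_packing(self, sequence, hexamer):
        assert count_nonoverlapping(sequence, hexamer) == brute_force_max_disjoint(
            sequence, hexamer
        )

    @given(
        st.text(alphabet="ACGT", min_size=6, max_size=60),
        st.text(alphabet="ACGT", min_size=6, max_size=6),
        st.lists(st.sampled_from("01"), min_size=6, max_size=60),
    )
    @settings(max_examples=200, deadline=None)
    def test_masked_count_never_exceeds_unmasked(self, sequence, hexamer, bits):
        mask = "".join(bits)[: len(sequence)].ljust(len(sequence), "1")
        assert count_nonoverlapping(sequence, hexamer, mask) <= count_nonoverlapping(
            sequence, hexamer
        )


class TestNormalizedCount:
    @pytest.mark.parametrize(
        "sequence, hexamer, expected",
        [
            ("AAAAAAAAAAAA", "AAAAAA", 2 / 12),
            ("GGGGGG", "AAAAAA", 0.0),
            ("AAAAAA", "AAAAAA", 1 / 6),  # maximum possible density
        ],
    )
    def test_examples(self, sequence, hexamer, expected):
        assert normalized_count(sequence, hexamer) == pytest.approx(expected)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            normalized_count("", "AAAAAA")


class TestCountMatrix:
    def test_values_in_range_and_shape(self):
        utrs = [UTRRecord("g1", "ACGTACGTACGTAC"), UTRRecord("g2", "AATTAATTAATT")]
        matrix = build_count_matrix(utrs, all_hexamers())
        assert matrix.shape == (2, 4096)
        assert (matrix.values >= 0).all() and (matrix.values <= 1 / 6 + 1e-12).all()

    def test_single_gene_single_hit(self):
        matrix = build_count_matrix([UTRRecord("g1", "ACGTAC")], all_hexamers())
        nonzero = matrix.loc["g1"][matrix.loc["g1"] > 0]
        assert list(nonzero.index) == ["ACGTAC"]
        assert nonzero.iloc[0] == pytest.approx(1 / 6)

    def test_mirna_panel_collapses_duplicate_hexamers(self):
        mirnas = [
            MIR1,
            MiRNARecord("mir-b", "UGGAAUGUAAAGAAGUAUGUAA"),  # same first 8 nt
            MiRNARecord("mir-c", "ACGUACGUACGUACGUACGUAC"),
        ]
        mapping, hexes = hexamers_for_mirnas(mirnas)
        assert len(mapping) == 3
        assert len(hexes) == 6  # 3 shared + 3 distinct
        assert len(hexes) <= 9

    def test_indexed_and_scan_paths_agree(self):
        utrs = [UTRRecord(f"g{i}", ("ACGTAA" * 30)[i:]) for i in range(5)]
        panel = all_hexamers()[:100]
        fast = build_count_matrix(utrs, panel)
        slow_vals = [
            [normalized_count(u.sequence, h) for h in panel] for u in utrs
        ]
        assert fast.values.tolist() == slow_vals

    def test_missing_mask_listed(self):
        utrs = [UTRRecord("g1", "ACGTAC", "111111"), UTRRecord("g2", "ACGTAC")]
        with pytest.raises(ValueError, match="g2"):
            build_count_matrix(utrs, ["ACGTAC"], use_masks=True)

    def test_masked_matrix_bounded_by_unmasked(self):
        utrs = [
            UTRRecord("g1", "AATTCCAATTCC", "110111011101"),
            UTRRecord("g2", "CATTCCCATTCC", "111111111111"),
        ]
        masked = build_count_matrix(utrs, ["CATTCC", "AATTCC"], use_masks=True)
        unmasked = build_count_matrix(utrs, ["CATTCC", "AATTCC"])
        assert (masked.values <= unmasked.values + 1e-12).all()


class TestAlignmentToMask:
    def test_identity_gap_and_mismatch(self):
        # mask covers ungapped reference; mismatch and gap columns are 0
        assert alignment_to_mask("ACGTA-C", "ACCTATC") == "110111"

    def test_simple(self):
        assert alignment_to_mask("ACGT", "ACCT") == "1101"
        assert alignment_to_mask("AC-GT", "ACAGT") == "1111"
        assert alignment_to_mask("ACGT", "AC-T") == "1101"

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            alignment_to_mask("ACG", "AC")
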