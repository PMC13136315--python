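"""Barcode parsing from Read 1, region assignment policies, and tallies."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photobarcode.codebook import (
    Codebook,
    Codeword,
    Letter,
    build_codebook,
    default_alphabet,
)
from photobarcode.demux import (
    DemuxError,
    ReadLayout,
    Rejection,
    assign_region,
    demux_pairs,
    parse_barcode,
    tabulate,
    validate_alphabet_separation,
)

HANDLE = "ACACGACGCTCTTCCGATCT"


def make_read1(codeword, letters, handle=HANDLE, pad=10):
    """Assemble an error-free Read 1: handle + letters in reverse order."""
    by_id = {let.id: let for let in letters}
    body = "".join(by_id[d].sequence for d in reversed(codeword.digits))
    return handle + body + "T" * pad


class TestParseBarcode:
    def test_exact_read_decodes_in_round_order(self, alphabet4):
        # L2L4 was ligated round-1=L2, round-2=L4; Read 1 shows L4 first
        layout = ReadLayout(HANDLE, 2, 20)
        cw = Codeword((2, 4))
        read = make_read1(cw, alphabet4)
        by_id = {let.id: let for let in alphabet4}
        assert read[len(HANDLE):len(HANDLE) + 20] == by_id[4].sequence
        assert parse_barcode(read, layout, alphabet4) == cw

    def test_single_substitution_tolerated_anywhere(self, alphabet4):
        layout = ReadLayout(HANDLE, 2, 20)
        cw = Codeword((2, 4))
        clean = make_read1(cw, alphabet4)
        start, stop = len(HANDLE), len(HANDLE) + 40
        for pos in range(start, stop):  # every barcode-slot position
            for base in "ACGT":
                if base == clean[pos]:
                    continue
                mutated = clean[:pos] + base + clean[pos + 1:]
                assert parse_barcode(mutated, layout, alphabet4, 2) == cw

    def test_all_n_read_rejected_no_handle(self, alphabet4):
        layout = ReadLayout(HANDLE, 2, 20)
        result = parse_barcode("N" * 70, layout, alphabet4)
        assert isinstance(result, Rejection) and result.reason == "no-handle"

    def test_handle_with_one_mismatch_still_found(self, alphabet4):
        layout = ReadLayout(HANDLE, 2, 20)
        cw = Codeword((1, 3))
        read = make_read1(cw, alphabet4)
        damaged = "G" + read[1:] if read[0] != "G" else "A" + read[1:]
        assert parse_barcode(damaged, layout, alphabet4) == cw

    def test_truncated_read_rejected_length_anomaly(self, alphabet4):
        layout = ReadLayout(HANDLE, 2, 20)
        read = make_read1(Codeword((1, 2)), alphabet4)[: len(HANDLE) + 25]
        result = parse_barcode(read, layout, alphabet4)
        assert isinstance(result, Rejection) and result.reason == "length-anomaly"

    def test_too_many_mismatches_rejected(self, alphabet4):
        layout = ReadLayout(HANDLE, 2, 20)
        clean = make_read1(Codeword((1, 2)), alphabet4)
        start = len(HANDLE)
        bad = clean[:start] + "A" * 20 + clean[start + 20:]
        # an all-A window is far from every letter in a separated alphabet
        result = parse_barcode(bad, layout, alphabet4)
        assert isinstance(result, Rejection)
        assert result.reason in ("letter-mismatch", "ambiguous")

    def test_equidistant_window_rejected_ambiguous(self):
        # two artificial letters 2 mismatches apart; a window 1 mismatch
        # from each is an exact tie
        a = Letter(1, "AAAAAAAAAAAAAAAAAAAA")
        b = Letter(2, "AAAAAAAAAAAAAAAAAACC")
        window = "AAAAAAAAAAAAAAAAAAAC"
        layout = ReadLayout(HANDLE, 1, 20)
        result = parse_barcode(HANDLE + window, layout, [a, b], 2)
        assert isinstance(result, Rejection) and result.reason == "ambiguous"

    def test_separation_validator_rejects_close_alphabets(self):
        a = Letter(1, "AAAAAAAAAAAAAAAAAAAA")
        b = Letter(2, "AAAAAAAAAAAAAAAAAACC")
        with pytest.raises(DemuxError, match="unsafe"):
            validate_alphabet_separation([a, b], max_mm_per_letter=2)
        validate_alphabet_separation(default_alphabet(4), 2)  # fine


class TestAssignRegion:
    def test_exact_match(self, mixed_species_codebook):
        assert assign_region(Codeword((2, 4)), mixed_species_codebook) == "bottom"
        assert assign_region(Codeword((1, 3)), mixed_species_codebook) == "top"

    def test_exact_detects_single_letter_errors(self, mixed_species_codebook):
        result = assign_region(Codeword((2, 3)), mixed_species_codebook, "exact")
        assert isinstance(result, Rejection) and result.reason == "no-match"

    def test_nearest_unique_rejects_equidistant(self, mixed_species_codebook):
        # L2L3 is Hamming-1 from both L1L3 and L2L4 (brute-force check)
        cw = Codeword((2, 3))
        dists = [
            cw.hamming(w) for w in mixed_species_codebook.assignment.values()
        ]
        assert dists == [1, 1]
        result = assign_region(cw, mixed_species_codebook, "nearest-unique")
        assert isinstance(result, Rejection) and result.reason == "ambiguous"

    def test_nearest_unique_accepts_single_neighbour(self, alphabet4):
        cb = Codebook(
            alphabet4, 2, [Codeword((1, 3))], {"only": Codeword((1, 3))}
        )
        assert assign_region(Codeword((1, 4)), cb, "nearest-unique") == "only"

    def test_repeat_collapse_survives_one_corrupted_repeat(self, alphabet4):
        cb = Codebook(
            alphabet4, 2, [Codeword((1, 2))], {"r": Codeword((1, 2))}
        )
        original = Codeword((1, 1, 2, 2))  # r=2 repeat code of L1L2
        # every single-digit corruption still decodes to L1L2
        for pos in range(4):
            for wrong in range(1, 5):
                if wrong == original.digits[pos]:
                    continue
                digits = list(original.digits)
                digits[pos] = wrong
                result = assign_region(
                    Codeword(tuple(digits)), cb, "repeat-collapse", repeats=2
                )
                assert result == "r"

    def test_repeat_collapse_length_mismatch(self, alphabet4):
        cb = Codebook(alphabet4, 2, [Codeword((1, 2))], {"r": Codeword((1, 2))})
        result = assign_region(Codeword((1, 2)), cb, "repeat-collapse", repeats=2)
        assert isinstance(result, Rejection)

    def test_unknown_policy_raises(self, mixed_species_codebook):
        with pytest.raises(DemuxError):
            assign_region(Codeword((1, 3)), mixed_species_codebook, "fuzzy")


class TestDemuxPairs:
    @given(
        m=st.integers(min_value=2, max_value=4),
        n=st.integers(min_value=1, max_value=3),
        seed=st.integers(min_value=0, max_value=10),
    )
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_error_free_reads_fully_assigned(self, m, n, seed):
        import numpy as np

        cb = build_codebook(m, n).with_full_assignment()
        rng = np.random.default_rng(seed)
        regions = list(cb.assignment)
        chosen = rng.choice(regions, size=30)
        layout = ReadLayout(HANDLE, n, len(cb.letters[0]))
        pairs = [
            (f"r{i}", make_read1(cb.assignment[rid], cb.letters), "ACGT" * 15)
            for i, rid in enumerate(chosen)
        ]
        result = demux_pairs(pairs, layout, cb, policy="exact")
        assert (result["region"].to_numpy() == chosen).all()
        assert (result["reason"] == "").all()

    def test_assigned_count_monotone_in_mismatch_budget(self, alphabet4):
        import numpy as np

        cb = Codebook(
            alphabet4,
            2,
            [Codeword((1, 3)), Codeword((2, 4))],
            {"top": Codeword((1, 3)), "bottom": Codeword((2, 4))},
        )
        layout = ReadLayout(HANDLE, 2, 20)
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        pairs = []
        for i in range(300):
            rid = ("top", "bottom")[i % 2]
            read = list(make_read1(cb.assignment[rid], alphabet4))
            hit = rng.random(len(read)) < 0.05
            for j in np.where(hit)[0]:
                read[j] = bases[rng.integers(0, 4)]
            pairs.append((f"r{i}", "".join(read), "A" * 60))
        counts = [
            (demux_pairs(pairs, layout, cb, max_mm_per_letter=mm)["region"] != "")
            .sum()
            for mm in range(4)
        ]
        assert counts == sorted(counts)


class TestTabulate:
    def test_perfect_purity(self):
        per_read = pd.DataFrame(
            {
                "read_id": ["a", "b"],
                "codeword": ["L1L3", "L1L3"],
                "region": ["top", "top"],
                "reason": ["", ""],
                "species": ["", ""],
            }
        )
        truth = pd.DataFrame(
            {"read_id": ["a", "b"], "region": ["top", "top"],
             "species": ["hs", "hs"]}
        )
        result = tabulate(per_read, truth)
        assert result.misassignment_rate == 0.0
        assert result.composition.loc["top", "hs"] == 1.0
        assert result.region_counts["top"] == 2

    def test_zero_assigned_reads_no_division_error(self):
        per_read = pd.DataFrame(
            {
                "read_id": ["a"],
                "codeword": [""],
                "region": [""],
                "reason": ["no-handle"],
                "species": [""],
            }
        )
        result = tabulate(per_read)
        assert result.n_assigned == 0
        assert result.misassignment_rate is None
        assert result.composition.empty
        assert result.reject_counts["no-handle"] == 1
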