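"""Alignment, masking, and percent-identity behaviour."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paralogon_scope.msa_identity import (
    AA_ALPHABET,
    BLOSUM62,
    MSA,
    build_msa,
    global_align,
    mask_from_regions,
    percent_identity,
    read_region_file,
)


def brute_force_score(a, b, go=10.0, ge=0.5):
    """Enumerate every monotone alignment of two short strings."""
    best = None

    def rec(i, j, cols):
        nonlocal best
        if i == len(a) and j == len(b):
            s, prev = 0.0, None
            for x, y in cols:
                if x is not None and y is not None:
                    s += BLOSUM62[
                        AA_ALPHABET.index(a[x]), AA_ALPHABET.index(b[y])
                    ]
                    prev = "m"
                else:
                    cur = "x" if x is None else "y"
                    s -= ge if prev == cur else go
                    prev = cur
            if best is None or s > best:
                best = s
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(i, j)])
        if i < len(a):
            rec(i + 1, j, cols + [(i, None)])
        if j < len(b):
            rec(i, j + 1, cols + [(None, j)])

    rec(0, 0, [])
    return best


class TestGlobalAlign:
    def test_identity_case_scores_diagonal_sum(self):
        aln = global_align("ACDE", "ACDE")
        expected = sum(
            BLOSUM62[AA_ALPHABET.index(c), AA_ALPHABET.index(c)] for c in "ACDE"
        )
        assert aln.score == expected
        assert aln.aligned_a == aln.aligned_b == "ACDE"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("A", "")

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError):
            global_align("AC1E", "ACDE")

    def test_degapping_recovers_inputs(self):
        aln = global_align("ACDEFGH", "ACDGH")
        assert aln.aligned_a.replace("-", "") == "ACDEFGH"
        assert aln.aligned_b.replace("-", "") == "ACDGH"
        assert not any(
            x == y == "-" for x, y in zip(aln.aligned_a, aln.aligned_b)
        )

    def test_matches_brute_force_on_short_pairs(self):
        rng = random.Random(11)
        for _ in range(120):
            a = "".join(
                rng.choice("ACDE") for _ in range(rng.randint(1, 6))
            )
            b = "".join(
                rng.choice("ACDE") for _ in range(rng.randint(1, 6))
            )
            assert global_align(a, b).score == pytest.approx(
                brute_force_score(a, b)
            ), (a, b)

    def test_matches_independent_optimal_aligner(self):
        """Same optimum as Biopython's C implementation on longer pairs."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        al = Align.PairwiseAligner()
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score, al.extend_gap_score = -10.0, -0.5
        al.mode = "global"
        rng = random.Random(5)
        for _ in range(20):
            a = "".join(rng.choice(AA_ALPHABET[:20]) for _ in range(40))
            b = "".join(rng.choice(AA_ALPHABET[:20]) for _ in range(35))
            assert global_align(a, b).score == pytest.approx(al.score(a, b))


class TestPercentIdentity:
    def test_three_of_four_columns(self):
        assert percent_identity(global_align("ACDE", "ACDK")) == 75.0

    def test_identical_sequences_are_100(self):
        msa = MSA(["a", "b"], ["ACDEF", "ACDEF"])
        assert percent_identity(msa) == 100.0

    @given(
        st.text(alphabet="ACDEFGHIK", min_size=1, max_size=30),
        st.text(alphabet="ACDEFGHIK", min_size=1, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, a, b):
        assert percent_identity(global_align(a, b)) == pytest.approx(
            percent_identity(global_align(b, a))
        )

    def test_mask_complement_consistency(self):
        """identity(full) is the count-weighted mean of mask and complement."""
        msa = MSA(["a", "b"], ["ACDEFGHIKL", "ACDKFGYIKV"])
        full = percent_identity(msa)
        mask = mask_from_regions(msa, "a", {"r": (2, 6)}, "include")
        comp = mask_from_regions(msa, "a", {"r": (2, 6)}, "exclude")
        n_m, n_c = len(mask.columns), len(comp.columns)
        combined = (
            percent_identity(msa, mask=mask) * n_m
            + percent_identity(msa, mask=comp) * n_c
        ) / (n_m + n_c)
        assert combined == pytest.approx(full)

    def test_empty_mask_errors(self):
        msa = MSA(["a", "b"], ["ACDE", "ACDE"])
        mask = mask_from_regions(msa, "a", {}, "include")
        with pytest.raises(ValueError):
            percent_identity(msa, mask=mask)

    def test_excluding_divergent_region_raises_identity(self):
        """Differences concentrated in one region: masking it out helps."""
        a = "ACDEFGHIK" + "LMNPQRSTVW" + "ACDEFGHIK"
        b = "ACDEFGHIK" + "WVTSRQPNML" + "ACDEFGHIK"
        msa = MSA(["a", "b"], [a, b])
        full = percent_identity(msa)
        masked = percent_identity(
            msa, mask=mask_from_regions(msa, "a", {"var": (9, 19)}, "exclude")
        )
        assert masked > full
        assert masked == 100.0


class TestMask:
    def test_exclude_projects_to_complement(self):
        msa = MSA(["r", "s"], ["ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY"])
        mask = mask_from_regions(msa, "r", {"IL3": (10, 20)}, "exclude")
        assert list(mask.columns) == list(range(10))

    def test_projection_through_reference_gaps(self):
        msa = MSA(["r", "s"], ["AC--DEF", "ACGGDEF"])
        mask = mask_from_regions(msa, "r", {"x": (2, 4)}, "include")
        # residues 2,3 of the reference are D,E at columns 4,5
        assert list(mask.columns) == [4, 5]

    def test_range_beyond_reference_errors(self):
        msa = MSA(["r"], ["ACDE"])
        with pytest.raises(ValueError):
            mask_from_regions(msa, "r", {"x": (2, 9)}, "include")

    def test_region_file_is_one_based_inclusive(self, tmp_path):
        p = tmp_path / "regions.tsv"
        p.write_text("name\tstart\tend\nTM1\t1\t4\nIL3\t10\t12\n")
        assert read_region_file(p) == {"TM1": (0, 4), "IL3": (9, 12)}


class TestBuildMsa:
    def test_identical_sequences_gapless(self):
        msa = build_msa({f"s{i}": "ACDEFGHIK" for i in range(4)})
        assert msa.width == 9
        assert all(r == "ACDEFGHIK" for r in msa.rows)

    def test_two_sequences_equal_pairwise(self):
        aln = global_align("ACDEFGH", "ACDGH")
        msa = build_msa({"a": "ACDEFGH", "b": "ACDGH"})
        assert msa.rows == [aln.aligned_a, aln.aligned_b]

    def test_single_sequence_warns(self):
        with pytest.warns(UserWarning):
            msa = build_msa({"a": "ACD"})
        assert msa.rows == ["ACD"]

    def test_indel_trio_degaps_to_inputs(self):
        seqs = {
            "a": "MKVLACDEFGHIKWWTS",
            "b": "MKVLACDEGHIKWWTS",  # one deletion
            "c": "MKVLACDEFGHIKWWTS",
        }
        msa = build_msa(seqs)
        assert msa.width >= 17
        for sid, seq in seqs.items():
            assert msa.degapped(sid) == seq

    def test_column_map_strictly_increasing(self):
        msa = build_msa({"a": "MKVACDEFGHIK", "b": "MKVACDGHIK", "c": "MKVACDEFGHIK"})
        for sid in msa.ids:
            cm = msa.column_map(sid)
            assert (np.diff(cm) > 0).all()
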