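"""Alignment parsing and conservation features, checked against brute force."""

import io
import math

import numpy as np
import pytest

from endopheno.alignment import (
    AMINO_ACIDS,
    GAP,
    MAX_COLUMN_ENTROPY,
    MultipleSequenceAlignment,
    check_native,
    column_entropies,
    column_profile,
    map_position,
    pssm_native,
    read_alignment,
    shannon_entropy,
    write_alignment,
)
from endopheno.errors import (
    AlignmentFormatError,
    AlphabetError,
    DegenerateColumnError,
    PositionError,
    ReferenceMismatchError,
    UndefinedBackgroundError,
)
from tests.conftest import random_msa


# ---------------------------------------------------------------------------
# Independent brute-force oracles (straight re-count from the row strings)


def brute_entropy(msa, col):
    residues = [seq[col] for seq in msa.seqs if seq[col] != GAP]
    h = 0.0
    for aa in set(residues):
        p = residues.count(aa) / len(residues)
        h -= p * math.log(p)
    return h


def brute_pssm(msa, col, native):
    residues = [seq[col] for seq in msa.seqs if seq[col] != GAP]
    all_res = [ch for seq in msa.seqs for ch in seq if ch != GAP]
    f_col = residues.count(native) / len(residues)
    if f_col == 0.0:
        f_col = 1.0 / (len(residues) + 1)
    return math.log(f_col / (all_res.count(native) / len(all_res)))


# ---------------------------------------------------------------------------
# Parsing


def test_identity_parse_two_records():
    msa = read_alignment(">a\nACDEF\n>b\nACDEF\n", reference_id="a")
    assert msa.n_rows == 2
    assert msa.length == 5
    assert msa.reference_row == "ACDEF"


def test_unequal_lengths_rejected():
    with pytest.raises(AlignmentFormatError):
        read_alignment(">a\nACDEF\n>b\nACDEFG\n", reference_id="a")


def test_missing_reference_rejected():
    with pytest.raises(KeyError):
        read_alignment(">a\nACDEF\n", reference_id="zz")


def test_illegal_characters_rejected_with_location():
    with pytest.raises(AlphabetError, match="'X'.*'b'.*column 3"):
        read_alignment(">a\nACDEF\n>b\nACXEF\n", reference_id="a")


def test_case_and_dot_gap_normalised():
    msa = read_alignment(">a\nac.de\n>b\nACDDE\n", reference_id="a")
    assert msa.seqs[0] == "AC-DE"


def test_roundtrip_write_read_unchanged():
    rng = np.random.default_rng(42)
    msa = random_msa(rng, 10, 50, gap_rate=0.1)
    buf = io.StringIO()
    write_alignment(msa, buf)
    again = read_alignment(buf.getvalue(), reference_id="ref")
    assert again.ids == msa.ids
    assert again.seqs == msa.seqs


# ---------------------------------------------------------------------------
# Position mapping and native checks


def test_map_position_counts_non_gaps():
    msa = MultipleSequenceAlignment([("ref", "AC-DE"), ("s", "ACDDE")], "ref")
    assert map_position(msa, 1) == 0
    assert map_position(msa, 3) == 3  # the 'D' after the gap
    assert map_position(msa, 4) == 4
    with pytest.raises(PositionError):
        map_position(msa, 5)
    with pytest.raises(PositionError):
        map_position(msa, 0)


def test_map_position_agrees_with_gap_stripping():
    rng = np.random.default_rng(7)
    for _ in range(20):
        msa = random_msa(rng, 4, 30)
        # regap the reference by hand
        ref = list(msa.seqs[0])
        for j in sorted(rng.choice(30, size=8, replace=False).tolist()):
            ref.insert(j, GAP)
        rows = [("ref", "".join(ref))] + [
            (f"x{i}", msa.seqs[1][:1] * len(ref)) for i in range(2)
        ]
        gapped = MultipleSequenceAlignment(rows, "ref")
        stripped = gapped.reference_row.replace(GAP, "")
        for pos in range(1, len(stripped) + 1):
            col = map_position(gapped, pos)
            assert gapped.reference_row[col] == stripped[pos - 1]
            # brute-force scan: col is the pos-th non-gap column
            assert sum(c != GAP for c in gapped.reference_row[: col + 1]) == pos


def test_check_native_pass_and_mismatch():
    msa = MultipleSequenceAlignment([("ref", "ACDE")], "ref")
    assert check_native(msa, 2, "C") is True
    with pytest.raises(ReferenceMismatchError) as exc:
        check_native(msa, 2, "G")
    assert exc.value.expected == "G"
    assert exc.value.observed == "C"
    assert check_native(msa, 2, "G", strict=False) is False


def test_check_native_never_falsely_passes():
    rng = np.random.default_rng(11)
    msa = random_msa(rng, 5, 40)
    stripped = msa.reference_row.replace(GAP, "")
    for pos in range(1, len(stripped) + 1):
        true_native = stripped[pos - 1]
        for aa in AMINO_ACIDS:
            ok = check_native(msa, pos, aa, strict=False)
            assert ok == (aa == true_native)


# ---------------------------------------------------------------------------
# Column profiles and entropy


def test_column_profile_counts_and_gaps(tiny_msa):
    prof = column_profile(tiny_msa, 1)  # A,A,C,C
    assert prof.counts == {"A": 2, "C": 2}
    assert prof.gap_count == 0
    prof5 = column_profile(tiny_msa, 5)  # E,E,E,-
    assert prof5.counts == {"E": 3}
    assert prof5.gap_count == 1
    assert prof5.depth == 3


def test_all_gap_column_rejected():
    msa = MultipleSequenceAlignment([("ref", "A-"), ("s", "C-")], "ref")
    with pytest.raises(DegenerateColumnError):
        column_profile(msa, 1)


def test_profile_matches_brute_force_tally():
    rng = np.random.default_rng(3)
    msa = random_msa(rng, 25, 40, gap_rate=0.15)
    for col in range(msa.length):
        residues = [seq[col] for seq in msa.seqs]
        non_gap = [r for r in residues if r != GAP]
        if not non_gap:
            continue
        prof = column_profile(msa, col)
        assert prof.gap_count == residues.count(GAP)
        assert prof.counts == {aa: non_gap.count(aa) for aa in set(non_gap)}


def test_entropy_trivial_cases(tiny_msa):
    assert shannon_entropy(column_profile(tiny_msa, 0)) == 0.0  # conserved
    h = shannon_entropy(column_profile(tiny_msa, 1))  # 50/50 A-C
    assert h == pytest.approx(math.log(2), abs=1e-12)


def test_entropy_zero_iff_conserved_and_bounded():
    rng = np.random.default_rng(5)
    for _ in range(50):
        msa = random_msa(rng, int(rng.integers(2, 20)), int(rng.integers(5, 30)))
        for col in range(msa.length):
            prof = column_profile(msa, col)
            h = shannon_entropy(prof)
            assert 0.0 <= h <= MAX_COLUMN_ENTROPY + 1e-15
            assert (h == 0.0) == (len(prof.counts) == 1)


def test_conservation_features_match_brute_force_oracle():
    """Both features equal independent brute-force evaluation to 1e-12."""
    rng = np.random.default_rng(17)
    for _ in range(100):
        msa = random_msa(
            rng, int(rng.integers(2, 21)), int(rng.integers(5, 51)), gap_rate=0.05
        )
        for _ in range(5):
            col = int(rng.integers(0, msa.length))
            residues = [s[col] for s in msa.seqs if s[col] != GAP]
            if not residues:
                continue
            assert shannon_entropy(column_profile(msa, col)) == pytest.approx(
                brute_entropy(msa, col), abs=1e-12
            )
            native = residues[0]  # guaranteed present in the alignment
            assert pssm_native(msa, col, native) == pytest.approx(
                brute_pssm(msa, col, native), abs=1e-12
            )


def test_row_permutation_invariance():
    rng = np.random.default_rng(23)
    msa = random_msa(rng, 12, 20)
    order = rng.permutation(12)
    rows = [(msa.ids[i], msa.seqs[i]) for i in order]
    shuffled = MultipleSequenceAlignment(rows, reference_id="ref")
    for col in range(msa.length):
        assert shannon_entropy(column_profile(msa, col)) == shannon_entropy(
            column_profile(shuffled, col)
        )
        native = msa.seqs[0][col]
        if native != GAP:
            assert pssm_native(msa, col, native) == pssm_native(shuffled, col, native)


def test_duplicating_identical_rows_preserves_entropy():
    msa2 = MultipleSequenceAlignment([("ref", "ACDE"), ("s1", "ACDE")], "ref")
    msa3 = MultipleSequenceAlignment(
        [("ref", "ACDE"), ("s1", "ACDE"), ("s2", "ACDE")], "ref"
    )
    for col in range(4):
        assert shannon_entropy(column_profile(msa2, col)) == shannon_entropy(
            column_profile(msa3, col)
        )


# ---------------------------------------------------------------------------
# PSSM specifics


def test_pssm_zero_when_column_matches_background():
    # Uniform alignment: every column 50/50 A-C, background 50/50 A-C.
    msa = MultipleSequenceAlignment([("ref", "AC"), ("s", "CA")], "ref")
    assert pssm_native(msa, 0, "A") == 0.0
    assert pssm_native(msa, 0, "C") == 0.0


def test_pssm_fixed_column_quarter_background():
    # Column 0 all W (f_col = 1); W is 4 of 16 non-gap cells (background 0.25).
    msa = MultipleSequenceAlignment(
        [("ref", "WACD"), ("s1", "WCDE"), ("s2", "WDEF"), ("s3", "WEFG")], "ref"
    )
    assert pssm_native(msa, 0, "W") == pytest.approx(math.log(4.0), abs=1e-12)


def test_pssm_absent_native_uses_pseudocount():
    msa = MultipleSequenceAlignment([("ref", "AC"), ("s", "AC")], "ref")
    # C absent from column 0; depth 2 -> floor 1/3; background of C = 0.5
    assert pssm_native(msa, 0, "C") == pytest.approx(math.log((1 / 3) / 0.5), abs=1e-12)


def test_pssm_unseen_residue_has_no_background():
    msa = MultipleSequenceAlignment([("ref", "AC"), ("s", "AC")], "ref")
    with pytest.raises(UndefinedBackgroundError):
        pssm_native(msa, 0, "W")


def test_column_entropies_vectorised_matches_scalar():
    rng = np.random.default_rng(29)
    msa = random_msa(rng, 15, 25, gap_rate=0.1)
    vec = column_entropies(msa)
    for col in range(msa.length):
        assert vec[col] == pytest.approx(
            shannon_entropy(column_profile(msa, col)), abs=1e-12
        )
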