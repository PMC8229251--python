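"""Multiple sequence alignments and the two conservation features.

The conservation component of every feature vector comes from a multiple
sequence alignment (MSA) of the target protein's orthologs or homologs.  For
a variant at reference position ``p`` two quantities are computed at the
alignment column holding that position:

* Shannon entropy of the column's amino-acid frequencies,
  ``H = -sum_i p_i ln p_i`` — low at conserved positions, at most ``ln 20``;
* the position-specific scoring matrix (PSSM) element for the native
  residue, ``ln(f_nat,col / f_nat,msa)`` — the log-ratio of the native
  residue's frequency in the column to its frequency over the whole
  alignment.

Conventions (fixed, documented constants of this implementation):

* natural logarithms for both features;
* gaps are excluded from every frequency: column frequencies are taken over
  the non-gap residues of the column, and the alignment-wide background over
  all non-gap cells;
* if the native residue is absent from its column, its column frequency is
  floored at ``1 / (depth + 1)`` (a minimal pseudocount) so the log-ratio
  stays finite; a native residue absent from the *entire* alignment is an
  error.

Protein positions are 1-based; alignment columns are 0-based internally.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentFormatError,
    ReferenceLookupError,
    AlphabetError,
    DegenerateColumnError,
    PositionError,
    ReferenceMismatchError,
    UndefinedBackgroundError,
)

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AA_TO_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: Entropy of a uniform distribution over the 20 amino acids (nats).
MAX_COLUMN_ENTROPY = math.log(20.0)

_GAP_CODE = 20  # internal integer code for the gap symbol


def _encode(seq: str) -> np.ndarray:
    """Encode a residue string as integer codes 0..19 (amino acids), 20 (gap)."""
    out = np.empty(len(seq), dtype=np.int8)
    for j, ch in enumerate(seq):
        if ch == GAP:
            out[j] = _GAP_CODE
        else:
            out[j] = AA_TO_INDEX[ch]
    return out


@dataclass(frozen=True)
class ColumnProfile:
    """Amino-acid counts of one alignment column (gaps tallied separately)."""

    counts: dict  # amino acid -> occurrence count (non-gap only)
    gap_count: int

    @property
    def depth(self) -> int:
        """Number of non-gap residues in the column."""
        return sum(self.counts.values())

    def frequency(self, residue: str) -> float:
        return self.counts.get(residue, 0) / self.depth


@dataclass(frozen=True)
class ConservationFeatures:
    """The two MSA-derived features at one variant position."""

    entropy: float
    pssm_native: float
    column_index: int  # 0-based alignment column
    protein_position: int  # 1-based reference position


class MultipleSequenceAlignment:
    """An aligned set of protein sequences with a designated reference row.

    Rows are equal-length strings over the 20 amino acids plus ``-``.  Input
    is normalised on construction: lower case is upper-cased and ``.`` gaps
    become ``-``; anything else (including ``X``) is rejected.
    """

    def __init__(self, rows: Iterable[tuple], reference_id: str):
        ids = []
        seqs = []
        for rid, seq in rows:
            ids.append(str(rid))
            seqs.append(self._normalise(str(rid), str(seq)))
        if not ids:
            raise AlignmentFormatError("alignment must contain at least one record")
        length = len(seqs[0])
        if length < 1:
            raise AlignmentFormatError("alignment rows must have length >= 1")
        for rid, seq in zip(ids, seqs):
            if len(seq) != length:
                raise AlignmentFormatError(
                    f"row {rid!r} has length {len(seq)}, expected {length}"
                )
        if len(set(ids)) != len(ids):
            raise AlignmentFormatError("duplicate sequence identifiers in alignment")
        if reference_id not in ids:
            raise ReferenceLookupError(
                f"reference id {reference_id!r} not found in alignment"
            )
        self.ids = ids
        self.seqs = seqs
        self.reference_id = reference_id
        self._codes = np.vstack([_encode(s) for s in seqs])

    @staticmethod
    def _normalise(rid: str, seq: str) -> str:
        seq = seq.upper().replace(".", GAP)
        for j, ch in enumerate(seq):
            if ch not in AA_TO_INDEX and ch != GAP:
                raise AlphabetError(
                    f"illegal character {ch!r} in row {rid!r} at column {j + 1}"
                    " (only the 20 canonical amino acids and '-' are accepted)"
                )
        return seq

    # -- basic geometry ----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def reference_row(self) -> str:
        return self.seqs[self.ids.index(self.reference_id)]

    @property
    def reference_length(self) -> int:
        """Number of non-gap residues in the reference row."""
        return len(self.reference_row) - self.reference_row.count(GAP)

    def codes(self) -> np.ndarray:
        """Integer-coded residue matrix (rows x columns); 20 encodes a gap."""
        return self._codes

    # -- derived frequencies -----------------------------------------------

    def background_counts(self) -> np.ndarray:
        """Occurrence count of each amino acid over all non-gap cells."""
        flat = self._codes.ravel()
        return np.bincount(flat[flat != _GAP_CODE], minlength=20)

    def background_frequencies(self) -> np.ndarray:
        counts = self.background_counts()
        return counts / counts.sum()


# ---------------------------------------------------------------------------
# I/O


def read_alignment(stream: Union[str, IO[str]], reference_id: str) -> MultipleSequenceAlignment:
    """Parse an aligned FASTA stream (path, text, or file object).

    All records must have equal length; residues are validated against the
    20-amino-acid alphabet plus gap.
    """
    if isinstance(stream, str):
        if "\n" in stream or stream.lstrip().startswith(">"):
            handle: IO[str] = io.StringIO(stream)
        else:
            handle = open(stream)
    else:
        handle = stream
    try:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if handle is not stream:
            handle.close()
    if not records:
        raise AlignmentFormatError("no FASTA records found")
    return MultipleSequenceAlignment(records, reference_id)


def write_alignment(msa: MultipleSequenceAlignment, stream: Union[str, IO[str]]) -> None:
    """Write an alignment as FASTA (wraps at Biopython's default width)."""
    records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in zip(msa.ids, msa.seqs)
    ]
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, stream, "fasta")


# ---------------------------------------------------------------------------
# Coordinate bridging


def map_position(msa: MultipleSequenceAlignment, protein_position: int) -> int:
    """0-based alignment column of the ``protein_position``-th reference residue.

    ``protein_position`` is 1-based and counts non-gap residues of the
    reference row.
    """
    if protein_position < 1:
        raise PositionError(f"protein position must be >= 1, got {protein_position}")
    seen = 0
    for col, ch in enumerate(msa.reference_row):
        if ch != GAP:
            seen += 1
            if seen == protein_position:
                return col
    raise PositionError(
        f"protein position {protein_position} exceeds reference length "
        f"({msa.reference_length} residues)"
    )


def check_native(
    msa: MultipleSequenceAlignment, protein_position: int, native: str, strict: bool = True
) -> bool:
    """Verify that the reference residue at ``protein_position`` equals ``native``.

    Returns True on agreement.  On mismatch raises
    :class:`ReferenceMismatchError` (or returns False when ``strict=False``).
    """
    col = map_position(msa, protein_position)
    observed = msa.reference_row[col]
    native = native.upper()
    if observed == native:
        return True
    if strict:
        raise ReferenceMismatchError(
            f"position {protein_position}: expected native {native!r} but the "
            f"reference carries {observed!r}",
            expected=native,
            observed=observed,
        )
    return False


# ---------------------------------------------------------------------------
# Conservation features


def column_profile(msa: MultipleSequenceAlignment, column: int) -> ColumnProfile:
    """Amino-acid counts of one column; gaps counted separately."""
    if not 0 <= column < msa.length:
        raise PositionError(f"column {column} outside alignment of length {msa.length}")
    col = msa.codes()[:, column]
    gap_count = int(np.sum(col == _GAP_CODE))
    if gap_count == msa.n_rows:
        raise DegenerateColumnError(f"column {column} contains only gaps")
    counts = np.bincount(col[col != _GAP_CODE], minlength=20)
    return ColumnProfile(
        counts={AMINO_ACIDS[i]: int(c) for i, c in enumerate(counts) if c > 0},
        gap_count=gap_count,
    )


def shannon_entropy(profile: ColumnProfile) -> float:
    """Non-negative Shannon entropy (nats) of a column's amino-acid frequencies."""
    depth = profile.depth
    h = 0.0
    for count in profile.counts.values():
        p = count / depth
        h -= p * math.log(p)
    return max(h, 0.0)  # clip -0.0


def pssm_native(msa: MultipleSequenceAlignment, column: int, native: str) -> float:
    """PSSM element ``ln(f_nat,col / f_nat,msa)`` for the native residue.

    The column frequency is floored at ``1/(depth+1)`` when the native is
    absent from the column; a native absent from the whole alignment has no
    defined background and raises :class:`UndefinedBackgroundError`.
    """
    native = native.upper()
    if native not in AA_TO_INDEX:
        raise AlphabetError(f"native residue must be canonical, got {native!r}")
    profile = column_profile(msa, column)
    background = msa.background_frequencies()[AA_TO_INDEX[native]]
    if background == 0.0:
        raise UndefinedBackgroundError(
            f"residue {native!r} never occurs in the alignment; its background "
            "frequency (and hence the PSSM element) is undefined"
        )
    f_col = profile.counts.get(native, 0) / profile.depth
    if f_col == 0.0:
        f_col = 1.0 / (profile.depth + 1)
    return math.log(f_col / background)


def conservation_features(
    msa: MultipleSequenceAlignment,
    protein_position: int,
    native: str,
    strict_native: bool = True,
) -> ConservationFeatures:
    """Compute both conservation features at a variant's reference position."""
    if strict_native:
        check_native(msa, protein_position, native)
    col = map_position(msa, protein_position)
    return ConservationFeatures(
        entropy=shannon_entropy(column_profile(msa, col)),
        pssm_native=pssm_native(msa, col, native),
        column_index=col,
        protein_position=protein_position,
    )


def column_entropies(msa: MultipleSequenceAlignment) -> np.ndarray:
    """Shannon entropy of every column, vectorised (gap-only columns -> nan)."""
    codes = msa.codes()
    out = np.empty(msa.length)
    for j in range(msa.length):
        col = codes[:, j]
        col = col[col != _GAP_CODE]
        if col.size == 0:
            out[j] = np.nan
            continue
        counts = np.bincount(col, minlength=20)
        p = counts[counts > 0] / col.size
        out[j] = float(-(p * np.log(p)).sum())
    return out
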