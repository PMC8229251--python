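"""Substitution-intrinsic features and assembly of variant feature vectors.

Three of the five predictive features depend only on the identity of the
amino-acid replacement, not on its position in the protein:

* the BLOSUM62 substitution score of the (native, mutant) pair;
* the change in van der Waals side-chain volume, ``V(mutant) - V(native)``;
* the change in hydropathy, ``KD(mutant) - KD(native)`` on the
  Kyte-Doolittle scale.

The remaining two (column Shannon entropy and the native-residue PSSM
element) come from :mod:`endopheno.alignment`.  ``build_features`` composes
all of them into a :class:`VariantFeatureVector` tagged with its feature set
(``"three"`` = BLOSUM62, entropy, PSSM; ``"five"`` adds the two property
deltas).  Three-feature vectors are exact prefixes of five-feature vectors.

Both property scales ship as package data with citation metadata and can be
overridden with a two-column text file (residue, value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .alignment import (
    AMINO_ACIDS,
    MultipleSequenceAlignment,
    conservation_features,
)
from .errors import AlphabetError, SchemaError

FEATURE_NAMES_THREE = ("blosum62", "entropy", "pssm")
FEATURE_NAMES_FIVE = FEATURE_NAMES_THREE + ("d_volume", "d_hydrophobicity")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class AminoAcidScale:
    """A per-residue numeric property with provenance."""

    name: str
    values: dict  # one-letter amino acid -> float, exactly 20 entries
    citation: str = ""

    def __post_init__(self):
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise SchemaError(
                f"scale {self.name!r} must cover exactly the 20 canonical amino "
                f"acids (missing: {sorted(missing)}, extra: {sorted(extra)})"
            )
        for aa, v in self.values.items():
            if not np.isfinite(v):
                raise SchemaError(f"scale {self.name!r} has non-finite value for {aa}")

    def __getitem__(self, residue: str) -> float:
        residue = residue.upper()
        if residue not in self.values:
            raise AlphabetError(f"non-canonical residue {residue!r}")
        return self.values[residue]


#: Side-chain van der Waals volumes in cubic angstroms
#: (Richards 1974, J Mol Biol 82:1-14, as tabulated by Creighton 1993).
VAN_DER_WAALS_VOLUME = AminoAcidScale(
    name="van_der_waals_volume",
    values={
        "A": 67.0, "R": 148.0, "N": 96.0, "D": 91.0, "C": 86.0,
        "Q": 114.0, "E": 109.0, "G": 48.0, "H": 118.0, "I": 124.0,
        "L": 124.0, "K": 135.0, "M": 124.0, "F": 135.0, "P": 90.0,
        "S": 73.0, "T": 93.0, "W": 163.0, "Y": 141.0, "V": 105.0,
    },
    citation="Richards FM (1974) J Mol Biol 82:1-14 (via Creighton 1993)",
)

#: Kyte-Doolittle hydropathy index (Kyte & Doolittle 1982, J Mol Biol 157:105-132).
KYTE_DOOLITTLE_HYDROPATHY = AminoAcidScale(
    name="kyte_doolittle_hydropathy",
    values={
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    },
    citation="Kyte J, Doolittle RF (1982) J Mol Biol 157:105-132",
)


def read_scale_file(stream: Union[str, IO[str]], name: str = "custom") -> AminoAcidScale:
    """Read a user scale: two whitespace/tab-separated columns (residue, value)."""
    df = pd.read_csv(stream, sep=r"\s+", header=None, comment="#", names=["residue", "value"])
    values = {}
    for _, row in df.iterrows():
        residue = str(row["residue"]).upper()
        if residue in values:
            raise SchemaError(f"duplicate residue {residue!r} in scale file")
        values[residue] = float(row["value"])
    return AminoAcidScale(name=name, values=values, citation="user-supplied")


def blosum62_score(native: str, mutant: str) -> int:
    """The published BLOSUM62 entry for the ordered pair (symmetric)."""
    native, mutant = native.upper(), mutant.upper()
    for residue in (native, mutant):
        if residue not in AMINO_ACIDS:
            raise AlphabetError(f"non-canonical residue {residue!r}")
    return int(_BLOSUM62[native, mutant])


def delta_scale(scale: AminoAcidScale, native: str, mutant: str) -> float:
    """Property difference ``scale[mutant] - scale[native]``."""
    return scale[mutant] - scale[native]


@dataclass(frozen=True)
class VariantFeatureVector:
    """The 3- or 5-feature representation of one missense variant."""

    blosum62: int
    entropy: float
    pssm: float
    d_volume: Optional[float]
    d_hydrophobicity: Optional[float]
    feature_set: str  # "three" | "five"

    def __post_init__(self):
        if self.feature_set not in ("three", "five"):
            raise SchemaError(f"feature_set must be 'three' or 'five', got {self.feature_set!r}")
        if self.feature_set == "five" and (self.d_volume is None or self.d_hydrophobicity is None):
            raise SchemaError("five-feature vectors require both property deltas")

    @property
    def names(self) -> tuple:
        return FEATURE_NAMES_THREE if self.feature_set == "three" else FEATURE_NAMES_FIVE

    def values(self) -> np.ndarray:
        if self.feature_set == "three":
            return np.array([self.blosum62, self.entropy, self.pssm], dtype=float)
        return np.array(
            [self.blosum62, self.entropy, self.pssm, self.d_volume, self.d_hydrophobicity],
            dtype=float,
        )


def feature_names(feature_set: str) -> tuple:
    if feature_set == "three":
        return FEATURE_NAMES_THREE
    if feature_set == "five":
        return FEATURE_NAMES_FIVE
    raise SchemaError(f"feature_set must be 'three' or 'five', got {feature_set!r}")


def build_features(
    variant,
    msa: MultipleSequenceAlignment,
    feature_set: str = "five",
    volume_scale: AminoAcidScale = VAN_DER_WAALS_VOLUME,
    hydrophobicity_scale: AminoAcidScale = KYTE_DOOLITTLE_HYDROPATHY,
    strict_native: bool = True,
) -> VariantFeatureVector:
    """Assemble the full feature vector for one variant.

    ``variant`` needs ``position`` (1-based), ``native`` and ``mutant``
    attributes.  With ``strict_native`` (default) the native residue must
    match the reference row at that position.
    """
    names = feature_names(feature_set)  # validates feature_set early
    cons = conservation_features(msa, variant.position, variant.native, strict_native=strict_native)
    five = "d_volume" in names
    return VariantFeatureVector(
        blosum62=blosum62_score(variant.native, variant.mutant),
        entropy=cons.entropy,
        pssm=cons.pssm_native,
        d_volume=delta_scale(volume_scale, variant.native, variant.mutant) if five else None,
        d_hydrophobicity=(
            delta_scale(hydrophobicity_scale, variant.native, variant.mutant) if five else None
        ),
        feature_set=feature_set,
    )


def feature_matrix(
    variants: Sequence,
    msa: MultipleSequenceAlignment,
    feature_set: str = "five",
    strict_native: bool = True,
    volume_scale: AminoAcidScale = VAN_DER_WAALS_VOLUME,
    hydrophobicity_scale: AminoAcidScale = KYTE_DOOLITTLE_HYDROPATHY,
) -> pd.DataFrame:
    """Feature matrix for a collection of variants (rows follow input order).

    Returns a DataFrame whose columns are the feature names and whose index
    holds the variant keys ``(protein, position, native, mutant)``.
    """
    rows = []
    keys = []
    for v in variants:
        vec = build_features(
            v,
            msa,
            feature_set=feature_set,
            volume_scale=volume_scale,
            hydrophobicity_scale=hydrophobicity_scale,
            strict_native=strict_native,
        )
        rows.append(vec.values())
        keys.append(v.key if hasattr(v, "key") else (v.position, v.native, v.mutant))
    return pd.DataFrame(
        np.array(rows).reshape(len(rows), -1),
        columns=list(feature_names(feature_set)),
        index=pd.Index(keys, tupleize_cols=False),
    )
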