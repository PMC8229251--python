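"""Exception hierarchy shared across the package.

Every error raised by endopheno derives from :class:`EndophenoError`, so the
command-line layer can map library failures to a single nonzero exit status
while programmatic users can still catch fine-grained subclasses.
"""


class EndophenoError(Exception):
    """Base class for all endopheno errors."""


class AlignmentFormatError(EndophenoError):
    """Alignment rows have unequal lengths or the FASTA stream is malformed."""


class AlphabetError(EndophenoError):
    """A residue outside the 20 canonical amino acids (plus gap) was seen."""


class ReferenceLookupError(EndophenoError, KeyError):
    """The declared reference identifier is not a row of the alignment."""

    def __str__(self) -> str:  # KeyError would repr() the message
        return Exception.__str__(self)


class ReferenceMismatchError(EndophenoError):
    """A variant's declared native residue disagrees with the reference row."""

    def __init__(self, message: str, expected: str, observed: str):
        super().__init__(message)
        self.expected = expected
        self.observed = observed


class DegenerateColumnError(EndophenoError):
    """An alignment column contains no amino acid (all gaps)."""


class UndefinedBackgroundError(EndophenoError):
    """The native residue never occurs anywhere in the alignment."""


class PositionError(EndophenoError):
    """A protein position falls outside the reference sequence."""


class SchemaError(EndophenoError):
    """A variant table is missing required columns or has bad values."""


class UniquenessError(EndophenoError):
    """Duplicate variant key within one dataset."""


class SizeError(EndophenoError):
    """A dataset is too small (or a split fraction degenerate) for the operation."""


class ClassCoverageError(EndophenoError):
    """A class required by resampling or classification has no members."""


class SingularDesignError(EndophenoError):
    """Rank-deficient design matrix in an ordinary least-squares fit."""


class NoGridError(EndophenoError):
    """A hyperparameter grid was requested for a model kind that has none."""


class ContractError(EndophenoError):
    """Inputs violate an interface contract (e.g. feature-set mismatch)."""


class JoinError(EndophenoError):
    """Two per-variant tables do not cover the same variants."""


class UndefinedCorrelationError(EndophenoError):
    """Rank correlation is undefined (zero variance in one input)."""


class ConfigError(EndophenoError):
    """Invalid simulation or run configuration."""


class CapacityError(EndophenoError):
    """More synthetic variants requested than distinct substitutions exist."""
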