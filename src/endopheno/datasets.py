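"""Variant datasets, train/test plans, splits and under-sampling.

Variants are protein-level: the identity key is ``(protein, position,
native, mutant)``.  A dataset holds records for a single protein — models
for different proteins are never pooled — with an optional continuous assay
score (HDR or SGE) and/or a binary clinical label.

The module also implements the dataset manipulations used by the training
plans: removal of train/test overlap, a seeded random split (default 75/25),
random under-sampling to the minority class (records of an "intermediate"
assay class are dropped before resampling), and the SGE functional
classification rule (pathogenic below -1.328, benign above -0.748, strict
inequalities — boundary scores are intermediate).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import IO, Callable, Iterable, Iterator, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS
from .errors import (
    AlphabetError,
    ClassCoverageError,
    SchemaError,
    SizeError,
    UniquenessError,
)

PATHOGENIC = "pathogenic"
BENIGN = "benign"
INTERMEDIATE = "intermediate"

#: Published SGE functional-class thresholds (strict inequalities).
SGE_PATHOGENIC_BELOW = -1.328
SGE_BENIGN_ABOVE = -0.748

_TABLE_COLUMNS = ["protein", "position", "native", "mutant", "assay", "score", "label"]
_REQUIRED_COLUMNS = ["protein", "position", "native", "mutant"]


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant, optionally with an assay score and clinical label."""

    protein: str
    position: int
    native: str
    mutant: str
    assay: Optional[str] = None  # "HDR" | "SGE" | None
    assay_score: Optional[float] = None
    clinical_label: Optional[str] = None  # "pathogenic" | "benign" | None

    def __post_init__(self):
        object.__setattr__(self, "native", self.native.upper())
        object.__setattr__(self, "mutant", self.mutant.upper())
        for residue in (self.native, self.mutant):
            if residue not in AMINO_ACIDS:
                raise AlphabetError(f"non-canonical residue {residue!r} in variant record")
        if self.native == self.mutant:
            raise SchemaError(
                f"{self.protein} p.{self.native}{self.position}{self.mutant}: "
                "native and mutant residues must differ"
            )
        if self.position < 1:
            raise SchemaError(f"variant position must be >= 1, got {self.position}")
        if (self.assay is None) != (self.assay_score is None):
            raise SchemaError(
                f"{self.protein} {self.native}{self.position}{self.mutant}: assay "
                "and assay_score must be present together"
            )
        if self.assay_score is not None and not math.isfinite(self.assay_score):
            raise SchemaError(
                f"{self.protein} {self.native}{self.position}{self.mutant}: "
                "assay_score must be finite"
            )
        if self.clinical_label not in (None, PATHOGENIC, BENIGN):
            raise SchemaError(
                f"clinical_label must be '{PATHOGENIC}' or '{BENIGN}', "
                f"got {self.clinical_label!r}"
            )

    @property
    def key(self) -> tuple:
        return (self.protein, self.position, self.native, self.mutant)


class VariantDataset:
    """An ordered, key-unique collection of variants of a single protein."""

    def __init__(self, records: Iterable[VariantRecord], provenance: str = ""):
        self.records = list(records)
        self.provenance = provenance
        if not self.records:
            self.protein = None
        else:
            proteins = {r.protein for r in self.records}
            if len(proteins) > 1:
                raise SchemaError(
                    f"a dataset must hold a single protein, got {sorted(proteins)}"
                )
            self.protein = self.records[0].protein
        seen = set()
        for r in self.records:
            if r.key in seen:
                raise UniquenessError(
                    f"duplicate variant {r.protein} {r.native}{r.position}{r.mutant}"
                )
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> VariantRecord:
        return self.records[i]

    def keys(self) -> set:
        return {r.key for r in self.records}

    def scores(self) -> np.ndarray:
        """Assay scores in record order; raises if any record lacks one."""
        vals = []
        for r in self.records:
            if r.assay_score is None:
                raise SchemaError(
                    f"variant {r.native}{r.position}{r.mutant} has no assay score"
                )
            vals.append(r.assay_score)
        return np.asarray(vals, dtype=float)

    def labels(self) -> list:
        """Clinical labels in record order; raises if any record lacks one."""
        out = []
        for r in self.records:
            if r.clinical_label is None:
                raise SchemaError(
                    f"variant {r.native}{r.position}{r.mutant} has no clinical label"
                )
            out.append(r.clinical_label)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "protein": r.protein,
                    "position": r.position,
                    "native": r.native,
                    "mutant": r.mutant,
                    "assay": r.assay if r.assay is not None else "",
                    "score": r.assay_score if r.assay_score is not None else "",
                    "label": r.clinical_label if r.clinical_label is not None else "",
                }
            )
        return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def _parse_optional(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s if s else None


def read_variant_table(stream: Union[str, IO[str]], provenance: str = "") -> VariantDataset:
    """Read a delimited variant table (TSV by default, '#' lines ignored).

    Required columns: ``protein position native mutant``; optional:
    ``assay score label``.  Duplicate variant keys are rejected.
    """
    if isinstance(stream, str) and ("\n" in stream or "\t" in stream):
        stream = io.StringIO(stream)
    try:
        df = pd.read_csv(stream, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # malformed stream
        raise SchemaError(f"could not parse variant table: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table is missing required columns: {missing}")
    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based, counting the header line
        try:
            position = int(row["position"])
        except (TypeError, ValueError):
            raise SchemaError(f"row {rownum}: unparseable position {row['position']!r}")
        assay = _parse_optional(row.get("assay"))
        score_raw = _parse_optional(row.get("score"))
        score: Optional[float] = None
        if score_raw is not None:
            try:
                score = float(score_raw)
            except ValueError:
                raise SchemaError(f"row {rownum}: unparseable score {score_raw!r}")
        label = _parse_optional(row.get("label"))
        records.append(
            VariantRecord(
                protein=str(row["protein"]).strip(),
                position=position,
                native=str(row["native"]).strip(),
                mutant=str(row["mutant"]).strip(),
                assay=assay,
                assay_score=score,
                clinical_label=label,
            )
        )
    return VariantDataset(records, provenance=provenance)


def write_variant_table(
    dataset: VariantDataset, stream: Union[str, IO[str]], header_comment: str = ""
) -> None:
    """Write a dataset as TSV (stable column order; optional '#' header line)."""

    def _write(fh: IO[str]) -> None:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        dataset.to_frame().to_csv(fh, sep="\t", index=False)

    if isinstance(stream, str):
        with open(stream, "w") as fh:
            _write(fh)
    else:
        _write(stream)


# ---------------------------------------------------------------------------
# Dataset manipulations


def exclude_overlap(
    train: VariantDataset, test: VariantDataset
) -> Tuple[VariantDataset, int]:
    """Drop from ``train`` every variant that also occurs in ``test``.

    Returns the reduced training set and the number of records removed.
    ``test`` is untouched.
    """
    if train.protein is not None and test.protein is not None and train.protein != test.protein:
        raise SchemaError(
            f"train ({train.protein}) and test ({test.protein}) must be the same protein"
        )
    test_keys = test.keys()
    kept = [r for r in train.records if r.key not in test_keys]
    removed = len(train) - len(kept)
    return VariantDataset(kept, provenance=train.provenance), removed


def split(
    dataset: VariantDataset, fraction: float, seed: int
) -> Tuple[VariantDataset, VariantDataset]:
    """Random disjoint partition with ``round(fraction * n)`` training records.

    Deterministic for a given seed; both halves preserve the original record
    order.
    """
    if not 0.0 < fraction < 1.0:
        raise SizeError(f"split fraction must lie in (0, 1), got {fraction}")
    n = len(dataset)
    if n < 2:
        raise SizeError(f"cannot split a dataset of size {n}")
    n_train = int(math.floor(fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)  # both halves non-empty
    rng = np.random.default_rng(seed)
    train_idx = set(rng.permutation(n)[:n_train].tolist())
    train = [r for i, r in enumerate(dataset.records) if i in train_idx]
    test = [r for i, r in enumerate(dataset.records) if i not in train_idx]
    return (
        VariantDataset(train, provenance=dataset.provenance),
        VariantDataset(test, provenance=dataset.provenance),
    )


def undersample(
    train: VariantDataset, class_of: Callable[[float], str], seed: int
) -> VariantDataset:
    """Random under-sampling of the training set to the minority class.

    ``class_of`` maps an assay score to a class name; records classified as
    ``"intermediate"`` are excluded before resampling.  Each remaining class
    is downsampled without replacement to the minority count.  Output record
    order follows the input.
    """
    classes: dict = {}
    for i, r in enumerate(train.records):
        if r.assay_score is None:
            raise SchemaError(
                f"variant {r.native}{r.position}{r.mutant} has no assay score to classify"
            )
        c = class_of(r.assay_score)
        if c == INTERMEDIATE:
            continue
        classes.setdefault(c, []).append(i)
    if len(classes) < 2:
        raise ClassCoverageError(
            f"under-sampling needs >= 2 non-intermediate classes, got {sorted(classes)}"
        )
    minority = min(len(idx) for idx in classes.values())
    rng = np.random.default_rng(seed)
    keep: set = set()
    for c in sorted(classes):  # deterministic class order
        idx = classes[c]
        chosen = rng.choice(len(idx), size=minority, replace=False)
        keep.update(idx[j] for j in chosen)
    kept = [r for i, r in enumerate(train.records) if i in keep]
    return VariantDataset(kept, provenance=train.provenance)


def sge_class(score: float) -> str:
    """SGE functional class: pathogenic < -1.328 < intermediate < -0.748 < benign.

    Strict inequalities — a score exactly at either threshold is intermediate.
    """
    if not math.isfinite(score):
        raise SchemaError(f"SGE score must be finite, got {score}")
    if score < SGE_PATHOGENIC_BELOW:
        return PATHOGENIC
    if score > SGE_BENIGN_ABOVE:
        return BENIGN
    return INTERMEDIATE


def threshold_class(pathogenic_below: float, benign_above: Optional[float] = None) -> Callable:
    """Build a score->class rule from thresholds (two-class when band is empty)."""
    if benign_above is None:
        benign_above = pathogenic_below

    def rule(score: float) -> str:
        if not math.isfinite(score):
            raise SchemaError(f"score must be finite, got {score}")
        if score < pathogenic_below:
            return PATHOGENIC
        if score > benign_above:
            return BENIGN
        return BENIGN if pathogenic_below == benign_above else INTERMEDIATE

    return rule


# ---------------------------------------------------------------------------
# Train/test plans


@dataclass(frozen=True)
class TrainTestPlan:
    """A training/testing combination: sources, validation mode, resampling.

    ``validation`` is ``"loocv"`` (train and test sources must coincide),
    ``"split"`` (one source partitioned by ``fraction``/``seed``) or
    ``"independent"`` (two distinct sources; overlap removed from training).
    """

    train_source: str
    test_source: str
    validation: str  # "loocv" | "split" | "independent"
    fraction: float = 0.75
    seed: int = 0
    resample: bool = False

    def __post_init__(self):
        if self.validation not in ("loocv", "split", "independent"):
            raise SchemaError(f"unknown validation mode {self.validation!r}")
        if self.validation == "loocv" and self.train_source != self.test_source:
            raise SchemaError("LOOCV requires train_source == test_source")
        if self.validation == "split" and not 0.0 < self.fraction < 1.0:
            raise SchemaError(f"split fraction must lie in (0, 1), got {self.fraction}")


def realize_plan(
    plan: TrainTestPlan,
    train_data: VariantDataset,
    test_data: Optional[VariantDataset] = None,
    class_of: Optional[Callable[[float], str]] = None,
) -> Tuple[VariantDataset, VariantDataset]:
    """Materialise a plan into concrete train/test datasets.

    For ``split`` plans, ``train_data`` is partitioned.  For ``independent``
    plans, variants shared with ``test_data`` are removed from training.  The
    optional under-sampling step runs last, on the training set only.  The
    train/test key intersection is verified to be empty before returning
    (except under LOOCV, where the fold machinery guarantees disjointness).
    """
    if plan.validation == "loocv":
        train, test = train_data, train_data
    elif plan.validation == "split":
        train, test = split(train_data, plan.fraction, plan.seed)
    else:
        if test_data is None:
            raise SchemaError("independent plans need an explicit test dataset")
        train, _ = exclude_overlap(train_data, test_data)
        test = test_data
    if plan.resample:
        if class_of is None:
            raise SchemaError("resampling plans need a score->class rule")
        train = undersample(train, class_of, plan.seed)
    if plan.validation != "loocv" and train.keys() & test.keys():
        raise SchemaError("internal error: realized train/test sets overlap")
    return train, test
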