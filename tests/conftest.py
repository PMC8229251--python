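"""Shared fixtures: small hand-built alignments and random generators."""

import numpy as np
import pytest

from endopheno.alignment import AMINO_ACIDS, GAP, MultipleSequenceAlignment
from endopheno.datasets import VariantDataset, VariantRecord


@pytest.fixture
def tiny_msa() -> MultipleSequenceAlignment:
    """4 rows x 6 columns with a gapped reference and known column structure.

    Columns: 0 fully conserved A; 1 A/C mix; 2 gap in reference; 3 all D;
    4 three-way mix; 5 E with one gap.
    """
    return MultipleSequenceAlignment(
        [
            ("ref", "AA-DWE"),
            ("s1", "AADDWE"),
            ("s2", "ACDDFE"),
            ("s3", "ACDDY-"),
        ],
        reference_id="ref",
    )


def random_msa(rng: np.random.Generator, n_rows: int, length: int, gap_rate: float = 0.0):
    """A random alignment whose first row (the reference) is gap-free."""
    aa = np.array(list(AMINO_ACIDS))
    rows = [("ref", "".join(aa[rng.integers(0, 20, size=length)]))]
    for i in range(n_rows - 1):
        chars = aa[rng.integers(0, 20, size=length)]
        if gap_rate > 0:
            chars = np.where(rng.random(length) < gap_rate, GAP, chars)
        rows.append((f"s{i}", "".join(chars)))
    return MultipleSequenceAlignment(rows, reference_id="ref")


@pytest.fixture
def msa_factory():
    return random_msa


def random_dataset(rng: np.random.Generator, n: int, protein: str = "P1",
                   with_scores: bool = True, with_labels: bool = False) -> VariantDataset:
    """A random single-protein variant dataset with unique keys."""
    keys = set()
    records = []
    while len(records) < n:
        pos = int(rng.integers(1, 200))
        native, mutant = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
        key = (protein, pos, native, mutant)
        if key in keys:
            continue
        keys.add(key)
        records.append(
            VariantRecord(
                protein=protein,
                position=pos,
                native=str(native),
                mutant=str(mutant),
                assay="SGE" if with_scores else None,
                assay_score=float(rng.normal(-1.0, 1.0)) if with_scores else None,
                clinical_label=("pathogenic" if rng.random() < 0.3 else "benign")
                if with_labels
                else None,
            )
        )
    return VariantDataset(records)


@pytest.fixture
def dataset_factory():
    return random_dataset
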