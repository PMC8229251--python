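"""Binarization of endophenotype estimates and baseline binary classifiers.

Continuous assay estimates become pathogenic/benign calls through published
functionality thresholds:

* BRCA1 HDR: estimates below 0.53 are pathogenic, above are benign;
* SGE: below -1.328 pathogenic, above -0.748 benign, the band in between is
  "unknown" and excluded from performance computations;
* BRCA2 HDR: threshold 2.25.  Only the cut value is published; by default an
  estimate below 2.25 is called pathogenic (loss of function lowers repair
  activity, consistent with the BRCA1 rule), and the direction can be
  flipped via ``direction="above_pathogenic"``.

For two-class schemes an estimate exactly at the cut is called benign, so
every estimate receives exactly one call and "unknown" can only arise from
the SGE band.

The module also provides the feature-identical baseline classifiers trained
on binary clinical labels rather than assay scores: a Random Forest with
pinned defaults (100 trees, unlimited depth, sqrt(p) candidate features,
Gini impurity) and a single-hidden-layer neural network with 5 hidden units
(ReLU, Adam, <= 1000 iterations).  Training folds are balanced by SMOTE
minority oversampling (synthetic points interpolated between a minority
sample and one of its 5 nearest minority neighbours), applied to training
data only so held-out variants never influence the synthetic points.
SMOTE is implemented here with seeded numpy + scikit-learn nearest
neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

from .datasets import BENIGN, INTERMEDIATE, PATHOGENIC
from .errors import ClassCoverageError, ContractError, SchemaError, SizeError

UNKNOWN = "unknown"


@dataclass(frozen=True)
class ThresholdScheme:
    """Assay-specific thresholds for turning estimates into calls."""

    assay: str  # "HDR" | "SGE"
    protein: str
    pathogenic_below: float
    benign_above: float
    direction: str = "below_pathogenic"  # or "above_pathogenic" (two-class only)
    note: str = ""

    def __post_init__(self):
        if self.pathogenic_below > self.benign_above:
            raise SchemaError("pathogenic_below must be <= benign_above")
        if self.direction not in ("below_pathogenic", "above_pathogenic"):
            raise SchemaError(f"unknown direction {self.direction!r}")
        if self.direction == "above_pathogenic" and self.has_band:
            raise SchemaError("direction override only applies to two-class schemes")

    @property
    def has_band(self) -> bool:
        return self.pathogenic_below < self.benign_above

    def classify(self, estimate: float) -> str:
        if not math.isfinite(estimate):
            raise ContractError(f"estimate must be finite, got {estimate}")
        if self.direction == "above_pathogenic":
            return PATHOGENIC if estimate > self.pathogenic_below else BENIGN
        if estimate < self.pathogenic_below:
            return PATHOGENIC
        if estimate > self.benign_above:
            return BENIGN
        return BENIGN if not self.has_band else UNKNOWN


#: Published threshold schemes, keyed by CLI name.
SCHEMES = {
    "brca1-hdr": ThresholdScheme(
        assay="HDR", protein="BRCA1", pathogenic_below=0.53, benign_above=0.53,
        note="HDR estimate below 0.53 -> pathogenic",
    ),
    "brca2-hdr": ThresholdScheme(
        assay="HDR", protein="BRCA2", pathogenic_below=2.25, benign_above=2.25,
        note="HDR estimate below 2.25 -> pathogenic (default direction)",
    ),
    "sge": ThresholdScheme(
        assay="SGE", protein="BRCA1", pathogenic_below=-1.328, benign_above=-0.748,
        note="SGE band (-1.328, -0.748) -> unknown, excluded from metrics",
    ),
}


@dataclass(frozen=True)
class PathogenicityCall:
    """One variant's call, with the underlying evidence for audit."""

    key: tuple
    call: str  # "pathogenic" | "benign" | "unknown"
    source: str  # "regression-binarized" | "classifier"
    estimate: Optional[float] = None


def binarize(
    estimates,
    scheme: ThresholdScheme,
    keys: Optional[Sequence] = None,
    source: str = "regression-binarized",
) -> list:
    """Turn continuous estimates into calls under a threshold scheme.

    ``estimates`` is a mapping key -> estimate, or a sequence of estimates
    with ``keys`` supplied alongside (defaults to 0..n-1).
    """
    if hasattr(estimates, "items"):
        items = list(estimates.items())
    else:
        values = list(estimates)
        if keys is None:
            keys = list(range(len(values)))
        if len(keys) != len(values):
            raise ContractError("keys and estimates must have equal length")
        items = list(zip(keys, values))
    calls = []
    for key, est in items:
        est = float(est)
        if not math.isfinite(est):
            raise ContractError(f"non-finite estimate for variant {key!r}")
        calls.append(
            PathogenicityCall(key=key, call=scheme.classify(est), source=source, estimate=est)
        )
    return calls


# ---------------------------------------------------------------------------
# Baseline classifiers


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of a baseline classifier."""

    kind: str  # "random_forest" | "neural_network"
    balancing: bool = True  # SMOTE on training folds
    seed: int = 0
    smote_k: int = 5

    def __post_init__(self):
        if self.kind not in ("random_forest", "neural_network"):
            raise SchemaError(f"unknown classifier kind {self.kind!r}")


def _make_classifier(spec: ClassifierSpec):
    if spec.kind == "random_forest":
        # Pinned "default" forest: 100 trees, unlimited depth, sqrt(p)
        # candidate features per split, Gini impurity.
        return RandomForestClassifier(
            n_estimators=100,
            criterion="gini",
            max_depth=None,
            max_features="sqrt",
            random_state=spec.seed,
        )
    return MLPClassifier(
        hidden_layer_sizes=(5,),
        activation="relu",
        solver="adam",
        max_iter=1000,
        random_state=spec.seed,
    )


def smote_oversample(
    x: np.ndarray, y: Sequence[str], seed: int, k: int = 5
) -> Tuple[np.ndarray, list]:
    """Balance classes by SMOTE-style minority oversampling.

    Every class is brought up to the majority count.  A synthetic point is
    drawn as ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)``, where ``x_nn``
    is one of the ``k`` nearest neighbours of ``x_i`` within its own class
    (fewer when the class is small; a singleton class is duplicated).
    Deterministic for a given seed.  Original rows are preserved, synthetic
    rows appended.
    """
    x = np.asarray(x, dtype=float)
    y = list(y)
    if x.shape[0] != len(y):
        raise ContractError("x and y must have equal length")
    rng = np.random.default_rng(seed)
    classes = sorted(set(y))
    counts = {c: y.count(c) for c in classes}
    target = max(counts.values())
    x_out = [x]
    y_out = list(y)
    for c in classes:
        deficit = target - counts[c]
        if deficit == 0:
            continue
        xc = x[np.asarray([lab == c for lab in y])]
        if xc.shape[0] == 1:
            synth = np.repeat(xc, deficit, axis=0)
        else:
            kk = min(k, xc.shape[0] - 1)
            nn = NearestNeighbors(n_neighbors=kk + 1).fit(xc)
            neighbours = nn.kneighbors(xc, return_distance=False)[:, 1:]
            base = rng.integers(0, xc.shape[0], size=deficit)
            pick = rng.integers(0, kk, size=deficit)
            u = rng.random(size=(deficit, 1))
            anchor = xc[base]
            partner = xc[neighbours[base, pick]]
            synth = anchor + u * (partner - anchor)
        x_out.append(synth)
        y_out.extend([c] * deficit)
    return np.vstack(x_out), y_out


def _fit_classifier(spec: ClassifierSpec, x: np.ndarray, y: list):
    if len(set(y)) < 2:
        raise ClassCoverageError("classifier training needs both classes present")
    if spec.balancing:
        x, y = smote_oversample(x, y, seed=spec.seed, k=spec.smote_k)
    clf = _make_classifier(spec)
    clf.fit(x, y)
    return clf


def train_classifier(spec: ClassifierSpec, x: np.ndarray, y: Sequence[str]):
    """Fit a baseline classifier (with optional SMOTE balancing)."""
    x = np.asarray(x, dtype=float)
    y = list(y)
    if x.shape[0] < 10:
        raise SizeError(f"classifier training needs n >= 10, got {x.shape[0]}")
    return _fit_classifier(spec, x, y)


def loocv_classify(
    spec: ClassifierSpec, x: np.ndarray, y: Sequence[str], keys: Optional[Sequence] = None
) -> list:
    """Leave-one-out calls: each fold's balancing and fit exclude the
    held-out variant entirely."""
    x = np.asarray(x, dtype=float)
    y = list(y)
    n = x.shape[0]
    if n < 10:
        raise SizeError(f"LOOCV classification needs n >= 10, got {n}")
    for c in set(y):
        if y.count(c) < 2:
            raise ClassCoverageError(f"class {c!r} needs >= 2 members for LOOCV")
    if keys is None:
        keys = list(range(n))
    calls = []
    for k_idx in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k_idx] = False
        clf = _fit_classifier(spec, x[mask], [lab for i, lab in enumerate(y) if i != k_idx])
        pred = clf.predict(x[k_idx : k_idx + 1])[0]
        calls.append(
            PathogenicityCall(key=keys[k_idx], call=str(pred), source="classifier")
        )
    return calls
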