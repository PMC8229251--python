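"""Performance assessment: confusion counts, binary metrics, rank correlation.

The positive class is *pathogenic* throughout.  From a 2x2 confusion table
(TP/FP/TN/FN; calls of "unknown" are excluded and counted separately) six
standard metrics are computed:

* sensitivity  = TP / (TP + FN)
* specificity  = TN / (TN + FP)
* accuracy     = (TP + TN) / total
* MCC          = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))
* PPV          = TP / (TP + FP)
* NPV          = TN / (TN + FN)

Degenerate denominators are flagged rather than hidden: an MCC with a zero
marginal is reported as 0.0 with the ``mcc_degenerate`` flag; a conditional
rate with no observations (e.g. PPV with TP+FP = 0) is reported as NaN with
a flag.

Continuous estimates are assessed with Spearman's rank correlation
(average ranks for ties; large-sample t-approximation for the p-value, via
scipy).  ``discordance`` lists the variants on which exactly one of two
call sets is correct — the variant-level audit of where an
endophenotype-based predictor and a direct classifier disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ContractError, JoinError, SchemaError, UndefinedCorrelationError
from .pathogenicity import PATHOGENIC, BENIGN, UNKNOWN, PathogenicityCall


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts, with unknown calls tallied separately."""

    tp: int
    fp: int
    tn: int
    fn: int
    excluded_unknown: int = 0

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn", "excluded_unknown"):
            if getattr(self, name) < 0:
                raise SchemaError(f"confusion count {name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceReport:
    """The six binary metrics plus the underlying counts and degeneracy flags."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    ppv: float
    npv: float
    counts: ConfusionCounts
    flags: tuple = ()

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "ppv": self.ppv,
            "npv": self.npv,
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
                "excluded_unknown": self.counts.excluded_unknown,
            },
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class RegressionPerformance:
    """Spearman rank correlation between observed and predicted scores."""

    spearman_rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class DiscordanceRecord:
    """A variant on which exactly one of two methods is correct."""

    key: tuple
    estimate: Optional[float]
    truth: str
    call_a: str
    call_b: str
    category: str  # "a-only-correct" | "b-only-correct"


def _as_call_map(calls) -> dict:
    if isinstance(calls, Mapping):
        return dict(calls)
    out = {}
    for c in calls:
        if isinstance(c, PathogenicityCall):
            out[c.key] = c.call
        else:
            key, call = c
            out[key] = call
    return out


def confusion(calls, truth: Mapping) -> ConfusionCounts:
    """Tally calls against binary truth labels (pathogenic = positive class).

    ``calls`` is a list of :class:`PathogenicityCall` (or a mapping
    key -> call); ``truth`` maps every non-unknown-called variant to
    "pathogenic" or "benign".  Unknown calls go to ``excluded_unknown``.
    """
    call_map = _as_call_map(calls)
    tp = fp = tn = fn = unknown = 0
    for key, call in call_map.items():
        if call == UNKNOWN:
            unknown += 1
            continue
        if key not in truth:
            raise JoinError(f"no truth label for variant {key!r}")
        label = truth[key]
        if label not in (PATHOGENIC, BENIGN):
            raise SchemaError(f"truth label for {key!r} must be binary, got {label!r}")
        if call == PATHOGENIC:
            if label == PATHOGENIC:
                tp += 1
            else:
                fp += 1
        elif call == BENIGN:
            if label == BENIGN:
                tn += 1
            else:
                fn += 1
        else:
            raise SchemaError(f"unrecognised call {call!r} for variant {key!r}")
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, excluded_unknown=unknown)


def metrics(counts: ConfusionCounts) -> PerformanceReport:
    """The six standard metrics of a confusion table, with degeneracy flags."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total < 1:
        raise SchemaError("cannot compute metrics on an empty confusion table")
    flags = []

    def rate(num: int, den: int, flag: str) -> float:
        if den == 0:
            flags.append(flag)
            return float("nan")
        return num / den

    sensitivity = rate(tp, tp + fn, "sensitivity_undefined")
    specificity = rate(tn, tn + fp, "specificity_undefined")
    accuracy = (tp + tn) / counts.total
    ppv = rate(tp, tp + fp, "ppv_undefined")
    npv = rate(tn, tn + fn, "npv_undefined")
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if denom == 0:
        flags.append("mcc_degenerate")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return PerformanceReport(
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        mcc=mcc,
        ppv=ppv,
        npv=npv,
        counts=counts,
        flags=tuple(flags),
    )


def spearman(observed: Sequence[float], predicted: Sequence[float]) -> RegressionPerformance:
    """Spearman rank correlation (average ranks for ties, t-approx p-value)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ContractError(
            f"observed and predicted must be equal-length 1-D, got "
            f"{observed.shape} vs {predicted.shape}"
        )
    n = observed.size
    if n < 3:
        raise ContractError(f"Spearman correlation needs n >= 3, got {n}")
    if not (np.all(np.isfinite(observed)) and np.all(np.isfinite(predicted))):
        raise ContractError("observed and predicted scores must be finite")
    if np.all(observed == observed[0]) or np.all(predicted == predicted[0]):
        raise UndefinedCorrelationError(
            "rank correlation undefined: one input has zero variance"
        )
    rho, p = stats.spearmanr(observed, predicted)
    return RegressionPerformance(spearman_rho=float(rho), p_value=float(p), n=n)


def discordance(
    calls_a,
    calls_b,
    truth: Mapping,
    estimates: Optional[Mapping] = None,
) -> list:
    """Variants on which exactly one of the two call sets is correct.

    Unknown calls on either side exclude the variant.  ``estimates``
    optionally carries the continuous endophenotype estimate for the audit.
    """
    map_a = _as_call_map(calls_a)
    map_b = _as_call_map(calls_b)
    if set(map_a) != set(map_b):
        raise JoinError("call sets must cover the same variants")
    records = []
    for key in map_a:
        a, b = map_a[key], map_b[key]
        if a == UNKNOWN or b == UNKNOWN:
            continue
        if key not in truth:
            raise JoinError(f"no truth label for variant {key!r}")
        label = truth[key]
        a_ok, b_ok = a == label, b == label
        if a_ok == b_ok:
            continue
        records.append(
            DiscordanceRecord(
                key=key,
                estimate=None if estimates is None else estimates.get(key),
                truth=label,
                call_a=a,
                call_b=b,
                category="a-only-correct" if a_ok else "b-only-correct",
            )
        )
    return records
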