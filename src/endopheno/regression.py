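"""Endophenotype regression: MLR, Ridge, Lasso, ElasticNet, RBF kernel ridge.

A fitted model maps a variant's feature vector to a continuous estimate of a
functional-assay score.  Five model families are supported:

========== ============================ =========================
kind        estimator                    tuned hyperparameters
========== ============================ =========================
mlr         ordinary least squares       (none)
ridge       L2-penalised least squares   alpha in [0.05, 100]
lasso       L1-penalised least squares   alpha in [0.05, 5]
elastic     L1+L2 penalty                alpha in [0.05, 5], l1_ratio in [0.1, 1]
kernel_rbf  kernel ridge, RBF kernel     alpha in [0.01, 5], gamma in [0.1, 10]
========== ============================ =========================

Tuning minimises cross-validated mean squared error over a fixed grid
(20 log-spaced alpha points; 10 evenly spaced l1_ratio/gamma points) —
leave-one-out CV for the penalised linear families, 3-fold CV for the kernel
family — on the training set only.  Ties are broken toward the largest alpha
(strongest regularisation), then the smallest gamma.

Penalised and kernel models operate on z-scored features with the scaler fit
on the training set; MLR uses raw features.  Fitted models are reduced to
plain arrays (coefficients / dual coefficients + scaler statistics), so
prediction is a deterministic numpy computation and models serialise to JSON.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import IO, Optional, Sequence, Union

import numpy as np
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import KFold, LeaveOneOut
from sklearn.preprocessing import StandardScaler

from .errors import ContractError, NoGridError, SchemaError, SingularDesignError, SizeError

MODEL_KINDS = ("mlr", "ridge", "lasso", "elastic", "kernel_rbf")
#: Families whose features are z-scored before fitting.
STANDARDIZED_KINDS = ("ridge", "lasso", "elastic", "kernel_rbf")

_N_ALPHA = 20
_N_SECONDARY = 10  # l1_ratio and gamma grid density


def default_grid(kind: str) -> dict:
    """The default hyperparameter grid for a model kind (sorted, in-bounds)."""
    if kind == "mlr":
        raise NoGridError("mlr has no hyperparameters to tune")
    if kind == "ridge":
        return {"alpha": np.geomspace(0.05, 100.0, _N_ALPHA)}
    if kind == "lasso":
        return {"alpha": np.geomspace(0.05, 5.0, _N_ALPHA)}
    if kind == "elastic":
        return {
            "alpha": np.geomspace(0.05, 5.0, _N_ALPHA),
            "l1_ratio": np.linspace(0.1, 1.0, _N_SECONDARY),
        }
    if kind == "kernel_rbf":
        return {
            "alpha": np.geomspace(0.01, 5.0, _N_ALPHA),
            "gamma": np.linspace(0.1, 10.0, _N_SECONDARY),
        }
    raise SchemaError(f"unknown model kind {kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: a model kind plus (optionally overridden) tuning grid."""

    kind: str
    grid: Optional[dict] = None  # None -> default_grid(kind)
    allow_rank_deficient: bool = False  # mlr: minimum-norm fallback instead of error

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise SchemaError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")
        if self.kind == "mlr" and self.grid:
            raise NoGridError("mlr takes no hyperparameter grid")

    def resolved_grid(self) -> Optional[dict]:
        if self.kind == "mlr":
            return None
        return self.grid if self.grid is not None else default_grid(self.kind)


@dataclass
class TuningResult:
    """Grid search record: every point evaluated, its CV score, the winner."""

    points: list  # list of dicts of hyperparameters, in evaluation order
    scores: list  # mean negative MSE per point
    selected: dict
    note: str = ""


@dataclass
class FittedEndophenotypeModel:
    """A trained regression reduced to arrays; predicts deterministically."""

    kind: str
    params: dict  # chosen hyperparameters ({} for mlr)
    n_features: int
    feature_set: Optional[str]  # "three" | "five" | None when untagged
    coef: Optional[np.ndarray] = None  # parametric kinds
    intercept: float = 0.0
    dual_coef: Optional[np.ndarray] = None  # kernel_rbf
    x_fit: Optional[np.ndarray] = None  # kernel_rbf: scaled training features
    scaler_mean: Optional[np.ndarray] = None
    scaler_scale: Optional[np.ndarray] = None
    n_train: int = 0
    seed: Optional[int] = None
    tuning: Optional[TuningResult] = None

    def _check_features(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x.reshape(1, -1)
        if x.shape[1] != self.n_features:
            raise ContractError(
                f"model expects {self.n_features} features, got {x.shape[1]}"
            )
        return x

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = self._check_features(x)
        if self.scaler_mean is not None:
            x = (x - self.scaler_mean) / self.scaler_scale
        if self.kind == "kernel_rbf":
            k = rbf_kernel(x, self.x_fit, gamma=self.params["gamma"])
            return k @ self.dual_coef
        return x @ self.coef + self.intercept

    # -- JSON persistence ----------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "kind": self.kind,
            "params": self.params,
            "n_features": self.n_features,
            "feature_set": self.feature_set,
            "coef": arr(self.coef),
            "intercept": self.intercept,
            "dual_coef": arr(self.dual_coef),
            "x_fit": arr(self.x_fit),
            "scaler_mean": arr(self.scaler_mean),
            "scaler_scale": arr(self.scaler_scale),
            "n_train": self.n_train,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedEndophenotypeModel":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        return cls(
            kind=d["kind"],
            params=dict(d["params"]),
            n_features=int(d["n_features"]),
            feature_set=d.get("feature_set"),
            coef=arr(d.get("coef")),
            intercept=float(d.get("intercept", 0.0)),
            dual_coef=arr(d.get("dual_coef")),
            x_fit=arr(d.get("x_fit")),
            scaler_mean=arr(d.get("scaler_mean")),
            scaler_scale=arr(d.get("scaler_scale")),
            n_train=int(d.get("n_train", 0)),
            seed=d.get("seed"),
        )


def save_model(model: FittedEndophenotypeModel, stream: Union[str, IO[str]], provenance: Optional[dict] = None) -> None:
    payload = model.to_dict()
    if provenance:
        payload["provenance"] = provenance
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    else:
        json.dump(payload, stream, indent=1, sort_keys=True)


def load_model(stream: Union[str, IO[str]]) -> FittedEndophenotypeModel:
    if isinstance(stream, str):
        with open(stream) as fh:
            payload = json.load(fh)
    else:
        payload = json.load(stream)
    return FittedEndophenotypeModel.from_dict(payload)


# ---------------------------------------------------------------------------
# Fitting


def _make_estimator(kind: str, params: dict):
    if kind == "ridge":
        return Ridge(alpha=params["alpha"])
    if kind == "lasso":
        return Lasso(alpha=params["alpha"], max_iter=50_000)
    if kind == "elastic":
        return ElasticNet(alpha=params["alpha"], l1_ratio=params["l1_ratio"], max_iter=50_000)
    if kind == "kernel_rbf":
        return KernelRidge(kernel="rbf", alpha=params["alpha"], gamma=params["gamma"])
    raise SchemaError(f"unknown tunable kind {kind!r}")


def _grid_points(grid: dict) -> list:
    """Cartesian product of a grid, in deterministic key-sorted order."""
    keys = sorted(grid)
    values = [np.atleast_1d(grid[k]) for k in keys]
    return [dict(zip(keys, combo)) for combo in itertools.product(*(v.tolist() for v in values))]


def _cv_splitter(kind: str, seed: int):
    if kind == "kernel_rbf":
        return KFold(n_splits=3, shuffle=True, random_state=seed)
    return LeaveOneOut()


def _cv_neg_mse(kind: str, params: dict, xs: np.ndarray, y: np.ndarray, cv) -> float:
    """Mean negative MSE of one grid point under the given splitter."""
    errors = []
    for train_idx, test_idx in cv.split(xs):
        est = _make_estimator(kind, params)
        est.fit(xs[train_idx], y[train_idx])
        resid = y[test_idx] - est.predict(xs[test_idx])
        errors.append(float(np.mean(resid**2)))
    return -float(np.mean(errors))


def _tune(
    kind: str, grid: dict, xs: np.ndarray, y: np.ndarray, seed: int
) -> TuningResult:
    cv = _cv_splitter(kind, seed)
    points = _grid_points(grid)
    scores = [_cv_neg_mse(kind, p, xs, y, cv) for p in points]
    # Maximise the CV score; break exact ties toward the largest alpha
    # (strongest regularisation), then the smallest gamma.
    def rank(i: int):
        p = points[i]
        return (scores[i], p.get("alpha", 0.0), -p.get("gamma", 0.0))

    best = max(range(len(points)), key=rank)
    note = ""
    ties = [i for i in range(len(points)) if scores[i] == scores[best] and i != best]
    if ties:
        note = f"{len(ties)} grid point(s) tied; kept largest alpha / smallest gamma"
    return TuningResult(points=points, scores=scores, selected=points[best], note=note)


def fit(
    spec: ModelSpec,
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    feature_set: Optional[str] = None,
) -> FittedEndophenotypeModel:
    """Fit a model (with nested hyperparameter tuning for tunable kinds).

    ``x`` is the (n, p) feature matrix, ``y`` the assay scores.  Tuning uses
    only the rows of ``x``/``y`` — never any test data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2:
        raise ContractError(f"feature matrix must be 2-D, got shape {x.shape}")
    n, p = x.shape
    if y.shape != (n,):
        raise ContractError(f"need one score per row: x has {n} rows, y has shape {y.shape}")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ContractError("features and scores must be finite")
    if spec.kind in ("mlr", "ridge", "lasso", "elastic") and n < p + 1:
        raise SizeError(f"{spec.kind} needs n >= p + 1 (= {p + 1}), got n = {n}")
    if spec.kind == "kernel_rbf" and n < 3:
        raise SizeError(f"kernel_rbf tuning needs n >= 3, got n = {n}")

    model = FittedEndophenotypeModel(
        kind=spec.kind,
        params={},
        n_features=p,
        feature_set=feature_set,
        n_train=n,
        seed=seed,
    )

    if spec.kind == "mlr":
        design = np.column_stack([np.ones(n), x])
        if np.linalg.matrix_rank(design) < p + 1 and not spec.allow_rank_deficient:
            raise SingularDesignError(
                "rank-deficient design matrix for MLR; pass allow_rank_deficient=True "
                "for the minimum-norm solution"
            )
        est = LinearRegression()
        est.fit(x, y)
        model.coef = np.asarray(est.coef_, dtype=float)
        model.intercept = float(est.intercept_)
        return model

    scaler = StandardScaler()
    xs = scaler.fit_transform(x)
    model.scaler_mean = np.asarray(scaler.mean_, dtype=float)
    model.scaler_scale = np.asarray(scaler.scale_, dtype=float)

    tuning = _tune(spec.kind, spec.resolved_grid(), xs, y, seed)
    model.tuning = tuning
    model.params = {k: float(v) for k, v in tuning.selected.items()}

    est = _make_estimator(spec.kind, model.params)
    est.fit(xs, y)
    if spec.kind == "kernel_rbf":
        model.dual_coef = np.asarray(est.dual_coef_, dtype=float).ravel()
        model.x_fit = np.asarray(est.X_fit_, dtype=float)
    else:
        model.coef = np.asarray(est.coef_, dtype=float)
        model.intercept = float(est.intercept_)
    return model


def predict(model: FittedEndophenotypeModel, x: np.ndarray) -> np.ndarray:
    """Apply a fitted model to feature vectors (one estimate per row)."""
    return model.predict(x)


def loocv(
    spec: ModelSpec, x: np.ndarray, y: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Leave-one-out estimates: the k-th value comes from a model fit (with
    nested tuning, for tunable kinds) on all records except the k-th."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise SizeError(f"LOOCV needs n >= 3, got n = {n}")
    out = np.empty(n)
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        fold_model = fit(spec, x[mask], y[mask], seed=seed)
        out[k] = float(fold_model.predict(x[k : k + 1])[0])
    return out
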