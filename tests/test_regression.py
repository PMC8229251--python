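"""Regression families: exact recovery, regularisation limits, tuning, LOOCV."""

import io

import numpy as np
import pytest

from endopheno.errors import (
    ContractError,
    NoGridError,
    SingularDesignError,
    SizeError,
)
from endopheno.regression import (
    FittedEndophenotypeModel,
    ModelSpec,
    default_grid,
    fit,
    load_model,
    loocv,
    predict,
    save_model,
)


def _linear_data(rng, n=40, p=3, beta=None, intercept=1.0, sigma=0.0):
    x = rng.normal(size=(n, p))
    if beta is None:
        beta = np.arange(1, p + 1, dtype=float)
    y = intercept + x @ beta + (sigma * rng.normal(size=n) if sigma else 0.0)
    return x, y, np.asarray(beta), intercept


# ---------------------------------------------------------------------------
# Grids


def test_default_grids_ranges_and_density():
    ridge = default_grid("ridge")["alpha"]
    assert ridge[0] == pytest.approx(0.05) and ridge[-1] == pytest.approx(100.0)
    assert len(ridge) == 20 and np.all(np.diff(ridge) > 0)
    lasso = default_grid("lasso")["alpha"]
    assert lasso[0] == pytest.approx(0.05) and lasso[-1] == pytest.approx(5.0)
    elastic = default_grid("elastic")
    assert elastic["l1_ratio"][0] == pytest.approx(0.1)
    assert elastic["l1_ratio"][-1] == pytest.approx(1.0)  # pure-lasso limit included
    kernel = default_grid("kernel_rbf")
    assert kernel["alpha"][0] == pytest.approx(0.01) and kernel["alpha"][-1] == pytest.approx(5.0)
    assert kernel["gamma"][0] == pytest.approx(0.1) and kernel["gamma"][-1] == pytest.approx(10.0)
    with pytest.raises(NoGridError):
        default_grid("mlr")


# ---------------------------------------------------------------------------
# Exact fits and limits


def test_mlr_recovers_noiseless_linear_system():
    rng = np.random.default_rng(0)
    x, y, beta, intercept = _linear_data(rng, n=30, p=2, beta=[2.0, -1.0], intercept=1.0)
    model = fit(ModelSpec("mlr"), x, y)
    assert model.coef == pytest.approx([2.0, -1.0], abs=1e-10)
    assert model.intercept == pytest.approx(1.0, abs=1e-10)
    assert model.predict(x) == pytest.approx(y, abs=1e-8)


def test_ridge_tiny_alpha_reproduces_mlr():
    rng = np.random.default_rng(1)
    x, y, *_ = _linear_data(rng, n=50, p=3, sigma=0.3)
    mlr = fit(ModelSpec("mlr"), x, y)
    ridge = fit(ModelSpec("ridge", grid={"alpha": np.array([1e-6])}), x, y)
    assert ridge.predict(x) == pytest.approx(mlr.predict(x), abs=1e-4)


def test_lasso_huge_alpha_predicts_training_mean():
    rng = np.random.default_rng(2)
    x, y, *_ = _linear_data(rng, n=40, p=3, sigma=0.5)
    lasso = fit(ModelSpec("lasso", grid={"alpha": np.array([1e6])}), x, y)
    assert np.allclose(lasso.coef, 0.0)
    assert lasso.predict(x) == pytest.approx(np.full_like(y, y.mean()), abs=1e-8)


def test_elastic_l1_ratio_one_equals_lasso():
    rng = np.random.default_rng(3)
    x, y, *_ = _linear_data(rng, n=60, p=4, sigma=0.4)
    alpha = 0.3
    lasso = fit(ModelSpec("lasso", grid={"alpha": np.array([alpha])}), x, y)
    elastic = fit(
        ModelSpec("elastic", grid={"alpha": np.array([alpha]), "l1_ratio": np.array([1.0])}),
        x,
        y,
    )
    probe = rng.normal(size=(20, 4))
    assert elastic.predict(probe) == pytest.approx(lasso.predict(probe), abs=1e-8)


def test_mlr_rank_deficiency_raises_with_optional_fallback():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(20, 2))
    x = np.column_stack([x, x[:, 0] + x[:, 1]])  # exact collinearity
    y = x[:, 0] - x[:, 1]
    with pytest.raises(SingularDesignError):
        fit(ModelSpec("mlr"), x, y)
    model = fit(ModelSpec("mlr", allow_rank_deficient=True), x, y)
    assert model.predict(x) == pytest.approx(y, abs=1e-8)


def test_too_few_rows_rejected():
    with pytest.raises(SizeError):
        fit(ModelSpec("mlr"), np.ones((3, 5)), np.ones(3))


# ---------------------------------------------------------------------------
# Prediction contract


def test_predict_is_coefficient_dot_product():
    rng = np.random.default_rng(5)
    x, y, *_ = _linear_data(rng, n=50, p=3, sigma=0.2)
    for kind, grid in [
        ("mlr", None),
        ("ridge", {"alpha": np.array([0.7])}),
        ("lasso", {"alpha": np.array([0.1])}),
    ]:
        model = fit(ModelSpec(kind, grid=grid), x, y)
        probe = rng.normal(size=(10, 3))
        xs = probe if model.scaler_mean is None else (probe - model.scaler_mean) / model.scaler_scale
        by_hand = xs @ model.coef + model.intercept
        assert predict(model, probe) == pytest.approx(by_hand, abs=1e-12)


def test_predict_permutation_equivariance_and_feature_check():
    rng = np.random.default_rng(6)
    x, y, *_ = _linear_data(rng, n=30, p=3)
    model = fit(ModelSpec("mlr"), x, y)
    probe = rng.normal(size=(8, 3))
    order = rng.permutation(8)
    assert predict(model, probe[order]) == pytest.approx(predict(model, probe)[order])
    with pytest.raises(ContractError):
        predict(model, np.ones((4, 5)))


def test_kernel_model_predicts_like_sklearn():
    """Dual-route check: our array-based predictor vs a direct sklearn fit."""
    from sklearn.kernel_ridge import KernelRidge
    from sklearn.preprocessing import StandardScaler

    rng = np.random.default_rng(7)
    x, y, *_ = _linear_data(rng, n=40, p=3, sigma=0.3)
    model = fit(
        ModelSpec("kernel_rbf", grid={"alpha": np.array([0.5]), "gamma": np.array([0.8])}),
        x,
        y,
    )
    scaler = StandardScaler().fit(x)
    ref = KernelRidge(kernel="rbf", alpha=0.5, gamma=0.8).fit(scaler.transform(x), y)
    probe = rng.normal(size=(12, 3))
    assert model.predict(probe) == pytest.approx(
        ref.predict(scaler.transform(probe)), abs=1e-10
    )


# ---------------------------------------------------------------------------
# Tuning


def test_tuning_selects_low_alpha_on_clean_linear_data():
    rng = np.random.default_rng(8)
    x, y, *_ = _linear_data(rng, n=60, p=3, sigma=0.1)
    model = fit(ModelSpec("ridge"), x, y, seed=0)
    assert model.params["alpha"] <= 1.0  # strong signal -> weak shrinkage wins
    assert model.tuning is not None
    assert len(model.tuning.points) == 20
    best = max(model.tuning.scores)
    assert model.tuning.scores[model.tuning.points.index(model.tuning.selected)] == best


def test_tuning_tie_break_prefers_largest_alpha():
    # Pure-noise target: grid points with identical CV score are possible only
    # in contrived settings, so check the rule directly on a constant target,
    # where every alpha yields the same (perfect) score.
    x = np.arange(24, dtype=float).reshape(12, 2)
    y = np.full(12, 3.0)
    model = fit(ModelSpec("ridge", grid={"alpha": np.array([0.1, 1.0, 10.0])}), x, y)
    assert model.params["alpha"] == 10.0


def test_tuning_ignores_anything_outside_training_rows():
    """Leakage guard: tuning output depends only on the rows passed in."""
    rng = np.random.default_rng(9)
    x, y, *_ = _linear_data(rng, n=40, p=3, sigma=0.5)
    model_a = fit(ModelSpec("ridge"), x, y, seed=1)
    # "poison" extra data that a leaky implementation might touch
    x_poison = np.vstack([x, 1e6 * np.ones((10, 3))])
    y_poison = np.concatenate([y, -1e6 * np.ones(10)])
    model_b = fit(ModelSpec("ridge"), x_poison[:40], y_poison[:40], seed=1)
    assert model_a.params == model_b.params
    assert model_a.coef == pytest.approx(model_b.coef, abs=1e-12)


# ---------------------------------------------------------------------------
# LOOCV


def test_loocv_exact_on_noiseless_linear_data():
    rng = np.random.default_rng(10)
    x, y, *_ = _linear_data(rng, n=5, p=2)
    est = loocv(ModelSpec("mlr"), x, y)
    assert est == pytest.approx(y, abs=1e-8)


def test_loocv_folds_are_independent_for_mlr():
    """Removing one variant leaves other folds' estimates unchanged."""
    rng = np.random.default_rng(11)
    x, y, *_ = _linear_data(rng, n=12, p=2, sigma=0.3)
    full = loocv(ModelSpec("mlr"), x, y)
    # Drop record 5, rerun; folds that exclude both 5 and k must not change --
    # for MLR each fold estimate depends only on the other n-1 records, so
    # refitting on the reduced data reproduces fold k when record 5 was not
    # in fold k's training set, i.e. never. Instead check fold 5's estimate:
    # a model fit on all records except 5 must equal the LOOCV entry.
    mask = np.ones(12, dtype=bool)
    mask[5] = False
    manual = fit(ModelSpec("mlr"), x[mask], y[mask]).predict(x[5:6])[0]
    assert full[5] == pytest.approx(manual, abs=1e-10)


def test_loocv_reproducible_per_seed():
    rng = np.random.default_rng(12)
    x, y, *_ = _linear_data(rng, n=15, p=3, sigma=0.4)
    a = loocv(ModelSpec("ridge", grid={"alpha": np.geomspace(0.1, 10, 4)}), x, y, seed=3)
    b = loocv(ModelSpec("ridge", grid={"alpha": np.geomspace(0.1, 10, 4)}), x, y, seed=3)
    assert np.array_equal(a, b)


def test_loocv_needs_three_records():
    with pytest.raises(SizeError):
        loocv(ModelSpec("mlr"), np.ones((2, 1)), np.ones(2))


# ---------------------------------------------------------------------------
# Persistence


@pytest.mark.parametrize("kind,grid", [
    ("mlr", None),
    ("ridge", {"alpha": np.array([0.5])}),
    ("kernel_rbf", {"alpha": np.array([0.3]), "gamma": np.array([1.2])}),
])
def test_model_json_roundtrip(kind, grid, tmp_path):
    rng = np.random.default_rng(13)
    x, y, *_ = _linear_data(rng, n=30, p=3, sigma=0.2)
    model = fit(ModelSpec(kind, grid=grid), x, y, seed=7, feature_set="three")
    path = tmp_path / "model.json"
    save_model(model, str(path))
    again = load_model(str(path))
    probe = rng.normal(size=(9, 3))
    assert again.kind == kind and again.feature_set == "three"
    assert again.predict(probe) == pytest.approx(model.predict(probe), abs=1e-12)
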