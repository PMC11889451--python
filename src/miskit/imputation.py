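"""Imputation suite: simple statistics, KNN, round-robin iterative, and MICE.

The iterative engine initializes missing cells with column means and then
cycles over incomplete features (most complete first, by default): each is
regressed on all other features using the rows where it is observed, and its
missing cells are replaced by predictions. Rounds stop when the largest
imputed-cell change falls below ``tol`` times the column's observed standard
deviation, or at ``max_iter``. Learners are pluggable: ordinary least
squares, cross-validated lasso, random forest, and gradient boosting
(XGBoost when installed, scikit-learn's gradient boosting otherwise).

MICE runs the same engine m times with prediction noise drawn from each
regression's residual distribution, yielding m completed datasets that are
pooled with Rubin's rules: for a scalar estimated in each draw,
total variance = within + (1 + 1/m) * between.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .data_model import DataMatrix
from .exceptions import UnusableFeatureError, ValidationError

LEARNERS = ("linear", "lasso_cv", "random_forest", "gradient_boosting")


@dataclass
class ImputationResult:
    """A completed matrix plus the mask of cells that were filled."""

    completed: np.ndarray
    imputed_mask: np.ndarray
    method: str
    n_iterations: Optional[int] = None
    converged: Optional[bool] = None
    notes: dict = field(default_factory=dict)

    def to_data_matrix(self, data: DataMatrix) -> DataMatrix:
        return DataMatrix(
            self.completed.copy(),
            list(data.feature_names),
            list(data.sample_ids),
            None if data.outcome is None else data.outcome.copy(),
        )


@dataclass
class MultipleImputationResult:
    """m completed datasets with Rubin pooling components."""

    draws: list[ImputationResult]
    pooled_mean: np.ndarray  # per-feature pooled mean estimate
    within_variance: np.ndarray  # per-feature mean of squared SEs
    between_variance: np.ndarray  # per-feature variance across draws
    method: str

    @property
    def m(self) -> int:
        return len(self.draws)

    @property
    def total_variance(self) -> np.ndarray:
        return self.within_variance + (1.0 + 1.0 / self.m) * self.between_variance


def _require_usable(data: DataMatrix) -> None:
    bad = data.all_missing_features()
    if bad:
        raise UnusableFeatureError(f"features with no observed values: {bad}")


def impute_simple(data: DataMatrix, statistic: str = "mean") -> ImputationResult:
    """Fill each missing cell with a per-column statistic.

    ``most_frequent`` breaks ties toward the smallest value.
    """
    _require_usable(data)
    X = data.values.copy()
    mask = data.mask
    for j in range(data.p):
        obs = X[~mask[:, j], j]
        if statistic == "mean":
            fill = float(obs.mean())
        elif statistic == "median":
            fill = float(np.median(obs))
        elif statistic == "most_frequent":
            vals, counts = np.unique(obs, return_counts=True)
            fill = float(vals[np.argmax(counts)])  # unique is sorted: ties -> smallest
        else:
            raise ValidationError(f"unknown statistic {statistic!r}")
        X[mask[:, j], j] = fill
    return ImputationResult(X, mask.copy(), f"simple({statistic})")


def impute_knn(data: DataMatrix, k: int = 5, weighting: str = "uniform") -> ImputationResult:
    """K-nearest-neighbour imputation with the nan-Euclidean distance.

    Row distances are Euclidean over mutually observed coordinates, rescaled
    by the proportion of coordinates used; each missing cell becomes the
    (distance-)weighted mean of the k nearest donors that observe the target
    column, falling back to the column mean when no donor exists.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if weighting not in ("uniform", "distance"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    _require_usable(data)
    from sklearn.impute import KNNImputer

    imputer = KNNImputer(n_neighbors=k, weights=weighting)
    completed = imputer.fit_transform(data.values)
    if completed.shape != data.values.shape:  # pragma: no cover - all-NaN guard above
        raise UnusableFeatureError("KNN imputer dropped a column")
    return ImputationResult(completed, data.mask.copy(), f"knn(k={k},{weighting})")


def _make_learner(name: str, seed: int):
    if name == "linear":
        from sklearn.linear_model import LinearRegression

        return LinearRegression()
    if name == "lasso_cv":
        from sklearn.linear_model import LassoCV

        return LassoCV(cv=5, random_state=seed, max_iter=2000)
    if name == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(n_estimators=50, random_state=seed, n_jobs=1)
    if name == "gradient_boosting":
        try:
            from xgboost import XGBRegressor

            return XGBRegressor(
                n_estimators=100,
                objective="reg:squarederror",
                random_state=seed,
                n_jobs=1,
                verbosity=0,
            )
        except ImportError:
            from sklearn.ensemble import GradientBoostingRegressor

            return GradientBoostingRegressor(random_state=seed)
    raise ValidationError(f"unknown learner {name!r}; choose one of {LEARNERS}")


def _round_robin(
    data: DataMatrix,
    learner: str,
    max_iter: int,
    tol: float,
    seed: int,
    order: str,
    rng: Optional[np.random.Generator] = None,
):
    """Shared round-robin core. When ``rng`` is given, predictions for missing
    cells are perturbed with Gaussian noise scaled by the training residual
    standard deviation (the stochastic variant used by MICE)."""
    if data.p < 2:
        raise ValidationError("iterative imputation needs at least 2 features")
    _require_usable(data)
    X = data.values.copy()
    mask = data.mask
    col_means = np.nanmean(data.values, axis=0)
    fill_idx = np.where(mask)
    X[fill_idx] = np.take(col_means, fill_idx[1])

    incomplete = np.flatnonzero(mask.any(axis=0))
    if order == "ascending":
        incomplete = incomplete[np.argsort(mask[:, incomplete].sum(axis=0), kind="stable")]
    elif order != "as_is":
        raise ValidationError(f"unknown visitation order {order!r}")

    col_scale = np.array(
        [
            max(np.std(data.values[~mask[:, j], j]), 1e-12)
            for j in range(data.p)
        ]
    )
    converged = False
    rounds = 0
    for rounds in range(1, max_iter + 1):
        max_rel_change = 0.0
        for j in incomplete:
            miss = mask[:, j]
            others = np.delete(X, j, axis=1)
            model = _make_learner(learner, seed + 31 * int(j))
            try:
                model.fit(others[~miss], X[~miss, j])
                pred = model.predict(others[miss])
                if rng is not None:
                    resid = X[~miss, j] - model.predict(others[~miss])
                    s = float(np.sqrt(np.mean(resid**2)))
                    pred = pred + rng.normal(0.0, s, size=pred.size)
            except Exception as exc:  # keep the round going on a single failure
                warnings.warn(
                    f"learner {learner!r} failed on feature "
                    f"{data.feature_names[j]!r}: {exc}; keeping current fill"
                )
                continue
            change = np.abs(pred - X[miss, j]).max(initial=0.0)
            max_rel_change = max(max_rel_change, change / col_scale[j])
            X[miss, j] = pred
        if max_rel_change < tol:
            converged = True
            break
    return X, mask.copy(), rounds, converged


def impute_iterative(
    data: DataMatrix,
    learner: str = "linear",
    max_iter: int = 10,
    tol: float = 1e-3,
    seed: int = 42,
    order: str = "ascending",
) -> ImputationResult:
    """Round-robin iterative imputation with a pluggable regressor."""
    X, mask, rounds, converged = _round_robin(
        data, learner, max_iter, tol, seed, order, rng=None
    )
    return ImputationResult(
        X, mask, f"iterative({learner})", n_iterations=rounds, converged=converged
    )


def impute_mice(
    data: DataMatrix,
    m: int = 5,
    learner: str = "linear",
    max_iter: int = 10,
    tol: float = 1e-3,
    seed: int = 42,
) -> MultipleImputationResult:
    """Multiple imputation by chained equations with Rubin pooling.

    Each of the m draws is an independent stochastic round-robin run (noise
    from the learner's training residuals, distinct sub-seed per draw). The
    pooled per-feature mean and its Rubin variance components are attached;
    :func:`pool_scalar` pools any other per-draw scalar.
    """
    if m < 2:
        raise ValidationError("MICE needs m >= 2 imputations")
    seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31 - 1)
    draws = []
    for d in range(m):
        sub = int(seeds[d])
        rng = np.random.default_rng(sub)
        X, mask, rounds, converged = _round_robin(
            data, learner, max_iter, tol, sub, "ascending", rng=rng
        )
        draws.append(
            ImputationResult(
                X,
                mask,
                f"mice(draw={d},{learner})",
                n_iterations=rounds,
                converged=converged,
            )
        )
    est = np.stack([dr.completed.mean(axis=0) for dr in draws])  # m x p
    sem2 = np.stack(
        [dr.completed.var(axis=0, ddof=1) / data.n for dr in draws]
    )
    pooled, within, between = pool_scalar(est, sem2)
    return MultipleImputationResult(draws, pooled, within, between, f"mice(m={m},{learner})")


def pool_scalar(estimates: np.ndarray, variances: np.ndarray):
    """Rubin's rules for m repeated estimates (rows) of scalar quantities.

    Returns (pooled estimate, within-imputation variance, between-imputation
    variance); total variance is within + (1 + 1/m) * between.
    """
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    variances = np.atleast_2d(np.asarray(variances, dtype=float))
    pooled = estimates.mean(axis=0)
    within = variances.mean(axis=0)
    between = estimates.var(axis=0, ddof=1)
    return pooled, within, between


# ---------------------------------------------------------------------------
# Method registry used by the comparison protocol and the CLI

METHOD_ALIASES = {
    "mean": ("simple", {"statistic": "mean"}),
    "median": ("simple", {"statistic": "median"}),
    "most_frequent": ("simple", {"statistic": "most_frequent"}),
    "knn": ("knn", {}),
    "iterative": ("iterative", {"learner": "linear"}),
    "rf": ("iterative", {"learner": "random_forest"}),
    "random_forest": ("iterative", {"learner": "random_forest"}),
    "lasso": ("iterative", {"learner": "lasso_cv"}),
    "gboost": ("iterative", {"learner": "gradient_boosting"}),
    "xgboost": ("iterative", {"learner": "gradient_boosting"}),
    "mice": ("mice", {}),
}


def run_method(data: DataMatrix, descriptor, seed: int = 42) -> ImputationResult:
    """Run an imputation method given a name or (name, kwargs) descriptor.

    For MICE the first draw's completed matrix is returned (the full
    multiple-imputation object is available through :func:`impute_mice`).
    """
    if isinstance(descriptor, str):
        name, kwargs = descriptor, {}
    else:
        name, kwargs = descriptor
        kwargs = dict(kwargs)
    if name in METHOD_ALIASES:
        base, defaults = METHOD_ALIASES[name]
        kwargs = {**defaults, **kwargs}
    else:
        base = name
    if base == "simple":
        return impute_simple(data, **kwargs)
    if base == "knn":
        return impute_knn(data, **kwargs)
    if base == "iterative":
        return impute_iterative(data, seed=seed, **kwargs)
    if base == "mice":
        mi = impute_mice(data, seed=seed, **kwargs)
        first = mi.draws[0]
        return ImputationResult(
            first.completed,
            first.imputed_mask,
            mi.method,
            first.n_iterations,
            first.converged,
        )
    raise ValidationError(f"unknown imputation method {name!r}")
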