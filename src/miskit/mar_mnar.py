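"""Feature-wise MAR-vs-MNAR likelihood-ratio test and the combined workflow.

For each incompletely observed feature, build the indicator D (1 where the
feature is observed, 0 where missing) and fit two nested logistic models:

  MAR:   logit P(D=1) = b0 + b' (other features)
  MNAR:  logit P(D=1) = b0' + b1' (other features) + b2' (added regressor)

The added regressor is the outcome Y when one is present, otherwise the
feature itself with its missing cells filled by its observed column mean
(the feature is unobserved exactly where D=0, so some completion is required
to make the MNAR model computable — a structural limitation that is surfaced
in the report, not hidden). The likelihood-ratio statistic
2 (l_MNAR - l_MAR) is referred to chi-square(1); a significant result points
at MNAR, dependence of missingness on the value itself.

Why a *constant* fill and not a model-based one: if the missing cells are
filled by a regression on the other features — the features the MAR model
already conditions on — the added regressor differs from a linear function
of the MAR covariates only through the fitted model's in-sample residuals,
which are mean-zero and orthogonal to those covariates by construction. The
LRT signal then cancels to first order and the test has essentially no
power against self-dependent missingness. The constant fill keeps the
contrast between observed values and an uninformative placeholder, which
does carry a signal when the features are correlated. The price is that
missingness driven strongly by *other* correlated features can also move
this contrast (MAR data flagged as MNAR); MNAR is not point-identifiable
from observed data, and this test is a heuristic screen, not an oracle.
A ``self_fill="iterative"`` variant (one round-robin imputation pass)
is retained for comparison.

Both fits carry the same small ridge penalty so the compared likelihoods are
identically penalized and the statistic stays non-negative; predictors are
standardized internally. Missing cells of the *other* features are filled
with column means for the fit only — the data are never modified.

The combined workflow runs Little's MCAR test first and performs the
feature-wise LRTs only when MCAR is rejected (or when forced).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .data_model import DataMatrix
from .exceptions import NotApplicableError
from .mcar_test import MCARTestResult, little_mcar

RIDGE = 1e-4  # applied to both logistic fits so the LRT compares like with like
MIN_N = 20


@dataclass
class FeatureLRTResult:
    feature: str
    conclusion: str  # "mar" | "mnar" | "skipped"
    lrt_stat: Optional[float] = None
    p_value: Optional[float] = None
    p_adjusted: Optional[float] = None
    df_added: int = 1
    l_mar: Optional[float] = None
    l_mnar: Optional[float] = None
    added_regressor: Optional[str] = None  # "outcome_Y" | "self_feature_imputed"
    skip_reason: Optional[str] = None
    separation_flag: bool = False
    notes: dict = field(default_factory=dict)


@dataclass
class MechanismReport:
    little: MCARTestResult
    per_feature: list[FeatureLRTResult]
    alpha: float
    overall_comment: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "feature": r.feature,
                    "lrt_stat": r.lrt_stat,
                    "p_value": r.p_value,
                    "p_adjusted": r.p_adjusted,
                    "conclusion": r.conclusion,
                    "skip_reason": r.skip_reason,
                }
                for r in self.per_feature
            ]
        )


def _fit_logistic_ridge(X: np.ndarray, y: np.ndarray, ridge: float = RIDGE):
    """Maximize the ridge-penalized Bernoulli log-likelihood by Newton steps.

    Returns (beta, penalized_loglik, converged, separation_flag). The
    intercept is unpenalized. Step-halving guards each Newton step so the
    penalized objective never decreases.
    """
    n, k = X.shape
    Z = np.column_stack([np.ones(n), X])
    pen = np.full(k + 1, ridge)
    pen[0] = 0.0

    def objective(beta):
        eta = Z @ beta
        # log-likelihood of Bernoulli with logit link, numerically stable
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - float(pen @ (beta * beta))

    beta = np.zeros(k + 1)
    obj = objective(beta)
    converged = False
    for _ in range(100):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        grad = Z.T @ (y - mu) - 2.0 * pen * beta
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        hess = (Z * w[:, None]).T @ Z + 2.0 * np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            t *= 0.5
        beta, new_obj = cand, cand_obj
        if abs(new_obj - obj) <= 1e-10 * (abs(obj) + 1.0):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    separation = bool(np.abs(beta[1:]).max(initial=0.0) > 25.0)
    return beta, obj, converged, separation


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _mean_filled(values: np.ndarray) -> np.ndarray:
    filled = values.copy()
    means = np.nanmean(filled, axis=0)
    idx = np.where(np.isnan(filled))
    filled[idx] = np.take(means, idx[1])
    return filled


def feature_lrt(
    data: DataMatrix,
    feature: str,
    alpha: float = 0.05,
    seed: int = 0,
    self_fill: str = "mean",
) -> FeatureLRTResult:
    """MAR-vs-MNAR likelihood-ratio test for one feature's missingness.

    ``self_fill`` chooses how the self regressor's missing cells are filled
    when no outcome is present: ``"mean"`` (default; see module docstring)
    or ``"iterative"`` (one round-robin imputation pass; near-zero power
    against self-dependent missingness, kept for comparison).
    """
    j = data.feature_names.index(feature)
    col_mask = data.mask[:, j]
    result = FeatureLRTResult(feature=feature, conclusion="skipped")
    if not col_mask.any() or col_mask.all():
        result.skip_reason = (
            "feature is fully observed" if not col_mask.any() else "feature is fully missing"
        )
        return result
    if data.n < MIN_N:
        result.skip_reason = f"small sample (n={data.n} < {MIN_N})"
        return result
    if data.p < 2 and data.outcome is None:
        result.skip_reason = "single-feature dataset without an outcome"
        return result

    D = (~col_mask).astype(float)
    others = np.delete(data.values, j, axis=1)
    X_mar = _standardize(_mean_filled(others)) if others.shape[1] else np.empty((data.n, 0))

    if data.outcome is not None:
        added = data.outcome.astype(float)
        result.added_regressor = "outcome_Y"
    elif self_fill == "mean":
        added = data.values[:, j].copy()
        added[col_mask] = np.nanmean(data.values[:, j])
        result.added_regressor = "self_feature_mean_filled"
    elif self_fill == "iterative":
        from .imputation import impute_iterative

        completed = impute_iterative(
            data, learner="linear", max_iter=1, seed=seed
        ).completed
        added = completed[:, j]
        result.added_regressor = "self_feature_imputed"
    else:
        raise ValueError(f"unknown self_fill {self_fill!r}")
    added = _standardize(added[:, None]).ravel()

    _, l_mar, conv1, sep1 = _fit_logistic_ridge(X_mar, D)
    X_mnar = np.column_stack([X_mar, added])
    _, l_mnar, conv2, sep2 = _fit_logistic_ridge(X_mnar, D)

    lrt = max(0.0, 2.0 * (l_mnar - l_mar))
    p = float(stats.chi2.sf(lrt, 1))
    result.l_mar = l_mar
    result.l_mnar = l_mnar
    result.lrt_stat = lrt
    result.p_value = p
    result.df_added = 1
    result.separation_flag = sep1 or sep2
    result.conclusion = "mnar" if p <= alpha else "mar"
    result.notes["fit_converged"] = conv1 and conv2
    if result.added_regressor != "outcome_Y":
        result.notes["caveat"] = (
            "the self regressor uses filled values where the feature is "
            "missing; MNAR is not point-identifiable from observed data"
        )
    return result


def combined_test(
    data: DataMatrix,
    alpha: float = 0.05,
    force_featurewise: bool = False,
    seed: int = 0,
    adjust: str = "fdr_bh",
) -> MechanismReport:
    """Little's MCAR test, then feature-wise MAR/MNAR LRTs if MCAR is rejected.

    Per-feature conclusions use the raw p-value at ``alpha``;
    Benjamini-Hochberg adjusted p-values are reported alongside.
    """
    if not data.mask.any():
        raise NotApplicableError("dataset is complete: no mechanism to diagnose")
    little = little_mcar(data, alpha=alpha)
    per_feature: list[FeatureLRTResult] = []
    if little.conclusion == "mcar_rejected" or force_featurewise:
        for name, col in zip(data.feature_names, data.mask.T):
            if col.any():
                per_feature.append(feature_lrt(data, name, alpha=alpha, seed=seed))
        tested = [r for r in per_feature if r.p_value is not None]
        if tested:
            from statsmodels.stats.multitest import multipletests

            _, p_adj, _, _ = multipletests([r.p_value for r in tested], method=adjust)
            for r, pa in zip(tested, p_adj):
                r.p_adjusted = float(pa)

    counts = {
        "mar": sum(r.conclusion == "mar" for r in per_feature),
        "mnar": sum(r.conclusion == "mnar" for r in per_feature),
        "skipped": sum(r.conclusion == "skipped" for r in per_feature),
    }
    if little.conclusion == "mcar_not_rejected" and not force_featurewise:
        comment = (
            "Little's test does not reject MCAR "
            f"(chi2={little.chi2:.3f}, df={little.df}, p={little.p_value:.3g}); "
            "feature-wise MAR/MNAR tests not performed."
        )
    else:
        comment = (
            f"Little's test: {little.conclusion} (p={little.p_value:.3g}). "
            f"Feature-wise LRTs on {len(per_feature)} features: "
            f"{counts['mar']} MAR, {counts['mnar']} MNAR, {counts['skipped']} skipped."
        )
    return MechanismReport(little, per_feature, alpha, comment)
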