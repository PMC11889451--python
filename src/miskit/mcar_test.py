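"""EM estimation for incomplete multivariate-normal data and Little's MCAR test.

The EM algorithm alternates a conditional-expectation step — filling the
sufficient statistics of the missing block of each row from the conditional
normal given the observed block — with a closed-form maximization step for
the mean vector and covariance matrix. The observed-data log-likelihood is
monotone non-decreasing across iterations, which the implementation tracks.

Little's test then measures, pattern by pattern, how far the mean of each
missingness pattern's observed variables sits from the EM grand mean, in the
metric of the EM covariance:

    d^2 = sum_j  m_j (ybar_obs,j - mu_obs,j)' Sigma_obs,j^{-1} (ybar_obs,j - mu_obs,j)

which is asymptotically chi-square with df = sum_j p_j - p under MCAR, where
p_j counts the observed variables of pattern j. A Henze-Zirkler multivariate
normality check is run first; failure is recorded as a warning on the result
but never blocks the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .data_model import DataMatrix, MissingnessPattern, extract_patterns
from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    NotApplicableError,
    UnusableFeatureError,
)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MVNEstimate:
    """EM-fitted mean and covariance with convergence metadata."""

    mu: np.ndarray
    sigma: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    tol_used: float
    loglik_history: list[float] = field(default_factory=list)


@dataclass
class PatternContribution:
    signature: tuple[bool, ...]
    count: int
    n_observed: int
    contribution: float
    included: bool


@dataclass
class MCARTestResult:
    """Little's chi-square test outcome with per-pattern decomposition."""

    chi2: float
    df: int
    p_value: float
    conclusion: str  # mcar_not_rejected | mcar_rejected | indeterminate
    pattern_contributions: list[PatternContribution]
    alpha: float
    normality_warning: Optional[str] = None
    comment: str = ""


def _solve_spd(a: np.ndarray, ridge_scale: float):
    """Cholesky factor of ``a``, adding a ridge only if factorization fails."""
    try:
        return np.linalg.cholesky(a), False
    except np.linalg.LinAlgError:
        bumped = a + ridge_scale * np.eye(a.shape[0])
        return np.linalg.cholesky(bumped), True


def _pattern_groups(data: DataMatrix):
    mask = data.mask
    return extract_patterns(mask)


def em_fit(
    data: DataMatrix,
    tol: float = 1e-6,
    max_iter: int = 200,
    ridge: Optional[float] = None,
) -> MVNEstimate:
    """Fit mean and covariance of a multivariate normal by EM on incomplete rows.

    Initialization is deterministic: observed column means and a diagonal of
    observed column variances. Iteration stops when the relative change of
    the observed-data log-likelihood drops below ``tol`` or after
    ``max_iter`` iterations (then ``converged=False``, never an exception).
    ``ridge`` (default ``1e-6 * trace(sigma)/p``) is added to an observed
    block only when its Cholesky factorization fails.
    """
    X = data.values
    n, p = X.shape
    obs_counts = (~data.mask).sum(axis=0)
    if (obs_counts == 0).any():
        bad = [data.feature_names[j] for j in np.flatnonzero(obs_counts == 0)]
        raise UnusableFeatureError(
            f"features with zero observed values cannot enter EM: {bad}"
        )
    if n <= p:
        import warnings

        warnings.warn(f"EM with n={n} <= p={p}: covariance may be ill-conditioned")

    mu = np.nanmean(X, axis=0)
    var0 = np.nanvar(X, axis=0)
    var0[var0 == 0] = 1.0
    sigma = np.diag(var0)

    patterns = _pattern_groups(data)
    groups = []
    for q in patterns:
        o = np.array(q.observed_idx, dtype=int)
        m = np.array(sorted(set(range(p)) - set(q.observed_idx)), dtype=int)
        rows = np.array(q.row_indices, dtype=int)
        groups.append((o, m, X[rows][:, o] if o.size else np.empty((rows.size, 0))))

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ridge_scale = (
            ridge if ridge is not None else 1e-6 * float(np.trace(sigma)) / p
        )
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        loglik = 0.0
        for o, m, Xo in groups:
            k = Xo.shape[0]
            if o.size == 0:
                # nothing observed: E-step fills from the marginal
                s1 += k * mu
                s2 += k * (sigma + np.outer(mu, mu))
                continue
            S_oo = sigma[np.ix_(o, o)]
            L, _ = _solve_spd(S_oo, ridge_scale)
            dev = Xo - mu[o]
            z = np.linalg.solve(L, dev.T)  # p_o x k
            logdet = 2.0 * np.log(np.diag(L)).sum()
            loglik += -0.5 * (
                k * (o.size * _LOG2PI + logdet) + float((z * z).sum())
            )
            s1[o] += Xo.sum(axis=0)
            s2[np.ix_(o, o)] += Xo.T @ Xo
            if m.size:
                S_mo = sigma[np.ix_(m, o)]
                B = np.linalg.solve(L.T, np.linalg.solve(L, S_mo.T)).T  # m x o
                cond = sigma[np.ix_(m, m)] - B @ S_mo.T
                Xm = mu[m] + dev @ B.T
                s1[m] += Xm.sum(axis=0)
                s2[np.ix_(m, m)] += Xm.T @ Xm + k * cond
                cross = Xo.T @ Xm
                s2[np.ix_(o, m)] += cross
                s2[np.ix_(m, o)] += cross.T
        mu = s1 / n
        sigma = s2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        history.append(loglik)
        if len(history) >= 2:
            prev, cur = history[-2], history[-1]
            if abs(cur - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
    return MVNEstimate(mu, sigma, history[-1], it, converged, tol, history)


def little_mcar(
    data: DataMatrix,
    alpha: float = 0.05,
    min_pattern_size: int = 1,
    em_kwargs: Optional[dict] = None,
) -> MCARTestResult:
    """Little's MCAR test: chi-square on pattern-wise observed-mean deviations.

    Patterns with fewer than ``min_pattern_size`` rows, or with zero observed
    variables, are excluded from both the statistic and the degrees of
    freedom. The multivariate-normality gate (Henze-Zirkler on complete
    rows) is advisory: its failure is recorded in ``normality_warning``.
    """
    mask = data.mask
    if not mask.any():
        raise NotApplicableError("no missing cells: nothing to test")
    patterns = extract_patterns(mask)
    if len(patterns) < 2:
        raise NotApplicableError(
            "need at least two distinct missingness patterns to test MCAR"
        )

    normality_warning = None
    from .distribution_tests import henze_zirkler

    try:
        hz = henze_zirkler(data, alpha)
        if not hz.normal_at_alpha:
            normality_warning = (
                f"Henze-Zirkler rejects multivariate normality on complete rows "
                f"(HZ={hz.statistic:.4g}, p={hz.p_value:.3g}); Little's test "
                f"assumes multivariate normality — interpret with caution."
            )
    except (InsufficientDataError, DegenerateDataError) as exc:
        normality_warning = f"normality gate could not run: {exc}"

    est = em_fit(data, **(em_kwargs or {}))
    X = data.values
    ridge_scale = 1e-6 * float(np.trace(est.sigma)) / data.p

    chi2 = 0.0
    df = 0
    contributions: list[PatternContribution] = []
    any_included = False
    for q in patterns:
        o = np.array(q.observed_idx, dtype=int)
        include = q.count >= min_pattern_size and o.size > 0
        contrib = 0.0
        if include:
            rows = np.array(q.row_indices, dtype=int)
            ybar = X[rows][:, o].mean(axis=0)
            dev = ybar - est.mu[o]
            L, _ = _solve_spd(est.sigma[np.ix_(o, o)], ridge_scale)
            z = np.linalg.solve(L, dev)
            contrib = q.count * float(z @ z)
            chi2 += contrib
            df += o.size
            any_included = True
        contributions.append(
            PatternContribution(q.signature, q.count, q.n_observed, contrib, include)
        )
    df -= data.p

    if not any_included or df <= 0:
        return MCARTestResult(
            chi2=chi2,
            df=max(df, 0),
            p_value=float("nan"),
            conclusion="indeterminate",
            pattern_contributions=contributions,
            alpha=alpha,
            normality_warning=normality_warning,
            comment=(
                "degrees of freedom are non-positive after pattern exclusions; "
                "the chi-square reference distribution is undefined"
            ),
        )

    p_value = float(stats.chi2.sf(chi2, df))
    conclusion = "mcar_not_rejected" if p_value > alpha else "mcar_rejected"
    comment = (
        "observed pattern means are consistent with a common multivariate "
        "normal mean (MCAR not rejected)"
        if conclusion == "mcar_not_rejected"
        else "pattern-wise observed means deviate from the EM grand mean more "
        "than MCAR predicts"
    )
    return MCARTestResult(
        chi2=float(chi2),
        df=int(df),
        p_value=p_value,
        conclusion=conclusion,
        pattern_contributions=contributions,
        alpha=alpha,
        normality_warning=normality_warning,
        comment=comment,
    )
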