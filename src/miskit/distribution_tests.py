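"""Normality tests used ahead of the mechanism diagnosis.

Univariate: Shapiro-Wilk (W statistic from normal order-statistic weights)
and a one-sample Kolmogorov-Smirnov test against a normal with parameters
estimated from the sample. Multivariate: the Henze-Zirkler test on complete
rows, which gates (but never blocks) Little's MCAR test.

Because the KS test standardizes by the sample's own mean and standard
deviation, the classical Kolmogorov p-value is conservative (the Lilliefors
situation). The result therefore carries both the classical p-value and a
Lilliefors-corrected one; ``normal_at_alpha`` follows the classical p-value
and the caveat is flagged explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .data_model import DataMatrix
from .exceptions import DegenerateDataError, InsufficientDataError

SHAPIRO_MAX_N = 5000


@dataclass
class NormalityResult:
    """Outcome of a single normality test.

    ``statistic`` holds W (Shapiro-Wilk), D (Kolmogorov-Smirnov) or HZ
    (Henze-Zirkler). ``normal_at_alpha`` is True iff p_value > alpha.
    """

    test_name: str
    statistic: float
    p_value: float
    n_used: int
    alpha: float
    normal_at_alpha: bool
    notes: dict = field(default_factory=dict)


def _observed(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return x[~np.isnan(x)]


def shapiro_wilk(x, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk normality test on the observed values of ``x``.

    W is the squared correlation between the ordered sample and the expected
    normal order statistics; values near 1 are consistent with normality and
    smaller W indicates stronger departure.
    """
    obs = _observed(x)
    if obs.size < 3:
        raise InsufficientDataError(
            f"Shapiro-Wilk needs >= 3 observed values, got {obs.size}"
        )
    if np.ptp(obs) == 0:
        raise DegenerateDataError("Shapiro-Wilk W is undefined for a constant vector")
    notes = {}
    if obs.size > SHAPIRO_MAX_N:
        warnings.warn(
            f"Shapiro-Wilk p-value approximation degrades for n > {SHAPIRO_MAX_N}"
            f" (n={obs.size})",
            stacklevel=2,
        )
        notes["large_n_warning"] = True
    w, p = stats.shapiro(obs)
    return NormalityResult(
        "shapiro_wilk", float(w), float(p), int(obs.size), alpha, p > alpha, notes
    )


def ks_normal(x, alpha: float = 0.05) -> NormalityResult:
    """One-sample KS test of ``x`` against a normal fitted to ``x``.

    The sample is standardized by its own mean and standard deviation and
    D = sup |F_n - Phi| is evaluated at the jump points (both one-sided
    gaps). The p-value comes from the Kolmogorov distribution and is
    conservative because the parameters were estimated from the data; a
    Lilliefors-corrected p-value is reported alongside in ``notes``.
    """
    obs = _observed(x)
    if obs.size < 3:
        raise InsufficientDataError(
            f"KS test needs >= 3 observed values, got {obs.size}"
        )
    sd = obs.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("KS test undefined for a constant vector")
    z = (obs - obs.mean()) / sd
    d, p = stats.kstest(z, "norm")
    from statsmodels.stats.diagnostic import lilliefors

    _, p_lillie = lilliefors(obs, dist="norm")
    notes = {
        "lilliefors_caveat": (
            "normal parameters estimated from the sample; the classical "
            "Kolmogorov p-value is conservative"
        ),
        "p_lilliefors": float(p_lillie),
    }
    return NormalityResult(
        "kolmogorov_smirnov", float(d), float(p), int(obs.size), alpha, p > alpha, notes
    )


def ks_statistic_standard_normal(x) -> float:
    """D = sup |F_n(x) - Phi(x)| against the *standard* normal, no fitting.

    Internal helper exposed for verification; evaluates both one-sided gaps
    at every jump of the empirical CDF.
    """
    obs = np.sort(_observed(x))
    n = obs.size
    cdf = stats.norm.cdf(obs)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def henze_zirkler(data: DataMatrix, alpha: float = 0.05) -> NormalityResult:
    """Henze-Zirkler multivariate normality test on the complete rows.

    The statistic is a weighted L2 distance between the empirical and the
    normal characteristic function, with the standard smoothing-parameter
    choice and a log-normal approximation for the p-value. Runs on complete
    cases only so the check stays independent of the EM estimator it gates.
    """
    complete = data.values[~data.mask.any(axis=1)]
    n_complete, p = complete.shape
    if n_complete < p + 2:
        raise InsufficientDataError(
            f"Henze-Zirkler needs at least p+2={p + 2} complete rows, found "
            f"{n_complete}; proceed with a normality warning"
        )
    cov = np.cov(complete, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < p:
        raise DegenerateDataError(
            "covariance of complete rows is singular; Henze-Zirkler undefined"
        )
    import pingouin

    hz, pval, normal = pingouin.multivariate_normality(complete, alpha=alpha)
    return NormalityResult(
        "henze_zirkler",
        float(hz),
        float(pval),
        int(n_complete),
        alpha,
        bool(normal),
        {"complete_rows": int(n_complete)},
    )


def normality_table(data: DataMatrix, alpha: float = 0.05):
    """Per-feature Shapiro-Wilk and KS results as a plain table."""
    import pandas as pd

    rows = []
    for j, name in enumerate(data.feature_names):
        col = data.values[:, j]
        entry: dict = {"feature": name}
        try:
            sw = shapiro_wilk(col, alpha)
            entry.update(W=sw.statistic, sw_p=sw.p_value, sw_normal=sw.normal_at_alpha)
        except (InsufficientDataError, DegenerateDataError) as exc:
            entry.update(W=np.nan, sw_p=np.nan, sw_normal=None, sw_error=str(exc))
        try:
            ks = ks_normal(col, alpha)
            entry.update(D=ks.statistic, ks_p=ks.p_value, ks_normal=ks.normal_at_alpha)
        except (InsufficientDataError, DegenerateDataError) as exc:
            entry.update(D=np.nan, ks_p=np.nan, ks_normal=None, ks_error=str(exc))
        rows.append(entry)
    return pd.DataFrame(rows)
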