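"""Post-imputation quality checks and the mask-and-score method comparison.

Quality checks ask whether imputed values are plausible: do they stay inside
the observed range of their column, and does their distribution differ from
the observed one (two-sample Kolmogorov-Smirnov)?

The comparison protocol hides a random 10-20% of the *observed* cells
(pre-existing missing cells stay missing), re-imputes with each candidate
method, and scores every method on the identical probe set with RMSE and a
bias p-value (paired t-test on true-minus-imputed differences by default;
two-sample KS optionally). Methods are ranked by ascending RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data_model import DataMatrix
from .exceptions import ContractError, ValidationError
from .imputation import ImputationResult, run_method

MASK_FRACTION_BAND = (0.10, 0.20)


@dataclass
class FeatureQuality:
    feature: str
    observed_stats: dict
    imputed_stats: Optional[dict]
    range_violation_count: int
    distribution_test_p: Optional[float]  # None when < 3 imputed cells


@dataclass
class QualityReport:
    per_feature: list[FeatureQuality]
    overall_pass: bool
    alpha: float
    notes: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "feature": f.feature,
                    "n_imputed": 0 if f.imputed_stats is None else f.imputed_stats["n"],
                    "range_violations": f.range_violation_count,
                    "ks_p": f.distribution_test_p,
                }
                for f in self.per_feature
            ]
        )


@dataclass
class MethodScore:
    method: str
    rmse: Optional[float]
    bias_p_value: Optional[float]
    error: Optional[str] = None


@dataclass
class CompareReport:
    masked_cells: list[tuple[int, int]]
    mask_fraction: float
    per_method: list[MethodScore]
    ranking: list[str]
    seed: int
    bias_test: str

    def to_frame(self):
        import pandas as pd

        order = {m: r + 1 for r, m in enumerate(self.ranking)}
        return pd.DataFrame(
            [
                {
                    "method": s.method,
                    "rmse": s.rmse,
                    "bias_p_value": s.bias_p_value,
                    "rank": order.get(s.method),
                    "error": s.error,
                }
                for s in self.per_method
            ]
        )


def _summary_stats(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "min": float(x.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(x.max()),
    }


def rmse(true_vals, imputed_vals) -> float:
    """Root-mean-square error between paired vectors."""
    a = np.asarray(true_vals, dtype=float).ravel()
    b = np.asarray(imputed_vals, dtype=float).ravel()
    if a.size != b.size or a.size == 0:
        raise ContractError(
            f"rmse needs equal nonzero lengths, got {a.size} and {b.size}"
        )
    return float(np.sqrt(np.mean((a - b) ** 2)))


def assess_quality(
    original: DataMatrix, result: ImputationResult, alpha: float = 0.05
) -> QualityReport:
    """Plausibility checks of an imputation against the original data.

    A feature passes when its imputed cells stay inside the observed
    [min, max] and the two-sample KS test between observed and imputed
    values is not significant (needs >= 3 imputed cells to run).
    """
    if result.imputed_mask.shape != original.mask.shape or not np.array_equal(
        result.imputed_mask, original.mask
    ):
        raise ContractError("imputation result does not match the original's mask")
    reports = []
    overall = True
    for j, name in enumerate(original.feature_names):
        obs = original.values[~original.mask[:, j], j]
        imp = result.completed[original.mask[:, j], j]
        if imp.size == 0:
            reports.append(FeatureQuality(name, _summary_stats(obs), None, 0, None))
            continue
        violations = int(((imp < obs.min()) | (imp > obs.max())).sum())
        p = None
        if imp.size >= 3:
            p = float(stats.ks_2samp(obs, imp).pvalue)
            if p <= alpha:
                overall = False
        if violations > 0:
            overall = False
        reports.append(
            FeatureQuality(name, _summary_stats(obs), _summary_stats(imp), violations, p)
        )
    notes = (
        "all features: imputed cells inside observed range and no significant "
        "observed-vs-imputed distribution shift"
        if overall
        else "at least one feature shows range violations or a distribution shift"
    )
    return QualityReport(reports, overall, alpha, notes)


def sample_probe_mask(
    data: DataMatrix,
    mask_fraction: float,
    seed: int,
    min_observed_per_column: int = 2,
) -> list[tuple[int, int]]:
    """Uniformly sample observed cells to hide, keeping a per-column floor."""
    lo, hi = MASK_FRACTION_BAND
    if not (lo <= mask_fraction <= hi):
        raise ValidationError(
            f"mask_fraction must lie in [{lo:.2f}, {hi:.2f}] (got {mask_fraction})"
        )
    rng = np.random.default_rng(seed)
    obs_cells = np.argwhere(~data.mask)
    n_obs = len(obs_cells)
    # round to a whole cell count, then clamp so the realized fraction
    # cannot fall outside the band through rounding alone
    lo_count = int(np.ceil(lo * n_obs))
    hi_count = int(np.floor(hi * n_obs))
    target = min(max(int(round(mask_fraction * n_obs)), lo_count), hi_count)
    if target < 1 or lo_count > hi_count:
        raise ValidationError("dataset too small for the requested mask fraction")
    order = rng.permutation(n_obs)
    col_remaining = (~data.mask).sum(axis=0).astype(int)
    chosen: list[tuple[int, int]] = []
    for idx in order:
        i, j = map(int, obs_cells[idx])
        if col_remaining[j] <= min_observed_per_column:
            continue
        chosen.append((i, j))
        col_remaining[j] -= 1
        if len(chosen) == target:
            break
    if len(chosen) < target:
        raise ValidationError(
            "cannot mask the requested fraction while keeping "
            f">= {min_observed_per_column} observed values per column"
        )
    return chosen


def compare_methods(
    data: DataMatrix,
    methods: Sequence,
    mask_fraction: float = 0.15,
    seed: int = 42,
    alpha: float = 0.05,
    bias_test: str = "t",
) -> CompareReport:
    """Mask-and-score comparison of imputation methods on a shared probe set."""
    if bias_test not in ("t", "ks"):
        raise ValidationError("bias_test must be 't' or 'ks'")
    cells = sample_probe_mask(data, mask_fraction, seed)
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    truth = data.values[rows, cols]

    probe = data.copy()
    probe.values[rows, cols] = np.nan

    scores: list[MethodScore] = []
    for desc in methods:
        if callable(desc):
            label = getattr(desc, "__name__", "custom")
        else:
            label = desc if isinstance(desc, str) else f"{desc[0]}{desc[1]}"
        try:
            result = desc(probe, seed) if callable(desc) else run_method(
                probe, desc, seed=seed
            )
            imputed = result.completed[rows, cols]
            err = rmse(truth, imputed)
            if bias_test == "t":
                diffs = truth - imputed
                if np.allclose(diffs, diffs[0]):
                    p = 1.0 if abs(diffs[0]) < 1e-12 else 0.0
                else:
                    p = float(stats.ttest_rel(truth, imputed).pvalue)
            else:
                p = float(stats.ks_2samp(truth, imputed).pvalue)
            scores.append(MethodScore(result.method, err, p))
        except Exception as exc:
            scores.append(MethodScore(str(label), None, None, error=str(exc)))

    ranked = sorted(
        (s for s in scores if s.rmse is not None), key=lambda s: s.rmse
    )
    realized = len(cells) / int((~data.mask).sum())
    return CompareReport(
        masked_cells=cells,
        mask_fraction=realized,
        per_method=scores,
        ranking=[s.method for s in ranked],
        seed=seed,
        bias_test=bias_test,
    )
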