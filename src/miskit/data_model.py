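"""Core data representation: numeric table with an explicit missingness mask.

A :class:`DataMatrix` is an n x p float matrix in which missing entries are
stored as NaN. The boolean mask is always recomputed from the values, never
kept as separate mutable state, so the two can not drift apart. An optional
fully observed outcome vector ``Y`` may accompany the features.

The module also provides the missing-data bookkeeping used throughout the
toolkit: row-wise missingness patterns, per-feature / per-sample missing
percentages, and the correlation matrix of the missing indicators.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, ParseError, ValidationError

#: Tokens that denote a missing cell when reading CSV files. Case-sensitive
#: apart from the NaN spellings.
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "null"})


@dataclass
class DataMatrix:
    """Numeric sample x feature table with NaN-coded missing entries.

    Parameters
    ----------
    values
        n x p float array; missing cells are NaN.
    feature_names
        p unique column names.
    sample_ids
        n unique row identifiers; defaults to stringified row positions.
    outcome
        Optional length-n outcome vector Y. Must be fully observed.
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str] = field(default_factory=list)
    outcome: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValidationError("need at least one row and one column")
        self.feature_names = [str(c) for c in self.feature_names]
        if len(self.feature_names) != p:
            raise ValidationError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            raise ValidationError("feature names must be unique")
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(n)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n or len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids must be unique and of length n")
        if self.outcome is not None:
            self.outcome = np.asarray(self.outcome, dtype=float)
            if self.outcome.shape != (n,):
                raise ValidationError("outcome must have length n")
            if np.isnan(self.outcome).any():
                raise ValidationError("outcome Y may not contain missing values")

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean n x p matrix; True where the cell is missing."""
        return np.isnan(self.values)

    def copy(self) -> "DataMatrix":
        return DataMatrix(
            self.values.copy(),
            list(self.feature_names),
            list(self.sample_ids),
            None if self.outcome is None else self.outcome.copy(),
        )

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def all_missing_features(self) -> list[str]:
        """Names of features with no observed value (kept, but flagged)."""
        return [
            name
            for name, col in zip(self.feature_names, self.mask.T)
            if col.all()
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=self.feature_names, index=self.sample_ids
        )
        if self.outcome is not None:
            df["Y"] = self.outcome
        return df


@dataclass(frozen=True)
class MissingnessPattern:
    """One distinct row-wise observed/missing signature.

    ``signature[j]`` is True when feature j is *observed* in member rows.
    """

    signature: tuple[bool, ...]
    row_indices: tuple[int, ...]
    observed_idx: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.row_indices)

    @property
    def n_observed(self) -> int:
        return len(self.observed_idx)


@dataclass
class MissingSummary:
    """Missing-percentage summaries and the pattern table."""

    per_feature_pct: np.ndarray
    per_sample_pct: np.ndarray
    total_pct: float
    pattern_table: list[MissingnessPattern]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Export the summary as plain tables (for reports and plotting)."""
        pat = pd.DataFrame(
            {
                "signature": [
                    "".join("O" if s else "." for s in q.signature)
                    for q in self.pattern_table
                ],
                "count": [q.count for q in self.pattern_table],
                "n_observed_features": [q.n_observed for q in self.pattern_table],
            }
        )
        return {
            "per_feature_pct": pd.DataFrame({"missing_pct": self.per_feature_pct}),
            "per_sample_pct": pd.DataFrame({"missing_pct": self.per_sample_pct}),
            "patterns": pat,
        }


# ---------------------------------------------------------------------------
# CSV I/O


def read_csv(
    path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    outcome_col: Optional[str] = None,
    id_col: Optional[str] = None,
) -> DataMatrix:
    """Read a rectangular numeric CSV (header row required) into a DataMatrix.

    Cells whose stripped text equals one of ``missing_tokens`` become missing.
    Any other non-numeric cell raises :class:`ParseError` naming row and
    column. ``outcome_col`` is split off into the outcome vector Y.
    """
    tokens = set(missing_tokens)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = next(csv.reader(fh), None)
    if header is None:
        raise ParseError(f"{path}: empty file")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ParseError(f"{path}: duplicate column names {dupes}")

    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    raw.columns = header  # undo pandas' duplicate-name mangling guard
    sample_ids: list[str] = []
    if id_col is not None:
        if id_col not in header:
            raise ParseError(f"{path}: id column {id_col!r} not found")
        sample_ids = [s.strip() for s in raw[id_col]]
        raw = raw.drop(columns=[id_col])

    names = list(raw.columns)
    n = len(raw)
    vals = np.empty((n, len(names)), dtype=float)
    for j, name in enumerate(names):
        col = raw[name].to_numpy()
        for i, cell in enumerate(col):
            text = cell.strip()
            if text in tokens:
                vals[i, j] = np.nan
                continue
            try:
                v = float(text)
            except ValueError:
                raise ParseError(
                    f"{path}: cell at row {i + 1}, column {name!r} is not "
                    f"numeric and not a missing token: {cell!r}"
                ) from None
            if not np.isfinite(v):
                raise ParseError(
                    f"{path}: non-finite value at row {i + 1}, column {name!r}"
                )
            vals[i, j] = v

    outcome = None
    if outcome_col is not None:
        if outcome_col not in names:
            raise ParseError(f"{path}: outcome column {outcome_col!r} not found")
        j = names.index(outcome_col)
        outcome = vals[:, j]
        if np.isnan(outcome).any():
            raise ParseError(
                f"{path}: outcome column {outcome_col!r} contains missing values"
            )
        vals = np.delete(vals, j, axis=1)
        names = [c for c in names if c != outcome_col]
        if not names:
            raise ParseError(f"{path}: no feature columns besides the outcome")

    return DataMatrix(vals, names, sample_ids, outcome)


def write_csv(data: DataMatrix, path, missing_token: str = "") -> None:
    """Write a DataMatrix as CSV; missing cells become ``missing_token``.

    Uses shortest-repr float formatting so finite decimal inputs round-trip
    through :func:`read_csv` bit-for-bit.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        header = ["sample_id", *data.feature_names]
        if data.outcome is not None:
            header.append("Y")
        writer.writerow(header)
        for i in range(data.n):
            row: list[str] = [data.sample_ids[i]]
            for v in data.values[i]:
                row.append(missing_token if np.isnan(v) else repr(float(v)))
            if data.outcome is not None:
                row.append(repr(float(data.outcome[i])))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Missingness bookkeeping


def extract_patterns(mask: np.ndarray) -> list[MissingnessPattern]:
    """Partition rows by their observed/missing signature.

    Patterns are sorted by descending member count; ties are broken by the
    lexicographic order of the signature (observed=True sorts after missing).
    """
    observed = ~np.asarray(mask, dtype=bool)
    sigs, inverse = np.unique(observed, axis=0, return_inverse=True)
    patterns = []
    for k, sig in enumerate(sigs):
        rows = tuple(int(i) for i in np.flatnonzero(inverse == k))
        obs_idx = tuple(int(j) for j in np.flatnonzero(sig))
        patterns.append(
            MissingnessPattern(tuple(bool(s) for s in sig), rows, obs_idx)
        )
    patterns.sort(key=lambda q: (-q.count, q.signature))
    return patterns


def missing_summary(data: DataMatrix) -> MissingSummary:
    """Per-feature, per-sample and overall missing percentages + patterns."""
    mask = data.mask
    n, p = mask.shape
    return MissingSummary(
        per_feature_pct=100.0 * mask.mean(axis=0),
        per_sample_pct=100.0 * mask.mean(axis=1),
        total_pct=100.0 * float(mask.mean()),
        pattern_table=extract_patterns(mask),
    )


def pattern_correlation(data: DataMatrix) -> np.ndarray:
    """Pearson correlation between missing-indicator columns.

    Entry (j, k) correlates the binary is-missing indicators of features j
    and k; high values point at shared causes of missingness. Rows/columns
    of constant indicators (fully observed or fully missing features) are
    NaN rather than raising.
    """
    if data.p < 2:
        raise ValidationError("pattern_correlation needs at least 2 features")
    ind = data.mask.astype(float)
    centered = ind - ind.mean(axis=0)
    sd = centered.std(axis=0)
    cov = centered.T @ centered / data.n
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return np.clip(corr, -1.0, 1.0, out=corr)
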