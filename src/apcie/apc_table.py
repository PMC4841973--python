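"""Age-period-cohort count tables (Lexis grids) and descriptive rates.

An :class:`APCTable` holds event counts and person-years of exposure on a
rectangular age-group x period grid with equal 5-year intervals on both
axes.  The anti-diagonals of the grid index birth cohorts: the cell for
age group ``i`` (1-based, youngest first) and period ``j`` belongs to
cohort ``k = a - i + j``, so a grid with ``a`` age groups and ``p``
periods contains ``a + p - 1`` cohorts.  Cohort 1 is the eldest age group
observed in the first period, i.e. the oldest birth cohort.

Rates are expressed per 100,000 person-years lived by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "APCTable",
    "RateTable",
    "cohort_index",
    "cohort_label",
    "cell_rates",
    "marginal_rates",
    "standardize_rates",
    "read_table",
    "write_table",
    "TableValidationError",
]

#: width of age groups, periods and birth-cohort intervals, in years
INTERVAL = 5

AXES = ("age", "period", "cohort")


class TableValidationError(ValueError):
    """Raised when a table or input file violates the grid contract."""


def _interval_label(start: int) -> str:
    """5-year interval label in ``1905-09`` style (lower bound inclusive)."""
    return f"{start}-{str(start + INTERVAL - 1)[-2:]}"


@dataclass(frozen=True)
class APCTable:
    """Event counts and exposures on a complete age x period grid.

    Parameters
    ----------
    deaths
        Non-negative integer counts, shape ``(a, p)``; rows are age groups
        (youngest first), columns are periods (earliest first).
    exposures
        Positive person-years per cell, same shape as ``deaths``.
    age_starts
        Lower bounds of the ``a`` age groups (strictly increasing, step 5).
    period_starts
        Lower bounds (calendar years) of the ``p`` periods (step 5).
    stratum
        Free-form metadata such as ``{"country": "Japan", "sex": "male"}``.
    """

    deaths: np.ndarray
    exposures: np.ndarray
    age_starts: np.ndarray
    period_starts: np.ndarray
    stratum: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        deaths = np.asarray(self.deaths, dtype=float)
        exposures = np.asarray(self.exposures, dtype=float)
        age_starts = np.asarray(self.age_starts, dtype=int)
        period_starts = np.asarray(self.period_starts, dtype=int)
        object.__setattr__(self, "deaths", deaths)
        object.__setattr__(self, "exposures", exposures)
        object.__setattr__(self, "age_starts", age_starts)
        object.__setattr__(self, "period_starts", period_starts)
        object.__setattr__(self, "stratum", dict(self.stratum))

        if deaths.ndim != 2:
            raise TableValidationError("deaths must be a 2-d array (age x period)")
        if deaths.shape != exposures.shape:
            raise TableValidationError(
                f"deaths shape {deaths.shape} != exposures shape {exposures.shape}"
            )
        a, p = deaths.shape
        if age_starts.shape != (a,) or period_starts.shape != (p,):
            raise TableValidationError("axis labels do not match grid shape")
        for name, starts in (("age_starts", age_starts), ("period_starts", period_starts)):
            step = np.diff(starts)
            if starts.size > 1 and not np.all(step == INTERVAL):
                raise TableValidationError(
                    f"{name} must increase in steps of {INTERVAL} years"
                )
        if np.any(deaths < 0):
            raise TableValidationError("deaths must be non-negative")
        if np.any(~np.isfinite(deaths)) or np.any(deaths != np.round(deaths)):
            raise TableValidationError("deaths must be finite integers")
        if np.any(~np.isfinite(exposures)) or np.any(exposures <= 0):
            raise TableValidationError("exposures must be finite and positive")

    # -- shape ---------------------------------------------------------------
    @property
    def n_ages(self) -> int:
        return self.deaths.shape[0]

    @property
    def n_periods(self) -> int:
        return self.deaths.shape[1]

    @property
    def n_cohorts(self) -> int:
        return self.n_ages + self.n_periods - 1

    # -- labels --------------------------------------------------------------
    @property
    def age_labels(self) -> list[str]:
        return [_interval_label(s) for s in self.age_starts]

    @property
    def period_labels(self) -> list[str]:
        return [str(s) for s in self.period_starts]

    @property
    def cohort_labels(self) -> list[str]:
        return [
            cohort_label(k, self.age_starts, self.period_starts)
            for k in range(1, self.n_cohorts + 1)
        ]

    def cohort_of_cell(self) -> np.ndarray:
        """1-based cohort index ``k`` for every cell, shape ``(a, p)``."""
        a, p = self.deaths.shape
        i = np.arange(1, a + 1)[:, None]
        j = np.arange(1, p + 1)[None, :]
        return a - i + j


@dataclass(frozen=True)
class RateTable:
    """Rates per ``scale`` person-years marginalized along one axis."""

    axis: str
    labels: list[str]
    rates: np.ndarray
    scale: float = 100_000.0
    standardized: bool = False
    reference: str | None = None

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if self.axis not in AXES + ("standardized",):
            raise ValueError(f"unknown axis {self.axis!r}")
        if len(self.labels) != rates.size:
            raise ValueError("labels and rates length mismatch")
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.axis: self.labels, "rate": self.rates})


# ---------------------------------------------------------------------------
# cohort-index algebra
# ---------------------------------------------------------------------------

def cohort_index(i: int, j: int, a: int) -> int:
    """Cohort index ``k = a - i + j`` of the cell (age row ``i``, period ``j``).

    All indices are 1-based.  ``k = 1`` is the oldest cohort (eldest age
    group in the first period); ``k = a + p - 1`` the youngest.
    """
    if not 1 <= i <= a:
        raise IndexError(f"age row i={i} out of bounds 1..{a}")
    if j < 1:
        raise IndexError(f"period column j={j} out of bounds (>= 1)")
    return a - i + j


def cohort_label(
    k: int, age_starts: Sequence[int], period_starts: Sequence[int]
) -> str:
    """Birth-year interval label of cohort ``k`` on the given grid.

    Cohort ``k`` was born in the 5-year interval starting at
    ``period_starts[0] - age_starts[-1] - 5 + 5*(k - 1)``; on a
    1985-2010 x ages-10-79 grid, ``k = 1`` maps to ``"1905-09"``.
    """
    n = len(age_starts) + len(period_starts) - 1
    if not 1 <= k <= n:
        raise IndexError(f"cohort index k={k} out of bounds 1..{n}")
    start = int(period_starts[0]) - int(age_starts[-1]) - INTERVAL + INTERVAL * (k - 1)
    return _interval_label(start)


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def cell_rates(table: APCTable, scale: float = 100_000.0) -> np.ndarray:
    """Per-cell rates ``scale * deaths / exposures`` (shape ``(a, p)``)."""
    return scale * table.deaths / table.exposures


def marginal_rates(
    table: APCTable, axis: str, scale: float = 100_000.0
) -> RateTable:
    """Pooled rates along one axis of the grid.

    For each category the rate is ``scale * sum(deaths) / sum(exposures)``
    over the cells in that category (a ratio of sums, i.e. person-years
    weighted, not a mean of cell rates).  Cohort categories are the
    anti-diagonals ``k = a - i + j``.
    """
    if axis == "age":
        d = table.deaths.sum(axis=1)
        e = table.exposures.sum(axis=1)
        labels = table.age_labels
    elif axis == "period":
        d = table.deaths.sum(axis=0)
        e = table.exposures.sum(axis=0)
        labels = table.period_labels
    elif axis == "cohort":
        k = table.cohort_of_cell()
        n = table.n_cohorts
        d = np.array([table.deaths[k == c].sum() for c in range(1, n + 1)])
        e = np.array([table.exposures[k == c].sum() for c in range(1, n + 1)])
        labels = table.cohort_labels
    else:
        raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")
    return RateTable(axis=axis, labels=labels, rates=scale * d / e, scale=scale)


def standardize_rates(
    age_rates: Sequence[float],
    weights: Sequence[float],
    reference: str | None = None,
) -> float:
    """Directly standardized rate: weighted mean of age-specific rates.

    ``weights`` is a reference age distribution (non-negative, normalized
    internally to sum to one) with one entry per age group.
    """
    r = np.asarray(age_rates, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.shape != w.shape:
        raise ValueError(f"{r.size} rates but {w.size} weights")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return float((w / total) @ r)


# ---------------------------------------------------------------------------
# tidy-file I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("age_start", "period_start", "deaths", "exposure")


def read_table(
    path: str | Path,
    stratum: Mapping[str, str] | None = None,
    sep: str = ",",
) -> APCTable:
    """Read a tidy long-format delimited file into an :class:`APCTable`.

    The file must contain the columns ``age_start, period_start, deaths,
    exposure``; any further columns are stratum metadata.  If ``stratum``
    is given the rows are filtered to those values first.  The grid must
    be complete: every (age_start, period_start) combination present
    exactly once.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing required columns: {missing}")

    meta_cols = [c for c in df.columns if c not in _REQUIRED_COLUMNS]
    if stratum:
        for key, value in stratum.items():
            if key not in df.columns:
                raise TableValidationError(f"no stratum column {key!r} in file")
            df = df[df[key].astype(str) == str(value)]
        if df.empty:
            raise TableValidationError(f"no rows match stratum {dict(stratum)}")

    for col in _REQUIRED_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()].tolist()
        if bad:
            raise TableValidationError(f"non-numeric {col!r} in rows {bad}")
        df[col] = values

    nonpos = df[df["exposure"] <= 0]
    if not nonpos.empty:
        cells = [
            f"(age_start={int(r.age_start)}, period_start={int(r.period_start)})"
            for r in nonpos.itertuples()
        ]
        raise TableValidationError(f"non-positive exposure in cells {cells}")

    age_starts = np.sort(df["age_start"].unique()).astype(int)
    period_starts = np.sort(df["period_start"].unique()).astype(int)
    pivot_d = df.pivot_table(
        index="age_start", columns="period_start", values="deaths", aggfunc="sum"
    ).reindex(index=age_starts, columns=period_starts)
    pivot_e = df.pivot_table(
        index="age_start", columns="period_start", values="exposure", aggfunc="sum"
    ).reindex(index=age_starts, columns=period_starts)
    if pivot_d.isna().any().any():
        holes = [
            f"(age_start={int(i)}, period_start={int(j)})"
            for i in age_starts
            for j in period_starts
            if pd.isna(pivot_d.loc[i, j])
        ]
        raise TableValidationError(f"incomplete grid; missing cells {holes}")

    meta: dict[str, str] = {}
    for col in meta_cols:
        uniq = df[col].unique()
        if len(uniq) == 1:
            meta[col] = str(uniq[0])

    return APCTable(
        deaths=pivot_d.to_numpy(),
        exposures=pivot_e.to_numpy(),
        age_starts=age_starts,
        period_starts=period_starts,
        stratum=meta,
    )


def write_table(table: APCTable, path: str | Path, sep: str = ",") -> None:
    """Write a table in tidy long format (lossless round-trip)."""
    rows = []
    for i, age in enumerate(table.age_starts):
        for j, per in enumerate(table.period_starts):
            row: dict[str, object] = {
                "age_start": int(age),
                "period_start": int(per),
                "deaths": int(table.deaths[i, j]),
                "exposure": float(table.exposures[i, j]),
            }
            row.update(table.stratum)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
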