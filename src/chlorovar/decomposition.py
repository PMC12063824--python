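"""Multiplicative timescale decomposition of a monthly chlorophyll series.

A monthly grab-sample record c_ij (year i, month j) is decomposed as

    c_ij = Cbar * y_i * m_j * eps_ij

where Cbar is the grand mean, y_i a dimensionless annual coefficient, m_j a
dimensionless seasonal (monthly) coefficient and eps_ij the sub-monthly
residual.  The sample standard deviations of {y_i}, {m_j} and {eps_ij} are
directly comparable dimensionless quantities and partition variability by
timescale: interannual, seasonal, and event-scale (sub-monthly).

Estimator conventions
---------------------
* Cbar is the mean of all observed cells.
* y_i is the mean of year i's observed cells divided by Cbar, then
  renormalized to unit mean over years.
* m_j is the mean over years (at observed cells) of c_ij / (Cbar * y_i),
  renormalized to unit mean over months.
* eps_ij = c_ij / (Cbar * y_i * m_j), which makes the reconstruction
  identity exact at every observed cell; any imbalance from missing cells is
  absorbed into the residuals.
* All standard deviations use the n-1 (sample) convention.

Chlorophyll is decomposed on the raw scale (the model is multiplicative,
not log-additive); all observed values must therefore be positive.  Missing
cells are skipped in every mean — no imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

MONTHS = tuple(range(1, 13))


@dataclass
class MonthlyMatrix:
    """Year x month chlorophyll values (µg/L); cells may be missing."""

    values: pd.DataFrame  # index: years (int), columns: 1..12

    def __post_init__(self) -> None:
        df = self.values.reindex(columns=list(MONTHS)).astype(float)
        df.index = df.index.astype(int)
        df.index.name = "year"
        df.columns.name = "month"
        if (df.stack() <= 0).any():
            raise ValidationError("monthly matrix: non-positive chlorophyll cell")
        self.values = df.sort_index()

    @property
    def years(self) -> list[int]:
        return list(self.values.index)


@dataclass
class DecompositionResult:
    """Fitted components of the multiplicative decomposition."""

    grand_mean: float
    annual: pd.Series  # index: year, unit mean
    monthly: pd.Series  # index: month 1..12 (NaN for never-observed months)
    residuals: pd.DataFrame  # year x month, NaN at missing cells
    sd_annual: float
    sd_seasonal: float
    sd_residual: float

    def reconstruct(self) -> pd.DataFrame:
        """Cbar * y_i * m_j * eps_ij for every observed cell."""
        outer = np.outer(self.annual.to_numpy(), self.monthly.to_numpy())
        return self.grand_mean * self.residuals * pd.DataFrame(
            outer, index=self.annual.index, columns=self.monthly.index
        )


def build_monthly_matrix(samples) -> MonthlyMatrix:
    """Assemble grab samples into a year x month matrix.

    ``samples`` is a DataFrame with columns ``date`` and ``chlorophyll`` or an
    iterable of ``(date, chlorophyll)`` pairs.  Multiple samples in one month
    are averaged; months without samples stay missing.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples[["date", "chlorophyll"]].copy()
    else:
        df = pd.DataFrame(list(samples), columns=["date", "chlorophyll"])
    if df.empty:
        raise ValidationError("no samples provided")
    if (df["chlorophyll"].dropna() <= 0).any():
        raise ValidationError("non-positive chlorophyll sample")
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"]))
    df["year"] = dates.year
    df["month"] = dates.month
    matrix = df.pivot_table(
        index="year", columns="month", values="chlorophyll", aggfunc="mean"
    )
    return MonthlyMatrix(values=matrix)


def fit_decomposition(matrix: MonthlyMatrix) -> DecompositionResult:
    """Fit the multiplicative decomposition to a monthly matrix.

    Years with no observed cells are dropped with a warning; at least two
    years must remain.
    """
    values = matrix.values
    empty_years = values.index[values.notna().sum(axis=1) == 0]
    if len(empty_years):
        logger.warning("dropping years with no observations: %s", list(empty_years))
        values = values.drop(index=empty_years)
    if len(values) < 2:
        raise ValidationError("decomposition needs at least 2 years with data")

    cells = values.to_numpy(dtype=float)
    grand_mean = float(np.nanmean(cells))

    y_raw = values.mean(axis=1, skipna=True) / grand_mean
    annual = y_raw / y_raw.mean()

    ratio = values.div(grand_mean * annual, axis=0)
    m_raw = ratio.mean(axis=0, skipna=True)
    monthly = m_raw / m_raw.mean()

    denom = grand_mean * pd.DataFrame(
        np.outer(annual.to_numpy(), monthly.reindex(values.columns).to_numpy()),
        index=values.index,
        columns=values.columns,
    )
    residuals = values / denom

    eps = residuals.to_numpy().ravel()
    eps = eps[np.isfinite(eps)]
    return DecompositionResult(
        grand_mean=grand_mean,
        annual=annual.rename("annual"),
        monthly=monthly.rename("monthly"),
        residuals=residuals,
        sd_annual=float(annual.std(ddof=1)),
        sd_seasonal=float(monthly.std(ddof=1)),
        sd_residual=float(np.std(eps, ddof=1)),
    )


_COMPONENT_ORDER = ("annual", "seasonal", "residual")


def variability_partition(result: DecompositionResult) -> pd.DataFrame:
    """Rank the timescale components by their standard deviation.

    Returns a table (component, sd, rank) ordered by descending SD; ties keep
    the input order annual, seasonal, residual.
    """
    sds = {
        "annual": result.sd_annual,
        "seasonal": result.sd_seasonal,
        "residual": result.sd_residual,
    }
    table = pd.DataFrame(
        {"component": _COMPONENT_ORDER, "sd": [sds[c] for c in _COMPONENT_ORDER]}
    )
    table = table.sort_values("sd", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
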