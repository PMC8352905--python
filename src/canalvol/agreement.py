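"""Inter-rater consistency of the volume measurements.

Two (or more) raters measure the same physical quantities — labyrinth
fluid volume at baseline, plugging volume after surgery — and their
agreement is summarized by the intraclass correlation coefficient for
*average measures* from the two-way ANOVA mean squares of the ratings
table (targets x raters):

    MSR = between-target mean square      (df n-1)
    MSC = between-rater mean square       (df k-1)
    MSE = residual mean square            (df (n-1)(k-1))

    two-way random, absolute agreement:  (MSR - MSE) / (MSR + (MSC - MSE)/n)
    two-way mixed, consistency:          (MSR - MSE) / MSR

Absolute agreement is the default: the raters report the same volume in
the same units, so calibration offsets between raters should count
against them.  The significance test is F = MSR/MSE with (n-1, (n-1)(k-1))
degrees of freedom.

Coefficients are mapped to qualitative labels with the bands
< 0.4 poor, 0.4-0.79 general, >= 0.80 good.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigError

__all__ = ["RatingsTable", "ICCResult", "icc_average", "consistency_label"]

MODELS = ("two_way_random_absolute", "two_way_mixed_consistency")


@dataclass(frozen=True)
class RatingsTable:
    """Measurements matrix: rows are targets, columns are raters."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ConfigError("ratings must be a 2D targets-by-raters table")
        n, k = arr.shape
        if n < 2 or k < 2:
            raise ConfigError("need at least 2 targets and 2 raters")
        if np.any(~np.isfinite(arr)):
            raise ConfigError("missing/non-finite cells are not supported")
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_csv(cls, path: str) -> "RatingsTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float))

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    coefficient: float
    model: str
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    label: str

    def to_dict(self) -> dict:
        return {"icc": self.coefficient, "model": self.model,
                "f": self.f_statistic, "df1": self.df1, "df2": self.df2,
                "p": self.p_value, "label": self.label}


def _mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)  # guard tiny negative round-off
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_average(r: RatingsTable,
                model: str = "two_way_random_absolute") -> ICCResult:
    """Average-measures intraclass correlation of a ratings table.

    Raises on zero between-target variance (the coefficient is undefined
    when every target has the same value).
    """
    if model not in MODELS:
        raise ConfigError(f"model must be one of {MODELS}")
    msr, msc, mse, n, k = _mean_squares(r.values)
    if msr <= 0:
        raise ConfigError("zero between-target variance: ICC undefined")
    if model == "two_way_mixed_consistency":
        icc = (msr - mse) / msr
    else:
        icc = (msr - mse) / (msr + (msc - mse) / n)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        f, p = float("inf"), 0.0
    else:
        f = msr / mse
        p = float(stats.f.sf(f, df1, df2))
    return ICCResult(float(icc), model, float(f), df1, df2, p,
                     consistency_label(float(icc)))


def consistency_label(coefficient: float) -> str:
    """Qualitative band: <0.4 poor, 0.4-0.79 general, >=0.80 good."""
    if not -1.0 <= coefficient <= 1.0:
        raise ConfigError("coefficient must lie in [-1, 1]")
    if coefficient < 0.4:
        return "poor"
    if coefficient < 0.8:
        return "general"
    return "good"
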