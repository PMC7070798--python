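"""Regression layer: per-batch records, OLS fits, per-treatment fits, ANOVA.

Mirrors the field workflow: LiDAR-derived quantities (number of scans, total
alpha-shape volume, volume without training structures) are regressed on the
per-batch dry pruning biomass, pooled and by treatment, and a sequential
(type-I) ANOVA tests the effect of a predictor plus treatment on biomass.
Plain OLS with the classical t-test throughout; no robust errors, no
multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "BatchRecord",
    "FitReport",
    "records_to_frame",
    "linear_fit",
    "fits_by_group",
    "anova",
]

PREDICTORS = ("n_scans", "volume_total", "volume_no_structures")


@dataclass(frozen=True)
class BatchRecord:
    """Per-batch summary row contrasted against ground-truth biomass."""

    treatment: str
    plot: int
    n_scans: int
    n_points: int
    volume_total: float  # m^3
    volume_no_structures: float  # m^3
    biomass: float  # kg (ground truth for synthetic runs)

    def __post_init__(self) -> None:
        if self.n_scans < 0 or self.n_points < 0:
            raise ValueError("counts must be >= 0")
        if self.volume_no_structures > self.volume_total + 1e-12:
            raise ValueError("volume without structures exceeds total volume")


@dataclass(frozen=True)
class FitReport:
    slope: float
    intercept: float
    se_slope: float
    p_value: float
    r_squared: float
    n: int


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) if isinstance(r, BatchRecord) else dict(r)
                         for r in records])


def linear_fit(x, y) -> FitReport:
    """Ordinary least squares of y on x with the classical slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0.0:
        raise ValueError("predictor has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return FitReport(slope=float(model.params[1]), intercept=float(model.params[0]),
                     se_slope=float(model.bse[1]), p_value=float(model.pvalues[1]),
                     r_squared=float(model.rsquared), n=len(x))


def fits_by_group(records, predictor: str = "volume_total",
                  response: str = "biomass", group: str = "treatment") -> pd.DataFrame:
    """One OLS fit per group plus the pooled fit, as a tidy table.

    Groups with fewer than 3 records are skipped with a warning.  Rows carry
    Variable/Treatment/Estimate/SE/p-Value plus intercept, R^2 and n.
    """
    df = records_to_frame(records)
    if predictor not in df.columns:
        raise ValueError(f"unknown predictor {predictor!r}")
    rows = []

    def row(label: str, fit: FitReport) -> dict:
        return {"variable": predictor, "treatment": label, "estimate": fit.slope,
                "se": fit.se_slope, "p_value": fit.p_value,
                "intercept": fit.intercept, "r_squared": fit.r_squared, "n": fit.n}

    for label, sub in df.groupby(group, sort=True):
        if len(sub) < 3:
            warnings.warn(f"group {label!r} has n={len(sub)} < 3: skipped", stacklevel=2)
            continue
        rows.append(row(str(label), linear_fit(sub[predictor], sub[response])))
    rows.append(row("pooled", linear_fit(df[predictor], df[response])))
    return pd.DataFrame(rows)


def anova(records, predictor: str = "volume_total",
          response: str = "biomass") -> pd.DataFrame:
    """Sequential (type-I) ANOVA for ``response ~ predictor + treatment``.

    The predictor enters first (its sum of squares is unadjusted for
    treatment); the treatment term is adjusted for the predictor.  Built
    from nested OLS fits so the entry order is exactly as stated.  Returns
    a table with df, sum_sq, F and PR(>F) per term plus the residual row.
    """
    df = records_to_frame(records)
    levels = df["treatment"].nunique()
    if levels < 2:
        raise ValueError("ANOVA needs at least 2 treatment levels")
    n = len(df)
    model_df = 1 + 1 + (levels - 1)  # intercept + slope + treatment contrasts
    if n <= model_df:
        raise ValueError("singular design: not enough observations per cell")
    y = df[response].to_numpy(dtype=float)
    x = df[predictor].to_numpy(dtype=float)
    dummies = pd.get_dummies(df["treatment"], drop_first=True, dtype=float)
    X1 = sm.add_constant(x)
    X2 = np.column_stack([X1, dummies.to_numpy()])
    if np.linalg.matrix_rank(X2) < X2.shape[1]:
        raise ValueError("singular design matrix")
    sse0 = float(np.sum((y - y.mean()) ** 2))
    sse1 = float(sm.OLS(y, X1).fit().ssr)
    fit2 = sm.OLS(y, X2).fit()
    sse2 = float(fit2.ssr)
    df_resid = n - model_df
    mse = sse2 / df_resid
    rows = {
        predictor: (1.0, sse0 - sse1),
        "C(treatment)": (float(levels - 1), sse1 - sse2),
    }
    table = pd.DataFrame(
        [{"df": d, "sum_sq": ss, "mean_sq": ss / d,
          "F": (ss / d) / mse if mse > 0 else np.inf,
          "PR(>F)": float(sps.f.sf((ss / d) / mse, d, df_resid))
          if mse > 0 else 0.0}
         for d, ss in rows.values()],
        index=list(rows))
    table.loc["Residual"] = [float(df_resid), sse2, mse, np.nan, np.nan]
    return table
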