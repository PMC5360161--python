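"""Interobserver agreement (ICC) and functional-vs-morphological correlation.

The ICC form is fixed to two-way random effects, absolute agreement, single
rater — ICC(2,1) — the standard choice when raters are interchangeable.
Its 95% confidence interval uses the F-distribution method of McGraw &
Wong.  Pearson correlation uses the t-transform p-value with n-2 degrees
of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    form: str
    n_targets: int
    n_raters: int
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "form": self.form,
            "n_targets": self.n_targets,
            "n_raters": self.n_raters,
        }


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p": self.p_value, "n": self.n}


def ratings_from_tidy(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy (target_id, rater, value) records into a complete wide table.

    Targets with any missing rater value are dropped with a logged warning.
    """
    required = {"target_id", "rater", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"tidy ratings need columns {sorted(required)}")
    wide = df.pivot(index="target_id", columns="rater", values="value")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.warning("%d incomplete rating rows dropped", dropped)
    return complete


def icc_two_way(ratings) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a targets-by-raters array or DataFrame with complete
    cells, >= 2 targets and >= 2 raters.  Zero between-target variance
    leaves the ICC undefined (NaN, ``defined=False``).
    """
    Y = np.asarray(ratings, dtype=np.float64)
    if Y.ndim != 2:
        raise ValueError("ratings must be a 2D targets-by-raters table")
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 targets and >= 2 raters")
    if not np.all(np.isfinite(Y)):
        raise ValueError("ratings table has missing/non-finite cells")

    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((Y - grand) ** 2))
    sse = sst - ssr - ssc

    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if ssr == 0:
        logger.warning("zero between-target variance: ICC undefined")
        return ICCResult(math.nan, math.nan, math.nan, "ICC(2,1)", n, k, defined=False)

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    if mse == 0 and msc == 0:
        # perfect agreement: degenerate CI
        return ICCResult(float(icc), float(icc), float(icc), "ICC(2,1)", n, k)

    alpha = 0.05
    fj = msc / mse if mse > 0 else math.inf
    with np.errstate(all="ignore"):
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return ICCResult(float(icc), float(lower), float(upper), "ICC(2,1)", n, k)


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson r with two-sided t-based p-value (n-2 df)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    for name, arr in (("x", x), ("y", y)):
        if np.all(arr == arr[0]):
            raise ValueError(f"{name} is constant: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(rho=float(r), p_value=float(p), n=int(x.size))
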