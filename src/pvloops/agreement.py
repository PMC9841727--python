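"""Agreement statistics for method-comparison studies: Bland-Altman bias and
limits of agreement, and the two-way absolute-agreement single-measure
intraclass correlation coefficient ICC(2,1).

Agreement levels follow the conventional banding: poor (0.00-0.30), weak
(0.31-0.50), moderate (0.51-0.70), strong (0.71-0.90), excellent
(0.91-1.00); values are rounded half-up to two decimals before banding, and
negative ICCs are labelled poor.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, UndefinedICCError

__all__ = ["AgreementResult", "bland_altman", "icc", "icc_label", "compare"]

_BANDS = [(0.30, "poor"), (0.50, "weak"), (0.70, "moderate"), (0.90, "strong"), (1.00, "excellent")]


@dataclass
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    icc: float
    icc_label: str
    r: float
    n: int


def bland_altman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement.

    Differences are ``d = x - y``; bias is their mean and the limits are
    ``bias +- 1.96 * SD(d)`` with the sample (n-1) standard deviation.

    Returns ``(bias, loa_low, loa_high)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ArgumentError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ArgumentError("need at least 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def icc_label(value: float) -> str:
    """Agreement label for an ICC, banded after half-up rounding to 2 dp."""
    rounded = float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    for upper, label in _BANDS:
        if rounded <= upper:
            return label
    return "excellent"


def icc(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Returns the coefficient and its agreement label.

    Raises
    ------
    UndefinedICCError
        If the total variance is zero (constant measurements).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ArgumentError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ArgumentError("need at least 3 pairs for an ICC")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise UndefinedICCError("ICC undefined: zero total variance")
    import pingouin as pg

    df = pd.DataFrame(
        {
            "targets": np.tile(np.arange(n), 2),
            "raters": np.repeat(["x", "y"], n),
            "ratings": np.concatenate([x, y]),
        }
    )
    table = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
    # two-way absolute-agreement single-measure row (naming varies by version)
    row = table.loc[table["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"]
    value = float(row.iloc[0])
    if not np.isfinite(value):
        raise UndefinedICCError("ICC undefined for these data")
    return value, icc_label(value)


def compare(x: np.ndarray, y: np.ndarray) -> AgreementResult:
    """Full agreement report: Bland-Altman + ICC(2,1) + Pearson r."""
    bias, lo, hi = bland_altman(x, y)
    value, label = icc(x, y)
    r = float(stats.pearsonr(np.asarray(x, float), np.asarray(y, float)).statistic)
    return AgreementResult(bias=bias, loa_low=lo, loa_high=hi, icc=value, icc_label=label, r=r, n=len(x))
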