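"""Derived physiological summaries: temperature sensitivity and acclimation
indices, gross assimilation, total CO2 conductance, and the A_G vs Cc/O
regression.

TSI = Y(CT, 25degC) / Y(CT, 38degC) measures the short-term response of
control-grown plants to a measurement-temperature jump (1 = insensitive).
TAI = Y(HT, 38degC) / Y(CT, 25degC) compares plants grown and measured at
their own temperature (1 = perfect homeostasis).  Both are plain ratios of
treatment means; standard errors propagate by the delta method for ratios
of independent means, and "differs from 1" uses a two-sided t test on the
log ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TreatmentSummary",
    "RatioIndex",
    "tsi",
    "tai",
    "gross_assimilation",
    "total_conductance",
    "ag_ccO_regression",
    "RegressionResult",
]


@dataclass(frozen=True)
class TreatmentSummary:
    """Mean ± SE of one parameter in the three index-defining treatments."""

    parameter: str
    species: str
    irrigation: str
    value_CT25: float
    value_CT38: float
    value_HT38: float
    se_CT25: float = 0.0
    se_CT38: float = 0.0
    se_HT38: float = 0.0
    n: int = 4

    def __post_init__(self) -> None:
        if min(self.se_CT25, self.se_CT38, self.se_HT38) < 0:
            raise ValueError("standard errors must be non-negative")

    def tsi(self) -> "RatioIndex":
        return tsi(self.value_CT25, self.value_CT38, self.se_CT25, self.se_CT38, self.n)

    def tai(self) -> "RatioIndex":
        return tai(self.value_HT38, self.value_CT25, self.se_HT38, self.se_CT25, self.n)


@dataclass(frozen=True)
class RatioIndex:
    """A ratio of treatment means with a delta-method SE.

    ``p_vs_one`` is a two-sided t probability on the log ratio that the
    index differs from 1 (NaN when SEs were not supplied).
    """

    value: float
    se: float
    p_vs_one: float


def _ratio_index(num: float, den: float, se_num: float, se_den: float, n: int) -> RatioIndex:
    if den == 0:
        raise ZeroDivisionError("index undefined: zero denominator mean")
    r = num / den
    if se_num == 0 and se_den == 0:
        return RatioIndex(r, 0.0, float("nan"))
    rel2 = (se_num / num) ** 2 + (se_den / den) ** 2
    se = abs(r) * math.sqrt(rel2)
    # two-sided t on log ratio; se(log r) ~ sqrt(rel2)
    t = abs(math.log(abs(r))) / math.sqrt(rel2)
    p = 2.0 * stats.t.sf(t, df=max(2 * (n - 1), 1))
    return RatioIndex(r, se, p)


def tsi(y_ct25: float, y_ct38: float, se25: float = 0.0, se38: float = 0.0, n: int = 4) -> RatioIndex:
    """Temperature sensitivity index, Y(CT-25) / Y(CT-38)."""
    return _ratio_index(y_ct25, y_ct38, se25, se38, n)


def tai(y_ht38: float, y_ct25: float, se38: float = 0.0, se25: float = 0.0, n: int = 4) -> RatioIndex:
    """Temperature acclimation index, Y(HT-38) / Y(CT-25)."""
    return _ratio_index(y_ht38, y_ct25, se38, se25, n)


def gross_assimilation(an, rdark):
    """Gross assimilation A_G = A_N + Rdark/2 (µmol m-2 s-1)."""
    return np.asarray(an, dtype=float) + 0.5 * np.asarray(rdark, dtype=float)


def total_conductance(gs_h2o: float, gm: float) -> float:
    """Total leaf conductance to CO2 from the series combination of the
    stomatal and mesophyll components: 1/gt = 1.6/gs + 1/gm.

    ``gs_h2o`` is the stomatal conductance to water vapour (the 1.6
    diffusivity ratio converts it to a CO2 conductance); ``gm`` is already
    a CO2 conductance.  gt < min(gs/1.6, gm) always.
    """
    if gs_h2o <= 0 or gm <= 0:
        raise ValueError("conductances must be positive")
    return 1.0 / (1.6 / gs_h2o + 1.0 / gm)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def ag_ccO_regression(cc_over_o: Sequence[float], ag: Sequence[float]) -> RegressionResult:
    """OLS (with intercept) of gross assimilation on the Cc/O ratio.

    The linearity of A_G in Cc/O reflects Rubisco operating below
    saturation, where carboxylation scales with the CO2:O2 ratio at the
    catalytic site.
    """
    x = np.asarray(cc_over_o, dtype=float)
    y = np.asarray(ag, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("degenerate regression: x has no variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=len(x),
    )
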