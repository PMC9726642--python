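"""Depth power-law model of hydrostatic-pressure inhibition.

In-situ activity, expressed as a percentage P of the activity the same
community shows at atmospheric pressure, decays with depth z as

    P(z) = a · z^b          (a in % at z = 1 m, b dimensionless)

fitted by ordinary least squares of log10 P on log10 z. The fitted curve is
also used to correct atmospheric-pressure heterotrophic production to
in-situ conditions, and an ANCOVA-style interaction test compares the
log–log slopes of two depth profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .radiotracer import RatioPoint


@dataclass(frozen=True)
class PowerLawFit:
    """Result of the log–log OLS fit P = a·z^b.

    ``ci_log10_a`` and ``ci_b`` are 95% confidence intervals from the t
    distribution with n−2 degrees of freedom; ``resid_sd`` is the residual
    standard deviation in log10 units.
    """

    a: float
    b: float
    r2: float
    n: int
    se_log10_a: float
    se_b: float
    ci_log10_a: tuple[float, float]
    ci_b: tuple[float, float]
    resid_sd: float

    @property
    def log10_a(self) -> float:
        return math.log10(self.a)

    @classmethod
    def from_coefficients(cls, a: float, b: float) -> "PowerLawFit":
        """Wrap published coefficients (no fit statistics available)."""
        return cls(
            a=a, b=b, r2=float("nan"), n=0,
            se_log10_a=float("nan"), se_b=float("nan"),
            ci_log10_a=(float("nan"), float("nan")),
            ci_b=(float("nan"), float("nan")),
            resid_sd=float("nan"),
        )

    def to_dict(self) -> dict:
        return {
            "a_percent_at_1m": self.a,
            "b_exponent": self.b,
            "r2": self.r2,
            "n": self.n,
            "se_log10_a": self.se_log10_a,
            "se_b": self.se_b,
            "ci95_log10_a": list(self.ci_log10_a),
            "ci95_b": list(self.ci_b),
            "resid_sd_log10": self.resid_sd,
        }


@dataclass(frozen=True)
class SlopeComparison:
    """Type-III F test of the condition × log-depth interaction."""

    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    groups: tuple[str, str]


def _as_zp(points: Sequence[RatioPoint] | Sequence[tuple[float, float]]) -> np.ndarray:
    rows = []
    for p in points:
        if isinstance(p, RatioPoint):
            if p.regression_eligible:
                rows.append((p.depth_m, p.percent))
        else:
            rows.append((float(p[0]), float(p[1])))
    return np.asarray(rows, dtype=float)


def fit_power_law(
    points: Sequence[RatioPoint] | Sequence[tuple[float, float]],
    exclude_zero_depth: bool = True,
) -> PowerLawFit:
    """Fit P = a·z^b by unweighted OLS in log10–log10 space.

    ``RatioPoint`` inputs flagged below detection are dropped; zero-depth
    points (atmospheric instrument tests) are excluded from the regression
    when ``exclude_zero_depth`` is set. Raises ``ValueError`` on fewer than
    3 usable points or non-positive ratios at positive depth.
    """
    zp = _as_zp(points)
    if zp.size and exclude_zero_depth:
        zp = zp[zp[:, 0] > 0]
    if len(zp) < 3:
        raise ValueError("need at least 3 points with positive depth to fit")
    if np.any(zp[:, 0] <= 0):
        raise ValueError("depths must be > 0 in the regression set")
    if np.any(zp[:, 1] <= 0):
        raise ValueError("ratios must be > 0 in the regression set")

    x = np.log10(zp[:, 0])
    y = np.log10(zp[:, 1])
    res = stats.linregress(x, y)
    n = len(x)
    dof = n - 2
    resid = y - (res.intercept + res.slope * x)
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else float("nan")
    return PowerLawFit(
        a=10.0**res.intercept,
        b=float(res.slope),
        r2=float(res.rvalue**2),
        n=n,
        se_log10_a=float(res.intercept_stderr),
        se_b=float(res.stderr),
        ci_log10_a=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        ci_b=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        resid_sd=resid_sd,
    )


def predict_fraction(z: float, fit: PowerLawFit, cap_at_100: bool = True) -> float:
    """Predicted in-situ activity as percent of atmospheric, a·z^b.

    Uncapped the curve exceeds 100% above ~145 m (for the default
    coefficients); with ``cap_at_100`` the inhibition factor saturates at
    100% since the correction only expresses inhibition.
    """
    if z <= 0:
        raise ValueError("depth must be > 0")
    p = fit.a * z**fit.b
    return min(p, 100.0) if cap_at_100 else p


def correct_php(php_atm: float, z: float, fit: PowerLawFit, cap_at_100: bool = True) -> float:
    """Correct atmospheric-pressure production to in-situ pressure.

    PHP_insitu = PHP_atm × P(z)/100, both in µmol C m⁻³ d⁻¹.
    """
    if php_atm < 0:
        raise ValueError("php_atm must be >= 0")
    return php_atm * predict_fraction(z, fit, cap_at_100=cap_at_100) / 100.0


def compare_slopes(
    profile_a: Sequence[tuple[float, float]],
    profile_b: Sequence[tuple[float, float]],
    labels: tuple[str, str] = ("A", "B"),
) -> SlopeComparison:
    """Test whether two depth profiles share a log–log slope.

    Pools both profiles into one linear model of log10 rate on log10 depth
    with a group main effect and a group × log-depth interaction (sum
    coding), and returns the type-III F test of the interaction term.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    for arr in (a, b):
        if len(arr) < 3:
            raise ValueError("each profile needs at least 3 points")
        if np.any(arr <= 0):
            raise ValueError("depths and rates must be > 0")
    df = pd.DataFrame(
        {
            "logz": np.log10(np.concatenate([a[:, 0], b[:, 0]])),
            "logy": np.log10(np.concatenate([a[:, 1], b[:, 1]])),
            "group": [labels[0]] * len(a) + [labels[1]] * len(b),
        }
    )
    model = smf.ols("logy ~ C(group, Sum) * logz", data=df).fit()
    import statsmodels.api as sm

    table = sm.stats.anova_lm(model, typ=3)
    row = table.loc["C(group, Sum):logz"]
    return SlopeComparison(
        f_statistic=float(row["F"]),
        p_value=float(row["PR(>F)"]),
        df_num=int(row["df"]),
        df_den=int(table.loc["Residual", "df"]),
        groups=labels,
    )
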