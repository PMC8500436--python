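"""Population-level scaling: power laws of HRV indices versus age.

Age is treated as a continuous variable over the whole span of life
(months to 99 years).  A power law value = A * age^E appears as a
straight line after log10 transformation of both axes, so every fit
here is ordinary least squares in log-log space; significance comes
from the slope t-test and ANOVA, scatter from the residual sd of
log10(value), and per-age uncertainty from standard OLS prediction
intervals back-transformed to index units.

Indices whose ageing reverses direction (SD_RR, rMSSD, pNN50 rise
through childhood and fall after adolescence) are modelled by a
two-branch power law; the breakpoint is found by scanning a candidate
grid and minimizing the pooled residual sum of squares of the two
branch fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "PowerLawFit",
    "PiecewiseFit",
    "AnovaTable",
    "GenderComparison",
    "fit_power_law",
    "find_breakpoint",
    "default_breakpoint_grid",
    "anova_table",
    "prediction_interval",
    "ancova_gender",
    "quadratic_comparison",
]


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(value) on log10(age): value = prefactor * age^exponent.

    ``sd`` is the residual standard deviation of log10(value), ``r``
    the Pearson correlation of the log-log scatter, and ``p`` the
    two-sided significance of the slope.  The design summary
    (``log_age_mean``, ``log_age_ss``) is retained for prediction
    intervals.
    """

    prefactor: float
    exponent: float
    prefactor_err: float
    exponent_err: float
    n: int
    r: float
    sd: float
    p: float
    log_age_mean: float
    log_age_ss: float

    @property
    def sse(self) -> float:
        """Residual sum of squares in log10 space."""
        return self.sd**2 * (self.n - 2)

    def predict(self, age) -> np.ndarray:
        return self.prefactor * np.asarray(age, float) ** self.exponent


@dataclass(frozen=True)
class PiecewiseFit:
    """Two-branch power law split at ``breakpoint`` (left branch owns it)."""

    breakpoint: float
    left: PowerLawFit
    right: PowerLawFit
    pooled_sse: float
    single_branch_sse: float

    def predict(self, age) -> np.ndarray:
        age = np.asarray(age, float)
        return np.where(
            age <= self.breakpoint, self.left.predict(age), self.right.predict(age)
        )


@dataclass(frozen=True)
class AnovaTable:
    """Sums of squares and mean squares of one regression fit."""

    sse: float
    sst: float
    msm: float
    mse: float
    df_model: int
    df_error: int


@dataclass(frozen=True)
class GenderComparison:
    """Per-sex power-law fits plus the ANCOVA F-test for any sex effect."""

    male: PowerLawFit
    female: PowerLawFit
    p_gender: float
    n: int


def fit_power_law(ages, values) -> PowerLawFit:
    """Fit value = prefactor * age^exponent by OLS in log-log space.

    The prefactor error follows by the delta method from the intercept
    standard error: se(10^b) = ln(10) * 10^b * se(b).
    """
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    if ages.size != values.size:
        raise ValueError("ages and values must have equal length")
    if ages.size < 3:
        raise ValueError(f"need >= 3 records, got {ages.size}")
    if np.any(ages <= 0):
        raise ValueError("ages must be positive for a log-log fit")
    if np.any(values <= 0):
        raise ValueError(
            f"{int(np.count_nonzero(values <= 0))} non-positive values cannot "
            "enter a log-log fit"
        )
    if np.unique(ages).size < 2:
        raise ValueError("need >= 2 distinct ages")
    lx, ly = np.log10(ages), np.log10(values)
    res = stats.linregress(lx, ly)
    n = ages.size
    resid = ly - (res.intercept + res.slope * lx)
    sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    prefactor = 10.0**res.intercept
    return PowerLawFit(
        prefactor=float(prefactor),
        exponent=float(res.slope),
        prefactor_err=float(np.log(10.0) * prefactor * res.intercept_stderr),
        exponent_err=float(res.stderr),
        n=int(n),
        r=float(res.rvalue),
        sd=sd,
        p=float(res.pvalue),
        log_age_mean=float(lx.mean()),
        log_age_ss=float(np.sum((lx - lx.mean()) ** 2)),
    )


def default_breakpoint_grid(lo: float = 2.0, hi: float = 30.0, n: int = 25) -> np.ndarray:
    """25 log-spaced candidate breakpoint ages in [2, 30] years."""
    return np.geomspace(lo, hi, n)


def find_breakpoint(
    ages,
    values,
    candidates: Optional[Sequence[float]] = None,
) -> PiecewiseFit:
    """Select the two-branch split minimizing pooled log-space SSE.

    For each candidate cut-off the two branches (ages <= c and
    ages > c) are fitted independently; the candidate with the
    smallest summed residual sum of squares wins, ties going to the
    smaller cut-off.  Candidates leaving fewer than 3 points on either
    side are skipped.  The single-branch SSE is co-reported so callers
    can judge whether a break is warranted at all.
    """
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    if candidates is None:
        candidates = default_breakpoint_grid()
    single = fit_power_law(ages, values)
    best = None
    for c in np.sort(np.asarray(candidates, float)):
        left_mask = ages <= c
        if left_mask.sum() < 3 or (~left_mask).sum() < 3:
            continue
        left = fit_power_law(ages[left_mask], values[left_mask])
        right = fit_power_law(ages[~left_mask], values[~left_mask])
        pooled = left.sse + right.sse
        if best is None or pooled < best[0]:  # strict <: ties keep smaller c
            best = (pooled, c, left, right)
    if best is None:
        raise ValueError(
            "no candidate cut-off leaves >= 3 points on each side"
        )
    pooled, c, left, right = best
    return PiecewiseFit(
        breakpoint=float(c),
        left=left,
        right=right,
        pooled_sse=float(pooled),
        single_branch_sse=float(single.sse),
    )


def anova_table(observed, fitted, df_model: int) -> AnovaTable:
    """ANOVA decomposition of one fit: SST = SSE + SSM."""
    observed = np.asarray(observed, float)
    fitted = np.asarray(fitted, float)
    if observed.size != fitted.size:
        raise ValueError("observed and fitted must have equal length")
    n = observed.size
    if n <= df_model:
        raise ValueError("need more observations than model degrees of freedom")
    sse = float(np.sum((observed - fitted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    df_error = n - df_model - 1
    return AnovaTable(
        sse=sse,
        sst=sst,
        msm=(sst - sse) / df_model,
        mse=sse / df_error if df_error > 0 else np.nan,
        df_model=df_model,
        df_error=df_error,
    )


def prediction_interval(
    fit: PowerLawFit, age: float, level: float = 0.95
) -> tuple[float, float]:
    """Interval expected to contain a future single observation at ``age``.

    Computed in log10 space by the standard OLS formula
    t * sd * sqrt(1 + 1/n + (x0 - xbar)^2 / Sxx) and back-transformed,
    so it is asymmetric in index units.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    lx = np.log10(age)
    t_crit = stats.t.ppf(0.5 + level / 2.0, fit.n - 2)
    half = t_crit * fit.sd * np.sqrt(
        1.0 + 1.0 / fit.n + (lx - fit.log_age_mean) ** 2 / fit.log_age_ss
    )
    centre = np.log10(fit.prefactor) + fit.exponent * lx
    return (float(10 ** (centre - half)), float(10 ** (centre + half)))


def ancova_gender(
    table: pd.DataFrame, index_name: str, age_min: float = 12.0
) -> GenderComparison:
    """Per-sex power laws above ``age_min`` plus the ANCOVA sex test.

    The p-value is the joint F comparing the pooled single-line model
    log10(value) ~ log10(age) against the full interaction model with
    sex-specific intercept and slope.
    """
    sub = table[
        (table["index_name"] == index_name)
        & (table["age_years"] > age_min)
        & (table["sex"].isin(["male", "female"]))
    ].copy()
    fits = {}
    for sex in ("male", "female"):
        grp = sub[sub["sex"] == sex]
        if len(grp) < 3:
            raise ValueError(
                f"sex {sex!r} has {len(grp)} records above age {age_min}; need >= 3"
            )
        fits[sex] = fit_power_law(grp["age_years"], grp["value"])
    sub["log_age"] = np.log10(sub["age_years"])
    sub["log_value"] = np.log10(sub["value"])
    pooled = smf.ols("log_value ~ log_age", data=sub).fit()
    full = smf.ols("log_value ~ log_age * C(sex)", data=sub).fit()
    comparison = anova_lm(pooled, full)
    p_gender = float(comparison["Pr(>F)"].iloc[1])
    return GenderComparison(
        male=fits["male"], female=fits["female"], p_gender=p_gender, n=len(sub)
    )


def quadratic_comparison(ages, values, space: str = "loglog") -> AnovaTable:
    """ANOVA of a quadratic polynomial fit, for model comparison.

    ``space="loglog"`` fits log10(value) on log10(age) (comparable
    with the power-law SSEs); ``space="linear"`` fits raw values on
    raw ages.
    """
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    if ages.size < 4:
        raise ValueError("need >= 4 records for a quadratic fit")
    if space == "loglog":
        if np.any(values <= 0) or np.any(ages <= 0):
            raise ValueError("log-log quadratic needs positive ages and values")
        x, y = np.log10(ages), np.log10(values)
    elif space == "linear":
        x, y = ages, values
    else:
        raise ValueError("space must be 'loglog' or 'linear'")
    if np.unique(x).size < 3:
        raise ValueError("quadratic fit is rank-deficient: < 3 distinct ages")
    design = sm.add_constant(np.column_stack([x, x**2]))
    fitted = sm.OLS(y, design).fit().fittedvalues
    return anova_table(y, fitted, df_model=2)
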