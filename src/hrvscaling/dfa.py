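"""Detrended fluctuation analysis (DFA) of RR-interval series.

DFA quantifies long-range correlation in a series through the scaling
of the root-mean-square fluctuation of its integrated, windowed and
polynomially detrended profile, F_m(s) ~ s^alpha.  Uncorrelated data
give alpha = 1/2; persistent long-range correlated data give
alpha > 1/2.  Three exponents are reported on fixed beat-scale ranges:

* alpha0 — scales 5 <= s <= 10 (very high frequency)
* alpha1 — scales 10 <= s <= 50 (high frequency)
* alpha2 — scales 50 <= s <= 200 (medium frequency)

The profile is split into floor(N/s) non-overlapping windows taken
from the start of the series only (the trailing remainder is
discarded); the variant that also scans windows from the end of the
series is deliberately not used.  Detrending degrees m = 3, 4 are
supported but flagged: detrending artifacts distort the small-scale
fluctuation function and m should be 1 or 2 for exponent estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats

from .io import RRSeries

__all__ = [
    "FluctuationFunction",
    "DfaExponents",
    "ALPHA_RANGES",
    "profile",
    "fluctuation_function",
    "fit_alpha",
    "alpha_suite",
    "default_scales",
]

#: Inclusive scale ranges (in beats) for the three reported exponents.
ALPHA_RANGES = {"alpha0": (5, 10), "alpha1": (10, 50), "alpha2": (50, 200)}


@dataclass(frozen=True)
class FluctuationFunction:
    """F_m(s) on a grid of window sizes, for one detrending degree m."""

    m: int
    scales: np.ndarray  # window sizes s, beats
    f_values: np.ndarray  # F_m(s), ms

    def __post_init__(self):
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if np.any(self.f_values < 0):
            raise ValueError("F values must be nonnegative")


@dataclass(frozen=True)
class AlphaFit:
    alpha: float
    r: float
    s_range: tuple[int, int]
    n_scales: int


@dataclass(frozen=True)
class DfaExponents:
    """The three scale-range exponents from one fluctuation function."""

    alpha0: float
    alpha1: float
    alpha2: float
    m: int
    r0: float
    r1: float
    r2: float
    #: True when m in {3, 4}: detrending artifacts appear at small
    #: scales and the exponents should not be trusted.
    artifact_warning: bool = False


def _as_array(series: Union[RRSeries, np.ndarray, Sequence[float]]) -> np.ndarray:
    if isinstance(series, RRSeries):
        return series.intervals
    return np.asarray(series, dtype=float)


def profile(series: Union[RRSeries, np.ndarray, Sequence[float]]) -> np.ndarray:
    """Cumulative sum of the mean-centred series, Y(k) = sum_{t<=k}(x_t - <x>)."""
    x = _as_array(series)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return np.cumsum(x - x.mean())


def default_scales(s_min: int = 5, s_max: int = 200, n: int = 25) -> np.ndarray:
    """Geometrically spaced integer scale grid over [s_min, s_max].

    Duplicates from integer rounding are removed and the endpoints of
    the three standard exponent ranges (5, 10, 50, 200, clipped to the
    requested span) are always included so every exponent fit sees both
    of its range endpoints.
    """
    grid = np.geomspace(s_min, s_max, n)
    scales = set(np.round(grid).astype(int))
    for lo, hi in ALPHA_RANGES.values():
        if s_min <= lo <= s_max:
            scales.add(lo)
        if s_min <= hi <= s_max:
            scales.add(hi)
    return np.array(sorted(scales), dtype=int)


def fluctuation_function(
    series: Union[RRSeries, np.ndarray, Sequence[float]],
    m: int = 1,
    scales: Union[np.ndarray, Sequence[int], None] = None,
) -> FluctuationFunction:
    """Compute the DFA fluctuation function F_m(s).

    For each window size s the profile is divided into floor(N/s)
    non-overlapping windows from the start of the series; a degree-m
    polynomial is least-squares fitted to each window on the abscissa
    k = 1..s; F^2 for a window is the mean squared residual, and
    F_m(s) is the square root of the mean of F^2 over windows.
    """
    x = _as_array(series)
    n = x.size
    if m not in (1, 2, 3, 4):
        raise ValueError(f"detrending degree m must be in 1..4, got {m}")
    if scales is None:
        scales = default_scales()
    scales = np.asarray(scales, dtype=int)
    if scales.size == 0:
        raise ValueError("empty scale grid")
    if np.any(scales > n):
        raise ValueError(
            f"scale {int(scales.max())} exceeds series length {n}"
        )
    if np.any(scales < m + 2):
        raise ValueError(
            f"every scale must be >= m + 2 = {m + 2} for an overdetermined fit"
        )

    y = np.cumsum(x - x.mean())
    f_values = np.empty(scales.size)
    for i, s in enumerate(scales):
        n_win = n // s
        segments = y[: n_win * s].reshape(n_win, s).T  # (s, n_win)
        k = np.arange(1, s + 1, dtype=float)
        design = np.vander(k, m + 1)  # shared abscissa across windows
        coef, _, _, _ = np.linalg.lstsq(design, segments, rcond=None)
        resid = segments - design @ coef
        f2_per_window = np.mean(resid**2, axis=0)
        f_values[i] = np.sqrt(f2_per_window.mean())
    return FluctuationFunction(m=m, scales=scales, f_values=f_values)


def fit_alpha(f: FluctuationFunction, s_lo: float, s_hi: float) -> AlphaFit:
    """OLS slope of log10 F versus log10 s over the inclusive range [s_lo, s_hi]."""
    mask = (f.scales >= s_lo) & (f.scales <= s_hi)
    if np.any(mask & (f.f_values == 0)):
        s_bad = int(f.scales[mask & (f.f_values == 0)][0])
        raise ValueError(
            f"F({s_bad}) = 0 inside the fit range: log-log slope undefined"
        )
    if np.count_nonzero(mask) < 3:
        raise ValueError(
            f"need >= 3 scales in [{s_lo}, {s_hi}], "
            f"got {int(np.count_nonzero(mask))}"
        )
    res = stats.linregress(np.log10(f.scales[mask]), np.log10(f.f_values[mask]))
    return AlphaFit(
        alpha=float(res.slope),
        r=float(res.rvalue),
        s_range=(int(s_lo), int(s_hi)),
        n_scales=int(np.count_nonzero(mask)),
    )


def alpha_suite(
    series: Union[RRSeries, np.ndarray, Sequence[float]],
    m: int = 1,
    scales: Union[np.ndarray, Sequence[int], None] = None,
) -> DfaExponents:
    """Compute alpha0, alpha1 and alpha2 from one fluctuation function.

    Requires N >= 400 so that the largest scale (s = 200) still
    averages over at least two windows.  Scale-range endpoints are
    inclusive on both sides, so s = 10 and s = 50 each contribute to
    two exponents.
    """
    x = _as_array(series)
    if x.size < 400:
        raise ValueError(
            f"series length {x.size} < 400: cannot average >= 2 windows at s = 200"
        )
    f = fluctuation_function(x, m=m, scales=scales)
    fits = {name: fit_alpha(f, lo, hi) for name, (lo, hi) in ALPHA_RANGES.items()}
    return DfaExponents(
        alpha0=fits["alpha0"].alpha,
        alpha1=fits["alpha1"].alpha,
        alpha2=fits["alpha2"].alpha,
        m=m,
        r0=fits["alpha0"].r,
        r1=fits["alpha1"].r,
        r2=fits["alpha2"].r,
        artifact_warning=m in (3, 4),
    )
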