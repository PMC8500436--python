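"""Synthetic RR series and synthetic populations.

Real 24-h Holter RR records are rarely shareable, so this module
provides statistical stand-ins for both levels of the analysis:

* :func:`synth_powerlaw_series` builds a Gaussian series with an exact
  power-law spectrum S(f) ~ f^(-beta) by spectral synthesis (fixed
  amplitudes, independent random phases), rescaled to a prescribed
  mean and standard deviation and optionally quantized to the 8 ms
  resolution typical of Holter R-peak timing.  The result is linear
  and Gaussian by construction — a null model for any nonlinearity
  claim, carrying only the second-order structure of real HRV.

* :func:`surrogate_series` produces the standard phase-randomization
  surrogate of a measured series: identical periodogram, randomized
  phases, nonlinear structure destroyed.

* :func:`synth_population` draws (age, sex, index value) records from
  one- or two-branch power laws of age with multiplicative log-normal
  scatter, the generative inverse of the published ageing curves.  The
  published fitted laws are provided as :data:`PUBLISHED_LAWS` and
  :data:`PUBLISHED_GENDER_LAWS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import RRSeries

__all__ = [
    "SeriesSpec",
    "ScalingLaw",
    "IndexLaw",
    "PopulationSpec",
    "PUBLISHED_LAWS",
    "PUBLISHED_GENDER_LAWS",
    "STUDY_AGE_HISTOGRAM",
    "synth_powerlaw_series",
    "surrogate_series",
    "synth_population",
    "synth_index_branches",
    "sample_ages",
]


@dataclass(frozen=True)
class SeriesSpec:
    """Specification of one synthetic power-law RR series.

    ``n`` must be a power of two (exact spectral synthesis);
    ``mean_rr > 3*sd_rr`` keeps intervals comfortably positive.
    ``quantization_ms`` defaults to the 8 ms RR measurement resolution
    of the Holter systems being emulated; set it to None for exact
    spectra in analytical tests.
    """

    n: int
    beta: float
    mean_rr: float = 800.0
    sd_rr: float = 50.0
    quantization_ms: Optional[float] = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 16 or (self.n & (self.n - 1)) != 0:
            raise ValueError("n must be a power of 2, at least 16")
        if not 0.0 <= self.beta <= 3.0:
            raise ValueError("beta must lie in [0, 3]")
        if not self.mean_rr > 3 * self.sd_rr:
            raise ValueError("need mean_rr > 3*sd_rr for positivity headroom")
        if self.quantization_ms is not None and self.quantization_ms <= 0:
            raise ValueError("quantization_ms must be positive or None")


def synth_powerlaw_series(spec: SeriesSpec) -> RRSeries:
    """Generate a Gaussian series with spectrum S(f) ~ f^(-beta).

    Amplitude at positive beat-frequency k/n is set to k^(-beta/2),
    phases are independent uniform on [0, 2pi), Hermitian symmetry is
    implied by the inverse real FFT.  The series is then rescaled to
    the target mean and standard deviation exactly (before any
    quantization) and is bit-reproducible given the spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    k = np.arange(1, n // 2 + 1, dtype=float)
    amplitude = k ** (-spec.beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n // 2)
    coeffs = np.zeros(n // 2 + 1, dtype=complex)
    coeffs[1:] = amplitude * np.exp(1j * phases)
    coeffs[-1] = coeffs[-1].real  # Nyquist bin must be real
    x = np.fft.irfft(coeffs, n)
    x = (x - x.mean()) / x.std()
    x = spec.mean_rr + spec.sd_rr * x
    if spec.quantization_ms is not None:
        x = np.round(x / spec.quantization_ms) * spec.quantization_ms
    return RRSeries(
        intervals=x,
        subject_id=f"synthetic-beta{spec.beta:g}-seed{spec.seed}",
        source="synthetic",
    )


def surrogate_series(series: RRSeries, seed: int = 0) -> RRSeries:
    """Phase-randomization surrogate: same periodogram, random phases.

    The DC component (hence the mean) and the magnitude of every
    Fourier coefficient are preserved to machine precision; phases of
    the non-DC, non-Nyquist bins are redrawn uniformly.  Linear
    (second-order) structure survives; any nonlinear structure does
    not, so order-sensitive indices such as rMSSD generally change.
    """
    x = series.intervals
    n = x.size
    if n < 16:
        raise ValueError("series too short for a surrogate (need >= 16)")
    coeffs = np.fft.rfft(x)
    rng = np.random.default_rng(seed)
    n_inner = coeffs.size - 2 if n % 2 == 0 else coeffs.size - 1
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_inner)
    coeffs[1 : 1 + n_inner] = np.abs(coeffs[1 : 1 + n_inner]) * np.exp(1j * phases)
    y = np.fft.irfft(coeffs, n)
    return series.replace(
        intervals=y,
        beat_times=None,
        subject_id=f"{series.subject_id}-surrogate{seed}",
        source="surrogate",
    )


# --------------------------------------------------------------------------
# Population generation


@dataclass(frozen=True)
class ScalingLaw:
    """value = prefactor * age**exponent."""

    prefactor: float
    exponent: float

    def __call__(self, age: np.ndarray) -> np.ndarray:
        return self.prefactor * np.asarray(age, float) ** self.exponent


@dataclass(frozen=True)
class IndexLaw:
    """One- or two-branch power law of age with log10-normal scatter.

    ``child`` applies below (and at) the breakpoint, ``adult`` above
    it; a one-branch law has ``adult=None`` and ``breakpoint=None``.
    ``sd_child`` / ``sd_adult`` are residual standard deviations of
    log10(value) per branch.
    """

    child: ScalingLaw
    adult: Optional[ScalingLaw] = None
    breakpoint: Optional[float] = None
    sd_child: float = 0.0
    sd_adult: Optional[float] = None

    def __post_init__(self):
        if (self.adult is None) != (self.breakpoint is None):
            raise ValueError("two-branch laws need both adult law and breakpoint")
        if self.sd_child < 0 or (self.sd_adult is not None and self.sd_adult < 0):
            raise ValueError("residual sds must be nonnegative")

    def mean_curve(self, age: np.ndarray) -> np.ndarray:
        age = np.asarray(age, float)
        if self.adult is None:
            return self.child(age)
        return np.where(age <= self.breakpoint, self.child(age), self.adult(age))

    def sd_log10(self, age: np.ndarray) -> np.ndarray:
        age = np.asarray(age, float)
        if self.adult is None:
            return np.full_like(age, self.sd_child)
        sd_adult = self.sd_child if self.sd_adult is None else self.sd_adult
        return np.where(age <= self.breakpoint, self.sd_child, sd_adult)


#: Published age-scaling laws of the four time-domain indices for
#: healthy subjects aged 0.08-99 y (pooled 24-h Holter data, ~700
#: subjects): mean RR is one monotonic power law; SD_RR, rMSSD and
#: pNN50 each break at 12 years, rising in childhood and declining
#: after adolescence.  Residual sds are in log10 units (per branch).
PUBLISHED_LAWS: dict[str, IndexLaw] = {
    "mean_rr": IndexLaw(ScalingLaw(505.0, 0.122), sd_child=0.045),
    "sd_rr": IndexLaw(
        ScalingLaw(80.0, 0.26), ScalingLaw(290.0, -0.20), 12.0, 0.1, 0.1
    ),
    "rmssd": IndexLaw(
        ScalingLaw(18.6, 0.34), ScalingLaw(166.0, -0.46), 12.0, 0.17, 0.16
    ),
    "pnn50": IndexLaw(
        ScalingLaw(0.037, 0.78), ScalingLaw(5.0, -1.1), 12.0, 0.37, 0.41
    ),
}

#: Published branch sample sizes accompanying PUBLISHED_LAWS
#: (child branch, adult branch; one-branch laws store a single count).
PUBLISHED_N: dict[str, tuple[int, ...]] = {
    "mean_rr": (560,),
    "sd_rr": (177, 435),
    "rmssd": (116, 268),
    "pnn50": (129, 257),
}

#: Published sex-specific laws above 12 years (log10 residual sd, N).
PUBLISHED_GENDER_LAWS: dict[str, dict[str, tuple[ScalingLaw, float, int]]] = {
    "sd_rr": {
        "male": (ScalingLaw(398.0, -0.28), 0.1, 123),
        "female": (ScalingLaw(229.0, -0.17), 0.1, 148),
    },
    "rmssd": {
        "male": (ScalingLaw(200.0, -0.54), 0.14, 125),
        "female": (ScalingLaw(160.0, -0.45), 0.16, 143),
    },
    "pnn50": {
        "male": (ScalingLaw(12.0, -1.4), 0.36, 124),
        "female": (ScalingLaw(1.7, -0.8), 0.46, 133),
    },
}

#: Age histogram of the recruited cohort (bin lower edge, upper edge,
#: count); usable as ``age_sampling`` for more realistic age mixes.
STUDY_AGE_HISTOGRAM: list[tuple[float, float, int]] = [
    (0.08, 0.17, 16),
    (0.17, 0.42, 28),
    (0.42, 0.67, 17),
    (0.67, 1.0, 12),
    (1.0, 2.0, 14),
    (2.0, 4.0, 14),
    (4.0, 7.0, 13),
    (7.0, 12.0, 17),
    (12.0, 30.0, 15),
    (30.0, 55.0, 8),
]


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a synthetic (age, sex, index value) population.

    ``age_sampling`` is ``"log-uniform"`` (default: both extremes of
    life are equally represented per decade) or a histogram given as a
    sequence of ``(lo, hi, count)`` bins.  ``laws`` maps index names to
    :class:`IndexLaw`; ``sex_laws`` optionally maps index names to
    per-sex :class:`ScalingLaw` pairs applied above the breakpoint.
    """

    n_subjects: int
    laws: dict
    age_range: tuple[float, float] = (0.08, 99.0)
    age_sampling: Union[str, Sequence[tuple[float, float, int]]] = "log-uniform"
    sex_laws: Optional[dict] = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise ValueError("age_range must satisfy 0 < lo < hi")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        for name, law in self.laws.items():
            if law.breakpoint is not None and not (
                lo < law.breakpoint < hi or self.sex_laws
            ):
                raise ValueError(
                    f"law {name!r}: breakpoint {law.breakpoint} outside "
                    f"age_range {self.age_range}"
                )


def sample_ages(
    n: int,
    age_range: tuple[float, float],
    sampling: Union[str, Sequence[tuple[float, float, int]]],
    rng: np.random.Generator,
) -> np.ndarray:
    lo, hi = age_range
    if isinstance(sampling, str):
        if sampling != "log-uniform":
            raise ValueError(f"unknown age sampling {sampling!r}")
        return 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
    bins = list(sampling)
    counts = np.array([c for _, _, c in bins], float)
    which = rng.choice(len(bins), size=n, p=counts / counts.sum())
    lows = np.array([b[0] for b in bins])
    highs = np.array([b[1] for b in bins])
    ages = rng.uniform(lows[which], highs[which])
    return np.clip(ages, lo, hi)


def synth_index_branches(
    law: IndexLaw,
    n_child: int,
    n_adult: int,
    age_range: tuple[float, float] = (0.08, 99.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one index with prescribed per-branch sample sizes.

    Published two-branch fits report separate record counts below and
    above the breakpoint; this draws ``n_child`` ages log-uniformly
    over [age_range[0], breakpoint) and ``n_adult`` over
    (breakpoint, age_range[1]], with the branch law and branch
    residual sd applied to each.  Returns ``(ages, values)``.
    """
    if law.adult is None:
        raise ValueError("synth_index_branches needs a two-branch law")
    rng = np.random.default_rng(seed)
    lo, hi = age_range
    bp = law.breakpoint
    ages_c = 10 ** rng.uniform(np.log10(lo), np.log10(bp), n_child)
    ages_a = 10 ** rng.uniform(np.log10(bp), np.log10(hi), n_adult)
    sd_a = law.sd_child if law.sd_adult is None else law.sd_adult
    vals_c = law.child(ages_c) * 10 ** rng.normal(0.0, law.sd_child, n_child)
    vals_a = law.adult(ages_a) * 10 ** rng.normal(0.0, sd_a, n_adult)
    return np.concatenate([ages_c, ages_a]), np.concatenate([vals_c, vals_a])


def synth_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a synthetic population table.

    Returns a long-format DataFrame with columns ``age_years``,
    ``sex``, ``index_name``, ``value``, ``source``.  Values follow the
    branch law for the subject's age times ``10**eps`` with
    ``eps ~ Normal(0, sd_log10)`` — multiplicative scatter, so values
    stay positive and the residual sd lands in log10 space where the
    fits operate.  Ages exactly at a breakpoint use the child branch.
    When sex-specific laws are given for an index they replace the
    adult branch above the breakpoint for that subject's sex.
    """
    rng = np.random.default_rng(spec.seed)
    ages = sample_ages(spec.n_subjects, spec.age_range, spec.age_sampling, rng)
    if spec.sex_laws:
        sexes = rng.choice(["male", "female"], size=spec.n_subjects)
    else:
        sexes = np.full(spec.n_subjects, "unknown", dtype=object)
    records = []
    for name, law in spec.laws.items():
        mean = law.mean_curve(ages)
        sd = law.sd_log10(ages)
        if spec.sex_laws and name in spec.sex_laws:
            cut = law.breakpoint if law.breakpoint is not None else -np.inf
            for sex, sex_law in spec.sex_laws[name].items():
                if isinstance(sex_law, tuple):  # accept PUBLISHED_GENDER_LAWS entries
                    sex_law = sex_law[0]
                sel = (sexes == sex) & (ages > cut)
                mean = np.where(sel, sex_law(ages), mean)
        eps = rng.normal(0.0, 1.0, size=spec.n_subjects) * sd
        values = mean * 10**eps
        records.append(
            pd.DataFrame(
                {
                    "age_years": ages,
                    "sex": sexes,
                    "index_name": name,
                    "value": values,
                    "source": "synthetic",
                }
            )
        )
    return pd.concat(records, ignore_index=True)
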