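"""Per-subject orchestration and the unified q statistic.

Theory relates the spectral exponent of a stationary power-law series
to its DFA exponent by beta = 2*alpha - 1.  The consistency ratio

    q = beta / (2*alpha2 - 1)

equals 1 when the relation holds over compatible scale ranges; alpha2
(the medium-frequency DFA exponent, scales 50-200 beats) is used
because it is the exponent whose scale range best overlaps the
frequency range used for beta.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dfa import DfaExponents, alpha_suite
from .io import RRSeries, screen_record
from .spectral import (
    DEFAULT_FIT_RANGE_HZ,
    BetaFit,
    averaged_periodogram,
    fit_beta,
    select_fit_range,
)
from .time_domain import TimeDomainIndices, compute_time_domain

__all__ = ["SubjectSummary", "compute_q", "summarize_subject", "summaries_to_frame"]

_Q_DENOM_TOL = 1e-6


def compute_q(beta: float, alpha2: float) -> float:
    """q = beta / (2*alpha2 - 1); undefined when alpha2 is near 1/2."""
    denom = 2.0 * alpha2 - 1.0
    if abs(denom) <= _Q_DENOM_TOL:
        raise ValueError(
            f"alpha2 = {alpha2} too close to 0.5 for a defined q "
            f"(|2*alpha2 - 1| <= {_Q_DENOM_TOL})"
        )
    return beta / denom


@dataclass
class SubjectSummary:
    """All per-subject measurements; failed stages are None with a reason."""

    subject_id: str
    age_years: Optional[float]
    sex: str
    indices: Optional[TimeDomainIndices] = None
    beta_fit: Optional[BetaFit] = None
    alphas: Optional[DfaExponents] = None
    q: Optional[float] = None
    failures: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def summarize_subject(
    series: RRSeries,
    *,
    segment_length: int = 4096,
    dfa_order: int = 1,
    beta_range: Union[tuple[float, float], str] = DEFAULT_FIT_RANGE_HZ,
    screen: bool = True,
    night_window: Optional[tuple[float, float]] = None,
) -> SubjectSummary:
    """Run the full per-subject pipeline, degrading gracefully.

    ``beta_range`` is either a fixed ``(f_lo, f_hi)`` in Hz or the
    string ``"auto"`` to select the per-subject optimal window.  Stages
    that cannot run (e.g. a series too short for one spectral segment)
    are recorded as absent with a machine-readable reason in
    ``failures`` — never as zero.  A failed quality screen is an error
    unless ``screen=False``.
    """
    summary = SubjectSummary(
        subject_id=series.subject_id, age_years=series.age_years, sex=series.sex
    )
    if screen:
        report = screen_record(series, night_window=night_window)
        if not report.passed:
            raise ValueError(
                f"screen: record failed the quality screen "
                f"(pause_violation={report.pause_violation}, "
                f"min_rate_violation={report.min_rate_violation}); "
                f"pass screen=False to override"
            )

    try:
        summary.indices = compute_time_domain(series)
    except ValueError as exc:
        summary.failures["time_domain"] = str(exc)

    try:
        spectrum = averaged_periodogram(series, segment_length=segment_length)
        if beta_range == "auto":
            rng = select_fit_range(spectrum)
        else:
            rng = beta_range
        summary.beta_fit = fit_beta(spectrum, rng)
    except ValueError as exc:
        summary.failures["spectral_beta"] = str(exc)

    try:
        summary.alphas = alpha_suite(series, m=dfa_order)
    except ValueError as exc:
        summary.failures["dfa"] = str(exc)

    if summary.beta_fit is not None and summary.alphas is not None:
        try:
            summary.q = compute_q(summary.beta_fit.beta, summary.alphas.alpha2)
        except ValueError as exc:
            summary.failures["q"] = str(exc)
    return summary


def summaries_to_frame(summaries: Sequence[SubjectSummary]) -> pd.DataFrame:
    """Flatten summaries to one wide row per subject (population input)."""
    rows = []
    for s in summaries:
        row = {
            "subject_id": s.subject_id,
            "age_years": s.age_years,
            "sex": s.sex,
            "q": s.q,
        }
        if s.indices is not None:
            row.update(dataclasses.asdict(s.indices))
        else:
            row.update(
                {k: np.nan for k in ("mean_rr", "sd_rr", "rmssd", "pnn50")}
            )
        row["beta"] = s.beta_fit.beta if s.beta_fit is not None else np.nan
        if s.alphas is not None:
            row.update(
                alpha0=s.alphas.alpha0, alpha1=s.alphas.alpha1, alpha2=s.alphas.alpha2
            )
        else:
            row.update(alpha0=np.nan, alpha1=np.nan, alpha2=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
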