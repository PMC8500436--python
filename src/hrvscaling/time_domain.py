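"""Linear time-domain HRV indices.

The four classical indices are computed on the complete, un-detrended
interval sequence: the mean RR interval, the standard deviation of all
intervals (SDNN), the root mean square of successive differences
(rMSSD), and the percentage of successive pairs differing by more than
50 ms (pNN50).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .io import RRSeries

__all__ = ["TimeDomainIndices", "compute_time_domain"]


@dataclass(frozen=True)
class TimeDomainIndices:
    """The four linear time-domain indices, all in ms except pNN50 (%)."""

    mean_rr: float
    sd_rr: float
    rmssd: float
    pnn50: float


def compute_time_domain(series: Union[RRSeries, np.ndarray]) -> TimeDomainIndices:
    """Compute mean RR, SDNN, rMSSD and pNN50 for one record.

    The standard deviation uses the sample convention (n-1 divisor),
    following HRV practice for SDNN.  rMSSD is the square root of the
    mean of the n-1 squared successive differences, and pNN50 counts
    absolute successive differences strictly greater than 50 ms.  No
    detrending, windowing or beat exclusion is applied.
    """
    x = series.intervals if isinstance(series, RRSeries) else np.asarray(series, float)
    if x.size < 2:
        raise ValueError("need at least 2 intervals (successive differences undefined)")
    diffs = np.diff(x)
    return TimeDomainIndices(
        mean_rr=float(x.mean()),
        sd_rr=float(x.std(ddof=1)),
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        pnn50=float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / diffs.size),
    )
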