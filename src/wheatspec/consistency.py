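"""Cross-instrument agreement of vegetation indices.

A portable three-band sensor is checked against a reference
spectroradiometer by pairing the two instruments' index values record by
record, min–max normalizing each side to [0, 1] (so indices with different
natural ranges, e.g. RVI vs NDVI, share one axis), and fitting the
portable-sensor values on the reference values by ordinary least squares.
Perfect agreement gives slope 1, intercept 0, R² 1 and RRMSE 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import rrmse
from .errors import DegenerateDataError

__all__ = [
    "PairedIndexSeries",
    "ConsistencyResult",
    "minmax_normalize",
    "linear_consistency",
    "consistency_table",
]


@dataclass
class PairedIndexSeries:
    """Record-paired index values from the test and reference instruments."""

    vi_name: str
    test_values: np.ndarray
    reference_values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.test_values, dtype=float)
        r = np.asarray(self.reference_values, dtype=float)
        if t.shape != r.shape or t.ndim != 1 or t.size < 3:
            raise ValueError(
                "test and reference series must be equal-length 1-d arrays "
                "with at least 3 paired values"
            )
        self.test_values = t
        self.reference_values = r


@dataclass(frozen=True)
class ConsistencyResult:
    vi_name: str
    slope: float
    intercept: float
    r2: float
    rrmse: float
    n: int


def minmax_normalize(values) -> np.ndarray:
    """Rescale a series to [0, 1] by (v − min)/(max − min)."""
    v = np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise DegenerateDataError("constant series cannot be min-max normalized")
    return (v - lo) / (hi - lo)


def linear_consistency(series: PairedIndexSeries) -> ConsistencyResult:
    """OLS of normalized test values on normalized reference values."""
    ref = minmax_normalize(series.reference_values)
    test = minmax_normalize(series.test_values)
    res = stats.linregress(ref, test)
    fitted = res.slope * ref + res.intercept
    return ConsistencyResult(
        vi_name=series.vi_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        rrmse=rrmse(test, fitted),
        n=test.size,
    )


def consistency_table(series_list) -> pd.DataFrame:
    """Per-index consistency metrics as one table."""
    rows = []
    for series in series_list:
        res = linear_consistency(series)
        rows.append(
            {"vi_name": res.vi_name, "slope": res.slope,
             "intercept": res.intercept, "r2": res.r2,
             "rrmse": res.rrmse, "n": res.n}
        )
    return pd.DataFrame(rows, columns=["vi_name", "slope", "intercept",
                                       "r2", "rrmse", "n"])
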