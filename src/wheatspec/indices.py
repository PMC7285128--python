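"""Two-band and three-band vegetation indices from 660/730/815 nm reflectance.

The two-band indices are the classical NDVI, RVI and DVI, computed for all
three band pairs. The three-band indices TVI-1 and TVI-2 follow the NDVI/DVI
construction with the red band replaced by the sum of red and red-edge
reflectance and the near-infrared term doubled to keep the magnitudes
comparable:

    NDVI  = (ρ1 − ρ2) / (ρ1 + ρ2)
    RVI   = ρ1 / ρ2
    DVI   = ρ1 − ρ2
    TVI-1 = (2·ρNIR − ρred − ρred-edge) / (2·ρNIR + ρred + ρred-edge)
    TVI-2 = 2·ρNIR − ρred − ρred-edge

For a pair written (λa, λb) with λa < λb, ρ1 is the longer-wavelength band,
so healthy canopies yield positive NDVI/DVI and RVI > 1. TVI band roles are
fixed: ρNIR = 815 nm, ρred = 660 nm, ρred-edge = 730 nm.

Functions accept scalars or numpy arrays; undefined denominators raise
:class:`~wheatspec.errors.UndefinedIndexError` rather than producing NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core_data import Dataset, ReflectanceTriplet
from .errors import UndefinedIndexError

__all__ = [
    "VIValue",
    "VI_NAMES",
    "BAND_PAIRS",
    "ndvi", "rvi", "dvi", "tvi1", "tvi2",
    "compute_index", "compute_all", "append_indices", "vi_series",
]

BAND_PAIRS = ((660, 730), (660, 815), (730, 815))

#: Canonical ordered names of the 11 indices the instrument supports.
VI_NAMES = tuple(
    [f"{kind}({a},{b})" for kind in ("NDVI", "RVI", "DVI") for a, b in BAND_PAIRS]
    + ["TVI1", "TVI2"]
)


@dataclass(frozen=True)
class VIValue:
    """A named vegetation-index value for one reflectance observation."""

    name: str
    value: float
    band_pair: Optional[tuple[int, int]] = None  # None for TVI1/TVI2


def _check_denominator(den, what: str):
    if np.any(np.asarray(den) == 0):
        raise UndefinedIndexError(f"{what}: zero denominator")


def ndvi(rho1, rho2):
    """(ρ1 − ρ2)/(ρ1 + ρ2); ρ1 is the longer-wavelength band."""
    rho1, rho2 = np.asarray(rho1, float), np.asarray(rho2, float)
    _check_denominator(rho1 + rho2, "NDVI")
    out = (rho1 - rho2) / (rho1 + rho2)
    return float(out) if out.ndim == 0 else out


def rvi(rho1, rho2):
    """ρ1/ρ2."""
    rho1, rho2 = np.asarray(rho1, float), np.asarray(rho2, float)
    _check_denominator(rho2, "RVI")
    out = rho1 / rho2
    return float(out) if out.ndim == 0 else out


def dvi(rho1, rho2):
    """ρ1 − ρ2."""
    out = np.asarray(rho1, float) - np.asarray(rho2, float)
    return float(out) if out.ndim == 0 else out


def tvi1(rho_nir, rho_red, rho_rededge):
    """(2·ρNIR − ρred − ρred-edge)/(2·ρNIR + ρred + ρred-edge)."""
    n = np.asarray(rho_nir, float)
    r = np.asarray(rho_red, float)
    e = np.asarray(rho_rededge, float)
    den = 2.0 * n + r + e
    _check_denominator(den, "TVI1")
    out = (2.0 * n - r - e) / den
    return float(out) if out.ndim == 0 else out


def tvi2(rho_nir, rho_red, rho_rededge):
    """2·ρNIR − ρred − ρred-edge."""
    out = (2.0 * np.asarray(rho_nir, float)
           - np.asarray(rho_red, float)
           - np.asarray(rho_rededge, float))
    return float(out) if out.ndim == 0 else out


_BAND_ATTR = {660: 0, 730: 1, 815: 2}


def compute_index(name: str, r660, r730, r815):
    """Evaluate one named index on reflectance scalars or arrays."""
    bands = {660: r660, 730: r730, 815: r815}
    if name == "TVI1":
        return tvi1(r815, r660, r730)
    if name == "TVI2":
        return tvi2(r815, r660, r730)
    kind, _, rest = name.partition("(")
    try:
        a, b = (int(x) for x in rest.rstrip(")").split(","))
        func = {"NDVI": ndvi, "RVI": rvi, "DVI": dvi}[kind]
    except (ValueError, KeyError):
        raise KeyError(f"unknown vegetation index {name!r}") from None
    # rho1 is the longer-wavelength band of the pair
    return func(bands[max(a, b)], bands[min(a, b)])


def compute_all(triplet: ReflectanceTriplet) -> list[VIValue]:
    """All 11 named indices for one reflectance triplet.

    Undefined indices raise, tagging which index failed.
    """
    out = []
    for name in VI_NAMES:
        try:
            v = compute_index(name, *triplet.as_tuple())
        except UndefinedIndexError as exc:
            raise UndefinedIndexError(f"{name} undefined: {exc}") from None
        pair = None
        if "(" in name:
            a, b = name[name.index("(") + 1:-1].split(",")
            pair = (int(a), int(b))
        out.append(VIValue(name=name, value=v, band_pair=pair))
    return out


def vi_series(data: Dataset, name: str) -> np.ndarray:
    """One named index evaluated over every record of a dataset."""
    r660, r730, r815 = data.reflectance_arrays()
    return np.asarray(compute_index(name, r660, r730, r815), dtype=float)


def append_indices(df: pd.DataFrame) -> pd.DataFrame:
    """Append the 11 index columns to a plot-record data frame."""
    out = df.copy()
    for name in VI_NAMES:
        out[name] = compute_index(name, df["r660"].to_numpy(),
                                  df["r730"].to_numpy(),
                                  df["r815"].to_numpy())
    return out
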