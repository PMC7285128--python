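"""Domain types and delimited-text I/O for plot-level wheat field records.

One record is a single plot observed at a single phenological stage: the
treatment metadata (nitrogen rate, planting density, replicate), the canopy
reflectance triplet at 660/730/815 nm, and — when destructive sampling was
done — the four growth indices LAI, LDW, LNC and LNA.

Units: LAI is dimensionless leaf area per ground area; LDW is leaf dry
weight in g·m⁻²; LNC is leaf nitrogen content as a percent of dry mass;
LNA is leaf nitrogen accumulation in g·m⁻², defined by the identity
LNA = (LNC/100) × LDW.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "NitrogenLevel",
    "Density",
    "GrowthStage",
    "Treatment",
    "ReflectanceTriplet",
    "GrowthIndices",
    "PlotRecord",
    "Dataset",
    "GROWTH_INDEX_NAMES",
    "read_records",
    "write_records",
    "check_lna_identity",
]

GROWTH_INDEX_NAMES = ("lai", "ldw", "lnc", "lna")

#: Fixed CSV schema (comma-delimited, "." decimal, UTF-8).
REQUIRED_COLUMNS = (
    "plot_id", "replicate", "nitrogen", "density", "stage",
    "r660", "r730", "r815",
)
GROWTH_COLUMNS = GROWTH_INDEX_NAMES
ALL_COLUMNS = REQUIRED_COLUMNS + GROWTH_COLUMNS


class NitrogenLevel(str, enum.Enum):
    """Pure-nitrogen application rate level."""

    N0 = "N0"  # 0 kg/hm^2
    N1 = "N1"  # 180 kg/hm^2
    N2 = "N2"  # 360 kg/hm^2

    @property
    def rate_kg_per_hm2(self) -> float:
        return {"N0": 0.0, "N1": 180.0, "N2": 360.0}[self.value]


class Density(str, enum.Enum):
    """Planting density expressed as line spacing."""

    D1 = "D1"  # 20 cm
    D2 = "D2"  # 35 cm
    D3 = "D3"  # 50 cm

    @property
    def line_spacing_cm(self) -> float:
        return {"D1": 20.0, "D2": 35.0, "D3": 50.0}[self.value]


class GrowthStage(enum.IntEnum):
    """Wheat phenological stage, totally ordered by calendar progression."""

    JOINTING = 1
    BOOTING = 2
    HEADING = 3
    FLOWERING = 4

    @property
    def token(self) -> str:
        return self.name.lower()

    @classmethod
    def from_token(cls, token: str) -> "GrowthStage":
        try:
            return cls[str(token).strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown growth stage {token!r}") from None


ALL_STAGES = tuple(GrowthStage)


@dataclass(frozen=True)
class Treatment:
    """Split-plot treatment cell: nitrogen level × density × replicate."""

    nitrogen: NitrogenLevel
    density: Density
    replicate: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "nitrogen", NitrogenLevel(self.nitrogen))
        object.__setattr__(self, "density", Density(self.density))
        if int(self.replicate) < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        object.__setattr__(self, "replicate", int(self.replicate))


@dataclass(frozen=True)
class ReflectanceTriplet:
    """Calibrated canopy reflectance at 660, 730 and 815 nm, each in [0, 1]."""

    r660: float
    r730: float
    r815: float

    def __post_init__(self) -> None:
        for band in ("r660", "r730", "r815"):
            v = float(getattr(self, band))
            if not math.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"reflectance {band}={v!r} outside [0, 1]"
                )
            object.__setattr__(self, band, v)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r660, self.r730, self.r815)


@dataclass(frozen=True)
class GrowthIndices:
    """Measured growth indices for one plot × stage; fields may be absent.

    The identity lna = lnc/100 × ldw is *not* enforced at construction so
    that measured (possibly inconsistent) records remain representable;
    audit a dataset with :func:`check_lna_identity`.
    """

    lai: Optional[float] = None
    ldw: Optional[float] = None
    lnc: Optional[float] = None
    lna: Optional[float] = None

    def __post_init__(self) -> None:
        for name in GROWTH_INDEX_NAMES:
            v = getattr(self, name)
            if v is None:
                continue
            v = float(v)
            if not math.isfinite(v) or v < 0.0:
                raise ValidationError(
                    f"growth index {name}={v!r} must be finite and >= 0"
                )
            object.__setattr__(self, name, v)

    def get(self, name: str) -> Optional[float]:
        if name not in GROWTH_INDEX_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class PlotRecord:
    """One plot observed at one growth stage."""

    plot_id: str
    treatment: Treatment
    stage: GrowthStage
    reflectance: ReflectanceTriplet
    growth: Optional[GrowthIndices] = None

    def __post_init__(self) -> None:
        if not str(self.plot_id):
            raise ValidationError("plot_id must be non-empty")
        object.__setattr__(self, "plot_id", str(self.plot_id))
        object.__setattr__(self, "stage", GrowthStage(self.stage))


@dataclass
class Dataset:
    """Ordered collection of plot records with a provenance tag."""

    records: list[PlotRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, GrowthStage]] = set()
        for rec in self.records:
            key = (rec.plot_id, rec.stage)
            if key in seen:
                raise ValidationError(
                    f"duplicate (plot_id, stage) = ({rec.plot_id!r}, "
                    f"{rec.stage.token})"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PlotRecord]:
        return iter(self.records)

    @property
    def plot_ids(self) -> list[str]:
        """Distinct plot ids in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for rec in self.records:
            if rec.plot_id not in seen:
                seen.add(rec.plot_id)
                out.append(rec.plot_id)
        return out

    def subset(self, indices: list[int], provenance: str | None = None) -> "Dataset":
        return Dataset(
            [self.records[i] for i in indices],
            provenance if provenance is not None else self.provenance,
        )

    def filter_stages(self, stages) -> "Dataset":
        stages = set(stages)
        return Dataset(
            [r for r in self.records if r.stage in stages], self.provenance
        )

    def growth_values(self, name: str) -> np.ndarray:
        """Array of one growth index over all records; raises if any missing."""
        vals = []
        for rec in self.records:
            v = None if rec.growth is None else rec.growth.get(name)
            if v is None:
                raise ValidationError(
                    f"record ({rec.plot_id!r}, {rec.stage.token}) lacks "
                    f"growth index {name!r}"
                )
            vals.append(v)
        return np.asarray(vals, dtype=float)

    def reflectance_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        r = np.array([rec.reflectance.as_tuple() for rec in self.records])
        return r[:, 0], r[:, 1], r[:, 2]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            g = rec.growth or GrowthIndices()
            rows.append(
                {
                    "plot_id": rec.plot_id,
                    "replicate": rec.treatment.replicate,
                    "nitrogen": rec.treatment.nitrogen.value,
                    "density": rec.treatment.density.value,
                    "stage": rec.stage.token,
                    "r660": rec.reflectance.r660,
                    "r730": rec.reflectance.r730,
                    "r815": rec.reflectance.r815,
                    "lai": g.lai,
                    "ldw": g.ldw,
                    "lnc": g.lnc,
                    "lna": g.lna,
                }
            )
        return pd.DataFrame(rows, columns=list(ALL_COLUMNS))


def _record_from_row(row: pd.Series, idx: int) -> PlotRecord:
    def _num(col: str, lo: float | None = None, hi: float | None = None,
             required: bool = True) -> Optional[float]:
        raw = row[col]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or (
            isinstance(raw, str) and raw.strip() == ""
        ):
            if required:
                raise ValidationError(f"row {idx}: missing value in {col!r}")
            return None
        try:
            v = float(raw)
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {idx}: non-numeric value {raw!r} in column {col!r}"
            ) from None
        if not math.isfinite(v):
            raise ValidationError(f"row {idx}: non-finite value in {col!r}")
        if (lo is not None and v < lo) or (hi is not None and v > hi):
            raise ValidationError(
                f"row {idx}: {col}={v} outside [{lo}, {hi}]"
            )
        return v

    try:
        treatment = Treatment(
            nitrogen=NitrogenLevel(str(row["nitrogen"]).strip()),
            density=Density(str(row["density"]).strip()),
            replicate=int(row["replicate"]),
        )
    except (ValueError, ValidationError) as exc:
        raise ValidationError(f"row {idx}: {exc}") from None

    reflectance = ReflectanceTriplet(
        r660=_num("r660", 0.0, 1.0),
        r730=_num("r730", 0.0, 1.0),
        r815=_num("r815", 0.0, 1.0),
    )
    growth_vals = {name: _num(name, lo=0.0, required=False)
                   for name in GROWTH_COLUMNS}
    growth = (GrowthIndices(**growth_vals)
              if any(v is not None for v in growth_vals.values()) else None)
    return PlotRecord(
        plot_id=str(row["plot_id"]),
        treatment=treatment,
        stage=GrowthStage.from_token(str(row["stage"])),
        reflectance=reflectance,
        growth=growth,
    )


def read_records(path, delimiter: str = ",", provenance: str | None = None) -> Dataset:
    """Read plot records from a delimited text file.

    The header must name at least the required columns
    (plot_id, replicate, nitrogen, density, stage, r660, r730, r815);
    the growth-index columns (lai, ldw, lnc, lna) are optional per row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"plot_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in GROWTH_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    records = [_record_from_row(row, idx) for idx, row in df.iterrows()]
    return Dataset(records, provenance if provenance is not None else str(path))


def write_records(data: Dataset, path, delimiter: str = ",") -> Path:
    """Write a dataset as delimited text, re-readable by :func:`read_records`.

    Floats are written with 12 significant digits, so a round trip preserves
    values well past the 10-significant-digit contract.
    """
    if len(data) == 0:
        raise ValidationError("refusing to serialize an empty dataset")
    path = Path(path)
    df = data.to_frame()
    df.to_csv(path, sep=delimiter, index=False, float_format="%.12g",
              encoding="utf-8")
    return path


class LnaCheckResult(list):
    """List of violating (plot_id, stage-token) identifiers.

    Records missing any of lnc/ldw/lna are skipped and listed in
    ``.skipped``.
    """

    def __init__(self, violations, skipped):
        super().__init__(violations)
        self.skipped: list[tuple[str, str]] = list(skipped)


def check_lna_identity(data: Dataset, rel_tol: float = 1e-9) -> LnaCheckResult:
    """Audit the identity LNA = LNC/100 × LDW across a dataset.

    Returns the identifiers of records where
    ``|lna − lnc/100·ldw| / max(lna, ε) > rel_tol``; an empty result means
    the identity holds everywhere it is checkable.
    """
    eps = 1e-12
    violations, skipped = [], []
    for rec in data:
        g = rec.growth
        ident = (rec.plot_id, rec.stage.token)
        if g is None or g.lnc is None or g.ldw is None or g.lna is None:
            skipped.append(ident)
            continue
        expected = g.lnc / 100.0 * g.ldw
        if abs(g.lna - expected) / max(g.lna, eps) > rel_tol:
            violations.append(ident)
    return LnaCheckResult(violations, skipped)
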