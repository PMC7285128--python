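"""Growth-stage-segmented monitoring models.

Vegetation indices saturate once the canopy closes, so a single exponential
model fitted across the whole season under-predicts large growth-index
values. Segmenting the season into an early period (period I) and a late
period (period II) — with the boundary chosen per growth index from the
stage-wise dynamics of that index — and fitting each period independently
recovers sensitivity in the late, saturation-prone period.

For growth indices whose early-period fit is no better than the whole-season
model evaluated on the same early records (typically LDW and LNA, whose
period I is a single stage with a narrow data range), prediction in period I
falls back to the whole-season model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .calibration import (
    EvaluationReport,
    ModelFit,
    evaluate_model,
    fit_model,
    r_squared,
    rrmse as _rrmse,
)
from .core_data import Dataset, GrowthStage, GROWTH_INDEX_NAMES
from .errors import DegenerateDataError, WheatspecError
from .indices import VI_NAMES, vi_series

__all__ = [
    "PeriodMap",
    "StagedModel",
    "DEFAULT_BEST_VI",
    "default_period_map",
    "default_best_vi",
    "select_best_vi",
    "fit_staged",
    "predict_staged",
    "evaluate_staged",
]

MIN_PERIOD_RECORDS = 3  # an exponential fit needs >= 3 points


@dataclass(frozen=True)
class PeriodMap:
    """Partition of the four stages into an early and a late period."""

    growth_index: str
    period1_stages: frozenset
    period2_stages: frozenset

    def __post_init__(self) -> None:
        p1 = frozenset(GrowthStage(s) for s in self.period1_stages)
        p2 = frozenset(GrowthStage(s) for s in self.period2_stages)
        if p1 | p2 != set(GrowthStage) or p1 & p2:
            raise ValueError("periods must partition the four growth stages")
        if max(p1) >= min(p2):
            raise ValueError("period I stages must all precede period II stages")
        object.__setattr__(self, "period1_stages", p1)
        object.__setattr__(self, "period2_stages", p2)

    def period_of(self, stage: GrowthStage) -> int:
        return 1 if GrowthStage(stage) in self.period1_stages else 2


_J, _B, _H, _F = (GrowthStage.JOINTING, GrowthStage.BOOTING,
                  GrowthStage.HEADING, GrowthStage.FLOWERING)

#: Per-index period partitions derived from the stage-wise index dynamics:
#: LAI plateaus after heading, LDW and LNA jump between jointing and booting
#: then stabilize, LNC is nearly stage-invariant but splits mid-season.
_DEFAULT_PERIODS = {
    "lai": ({_J, _B}, {_H, _F}),
    "ldw": ({_J}, {_B, _H, _F}),
    "lnc": ({_J, _B}, {_H, _F}),
    "lna": ({_J}, {_B, _H, _F}),
}

#: Vegetation index with the highest whole-season prediction accuracy
#: per growth index.
DEFAULT_BEST_VI = {
    "lai": "TVI2",
    "ldw": "TVI1",
    "lnc": "NDVI(730,815)",
    "lna": "NDVI(730,815)",
}


def default_period_map(growth_index: str) -> PeriodMap:
    if growth_index not in GROWTH_INDEX_NAMES:
        raise KeyError(f"unknown growth index {growth_index!r}")
    p1, p2 = _DEFAULT_PERIODS[growth_index]
    return PeriodMap(growth_index, frozenset(p1), frozenset(p2))


def default_best_vi(growth_index: str) -> str:
    if growth_index not in DEFAULT_BEST_VI:
        raise KeyError(f"unknown growth index {growth_index!r}")
    return DEFAULT_BEST_VI[growth_index]


@dataclass
class StagedModel:
    """Per-period exponential fits plus whole-season fallback flags."""

    growth_index: str
    vi_name: str
    period_map: PeriodMap
    fit_whole: ModelFit
    fit_p1: Optional[ModelFit]
    fit_p2: Optional[ModelFit]
    use_whole_in_p1: bool
    use_whole_in_p2: bool = False

    def fit_for_stage(self, stage: GrowthStage) -> ModelFit:
        if self.period_map.period_of(stage) == 1:
            return self.fit_whole if self.use_whole_in_p1 else self.fit_p1
        return self.fit_whole if self.use_whole_in_p2 else self.fit_p2


def select_best_vi(train: Dataset, validation: Dataset,
                   growth_index: str) -> list[tuple[str, EvaluationReport]]:
    """Fit every index on the training set, score on validation, and rank.

    Ranking: validation R² descending, ties broken by lower RRMSE, then by
    canonical index order. Indices undefined on some record are excluded
    (collected in the returned list's ``excluded`` attribute) rather than
    aborting the screen.
    """
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("train and validation datasets must be non-empty")
    scored: list[tuple[str, EvaluationReport]] = []
    excluded: list[tuple[str, str]] = []
    for vi_name in VI_NAMES:
        try:
            fit = fit_model(train, growth_index, vi_name)
            scored.append((vi_name, evaluate_model(fit, validation)))
        except WheatspecError as exc:
            excluded.append((vi_name, str(exc)))
    scored.sort(key=lambda item: (-item[1].r2, item[1].rrmse,
                                  VI_NAMES.index(item[0])))

    class _Ranking(list):
        pass

    out = _Ranking(scored)
    out.excluded = excluded
    return out


def _whole_r2_on_subset(fit_whole: ModelFit, subset: Dataset) -> float:
    """Calibration R² of the whole-season model restricted to a stage subset."""
    y = subset.growth_values(fit_whole.growth_index)
    yhat = fit_whole.predict(vi_series(subset, fit_whole.vi_name))
    return r_squared(y, yhat, mode="calibration")


def fit_staged(train: Dataset, growth_index: str, vi_name: str,
               period_map: Optional[PeriodMap] = None,
               fallback: str = "auto") -> StagedModel:
    """Fit whole-season and per-period models for one growth index.

    The period-I fallback flag is raised when the period-I fit's calibration
    R² is below the whole-season model's calibration R² computed on the same
    period-I records (``fallback="auto"``); ``"always_whole"`` and
    ``"never"`` force the flag. A period with fewer than 3 records always
    falls back to the whole-season model, with a warning.
    """
    if period_map is None:
        period_map = default_period_map(growth_index)
    if fallback not in ("auto", "always_whole", "never"):
        raise ValueError(f"unknown fallback policy {fallback!r}")
    fit_whole = fit_model(train, growth_index, vi_name)

    sub1 = train.filter_stages(period_map.period1_stages)
    sub2 = train.filter_stages(period_map.period2_stages)

    def _fit_period(sub: Dataset, label: str):
        if len(sub) < MIN_PERIOD_RECORDS:
            warnings.warn(
                f"{growth_index}/{vi_name}: period {label} has only "
                f"{len(sub)} record(s); falling back to the whole-season model",
                stacklevel=3,
            )
            return None, True
        try:
            return fit_model(sub, growth_index, vi_name), False
        except (DegenerateDataError, WheatspecError):
            warnings.warn(
                f"{growth_index}/{vi_name}: period {label} fit degenerate; "
                "falling back to the whole-season model",
                stacklevel=3,
            )
            return None, True

    fit_p1, forced1 = _fit_period(sub1, "I")
    fit_p2, forced2 = _fit_period(sub2, "II")

    use_whole_in_p1 = forced1
    if fit_p1 is not None and fallback == "auto":
        try:
            use_whole_in_p1 = fit_p1.train_r2 < _whole_r2_on_subset(fit_whole, sub1)
        except DegenerateDataError:
            use_whole_in_p1 = True
    if fallback == "always_whole":
        use_whole_in_p1 = True
    elif fallback == "never" and fit_p1 is not None:
        use_whole_in_p1 = False

    return StagedModel(
        growth_index=growth_index,
        vi_name=vi_name,
        period_map=period_map,
        fit_whole=fit_whole,
        fit_p1=fit_p1,
        fit_p2=fit_p2,
        use_whole_in_p1=use_whole_in_p1,
        use_whole_in_p2=forced2,
    )


def predict_staged(model: StagedModel, records: Dataset) -> np.ndarray:
    """Route each record through its period's fit and predict."""
    x = vi_series(records, model.vi_name)
    preds = np.empty(len(records), dtype=float)
    for i, rec in enumerate(records):
        fit = model.fit_for_stage(rec.stage)
        preds[i] = float(fit.predict(x[i]))
    return preds


def evaluate_staged(model: StagedModel, validation: Dataset) -> EvaluationReport:
    """Pooled validation report for a staged model."""
    if len(validation) == 0:
        raise ValueError("validation dataset is empty")
    observed = validation.growth_values(model.growth_index)
    predicted = predict_staged(model, validation)
    return EvaluationReport(
        r2=r_squared(observed, predicted, mode="validation"),
        rrmse=_rrmse(observed, predicted),
        n=len(validation),
        predicted=predicted,
        observed=observed,
    )
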