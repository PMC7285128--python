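"""Exponential calibration of growth indices against vegetation indices.

Monitoring models take the form y = a·exp(b·x), where x is a vegetation
index and y a growth index (LAI, LDW, LNC or LNA). Fitting minimizes the
squared error on the original scale by nonlinear least squares, initialized
from the log-linear closed form (regress ln y on x).

Model quality is summarized by the coefficient of determination R² and the
relative root-mean-square error RRMSE = RMSE / mean(observed), reported as
a fraction. Two R² flavours are used:

* calibration mode — SSR/SST = Σ(ŷ−ȳ)² / Σ(y−ȳ)² of the fitted values;
* validation mode — the squared Pearson correlation of predicted vs
  observed values (the trend-line R² of an observed-vs-predicted scatter
  with a free intercept).

Train/validation splitting is done on whole plots so that no plot
contributes records to both sides (spatial-leakage control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .core_data import Dataset
from .errors import DegenerateDataError, DomainError, FitConvergenceError
from .indices import vi_series

__all__ = [
    "ModelFit",
    "EvaluationReport",
    "SplitResult",
    "fit_exponential",
    "predict_exponential",
    "r_squared",
    "rrmse",
    "split_by_plot",
    "fit_model",
    "evaluate_model",
]


@dataclass(frozen=True)
class ModelFit:
    """A fitted exponential monitoring model y = a·exp(b·x)."""

    growth_index: str
    vi_name: str
    coef_a: float
    coef_b: float
    n_train: int
    train_r2: float
    train_rrmse: float

    def predict(self, x) -> np.ndarray:
        return predict_exponential(self.coef_a, self.coef_b, x)


@dataclass
class EvaluationReport:
    """R², RRMSE and sample size for one (model, dataset) pair."""

    r2: float
    rrmse: float
    n: int
    predicted: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)


@dataclass
class SplitResult:
    """A plot-disjoint train/validation partition."""

    train: Dataset
    validation: Dataset
    train_fraction_requested: float
    train_count_target: int
    train_count_achieved: int

    @property
    def exact(self) -> bool:
        return self.train_count_achieved == self.train_count_target


def predict_exponential(a: float, b: float, x) -> np.ndarray:
    return a * np.exp(b * np.asarray(x, dtype=float))


def _sse(a: float, b: float, x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum((y - a * np.exp(b * x)) ** 2))


def fit_exponential(x, y) -> tuple[float, float]:
    """Least-squares fit of y = a·exp(b·x) on the original scale.

    The log-linear closed form (ordinary regression of ln y on x) seeds a
    nonlinear least-squares refinement; the returned solution is never worse
    than the initializer in squared error.

    Raises
    ------
    DomainError
        if any y ≤ 0 (the exponential family is positive).
    DegenerateDataError
        if x carries no variation.
    FitConvergenceError
        if the nonlinear solver fails; carries the initializer (a, b).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for an exponential fit")
    if np.any(y <= 0):
        raise DomainError("exponential fit requires strictly positive y")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all x values identical; design is degenerate")

    # closed-form initializer: ln y = ln a + b x
    b0, log_a0 = np.polyfit(x, np.log(y), 1)
    a0 = float(np.exp(log_a0))
    b0 = float(b0)

    def residuals(p):
        return p[0] * np.exp(p[1] * x) - y

    try:
        sol = optimize.least_squares(
            residuals, x0=[a0, b0],
            bounds=([np.finfo(float).tiny, -np.inf], [np.inf, np.inf]),
            method="trf",
        )
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise FitConvergenceError(str(exc), (a0, b0)) from exc
    if not sol.success:
        raise FitConvergenceError(
            f"nonlinear least squares did not converge: {sol.message}",
            (a0, b0),
        )
    a, b = float(sol.x[0]), float(sol.x[1])
    # guarantee the refinement never degrades the initializer
    if _sse(a, b, x, y) > _sse(a0, b0, x, y):
        a, b = a0, b0
    return a, b


def r_squared(observed, predicted,
              mode: Literal["calibration", "validation"] = "calibration") -> float:
    """Coefficient of determination in one of two modes.

    calibration: SSR/SST = Σ(ŷ−ȳ)²/Σ(y−ȳ)² of fitted values.
    validation:  squared Pearson correlation of predicted vs observed
                 (invariant under affine transforms of the predictions).

    The returned value is clipped to [0, 1].
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 2:
        raise ValueError("observed and predicted must be equal length >= 2")
    if np.ptp(o) == 0:
        raise DegenerateDataError("constant observed values: R² undefined")
    if mode == "calibration":
        sst = float(np.sum((o - o.mean()) ** 2))
        ssr = float(np.sum((p - o.mean()) ** 2))
        r2 = ssr / sst
    elif mode == "validation":
        if np.ptp(p) == 0:
            raise DegenerateDataError("constant predictions: R² undefined")
        r2 = float(stats.pearsonr(o, p).statistic ** 2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(min(max(r2, 0.0), 1.0))


def rrmse(observed, predicted) -> float:
    """Root-mean-square error divided by the mean observed value (fraction)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 1:
        raise ValueError("observed and predicted must be equal length >= 1")
    mean_o = float(o.mean())
    if mean_o <= 0:
        raise DomainError("RRMSE undefined for non-positive mean observed value")
    return float(np.sqrt(np.mean((p - o) ** 2)) / mean_o)


def split_by_plot(data: Dataset, train_fraction: float, seed: int) -> SplitResult:
    """Assign whole plots to the training set until its record count reaches
    floor(train_fraction · n); the remaining plots form the validation set.

    Plots are considered in a seeded random order. Because whole plots are
    indivisible, the exact target may be unreachable for some orderings; a
    subset-sum reachability table over the remaining plots guides the greedy
    assignment so the achieved count is always the maximum achievable count
    ≤ target (the target itself whenever any plot combination attains it),
    independent of the seed. Train and validation plot sets are disjoint by
    construction and their union is the input.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    plots = data.plot_ids
    if len(plots) < 2:
        raise DegenerateDataError("need at least 2 distinct plots to split")
    n = len(data)
    target = int(np.floor(train_fraction * n))

    rng = np.random.default_rng(seed)
    order = [plots[i] for i in rng.permutation(len(plots))]
    sizes = {p: 0 for p in plots}
    for rec in data:
        sizes[rec.plot_id] += 1

    # suffix reachability: reachable[i] = sums attainable from plots order[i:]
    k = len(order)
    reachable: list[set[int]] = [set() for _ in range(k + 1)]
    reachable[k] = {0}
    for i in range(k - 1, -1, -1):
        s = sizes[order[i]]
        nxt = reachable[i + 1]
        reachable[i] = nxt | {v + s for v in nxt if v + s <= target}
    achieved = max(reachable[0])

    train_plots: set[str] = set()
    remaining = achieved
    for i, plot in enumerate(order):
        s = sizes[plot]
        if s <= remaining and (remaining - s) in reachable[i + 1]:
            train_plots.add(plot)
            remaining -= s
    assert remaining == 0

    train_idx = [i for i, rec in enumerate(data) if rec.plot_id in train_plots]
    val_idx = [i for i, rec in enumerate(data) if rec.plot_id not in train_plots]
    tag = f"{data.provenance}|split seed={seed}"
    return SplitResult(
        train=data.subset(train_idx, provenance=tag + "|train"),
        validation=data.subset(val_idx, provenance=tag + "|validation"),
        train_fraction_requested=train_fraction,
        train_count_target=target,
        train_count_achieved=achieved,
    )


def fit_model(train: Dataset, growth_index: str, vi_name: str) -> ModelFit:
    """Fit one exponential monitoring model on a training dataset."""
    x = vi_series(train, vi_name)
    y = train.growth_values(growth_index)
    a, b = fit_exponential(x, y)
    fitted = predict_exponential(a, b, x)
    return ModelFit(
        growth_index=growth_index,
        vi_name=vi_name,
        coef_a=a,
        coef_b=b,
        n_train=len(train),
        train_r2=r_squared(y, fitted, mode="calibration"),
        train_rrmse=rrmse(y, fitted),
    )


def evaluate_model(fit: ModelFit, validation: Dataset) -> EvaluationReport:
    """Predict the growth index on a validation dataset and score it."""
    if len(validation) == 0:
        raise ValueError("validation dataset is empty")
    x = vi_series(validation, fit.vi_name)
    observed = validation.growth_values(fit.growth_index)
    predicted = fit.predict(x)
    return EvaluationReport(
        r2=r_squared(observed, predicted, mode="validation"),
        rrmse=rrmse(observed, predicted),
        n=len(validation),
        predicted=predicted,
        observed=observed,
    )
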