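"""Synthetic split-plot wheat field experiments.

Emulates a 3 nitrogen levels × 3 planting densities × 3 replicates layout
(27 plots), observed at the jointing, booting, heading and flowering stages
(108 records by default). Per plot × stage the generator:

1. draws LAI and LNC from truncated normals whose stage-wise means and
   ranges follow the observed dynamics of a wheat nitrogen × density trial,
   scaled by multiplicative treatment effects;
2. derives LDW from LAI through a noisy allometric link
   LDW = c_stage · (LAI/LAI_stage_mean)^d · ε (lognormal, mean-one ε),
   clipped to the stage range — so biomass and canopy size are correlated
   as in real canopies;
3. sets LNA = LNC/100 × LDW exactly;
4. computes latent canopy reflectance at 660/730/815 nm from LAI with a
   Beer–Lambert-style two-stream mixing model
   R(band) = R_leaf + (R_soil − R_leaf)·exp(−k·LAI),
   which saturates at high LAI exactly the way field indices do;
5. adds independent per-band Gaussian sensor noise for the portable
   instrument (larger at 660 nm, where canopy reflectance is low and the
   detector works against a weaker signal) and a small uniform-σ noise for
   the paired reference spectroradiometer.

The generator is fully deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats as sps

from .core_data import (
    ALL_STAGES,
    Dataset,
    Density,
    GrowthIndices,
    GrowthStage,
    NitrogenLevel,
    PlotRecord,
    ReflectanceTriplet,
    Treatment,
)
from .errors import ConfigError, DegenerateDataError
from .indices import VI_NAMES, compute_index
from .consistency import PairedIndexSeries

__all__ = [
    "StageTarget",
    "SyntheticConfig",
    "generate_experiment",
    "canopy_reflectance",
    "saturation_diagnostic",
    "campaign_subsample",
    "DEFAULT_STAGE_TARGETS",
]

BANDS = (660, 730, 815)


@dataclass(frozen=True)
class StageTarget:
    """Target mean and (min, max) range of one growth index at one stage."""

    mean: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo <= self.mean <= self.hi:
            raise ConfigError(
                f"infeasible target: mean {self.mean} outside "
                f"[{self.lo}, {self.hi}]"
            )


_J, _B, _H, _F = ALL_STAGES

#: Stage-wise means and ranges of the four growth indices in a wheat
#: nitrogen × density trial (jointing → flowering). The heading-stage LDW
#: range is uncertain in the source dynamics (the printed range order is
#: ambiguous); 27.83–302.18 g/m² is assigned to heading.
#: LNA targets are descriptive only: LNA is computed exactly as
#: LNC/100 × LDW, never sampled or clipped.
DEFAULT_STAGE_TARGETS: dict[str, dict[GrowthStage, StageTarget]] = {
    "lai": {
        _J: StageTarget(1.75, 0.55, 2.87),
        _B: StageTarget(2.06, 0.69, 3.88),
        _H: StageTarget(2.80, 0.80, 5.48),
        _F: StageTarget(2.98, 1.02, 5.54),
    },
    "ldw": {
        _J: StageTarget(112.13, 36.56, 199.52),
        _B: StageTarget(191.48, 53.35, 371.49),
        _H: StageTarget(144.05, 27.83, 302.18),
        _F: StageTarget(143.03, 46.64, 330.31),
    },
    "lnc": {
        _J: StageTarget(2.93, 1.7, 3.5),
        _B: StageTarget(2.77, 1.7, 3.5),
        _H: StageTarget(2.82, 1.8, 4.0),
        _F: StageTarget(2.84, 1.8, 4.0),
    },
    "lna": {
        _J: StageTarget(3.45, 0.64, 7.13),
        _B: StageTarget(5.70, 0.94, 13.27),
        _H: StageTarget(4.47, 0.55, 10.00),
        _F: StageTarget(4.51, 1.03, 11.97),
    },
}


def _default_stage_targets():
    return {k: dict(v) for k, v in DEFAULT_STAGE_TARGETS.items()}


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the synthetic experiment.

    Defaults encode the emulated trial: 3 N levels × 3 densities × 3
    replicates, four stages, band-dependent sensor noise with the 660 nm
    channel noisiest, and a wheat-typical canopy extinction coefficient.
    """

    n_reps: int = 3
    stages: tuple = ALL_STAGES
    seed: int = 0
    stage_targets: dict = field(default_factory=_default_stage_targets)
    #: bare-soil reflectance per band (LAI → 0 limit)
    soil_reflectance: dict = field(
        default_factory=lambda: {660: 0.15, 730: 0.18, 815: 0.22})
    #: dense-canopy asymptotic reflectance per band (LAI → ∞ limit)
    leaf_reflectance: dict = field(
        default_factory=lambda: {660: 0.03, 730: 0.25, 815: 0.50})
    extinction_k: float = 0.7
    #: portable-sensor noise sd per band; 660 nm is the weak-signal channel
    sensor_noise_sd: dict = field(
        default_factory=lambda: {660: 0.02, 730: 0.003, 815: 0.003})
    #: reference spectroradiometer noise sd (all bands)
    reference_noise_sd: float = 0.005
    #: multiplicative N-level effects (LDW inherits the LAI effect through
    #: the allometric link)
    n_effect: dict = field(default_factory=lambda: {
        "lai": {"N0": 0.7, "N1": 1.0, "N2": 1.3},
        "lnc": {"N0": 0.82, "N1": 1.0, "N2": 1.18},
    })
    #: multiplicative density effects (densest sowing D1 → largest canopy)
    density_effect: dict = field(default_factory=lambda: {
        "lai": {"D1": 1.15, "D2": 1.0, "D3": 0.85},
    })
    #: LAI sampling sd as a fraction of the stage range width
    lai_sd_frac: float = 0.125
    lnc_sd: float = 0.28
    #: allometric link LDW = c_stage · (LAI/LAI_mean)^d · lognormal ε
    ldw_allometry_exponent: float = 1.3
    ldw_noise_sigma: float = 0.18

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        if self.extinction_k <= 0:
            raise ConfigError("extinction_k must be > 0")
        if self.reference_noise_sd < 0 or any(
            v < 0 for v in self.sensor_noise_sd.values()
        ):
            raise ConfigError("noise standard deviations must be >= 0")
        self.stages = tuple(GrowthStage(s) for s in self.stages)
        for index, per_stage in self.stage_targets.items():
            for stage, tgt in per_stage.items():
                if not isinstance(tgt, StageTarget):
                    per_stage[stage] = StageTarget(*tgt)  # validates feasibility

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed,
                       stage_targets={k: dict(v)
                                      for k, v in self.stage_targets.items()})


def canopy_reflectance(lai, band: int, config: SyntheticConfig):
    """Latent (noise-free) canopy reflectance at one band.

    R(band) = R_leaf + (R_soil − R_leaf)·exp(−k·LAI): equals the soil
    reflectance at LAI = 0, approaches the dense-canopy asymptote as
    LAI → ∞, and is strictly monotone in LAI in between.
    """
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0):
        raise ValueError("LAI must be >= 0")
    soil = config.soil_reflectance[band]
    leaf = config.leaf_reflectance[band]
    out = leaf + (soil - leaf) * np.exp(-config.extinction_k * lai)
    return float(out) if out.ndim == 0 else out


def _truncnorm(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_experiment(
    config: Optional[SyntheticConfig] = None,
) -> tuple[Dataset, list[PairedIndexSeries]]:
    """Generate one synthetic experiment.

    Returns the plot-record dataset (portable-sensor reflectance) and, for
    each of the 11 vegetation indices, the record-paired series of
    portable-sensor vs reference-spectroradiometer index values.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    lai_t = config.stage_targets["lai"]
    ldw_t = config.stage_targets["ldw"]
    lnc_t = config.stage_targets["lnc"]

    records: list[PlotRecord] = []
    test_refl: list[tuple[float, float, float]] = []
    ref_refl: list[tuple[float, float, float]] = []

    for rep in range(1, config.n_reps + 1):
        for density in Density:
            for nitrogen in NitrogenLevel:
                plot_id = f"R{rep}-{density.value}-{nitrogen.value}"
                treatment = Treatment(nitrogen, density, rep)
                lai_mult = (config.n_effect["lai"][nitrogen.value]
                            * config.density_effect["lai"][density.value])
                lnc_mult = config.n_effect["lnc"][nitrogen.value]
                for stage in config.stages:
                    tgt = lai_t[stage]
                    sd = config.lai_sd_frac * (tgt.hi - tgt.lo)
                    mu = float(np.clip(tgt.mean * lai_mult, tgt.lo, tgt.hi))
                    lai = _truncnorm(rng, mu, sd, tgt.lo, tgt.hi)

                    ct = lnc_t[stage]
                    mu_c = float(np.clip(ct.mean * lnc_mult, ct.lo, ct.hi))
                    lnc = _truncnorm(rng, mu_c, config.lnc_sd, ct.lo, ct.hi)

                    dt = ldw_t[stage]
                    d = config.ldw_allometry_exponent
                    sig = config.ldw_noise_sigma
                    eps = float(np.exp(rng.normal(0.0, sig) - sig**2 / 2.0))
                    ldw = dt.mean * (lai / lai_t[stage].mean) ** d * eps
                    ldw = float(np.clip(ldw, dt.lo, dt.hi))

                    lna = lnc / 100.0 * ldw  # identity, exact

                    latent = {b: canopy_reflectance(lai, b, config)
                              for b in BANDS}
                    # floor at 0.001: a real detector never reports exactly
                    # zero reflectance, and ratio indices need positive bands
                    test = tuple(
                        float(np.clip(
                            latent[b] + rng.normal(0.0, config.sensor_noise_sd[b]),
                            1e-3, 1.0))
                        for b in BANDS
                    )
                    ref = tuple(
                        float(np.clip(
                            latent[b] + rng.normal(0.0, config.reference_noise_sd),
                            1e-3, 1.0))
                        for b in BANDS
                    )
                    records.append(PlotRecord(
                        plot_id=plot_id,
                        treatment=treatment,
                        stage=stage,
                        reflectance=ReflectanceTriplet(*test),
                        growth=GrowthIndices(lai=lai, ldw=ldw, lnc=lnc, lna=lna),
                    ))
                    test_refl.append(test)
                    ref_refl.append(ref)

    dataset = Dataset(records, provenance=f"synthetic seed={config.seed}")
    t = np.asarray(test_refl)
    r = np.asarray(ref_refl)
    paired = [
        PairedIndexSeries(
            vi_name=name,
            test_values=np.asarray(
                compute_index(name, t[:, 0], t[:, 1], t[:, 2])),
            reference_values=np.asarray(
                compute_index(name, r[:, 0], r[:, 1], r[:, 2])),
        )
        for name in VI_NAMES
    ]
    return dataset, paired


def campaign_subsample(data: Dataset, seed: int) -> Dataset:
    """Thin a full 27-plot × 4-stage dataset (108 records) to 91 records.

    Field campaigns rarely yield a complete plot × stage grid; this preset
    drops one randomly chosen stage record from 17 randomly chosen plots,
    leaving 17 plots with 3 records and 10 with 4 (91 total) — a size at
    which a 70% plot-disjoint train split lands on exactly 63 records.
    """
    plots = data.plot_ids
    if len(plots) != 27 or len(data) != 108:
        raise ValueError("campaign preset expects the default 27×4 design")
    rng = np.random.default_rng(seed)
    chosen = set(np.asarray(plots, dtype=object)[rng.permutation(27)[:17]])
    drop: set[int] = set()
    for plot in sorted(chosen):
        idx = [i for i, rec in enumerate(data) if rec.plot_id == plot]
        drop.add(int(rng.choice(idx)))
    keep = [i for i in range(len(data)) if i not in drop]
    return data.subset(keep, provenance=f"{data.provenance}|campaign-size")


def saturation_diagnostic(data: Dataset, vi_name: str, growth_index: str,
                          threshold: float) -> tuple[float, float]:
    """Local index sensitivity below and above a growth-index threshold.

    Returns the least-squares slopes of the vegetation index against the
    growth index on records below and above the threshold. Saturation shows
    up as ``sensitivity_high < sensitivity_low``.
    """
    from .indices import vi_series

    x = data.growth_values(growth_index)
    y = vi_series(data, vi_name)
    below = x < threshold
    above = ~below
    for side, mask in (("below", below), ("above", above)):
        if int(mask.sum()) < 10:
            raise DegenerateDataError(
                f"fewer than 10 records {side} threshold {threshold}"
            )

    def _slope(mask) -> float:
        return float(np.polyfit(x[mask], y[mask], 1)[0])

    return _slope(below), _slope(above)
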