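"""Synthetic-data generators for every input the pipeline consumes.

Each generator is a deterministic function of its parameters and the noise
seed, and is the exact forward counterpart ("adjoint") of one estimator:
fitting a noise-free generated dataset recovers the generating parameters.

Default measurement ladders match the field protocol: 14 PPFD levels from
2000 down to 0 µmol m⁻² s⁻¹ for light curves; 13 CO2 setpoints (425 down
to 50, then 500 up to 1800 ppm) for A/Ci curves; 45 s closed / 495 s open
chamber cycling logged at 1 Hz; grain weights sampled every 5 days after
anthesis. Noise is additive Gaussian; the default σ for leaf Pn is about
0.5 µmol m⁻² s⁻¹, the typical replicate scatter of such measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ricephys.chamber import ChamberSeries, ChamberSpec, ClosureSchedule, segment_closures
from ricephys.curves import CI_LADDER, PPFD_LADDER, GasExchangeCurve
from ricephys.photomodels import (
    FvCBParams,
    KineticConstants,
    LightResponseParams,
    RichardsParams,
    fvcb_pn,
    nrh_pn,
    richards_mass,
)
from ricephys.traits import TraitTable

__all__ = [
    "NoiseModel",
    "gen_light_curve",
    "gen_aci_curve",
    "gen_chamber_series",
    "gen_grain_filling",
    "gen_trial_table",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise specification: ``kind`` "gaussian" or "none",
    ``sigma`` in the units of the signal, ``seed`` for reproducibility."""

    kind: str = "none"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "none"):
            raise ValueError("kind must be 'gaussian' or 'none'")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def draw(self, n: int) -> np.ndarray:
        if self.kind == "none" or self.sigma == 0.0:
            return np.zeros(n)
        rng = np.random.default_rng(self.seed)
        return rng.normal(0.0, self.sigma, size=n)


def gen_light_curve(
    p: LightResponseParams,
    ladder=PPFD_LADDER,
    noise: NoiseModel = NoiseModel(),
    cultivar: str = "",
    stage: str = "",
    date: str = "",
) -> GasExchangeCurve:
    """Light-response curve: Pn = NRH(I) + ε on the PPFD ladder."""
    i = np.asarray(ladder, dtype=float)
    pn = np.asarray(nrh_pn(i, p)) + noise.draw(len(i))
    return GasExchangeCurve("ppfd", i, pn, cultivar, stage, date)


def gen_aci_curve(
    p: FvCBParams,
    k: KineticConstants = KineticConstants(),
    ladder=CI_LADDER,
    noise: NoiseModel = NoiseModel(),
    cultivar: str = "",
    stage: str = "",
    date: str = "",
    canonical: bool = False,
) -> GasExchangeCurve:
    """A/Ci curve: Pn = min(Wc, Wj) − Rd + ε on the CO2 setpoint ladder.

    The chamber CO2 setpoints are used directly as Ci (in a real leaf
    Ci < Ca; for synthesis the distinction is irrelevant because the same
    values are fed to the fitter).
    """
    ci = np.asarray(ladder, dtype=float)
    pn = np.asarray(fvcb_pn(ci, p, k, canonical=canonical)) + noise.draw(len(ci))
    return GasExchangeCurve("ci", ci, pn, cultivar, stage, date)


def gen_chamber_series(
    true_flux,
    spec: ChamberSpec = ChamberSpec(),
    schedule: ClosureSchedule = ClosureSchedule(),
    start_co2: float = 400.0,
    duration: float = 540.0,
    noise: NoiseModel = NoiseModel(),
    cycle_start: float = 0.0,
    chamber_id: str = "1",
    ppfd=None,
) -> ChamberSeries:
    """Per-second chamber [CO2] log under a constant or time-varying flux.

    During each closure the mole fraction falls at
    d[CO2]/dt = −flux·A_ground/n_air (the exact inverse of the estimator's
    slope→flux conversion); during open periods it sits at ``start_co2``
    (instantaneous reset — the estimator never reads open periods).
    ``true_flux`` may be a number or a callable of time (s); ``ppfd``
    likewise (optional).
    """
    t = np.arange(0.0, float(duration), 1.0)
    flux_fn = true_flux if callable(true_flux) else (lambda _t: float(true_flux))
    co2 = np.full_like(t, float(start_co2))
    windows = segment_closures(
        ChamberSeries(t, np.full_like(t, start_co2), chamber_id), schedule, cycle_start
    )
    rate = spec.ground_area / spec.n_air
    for (w0, w1) in windows:
        mask = (t >= w0) & (t < w1)
        tw = t[mask]
        # integrate the drawdown from closure start
        dt = np.diff(np.concatenate([[w0], tw]))
        fluxes = np.array([flux_fn(ti) for ti in tw])
        co2[mask] = start_co2 - rate * np.cumsum(fluxes * dt)
    co2 = co2 + noise.draw(len(t))
    co2 = np.maximum(co2, 1e-3)
    ppfd_arr = None
    if ppfd is not None:
        ppfd_fn = ppfd if callable(ppfd) else (lambda _t: float(ppfd))
        ppfd_arr = np.array([ppfd_fn(ti) for ti in t])
    return ChamberSeries(t, co2, chamber_id, ppfd_arr)


def gen_grain_filling(
    p: RichardsParams,
    interval: float = 5.0,
    t_max: float = 40.0,
    noise: NoiseModel = NoiseModel(),
):
    """Grain-weight trajectory sampled every ``interval`` days on
    [0, t_max]: returns ``(t, weight)`` arrays (days, mg grain⁻¹).

    Superior/middle/inferior grain classes are emulated by calling this
    once per parameter bundle (inferior grains: larger ``b`` = delayed
    onset, smaller ``a``).
    """
    if t_max < 3 * interval:
        raise ValueError("t_max must cover at least 3 sampling intervals")
    t = np.arange(0.0, t_max + 0.5 * interval, interval)
    w = np.asarray(richards_mass(t, p)) + noise.draw(len(t))
    return t, np.maximum(w, 1e-6)


def gen_trial_table(
    base_means: dict,
    cultivar_effect: dict | None = None,
    year_effects: dict | None = None,
    interaction: dict | None = None,
    n_reps: int = 3,
    noise: NoiseModel = NoiseModel(),
    cultivars=("test", "reference"),
    years=(2013, 2014, 2015),
    units: dict | None = None,
) -> TraitTable:
    """Balanced replicated trial table with additive effects.

    value = base + cultivar_effect + year_effect + interaction + ε, where
    ``cultivar_effect[trait]`` applies to the first (test) cultivar only,
    ``year_effects[(trait, year)]`` and ``interaction[(trait, cultivar,
    year)]`` default to 0. Emulates a 2-cultivar × multi-year trial with
    ``n_reps`` plot replicates per cell.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    cultivar_effect = cultivar_effect or {}
    year_effects = year_effects or {}
    interaction = interaction or {}
    units = units or {}
    rng = np.random.default_rng(noise.seed)
    rows = []
    for trait, base in base_means.items():
        for cv in cultivars:
            for yr in years:
                mu = base
                if cv == cultivars[0]:
                    mu += cultivar_effect.get(trait, 0.0)
                mu += year_effects.get((trait, yr), 0.0)
                mu += interaction.get((trait, cv, yr), 0.0)
                eps = (
                    rng.normal(0.0, noise.sigma, size=n_reps)
                    if noise.kind == "gaussian" and noise.sigma > 0
                    else np.zeros(n_reps)
                )
                for rep in range(n_reps):
                    rows.append(
                        {
                            "cultivar": cv,
                            "year": yr,
                            "replicate": rep + 1,
                            "trait": trait,
                            "value": mu + eps[rep],
                            "unit": units.get(trait, ""),
                        }
                    )
    return TraitTable(pd.DataFrame(rows))
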