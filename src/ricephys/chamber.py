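"""Closed-chamber canopy CO2-flux estimation.

A multi-chamber system closes a transparent chamber over a 1 m² canopy plot
for a short interval (default 45 s) while logging chamber [CO2] at 1 Hz,
then leaves it open (default 495 s) while the other chambers are measured.
During a closure, canopy net CO2 uptake draws the chamber mole fraction
down linearly; the flux per unit ground area follows from the regression
slope and the amount of air enclosed:

    F = −slope · n_air / A_ground,      n_air = P·V / (R·T)

with slope in µmol mol⁻¹ s⁻¹, so F is in µmol CO2 m⁻² ground s⁻¹ and
positive for net uptake (daytime canopy photosynthesis).

The first seconds after closure are usually discarded (imperfect mixing);
``trim_head`` defaults to 5 s and can be set to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ricephys.errors import InputDataError

__all__ = [
    "R_GAS",
    "ChamberSpec",
    "ClosureSchedule",
    "ChamberSeries",
    "FluxEstimate",
    "segment_closures",
    "estimate_slope",
    "slope_to_flux",
    "closure_fluxes",
    "flux_light_curve",
]

#: Universal gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314


@dataclass(frozen=True)
class ChamberSpec:
    """Chamber geometry and enclosed-air state.

    Defaults: 1 m × 1 m × 1.5 m chamber over 1 m² of ground, 30 °C,
    standard pressure (pressure is flagged as assumed when not logged).
    """

    length: float = 1.0
    width: float = 1.0
    height: float = 1.5
    ground_area: float = 1.0
    air_temperature: float = 303.15
    pressure: float = 101325.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("chamber volume must be positive")
        if self.ground_area <= 0:
            raise ValueError("ground_area must be positive")
        if not 250.0 < self.air_temperature < 330.0:
            raise ValueError("air_temperature must be in (250, 330) K")
        if not 8e4 < self.pressure < 1.1e5:
            raise ValueError("pressure must be in (8e4, 1.1e5) Pa")

    @property
    def volume(self) -> float:
        """Chamber volume, m³."""
        return self.length * self.width * self.height

    @property
    def n_air(self) -> float:
        """Moles of air enclosed, from the ideal-gas law."""
        return self.pressure * self.volume / (R_GAS * self.air_temperature)


@dataclass(frozen=True)
class ClosureSchedule:
    """Closure cycling: ``closed_duration`` s closed then ``open_duration``
    s open, repeating; ``n_chambers`` chambers share one controller with
    staggered phases."""

    closed_duration: float = 45.0
    open_duration: float = 495.0
    n_chambers: int = 10

    def __post_init__(self) -> None:
        if self.closed_duration <= 0:
            raise ValueError("closed_duration must be positive")
        if self.open_duration < 0:
            raise ValueError("open_duration must be nonnegative")

    @property
    def period(self) -> float:
        return self.closed_duration + self.open_duration

    def chamber_offset(self, chamber_index: int) -> float:
        """Phase offset of chamber ``chamber_index`` (0-based) when the
        chambers are measured consecutively within one period."""
        return chamber_index * self.period / self.n_chambers


@dataclass
class ChamberSeries:
    """Per-second [CO2] log from one chamber.

    ``timestamps`` in s (strictly increasing, nominally 1 Hz), ``co2`` in
    µmol mol⁻¹, optional per-second PPFD.
    """

    timestamps: np.ndarray
    co2: np.ndarray
    chamber_id: str = "1"
    ppfd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if self.timestamps.shape != self.co2.shape or self.timestamps.ndim != 1:
            raise ValueError("timestamps and co2 must be 1-D arrays of equal length")
        if len(self.timestamps) and np.any(np.diff(self.timestamps) <= 0):
            raise InputDataError("timestamps must be strictly increasing")
        if np.any(self.co2 <= 0):
            raise ValueError("co2 must be positive everywhere")
        if self.ppfd is not None:
            self.ppfd = np.asarray(self.ppfd, dtype=float)
            if self.ppfd.shape != self.timestamps.shape:
                raise ValueError("ppfd must match timestamps in length")
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps)
            if np.any(np.abs(dt - 1.0) > 1e-6):
                warnings.warn(
                    f"chamber {self.chamber_id}: sampling deviates from 1 Hz "
                    f"({np.sum(np.abs(dt - 1.0) > 1e-6)} gaps)",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class FluxEstimate:
    """One closure's flux estimate.

    ``flux`` is canopy net CO2 uptake in µmol m⁻² ground s⁻¹ (positive =
    uptake); ``slope`` the [CO2]-vs-time regression slope in
    µmol mol⁻¹ s⁻¹ with its standard error and r².
    """

    flux: float
    slope: float
    slope_se: float
    r_squared: float
    window: tuple
    chamber_id: str = "1"
    mean_ppfd: float | None = None


def segment_closures(
    series: ChamberSeries,
    schedule: ClosureSchedule = ClosureSchedule(),
    cycle_start: float = 0.0,
) -> list:
    """Closure windows [t0, t0 + closed_duration) present in the series.

    Windows start at ``cycle_start + k·period``; a trailing closure is kept
    only if the full closed interval is covered by the log.
    """
    if len(series) == 0:
        warnings.warn("empty series: no closures", stacklevel=2)
        return []
    t0, t_end = series.timestamps[0], series.timestamps[-1] + 1.0
    if t_end - max(t0, cycle_start) < schedule.closed_duration:
        warnings.warn("series shorter than one closure", stacklevel=2)
        return []
    windows = []
    k = int(np.ceil((t0 - cycle_start) / schedule.period)) if t0 > cycle_start else 0
    while True:
        start = cycle_start + k * schedule.period
        if start + schedule.closed_duration > t_end:
            break
        if start >= t0:
            windows.append((start, start + schedule.closed_duration))
        k += 1
    if not windows:
        warnings.warn("series shorter than one closure", stacklevel=2)
    return windows


def estimate_slope(
    series: ChamberSeries,
    window: tuple,
    trim_head: float = 5.0,
) -> tuple:
    """OLS slope of [CO2] vs time over ``[window[0] + trim_head, window[1])``.

    Returns ``(slope, slope_se, r_squared)``; requires ≥ 10 samples after
    trimming. A perfectly constant [CO2] trace yields slope 0 with r² 0.
    """
    lo, hi = window[0] + trim_head, window[1]
    mask = (series.timestamps >= lo) & (series.timestamps < hi)
    n = int(mask.sum())
    if n < 10:
        raise InputDataError(
            f"only {n} samples in window after trimming; need at least 10"
        )
    t = series.timestamps[mask]
    c = series.co2[mask]
    if np.ptp(c) < 1e-15:
        return 0.0, 0.0, 0.0
    res = stats.linregress(t, c)
    return float(res.slope), float(res.stderr), float(res.rvalue**2)


def slope_to_flux(slope: float, spec: ChamberSpec = ChamberSpec()) -> float:
    """Convert a [CO2] drawdown slope (µmol mol⁻¹ s⁻¹) into canopy flux
    (µmol CO2 m⁻² ground s⁻¹, positive = net uptake)."""
    return -slope * spec.n_air / spec.ground_area


def closure_fluxes(
    series: ChamberSeries,
    spec: ChamberSpec = ChamberSpec(),
    schedule: ClosureSchedule = ClosureSchedule(),
    cycle_start: float = 0.0,
    trim_head: float = 5.0,
) -> list:
    """Segment the series into closures and estimate one flux per closure."""
    out = []
    for window in segment_closures(series, schedule, cycle_start):
        slope, se, r2 = estimate_slope(series, window, trim_head)
        mean_ppfd = None
        if series.ppfd is not None:
            mask = (series.timestamps >= window[0]) & (series.timestamps < window[1])
            mean_ppfd = float(np.mean(series.ppfd[mask]))
        out.append(
            FluxEstimate(
                flux=slope_to_flux(slope, spec),
                slope=slope,
                slope_se=se * spec.n_air / spec.ground_area,
                r_squared=r2,
                window=window,
                chamber_id=series.chamber_id,
                mean_ppfd=mean_ppfd,
            )
        )
    return out


def flux_light_curve(estimates: list, bins=None) -> pd.DataFrame:
    """Bin per-closure fluxes by their mean PPFD.

    Returns a DataFrame with columns ``ppfd_bin`` (interval midpoint),
    ``mean_flux``, ``sd_flux`` (NaN for singleton bins) and ``n``.
    Default bins: 200 µmol m⁻² s⁻¹ wide from 0 to the observed maximum.
    """
    vals = [(e.mean_ppfd, e.flux) for e in estimates if e.mean_ppfd is not None]
    if not vals:
        raise InputDataError("no estimates carry PPFD data")
    df = pd.DataFrame(vals, columns=["ppfd", "flux"])
    if bins is None:
        top = max(200.0, float(np.ceil(df["ppfd"].max() / 200.0) * 200.0))
        bins = np.arange(0.0, top + 200.0, 200.0)
    cut = pd.cut(df["ppfd"], bins=bins, include_lowest=True)
    grouped = df.groupby(cut, observed=True)["flux"]
    out = pd.DataFrame(
        {
            "ppfd_bin": [iv.mid for iv in grouped.mean().index],
            "mean_flux": grouped.mean().to_numpy(),
            "sd_flux": grouped.std(ddof=1).to_numpy(),
            "n": grouped.count().to_numpy(),
        }
    )
    return out.reset_index(drop=True)
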