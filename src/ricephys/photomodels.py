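"""Forward models for leaf photosynthesis and grain filling.

Three model families, all pure functions of their parameters:

* the non-rectangular hyperbola light response of net photosynthesis
  (:func:`nrh_pn`), parameterised by the light-saturated rate ``Pnmax``,
  the apparent quantum yield ``alpha``, the convexity ``theta`` and the
  dark respiration ``Rd``;
* the FvCB A/Ci model as the minimum of a Rubisco-carboxylation-limited
  rate ``Wc`` and an RuBP-regeneration-limited rate ``Wj``
  (:func:`fvcb_wc`, :func:`fvcb_wj`, :func:`fvcb_pn`);
* the Richards growth curve for single-grain dry weight after anthesis
  (:func:`richards_mass`, :func:`richards_rate`).

All rates are in µmol CO2 m⁻² s⁻¹, PPFD in µmol photons m⁻² s⁻¹, CO2
concentrations in µmol mol⁻¹ (ppm) and grain weight in mg grain⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LightResponseParams",
    "FvCBParams",
    "KineticConstants",
    "RichardsParams",
    "nrh_pn",
    "fvcb_wc",
    "fvcb_wj",
    "fvcb_pn",
    "fvcb_crossover_ci",
    "richards_mass",
    "richards_rate",
]


@dataclass(frozen=True)
class LightResponseParams:
    """Parameters of the non-rectangular hyperbola light response.

    Attributes
    ----------
    pn_max : float
        Maximal net photosynthesis at light saturation (µmol m⁻² s⁻¹).
    aqy : float
        Apparent quantum yield α (mol CO2 per mol photons).
    theta : float
        Curve convexity θ in [0, 1]; θ = 0 is the rectangular hyperbola,
        θ = 1 the Blackman (two-line) limit.
    rd : float
        Dark respiration rate (µmol m⁻² s⁻¹).
    """

    pn_max: float
    aqy: float
    theta: float
    rd: float

    def __post_init__(self) -> None:
        if not self.pn_max > 0:
            raise ValueError("pn_max must be > 0")
        if not self.aqy > 0:
            raise ValueError("aqy must be > 0")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.rd < 0:
            raise ValueError("rd must be >= 0")


@dataclass(frozen=True)
class FvCBParams:
    """FvCB capacities: Vcmax, Jmax and dark respiration (µmol m⁻² s⁻¹)."""

    vcmax: float
    jmax: float
    rd: float

    def __post_init__(self) -> None:
        if not self.vcmax > 0:
            raise ValueError("vcmax must be > 0")
        if not self.jmax > 0:
            raise ValueError("jmax must be > 0")
        if self.rd < 0:
            raise ValueError("rd must be >= 0")


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetic constants and air composition used by the A/Ci model.

    Defaults are the set used when fitting the milk-stage flag-leaf curves:
    ``kc`` = 404 µmol mol⁻¹ and ``gamma_star`` = 45 µmol mol⁻¹ (CO2-side
    constants, ppm at ambient pressure), ``ko`` = 278 mbar and ``o`` = 210
    mbar (O2-side, partial pressures), so the ratio ``o/ko`` entering the
    effective Michaelis constant is dimensionless.
    """

    kc: float = 404.0
    ko: float = 278.0
    o: float = 210.0
    gamma_star: float = 45.0

    def __post_init__(self) -> None:
        if min(self.kc, self.ko, self.o, self.gamma_star) <= 0:
            raise ValueError("all kinetic constants must be strictly positive")

    @property
    def km_effective(self) -> float:
        """Effective Michaelis constant K' = kc·(1 + o/ko) (µmol mol⁻¹)."""
        return self.kc * (1.0 + self.o / self.ko)


@dataclass(frozen=True)
class RichardsParams:
    """Richards growth-curve parameters W(t) = A·(1 + B·e^(−k·t))^(−1/N).

    ``a`` is the asymptotic final grain weight (mg grain⁻¹), ``b`` sets the
    initial condition (larger b ⇒ later filling onset), ``k`` is the rate
    constant (day⁻¹) and ``n`` the shape parameter (n = 1 is logistic).
    """

    a: float
    b: float
    k: float
    n: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.k, self.n) <= 0:
            raise ValueError("all Richards parameters must be strictly positive")


def _check_nonnegative(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be nonnegative")
    return x


def nrh_pn(i, p: LightResponseParams, *, clamp_flag: list | None = None):
    """Net photosynthesis of the non-rectangular hyperbola at PPFD ``i``.

    Pn = [αI + Pnmax − sqrt((αI + Pnmax)² − 4θαI·Pnmax)] / (2θ) − Rd,
    taking the minus-branch root. At θ = 0 the analytic rectangular-
    hyperbola limit αI·Pnmax/(αI + Pnmax) − Rd is used (never a division
    by zero). Discriminants driven slightly negative by floating-point
    noise are clamped to zero; pass a list as ``clamp_flag`` to be told
    when that happened.

    Parameters
    ----------
    i : array_like
        PPFD, µmol photons m⁻² s⁻¹; must be ≥ 0.
    p : LightResponseParams
    clamp_flag : list, optional
        If given, ``True`` is appended when any discriminant was clamped.

    Returns
    -------
    ndarray or float
        Net photosynthesis, µmol CO2 m⁻² s⁻¹.
    """
    i = _check_nonnegative(i, "PPFD")
    ai = p.aqy * i
    b = ai + p.pn_max
    disc = b**2 - 4.0 * p.theta * ai * p.pn_max
    clamped = disc < 0
    if np.any(clamped):
        if clamp_flag is not None:
            clamp_flag.append(True)
        disc = np.where(clamped, 0.0, disc)
    # rationalized minus-branch root: (b - sqrt(disc)) / (2θ) rewritten as
    # 2·αI·Pnmax / (b + sqrt(disc)); algebraically identical, but free of the
    # catastrophic cancellation at small θ and defined at θ = 0 (the
    # rectangular-hyperbola limit αI·Pnmax/(αI + Pnmax)) without a branch.
    gross = 2.0 * ai * p.pn_max / (b + np.sqrt(disc))
    out = gross - p.rd
    return out if out.ndim else float(out)


def fvcb_wc(ci, p: FvCBParams, k: KineticConstants = KineticConstants(), *,
            canonical: bool = False):
    """Rubisco-carboxylation-limited rate Wc at intercellular CO2 ``ci``.

    Default form: Wc = Vcmax·Ci / (Ci + Kc·(1 + O/Ko)).  With
    ``canonical=True`` the numerator carries the (Ci − Γ*) compensation
    term instead: Wc = Vcmax·(Ci − Γ*) / (Ci + Kc·(1 + O/Ko)).
    """
    ci = _check_nonnegative(ci, "ci")
    num = (ci - k.gamma_star) if canonical else ci
    out = p.vcmax * num / (ci + k.km_effective)
    return out if out.ndim else float(out)


def fvcb_wj(ci, p: FvCBParams, k: KineticConstants = KineticConstants(), *,
            canonical: bool = False):
    """RuBP-regeneration-limited rate Wj = Jmax·Ci / (4·Ci + 8·Γ*).

    With ``canonical=True`` the numerator is Jmax·(Ci − Γ*).
    """
    ci = _check_nonnegative(ci, "ci")
    num = (ci - k.gamma_star) if canonical else ci
    out = p.jmax * num / (4.0 * ci + 8.0 * k.gamma_star)
    return out if out.ndim else float(out)


def fvcb_pn(ci, p: FvCBParams, k: KineticConstants = KineticConstants(), *,
            canonical: bool = False):
    """Net photosynthesis Pn = min(Wc, Wj) − Rd of the FvCB model."""
    wc = np.asarray(fvcb_wc(ci, p, k, canonical=canonical))
    wj = np.asarray(fvcb_wj(ci, p, k, canonical=canonical))
    out = np.minimum(wc, wj) - p.rd
    return out if out.ndim else float(out)


def fvcb_crossover_ci(p: FvCBParams, k: KineticConstants = KineticConstants()):
    """Intercellular CO2 at which Wc = Wj, or ``None`` when no positive
    crossover exists.

    Setting Eq. Wc = Wj (default, non-canonical forms) and solving for Ci
    gives Ci* = (Jmax·K' − 8·Γ*·Vcmax) / (4·Vcmax − Jmax) with
    K' = Kc·(1 + O/Ko). Below Ci* the leaf is carboxylation-limited (Wc),
    above it regeneration-limited (Wj). The same closed form holds for the
    canonical variants because the (Ci − Γ*) factor cancels.
    """
    denom = 4.0 * p.vcmax - p.jmax
    if denom <= 0:
        return None
    ci_star = (p.jmax * k.km_effective - 8.0 * k.gamma_star * p.vcmax) / denom
    return ci_star if ci_star > 0 else None


def richards_mass(t, p: RichardsParams):
    """Grain dry weight W(t) = A·(1 + B·e^(−k·t))^(−1/N) at ``t`` days
    after anthesis (mg grain⁻¹). Strictly increasing; W → A as t → ∞."""
    t = np.asarray(t, dtype=float)
    out = p.a * (1.0 + p.b * np.exp(-p.k * t)) ** (-1.0 / p.n)
    return out if out.ndim else float(out)


def richards_rate(t, p: RichardsParams):
    """Analytic grain-filling rate dW/dt (mg grain⁻¹ day⁻¹).

    dW/dt = (A·k·B/N)·e^(−k·t)·(1 + B·e^(−k·t))^(−1/N − 1), nonnegative
    everywhere and → 0 as t → ∞.
    """
    t = np.asarray(t, dtype=float)
    e = np.exp(-p.k * t)
    out = (p.a * p.k * p.b / p.n) * e * (1.0 + p.b * e) ** (-1.0 / p.n - 1.0)
    return out if out.ndim else float(out)
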