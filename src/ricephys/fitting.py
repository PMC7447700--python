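"""Nonlinear least-squares estimation of the photosynthesis and grain-filling
models, plus the SPAD→chlorophyll linear calibration.

The module follows the statsmodels convention: a model class is built from
data, ``fit()`` returns a results object carrying the estimates, their
standard errors and diagnostics, and ``summary()`` renders a table.

All nonlinear fits use bounded trust-region least squares started from a
deterministic lattice over the bound box (three values per free parameter;
log-spaced for scale-like parameters). The best final SSE wins, ties broken
by lattice order, so a given input always produces bit-identical estimates.
Standard errors come from the Gauss–Newton approximation
cov = s²·(JᵀJ)⁻¹ at the optimum and are reported as NaN when JᵀJ is
singular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from ricephys.curves import GasExchangeCurve
from ricephys.errors import InputDataError
from ricephys.photomodels import (
    FvCBParams,
    KineticConstants,
    LightResponseParams,
    RichardsParams,
    fvcb_pn,
    fvcb_wc,
    fvcb_wj,
    nrh_pn,
    richards_mass,
)

__all__ = [
    "FitResult",
    "SpadCalibration",
    "LightResponseModel",
    "ACiModel",
    "RichardsModel",
    "SpadCalibrationModel",
    "fit_light_response",
    "fit_aci",
    "fit_richards",
    "fit_spad_calibration",
    "apply_calibration",
]

#: Relative SSE change below which an optimizer start is declared converged.
SSE_RTOL = 1e-10
#: Cap on function evaluations per start.
MAX_NFEV = 500


@dataclass
class FitResult:
    """Results of one nonlinear curve fit.

    Attributes
    ----------
    params : LightResponseParams | FvCBParams | RichardsParams
        Fitted parameter bundle.
    se : dict
        Per-parameter standard errors (NaN when unavailable).
    sse : float
        Residual sum of squares, (µmol m⁻² s⁻¹)² (mg² for grain fits).
    n_obs : int
    converged : bool
    flags : list of str
        Diagnostics: ``"degenerate_input"``, ``"bound_hit:<name>"``,
        ``"jmax_unidentifiable"``, ``"se_unavailable"``,
        ``"discriminant_clamped"``, ...
    limitation_labels : list of str or None
        For A/Ci fits only: per-point ``"Wc"`` / ``"Wj"`` at the optimum.
    """

    params: object
    se: dict
    sse: float
    n_obs: int
    converged: bool
    flags: list = field(default_factory=list)
    limitation_labels: list | None = None
    model: object = None

    @property
    def params_dict(self) -> dict:
        return {k: getattr(self.params, k) for k in self.se}

    def predict(self, x):
        """Evaluate the fitted curve at new driver values."""
        return self.model.predict(self.params, x)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit: n_obs={self.n_obs}, "
            f"sse={self.sse:.6g}, converged={self.converged}",
            f"{'parameter':>12} {'estimate':>12} {'std err':>12}",
        ]
        for name, value in self.params_dict.items():
            lines.append(f"{name:>12} {value:>12.5g} {self.se[name]:>12.4g}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        if self.limitation_labels is not None:
            lines.append("limitation: " + " ".join(self.limitation_labels))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: observations and the fitted curve.

        Requires matplotlib; returns the axes.
        """
        try:
            import matplotlib.pyplot as plt
        except ImportError as exc:  # pragma: no cover
            raise ImportError("plotting requires matplotlib") from exc
        if hasattr(self.model, "curve"):
            x, y = self.model.curve.driver, self.model.curve.pn
            xlabel = "PPFD (µmol m⁻² s⁻¹)" if self.model.curve.driver_kind == "ppfd" \
                else "Ci (µmol mol⁻¹)"
            ylabel = "Pn (µmol m⁻² s⁻¹)"
        else:
            x, y = self.model.t, self.model.weight
            xlabel, ylabel = "days after anthesis", "grain weight (mg)"
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(x, y, "o", label="observed")
        grid = np.linspace(float(np.min(x)), float(np.max(x)), 200)
        ax.plot(grid, self.predict(grid), "-", label="fitted")
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        """JSON-serializable report."""
        out = {
            "schema_version": 1,
            "model": type(self.model).__name__ if self.model is not None else None,
            "params": {k: float(v) for k, v in self.params_dict.items()},
            "se": {k: (None if np.isnan(v) else float(v)) for k, v in self.se.items()},
            "sse": float(self.sse),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "flags": list(self.flags),
        }
        if self.limitation_labels is not None:
            out["limitation_labels"] = list(self.limitation_labels)
        return out


def _lattice(bounds_lo, bounds_hi, log_mask):
    """Deterministic 3-per-parameter start lattice over the bound box."""
    fractions = (0.1, 0.5, 0.9)
    axes = []
    for lo, hi, lg in zip(bounds_lo, bounds_hi, log_mask):
        if lg:
            llo = np.log10(max(lo, 1e-3 * hi, 1e-8))
            lhi = np.log10(hi)
            axes.append([10 ** (llo + f * (lhi - llo)) for f in fractions])
        else:
            axes.append([lo + f * (hi - lo) for f in fractions])
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


class _CurveModel:
    """Shared multi-start bounded least-squares machinery."""

    param_names: tuple
    bounds_lo: tuple
    bounds_hi: tuple
    log_mask: tuple

    def _residual(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _make_params(self, x: np.ndarray):  # pragma: no cover
        raise NotImplementedError

    def predict(self, params, x):  # pragma: no cover
        raise NotImplementedError

    def _fit_multistart(self, y: np.ndarray) -> FitResult:
        lo = np.asarray(self.bounds_lo, dtype=float)
        hi = np.asarray(self.bounds_hi, dtype=float)
        starts = _lattice(lo, hi, self.log_mask)
        best = None
        for x0 in starts:
            try:
                res = least_squares(
                    self._residual,
                    np.clip(x0, lo, hi),
                    bounds=(lo, hi),
                    method="trf",
                    ftol=SSE_RTOL,
                    xtol=1e-12,
                    gtol=1e-12,
                    max_nfev=MAX_NFEV,
                )
            except Exception:
                continue
            sse = 2.0 * res.cost
            if best is None or sse < best[0] - 1e-15 * (1 + best[0]):
                best = (sse, res)
        if best is None:
            raise InputDataError("optimization failed from every start")
        sse, res = best
        x = res.x
        flags: list[str] = []
        converged = res.status > 0
        if np.ptp(y) < 1e-12:
            converged = False
            flags.append("degenerate_input")
        span = hi - lo
        for name, xi, l, h, s in zip(self.param_names, x, lo, hi, span):
            if xi - l < 1e-6 * s or h - xi < 1e-6 * s:
                flags.append(f"bound_hit:{name}")
        n, p = len(y), len(x)
        se = np.full(p, np.nan)
        if n > p:
            jtj = res.jac.T @ res.jac
            s2 = sse / (n - p)
            try:
                cov = s2 * np.linalg.inv(jtj)
                d = np.diag(cov)
                if np.all(d >= 0) and np.all(np.isfinite(d)):
                    se = np.sqrt(d)
                else:
                    flags.append("se_unavailable")
            except np.linalg.LinAlgError:
                flags.append("se_unavailable")
        else:
            flags.append("se_unavailable")
        return FitResult(
            params=self._make_params(x),
            se=dict(zip(self.param_names, se)),
            sse=float(sse),
            n_obs=n,
            converged=bool(converged),
            flags=flags,
            model=self,
        )


class LightResponseModel(_CurveModel):
    """Fit the non-rectangular hyperbola to a PPFD light-response curve.

    Parameters are estimated within pn_max ∈ (0, 100], aqy ∈ (0, 0.15],
    theta ∈ [0, 1] and rd ∈ [0, 10]. A curve should span at least one
    point below 100 and one above 1000 µmol m⁻² s⁻¹ so that both the
    initial slope and the plateau are constrained; otherwise a warning is
    issued and the fit proceeds.
    """

    param_names = ("pn_max", "aqy", "theta", "rd")
    bounds_lo = (1e-6, 1e-6, 0.0, 0.0)
    bounds_hi = (100.0, 0.15, 1.0, 10.0)
    log_mask = (False, False, False, False)

    def __init__(self, curve: GasExchangeCurve):
        if curve.driver_kind != "ppfd":
            raise InputDataError("LightResponseModel requires a PPFD curve")
        if len(curve) < 5:
            raise InputDataError("need at least 5 points to fit the light response")
        if not (np.any(curve.driver < 100) and np.any(curve.driver > 1000)):
            warnings.warn(
                "light curve does not span both PPFD < 100 and > 1000; "
                "initial slope or plateau may be poorly constrained",
                stacklevel=2,
            )
        self.curve = curve

    def _residual(self, x):
        p = self._make_params(x)
        return nrh_pn(self.curve.driver, p) - self.curve.pn

    def _make_params(self, x):
        return LightResponseParams(
            pn_max=float(x[0]), aqy=float(x[1]), theta=float(x[2]), rd=float(x[3])
        )

    def predict(self, params, i):
        return nrh_pn(i, params)

    def fit(self) -> FitResult:
        return self._fit_multistart(self.curve.pn)


class ACiModel(_CurveModel):
    """Fit the FvCB model Pn = min(Wc, Wj) − Rd to an A/Ci curve.

    Parameters
    ----------
    curve : GasExchangeCurve
        With ``driver_kind="ci"``.
    kinetics : KineticConstants
        Rubisco constants; defaults are the standard set (Kc 404, Ko 278,
        O 210, Γ* 45).
    rd_mode : "fit" or float
        ``"fit"`` estimates Rd together with Vcmax and Jmax; passing a
        number fixes Rd at a separately measured dark-respiration value.
    canonical : bool
        Use the (Ci − Γ*) numerator variants of Wc and Wj (off by default).

    The fitted results carry per-point limitation labels ("Wc" below the
    crossover, "Wj" above); if every point falls on one side the other
    capacity is flagged unidentifiable.
    """

    def __init__(
        self,
        curve: GasExchangeCurve,
        kinetics: KineticConstants = KineticConstants(),
        rd_mode: str | float = "fit",
        canonical: bool = False,
    ):
        if curve.driver_kind != "ci":
            raise InputDataError("ACiModel requires a Ci curve")
        if len(curve) < 6:
            raise InputDataError("need at least 6 points to fit the A/Ci model")
        if np.sum(curve.driver < 300) < 2 or np.sum(curve.driver > 600) < 2:
            warnings.warn(
                "A/Ci curve has fewer than 2 points below 300 or above 600 "
                "µmol mol⁻¹; limitation states poorly covered",
                stacklevel=2,
            )
        self.curve = curve
        self.kinetics = kinetics
        self.canonical = canonical
        if rd_mode == "fit":
            self.fixed_rd = None
            self.param_names = ("vcmax", "jmax", "rd")
            self.bounds_lo = (1e-3, 1e-3, 0.0)
            self.bounds_hi = (500.0, 1000.0, 10.0)
            self.log_mask = (False, False, False)
        else:
            self.fixed_rd = float(rd_mode)
            if self.fixed_rd < 0:
                raise ValueError("fixed rd must be >= 0")
            self.param_names = ("vcmax", "jmax")
            self.bounds_lo = (1e-3, 1e-3)
            self.bounds_hi = (500.0, 1000.0)
            self.log_mask = (False, False)

    def _make_params(self, x):
        rd = self.fixed_rd if self.fixed_rd is not None else float(x[2])
        return FvCBParams(vcmax=float(x[0]), jmax=float(x[1]), rd=rd)

    def _residual(self, x):
        p = self._make_params(x)
        return (
            fvcb_pn(self.curve.driver, p, self.kinetics, canonical=self.canonical)
            - self.curve.pn
        )

    def predict(self, params, ci):
        return fvcb_pn(ci, params, self.kinetics, canonical=self.canonical)

    def fit(self) -> FitResult:
        result = self._fit_multistart(self.curve.pn)
        p = result.params
        wc = np.asarray(
            fvcb_wc(self.curve.driver, p, self.kinetics, canonical=self.canonical)
        )
        wj = np.asarray(
            fvcb_wj(self.curve.driver, p, self.kinetics, canonical=self.canonical)
        )
        labels = ["Wc" if c <= j else "Wj" for c, j in zip(wc, wj)]
        result.limitation_labels = labels
        if all(l == "Wc" for l in labels):
            result.flags.append("jmax_unidentifiable")
        elif all(l == "Wj" for l in labels):
            result.flags.append("vcmax_unidentifiable")
        return result


class RichardsModel(_CurveModel):
    """Fit the Richards growth curve to a grain-weight trajectory.

    ``t`` in days after anthesis, ``weight`` in mg grain⁻¹. Bounds:
    a ∈ (0, 2·max(weight)], b ∈ (0, 1e4] (log-spaced starts), k ∈ (0, 2],
    n ∈ (0, 10]. The final observation should reach at least 80% of the
    maximum, otherwise the asymptote is flagged as uncertain via a warning.
    """

    param_names = ("a", "b", "k", "n")
    log_mask = (False, True, False, False)

    def __init__(self, t: Sequence[float], weight: Sequence[float]):
        t = np.asarray(t, dtype=float)
        w = np.asarray(weight, dtype=float)
        if t.shape != w.shape or t.ndim != 1:
            raise InputDataError("t and weight must be 1-D arrays of equal length")
        if len(t) < 6:
            raise InputDataError("need at least 6 time points to fit the Richards curve")
        if np.any(w <= 0):
            raise InputDataError("grain weights must be positive")
        if w[-1] < 0.8 * w.max():
            warnings.warn(
                "final weight is below 80% of the maximum; asymptote uncertain",
                stacklevel=2,
            )
        self.t = t
        self.weight = w
        wmax = float(w.max())
        self.bounds_lo = (1e-6, 1e-6, 1e-6, 1e-3)
        self.bounds_hi = (2.0 * wmax, 1e4, 2.0, 10.0)

    def _make_params(self, x):
        return RichardsParams(a=float(x[0]), b=float(x[1]), k=float(x[2]), n=float(x[3]))

    def _residual(self, x):
        return richards_mass(self.t, self._make_params(x)) - self.weight

    def predict(self, params, t):
        return richards_mass(t, params)

    def fit(self) -> FitResult:
        return self._fit_multistart(self.weight)


@dataclass
class SpadCalibration:
    """Linear SPAD → chlorophyll calibration for one cultivar.

    ``chlorophyll = intercept + slope · SPAD`` in mg g⁻¹ fresh weight.
    """

    intercept: float
    slope: float
    r_squared: float
    cultivar: str = ""
    n_obs: int = 0
    se_intercept: float = float("nan")
    se_slope: float = float("nan")
    residuals: np.ndarray | None = None

    def outlier_indices(self, threshold: float = 2.5) -> list:
        """Indices of calibration pairs with |studentized residual| above
        ``threshold`` (internally studentized, per-point leave-in)."""
        r = self.residuals
        if r is None or len(r) < 3:
            return []
        s = np.std(r, ddof=2)
        if s == 0:
            return []
        return [int(i) for i in np.flatnonzero(np.abs(r / s) > threshold)]


class SpadCalibrationModel:
    """Ordinary least-squares calibration line per cultivar.

    Requires ≥ 3 (SPAD, chlorophyll) pairs with non-constant SPAD readings.
    Calibrations are kept cultivar-specific; pooling across cultivars is
    the caller's explicit choice.
    """

    def __init__(self, spad: Sequence[float], chlorophyll: Sequence[float],
                 cultivar: str = ""):
        spad = np.asarray(spad, dtype=float)
        chl = np.asarray(chlorophyll, dtype=float)
        if spad.shape != chl.shape or spad.ndim != 1:
            raise InputDataError("spad and chlorophyll must be 1-D and equal length")
        if len(spad) < 3:
            raise InputDataError("need at least 3 calibration pairs")
        if np.ptp(spad) < 1e-12:
            raise InputDataError("constant SPAD readings: slope undefined")
        self.spad = spad
        self.chl = chl
        self.cultivar = cultivar

    def fit(self) -> SpadCalibration:
        import statsmodels.api as sm

        x = sm.add_constant(self.spad)
        ols = sm.OLS(self.chl, x).fit()
        return SpadCalibration(
            intercept=float(ols.params[0]),
            slope=float(ols.params[1]),
            r_squared=float(ols.rsquared) if np.isfinite(ols.rsquared) else 1.0,
            cultivar=self.cultivar,
            n_obs=len(self.spad),
            se_intercept=float(ols.bse[0]),
            se_slope=float(ols.bse[1]),
            residuals=np.asarray(ols.resid),
        )


def fit_light_response(curve: GasExchangeCurve) -> FitResult:
    """Convenience wrapper: ``LightResponseModel(curve).fit()``."""
    return LightResponseModel(curve).fit()


def fit_aci(
    curve: GasExchangeCurve,
    kinetics: KineticConstants = KineticConstants(),
    rd_mode: str | float = "fit",
    canonical: bool = False,
) -> FitResult:
    """Convenience wrapper: ``ACiModel(curve, ...).fit()``."""
    return ACiModel(curve, kinetics, rd_mode, canonical).fit()


def fit_richards(t, weight) -> FitResult:
    """Convenience wrapper: ``RichardsModel(t, weight).fit()``."""
    return RichardsModel(t, weight).fit()


def fit_spad_calibration(pairs, cultivar: str = "") -> SpadCalibration:
    """Fit the calibration line from (SPAD, chlorophyll mg g⁻¹ FW) pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InputDataError("pairs must be a sequence of (spad, chlorophyll)")
    return SpadCalibrationModel(arr[:, 0], arr[:, 1], cultivar).fit()


def apply_calibration(cal: SpadCalibration, spad, *, clamp_flag: list | None = None):
    """Chlorophyll content (mg g⁻¹ FW) at a SPAD reading; negative
    predictions are clamped to 0 (appends to ``clamp_flag`` if given)."""
    spad = np.asarray(spad, dtype=float)
    out = cal.intercept + cal.slope * spad
    neg = out < 0
    if np.any(neg):
        if clamp_flag is not None:
            clamp_flag.append(True)
        out = np.where(neg, 0.0, out)
    return out if out.ndim else float(out)
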