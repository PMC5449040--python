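"""Recover model parameters from measured shift-vs-pressure series.

Two fitters:

* :func:`fit_quadratic` — the second-order Taylor model. The model is
  linear in (delta0, B1, B2), so the weighted linear least-squares
  solution is computed in closed form; it is the exact fixed point of
  the iterative Levenberg-Marquardt procedure typically used for this
  fit, with standard errors from the parameter covariance.
* :func:`fit_two_state` — a two-state Boltzmann ensemble (two state
  shifts, dG0, dV0 and optionally dbeta0) by nonlinear least squares
  from a deterministic grid of starting points, with an F-test flag
  when the plain quadratic describes the data equally well
  (non-identifiability of the thermodynamic parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    MPA_PER_GPA,
    EnsembleModel,
    PressureCoefficients,
    ThermoState,
    ensemble_shift,
)

__all__ = [
    "PressureSeries",
    "FitResult",
    "TwoStateFit",
    "FitError",
    "FitConvergenceError",
    "fit_quadratic",
    "fit_two_state",
    "read_series",
    "write_series",
]


class FitError(ValueError):
    """Raised for invalid fitting inputs."""


class FitConvergenceError(RuntimeError):
    """Raised when no optimizer start converges; carries diagnostics."""


@dataclass(frozen=True)
class PressureSeries:
    """One measured shift-vs-pressure series.

    ``pressures`` in MPa (strictly increasing), ``shifts`` in ppm,
    optional per-point inverse-variance ``weights`` (ppm^-2).
    """

    pressures: np.ndarray
    shifts: np.ndarray
    nucleus: Optional[str] = None
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        s = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "shifts", s)
        if p.ndim != 1 or s.shape != p.shape:
            raise FitError(
                f"pressures and shifts must be matching 1-D arrays, got "
                f"shapes {p.shape} and {s.shape}"
            )
        if len(p) < 3:
            raise FitError(f"need >= 3 pressure points, got {len(p)}")
        if np.any(p < 0) or np.any(p > 1000):
            raise FitError("pressures must lie within [0, 1000] MPa")
        if np.any(np.diff(p) <= 0):
            raise FitError("pressures must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise FitError("shifts must be finite")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", w)
            if w.shape != p.shape:
                raise FitError("weights must match pressures in length")
            if np.any(w <= 0) or not np.all(np.isfinite(w)):
                raise FitError("weights must be positive and finite")

    def __len__(self) -> int:
        return len(self.pressures)


@dataclass(frozen=True)
class FitResult:
    """Quadratic fit output: coefficients with errors plus residual diagnostics."""

    coefficients: PressureCoefficients
    residuals: np.ndarray
    rms: float
    dof: int

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))


def _design_matrix(pressures: np.ndarray, p0: float) -> np.ndarray:
    # dp in GPa keeps the Vandermonde columns O(1) over 0.1-200 MPa
    dp = (pressures - p0) / MPA_PER_GPA
    return np.column_stack([np.ones_like(dp), dp, dp * dp])


def fit_quadratic(series: PressureSeries, p0: float = 0.1) -> FitResult:
    """Least-squares (delta0, B1, B2) for a series, expanded about ``p0`` MPa.

    Unweighted by default; if the series carries inverse-variance
    weights they are used and treated as absolute, so parameter errors
    come straight from the weighted covariance. Otherwise the covariance
    is scaled by the residual variance (dof = n - 3). With exactly three
    points the fit interpolates and the errors are reported as absent.
    """
    p = series.pressures
    y = series.shifts
    n = len(p)
    X = _design_matrix(p, p0)

    if series.weights is not None:
        sw = np.sqrt(series.weights)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)

    fitted = X @ coef
    residuals = y - fitted
    dof = n - 3
    rms = float(np.sqrt(np.mean(residuals**2)))

    errs = (None, None, None)
    if dof > 0 or series.weights is not None:
        if series.weights is not None:
            xtwx = X.T @ (series.weights[:, None] * X)
            cov = np.linalg.inv(xtwx)  # absolute: weights are 1/sigma^2
        else:
            s2 = float(residuals @ residuals) / dof
            cov = s2 * np.linalg.inv(X.T @ X)
        errs = tuple(float(v) for v in np.sqrt(np.diag(cov)))

    coeffs = PressureCoefficients(
        delta0=float(coef[0]),
        B1=float(coef[1]),
        B2=float(coef[2]),
        delta0_err=errs[0],
        B1_err=errs[1],
        B2_err=errs[2],
        p0=p0,
    )
    return FitResult(coefficients=coeffs, residuals=residuals, rms=rms, dof=dof)


# deterministic multistart grid for the two-state fit
_DG_STARTS = (-5000.0, 0.0, 5000.0)      # J/mol
_DV_STARTS = (-100.0, -25.0, 25.0)       # mL/mol
_SSE_TIE_TOL = 1e-10


@dataclass(frozen=True)
class TwoStateFit:
    """Two-state ensemble fit with non-identifiability diagnostics.

    ``quadratic_sufficient`` is True when an F-test cannot distinguish
    the 5-parameter thermodynamic model from the 3-parameter quadratic
    at the 5% level — i.e. the thermodynamic parameters are not
    identifiable from this series.
    """

    model: EnsembleModel
    residuals: np.ndarray
    rms: float
    dof: int
    sse: float
    param_errors: dict = field(default_factory=dict)
    quadratic_sufficient: bool = False
    quadratic_sse: float = float("nan")
    n_starts_converged: int = 0

    @property
    def dG0(self) -> float:
        return self.model.states[1].G0

    @property
    def dV0(self) -> float:
        return self.model.states[1].V0

    @property
    def dbeta0(self) -> float:
        return self.model.states[1].beta0


def _two_state_model(
    params: np.ndarray, temperature: float, p0: float, fix_beta: bool
) -> EnsembleModel:
    delta_a, delta_b, dg, dv = params[:4]
    dbeta = 0.0 if fix_beta else params[4]
    return EnsembleModel(
        (
            ThermoState("A", shift=delta_a),
            ThermoState("B", shift=delta_b, G0=dg, V0=dv, beta0=dbeta),
        ),
        temperature=temperature,
        p0=p0,
    )


def fit_two_state(
    series: PressureSeries,
    temperature: float = 283.0,
    p0: float = 0.1,
    fix_beta: bool = False,
) -> TwoStateFit:
    """Fit a two-state ensemble (state A fixed at G=V=beta=0) to a series.

    Free parameters: the two state shifts, dG0 (J/mol), dV0 (mL/mol) and,
    unless ``fix_beta``, dbeta0 (mL/(mol*MPa)). Starts from a fixed
    3x3 grid over dG0 x dV0 with endpoint-derived shift initials; the
    lowest-SSE converged solution wins (ties broken by start order at
    1e-10 SSE tolerance).
    """
    n_par = 4 if fix_beta else 5
    if len(series) < n_par + 1:
        raise FitError(
            f"two-state fit needs >= {n_par + 1} points for {n_par} "
            f"parameters, got {len(series)}"
        )
    p = series.pressures
    y = series.shifts
    sw = np.sqrt(series.weights) if series.weights is not None else None

    def residual(params):
        model = _two_state_model(params, temperature, p0, fix_beta)
        r = ensemble_shift(model, p) - y
        return r * sw if sw is not None else r

    best = None
    best_sse = np.inf
    n_ok = 0
    failures = []
    for dg in _DG_STARTS:
        for dv in _DV_STARTS:
            x0 = [y[0], y[-1], dg, dv]
            if not fix_beta:
                x0.append(0.0)
            try:
                sol = optimize.least_squares(
                    residual, np.asarray(x0, dtype=float), method="lm",
                    xtol=1e-12, ftol=1e-12, max_nfev=3000,
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(f"start (dG={dg}, dV={dv}): {exc}")
                continue
            if not sol.success or not np.all(np.isfinite(sol.x)):
                failures.append(
                    f"start (dG={dg}, dV={dv}): {sol.message}"
                )
                continue
            n_ok += 1
            sse = float(sol.fun @ sol.fun)
            if sse < best_sse - _SSE_TIE_TOL:
                best, best_sse = sol, sse
    if best is None:
        raise FitConvergenceError(
            "two-state fit failed to converge from every start: "
            + "; ".join(failures)
        )

    model = _two_state_model(best.x, temperature, p0, fix_beta)
    fitted = ensemble_shift(model, p)
    residuals = y - fitted
    dof = len(p) - n_par
    rms = float(np.sqrt(np.mean(residuals**2)))

    # parameter errors from J^T J at the optimum, scaled by residual variance
    names = ["delta_a", "delta_b", "dG0", "dV0"] + ([] if fix_beta else ["dbeta0"])
    param_errors = {}
    if dof > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj)
            if sw is None:
                cov *= best_sse / dof
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            param_errors = dict(zip(names, (float(v) for v in se)))
        except np.linalg.LinAlgError:
            pass

    quad = fit_quadratic(series, p0=p0)
    quadratic_sufficient = _quadratic_sufficient(
        quad.sse, best_sse, n=len(p), n_par=n_par
    )

    return TwoStateFit(
        model=model,
        residuals=residuals,
        rms=rms,
        dof=dof,
        sse=best_sse,
        param_errors=param_errors,
        quadratic_sufficient=quadratic_sufficient,
        quadratic_sse=quad.sse,
        n_starts_converged=n_ok,
    )


def _quadratic_sufficient(
    sse_quad: float, sse_two: float, n: int, n_par: int, alpha: float = 0.05
) -> bool:
    """Extra-sum-of-squares F-test: does the ensemble model beat the quadratic?

    Returns True (quadratic sufficient / two-state not identifiable)
    unless the SSE reduction is significant at level ``alpha``.
    """
    extra = n_par - 3
    dof_two = n - n_par
    if dof_two <= 0 or extra <= 0:
        return True
    if sse_quad <= 1e-22:  # numerically perfect quadratic fit
        return True
    if sse_two <= 1e-22 < sse_quad:
        return False
    f_stat = ((sse_quad - sse_two) / extra) / (sse_two / dof_two)
    return f_stat < stats.f.ppf(1.0 - alpha, extra, dof_two)


# -- delimited-text I/O -----------------------------------------------------

_SERIES_COLUMNS = ["pressure_MPa", "shift_ppm"]


def read_series(path: Union[str, Path], nucleus: Optional[str] = None) -> PressureSeries:
    """Read a series from CSV with header columns pressure_MPa, shift_ppm."""
    df = pd.read_csv(path)
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise FitError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {_SERIES_COLUMNS}"
        )
    return PressureSeries(
        pressures=df["pressure_MPa"].to_numpy(dtype=float),
        shifts=df["shift_ppm"].to_numpy(dtype=float),
        nucleus=nucleus,
    )


def write_series(series: PressureSeries, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {"pressure_MPa": series.pressures, "shift_ppm": series.shifts}
    ).to_csv(path, index=False)
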