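"""Forward models for pressure-dependent chemical shifts.

Two complementary descriptions of a shift-vs-pressure curve:

* a second-order Taylor expansion about atmospheric pressure,
  ``delta(p) = delta0 + B1*dp + B2*dp**2`` with ``dp`` in GPa
  (:func:`predict_shift`), and
* a multistate Boltzmann ensemble in fast exchange, where each
  conformational state carries a shift expectation value and a
  pressure-dependent free energy
  ``G(p) = G0 + V0*dp + 0.5*beta0*dp**2`` (:func:`ensemble_shift`).

Unit bookkeeping: pressures enter the API in MPa (the experimental
unit), Taylor coefficients are stored per GPa / GPa^2 as printed in
coefficient tables, free energies in J/mol, volumes in mL/mol and
compressibility factors in mL/(mol*MPa) so that the Boltzmann exponent
is dimensionless without conversion constants (1 mL*MPa = 1 J).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "MPA_PER_GPA",
    "PressureCoefficients",
    "ThermoState",
    "EnsembleModel",
    "ExchangeCheck",
    "predict_shift",
    "state_populations",
    "ensemble_shift",
    "taylor_coefficients",
    "check_fast_exchange",
]

#: Gas constant in J/(mol*K).
GAS_CONSTANT = 8.31446

#: Exact MPa -> GPa conversion used everywhere Taylor coefficients meet pressures.
MPA_PER_GPA = 1000.0


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")


@dataclass(frozen=True)
class PressureCoefficients:
    """Taylor coefficients of shift versus pressure about ``p0``.

    ``delta0`` in ppm, ``B1`` in ppm/GPa, ``B2`` in ppm/GPa^2, ``p0`` in
    MPa (default atmospheric, 0.1). Standard errors are optional and
    share the units of their coefficient.
    """

    delta0: float
    B1: float
    B2: float
    delta0_err: Optional[float] = None
    B1_err: Optional[float] = None
    B2_err: Optional[float] = None
    p0: float = 0.1

    def __post_init__(self) -> None:
        for name in ("delta0", "B1", "B2", "p0"):
            _require_finite(name, getattr(self, name))
        if self.p0 < 0:
            raise ValueError(f"p0 must be >= 0 MPa, got {self.p0}")
        for name in ("delta0_err", "B1_err", "B2_err"):
            err = getattr(self, name)
            if err is not None and not err >= 0:
                raise ValueError(f"{name} must be >= 0, got {err}")

    def predict(self, p: Union[float, Sequence[float], np.ndarray]):
        return predict_shift(self, p)

    def with_errors(self, delta0_err=None, B1_err=None, B2_err=None):
        return replace(
            self, delta0_err=delta0_err, B1_err=B1_err, B2_err=B2_err
        )


def predict_shift(coeffs: PressureCoefficients, p) -> Union[float, np.ndarray]:
    """Evaluate the quadratic shift model at pressure(s) ``p`` in MPa.

    Returns ppm; scalar in, scalar out. ``(p - p0)`` is converted to GPa
    by exact division by 1000 before the polynomial is applied.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0):
        raise ValueError("pressure must be >= 0 MPa")
    dp = (p_arr - coeffs.p0) / MPA_PER_GPA
    out = coeffs.delta0 + coeffs.B1 * dp + coeffs.B2 * dp * dp
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


@dataclass(frozen=True)
class ThermoState:
    """One conformational state of the ensemble model.

    ``shift`` is the state's shift expectation value in ppm; ``G0`` the
    free energy in J/mol relative to an arbitrary reference state;
    ``V0`` the partial molar volume difference in mL/mol; ``beta0`` the
    compressibility factor in mL/(mol*MPa). All refer to (p0, T0).
    """

    label: str
    shift: float
    G0: float = 0.0
    V0: float = 0.0
    beta0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("shift", "G0", "V0", "beta0"):
            _require_finite(f"state {self.label!r}: {name}", getattr(self, name))

    def free_energy(self, dp) -> float:
        """G(p) = G0 + V0*dp + 0.5*beta0*dp^2 with dp in MPa; J/mol."""
        return self.G0 + self.V0 * dp + 0.5 * self.beta0 * dp * dp

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "shift": self.shift,
            "G0": self.G0,
            "V0": self.V0,
            "beta0": self.beta0,
        }


@dataclass(frozen=True)
class EnsembleModel:
    """N >= 2 conformational states in fast exchange at fixed temperature."""

    states: tuple
    temperature: float = 283.0
    p0: float = 0.1

    #: gas constant, J/(mol*K); fixed, not a per-model parameter
    R = GAS_CONSTANT

    def __init__(self, states, temperature: float = 283.0, p0: float = 0.1):
        states = tuple(states)
        if len(states) < 2:
            raise ValueError(f"need at least two states, got {len(states)}")
        labels = [s.label for s in states]
        if len(set(labels)) != len(labels):
            raise ValueError(f"state labels must be unique, got {labels}")
        if not temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {temperature}")
        if p0 < 0:
            raise ValueError(f"p0 must be >= 0 MPa, got {p0}")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "temperature", float(temperature))
        object.__setattr__(self, "p0", float(p0))

    @property
    def rt(self) -> float:
        """R*T in J/mol."""
        return GAS_CONSTANT * self.temperature

    def populations(self, p):
        return state_populations(self, p)

    def shift(self, p):
        return ensemble_shift(self, p)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "temperature": self.temperature,
            "p0": self.p0,
            "states": [s.to_dict() for s in self.states],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "EnsembleModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        states = tuple(ThermoState(**s) for s in payload["states"])
        return cls(
            states, temperature=payload["temperature"], p0=payload["p0"]
        )


def _exponents(model: EnsembleModel, p) -> np.ndarray:
    """-G_i(p)/RT for every state; shape (n_states,) + shape(p)."""
    dp = np.asarray(p, dtype=float) - model.p0
    rt = model.rt
    rows = []
    with np.errstate(over="ignore", invalid="ignore"):
        for s in model.states:
            x = -np.asarray(s.free_energy(dp)) / rt
            if not np.all(np.isfinite(x)):
                raise ValueError(
                    f"non-finite Boltzmann exponent for state {s.label!r}"
                )
            rows.append(x)
    return np.stack(rows)


def state_populations(model: EnsembleModel, p) -> np.ndarray:
    """Boltzmann populations of every state at pressure(s) ``p`` in MPa.

    Shape ``(n_states,) + shape(p)``; sums to 1 over the state axis.
    Normalization is overflow-safe: the largest exponent is subtracted
    before exponentiating, which leaves the populations unchanged.
    """
    x = _exponents(model, p)
    x = x - np.max(x, axis=0, keepdims=True)
    w = np.exp(x)
    return w / np.sum(w, axis=0, keepdims=True)


def ensemble_shift(model: EnsembleModel, p) -> Union[float, np.ndarray]:
    """Population-weighted average shift at pressure(s) ``p`` in MPa; ppm."""
    pops = state_populations(model, p)
    shifts = np.array([s.shift for s in model.states])
    out = np.tensordot(shifts, pops, axes=(0, 0))
    p_arr = np.asarray(p)
    return float(out) if p_arr.ndim == 0 else out


def taylor_coefficients(model: EnsembleModel) -> PressureCoefficients:
    """Analytic Taylor coefficients of the ensemble shift about p0.

    With population averages ``<.>`` taken at p0,

    * ``d(delta)/dp   = -Cov(delta, V) / RT``
    * ``d2(delta)/dp2 =  E[(delta-<delta>)(V-<V>)^2] / (RT)^2
                         - Cov(delta, beta) / RT``

    both per MPa; ``B1 = d(delta)/dp * 1e3`` (ppm/GPa) and
    ``B2 = 0.5 * d2(delta)/dp2 * 1e6`` (ppm/GPa^2).
    """
    w = state_populations(model, model.p0)
    d = np.array([s.shift for s in model.states])
    v = np.array([s.V0 for s in model.states])
    b = np.array([s.beta0 for s in model.states])
    rt = model.rt

    d_mean = float(w @ d)
    v_mean = float(w @ v)
    cov_dv = float(w @ (d * v)) - d_mean * v_mean
    cov_db = float(w @ (d * b)) - d_mean * float(w @ b)
    third = float(w @ ((d - d_mean) * (v - v_mean) ** 2))

    d1 = -cov_dv / rt                     # ppm/MPa
    d2 = third / rt**2 - cov_db / rt      # ppm/MPa^2
    return PressureCoefficients(
        delta0=d_mean,
        B1=d1 * MPA_PER_GPA,
        B2=0.5 * d2 * MPA_PER_GPA**2,
        p0=model.p0,
    )


@dataclass(frozen=True)
class ExchangeCheck:
    """Result of the fast-exchange criterion |dOmega * tau| << 1."""

    delta_omega: float  # rad/s
    tau: float          # s
    product: float      # dimensionless
    fast: bool
    threshold: float


def check_fast_exchange(
    delta_omega: float, tau: float, threshold: float = 0.1
) -> ExchangeCheck:
    """Evaluate |delta_omega * tau| against a concrete '<< 1' threshold.

    ``delta_omega`` in rad/s, ``tau`` (exchange correlation time) in s.
    The default threshold of 0.1 is one reading of "much less than one";
    it is reported alongside the boolean so callers can re-decide.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0 s, got {tau}")
    product = abs(delta_omega * tau)
    return ExchangeCheck(
        delta_omega=float(delta_omega),
        tau=float(tau),
        product=float(product),
        fast=bool(product < threshold),
        threshold=float(threshold),
    )
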