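"""Synthetic pressure-series generator.

Emulates the high-pressure titration that underlies the reference
tables: shifts on a 0.1-200 MPa grid following either the quadratic
model or a thermodynamic ensemble, plus i.i.d. Gaussian reading noise
at the nucleus-appropriate uncertainty (0.01 ppm for 15N, 0.001 ppm for
amide 1H). All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np

from .correction import PeakTrack
from .fitting import PressureSeries
from .model import EnsembleModel, PressureCoefficients, ensemble_shift, predict_shift
from .reference import Nucleus, ReferenceLibrary, load_reference

__all__ = [
    "SimulationConfig",
    "default_pressure_grid",
    "simulate_series",
    "simulate_reference_panel",
    "simulate_two_state",
]


def default_pressure_grid(n_points: int = 9) -> np.ndarray:
    """Evenly spaced pressures over the experimental 0.1-200 MPa range."""
    return np.linspace(0.1, 200.0, n_points)


@dataclass(frozen=True)
class SimulationConfig:
    """Grid, noise and seeding for the generator.

    Noise defaults are the stated shift-reading uncertainties of the
    reference measurement (per nucleus); the 9-point grid is an assumed
    titration density, configurable.
    """

    pressure_grid: np.ndarray = field(default_factory=default_pressure_grid)
    noise_sd_H1: float = 0.001
    noise_sd_N15: float = 0.01
    seed: Optional[int] = None
    replicates: int = 1

    def __post_init__(self) -> None:
        grid = np.asarray(self.pressure_grid, dtype=float)
        object.__setattr__(self, "pressure_grid", grid)
        if grid.ndim != 1 or len(grid) < 3:
            raise ValueError("pressure_grid must be 1-D with >= 3 points")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("pressure_grid must be strictly increasing")
        if np.any(grid < 0) or np.any(grid > 1000):
            raise ValueError("pressure_grid must lie within [0, 1000] MPa")
        if self.noise_sd_H1 < 0 or self.noise_sd_N15 < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def noise_sd(self, nucleus: Union[Nucleus, str]) -> float:
        nucleus = Nucleus.coerce(nucleus)
        return self.noise_sd_N15 if nucleus is Nucleus.N15 else self.noise_sd_H1

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_series(
    coeffs: PressureCoefficients,
    config: SimulationConfig,
    nucleus: Union[Nucleus, str] = Nucleus.N15,
    rng: Optional[np.random.Generator] = None,
) -> PressureSeries:
    """Quadratic-model series on the config grid plus Gaussian noise.

    Pass an explicit ``rng`` to draw several series from one stream;
    otherwise a fresh generator is created from ``config.seed``.
    """
    nucleus = Nucleus.coerce(nucleus)
    if rng is None:
        rng = config.rng()
    grid = config.pressure_grid
    clean = np.asarray(predict_shift(coeffs, grid), dtype=float)
    sd = config.noise_sd(nucleus)
    noisy = clean + rng.normal(0.0, sd, size=grid.shape) if sd > 0 else clean
    return PressureSeries(pressures=grid, shifts=noisy, nucleus=nucleus.value)


def simulate_reference_panel(
    config: SimulationConfig,
    reference: Optional[ReferenceLibrary] = None,
) -> List[PeakTrack]:
    """One synthetic track per reference entry (22 15N then 19 1HN).

    Residue ids run 1..41 in table order; every track is generated from
    the entry's own published coefficients, so a noiseless panel is the
    exact null input for the correction pipeline.
    """
    if reference is None:
        reference = load_reference()
    rng = config.rng()
    tracks = []
    ordered = list(reference.subset(Nucleus.N15)) + list(reference.subset(Nucleus.H1N))
    for i, entry in enumerate(ordered, start=1):
        series = simulate_series(entry.coefficients, config, entry.nucleus, rng=rng)
        tracks.append(
            PeakTrack(
                residue_id=i,
                residue_type=entry.residue,
                nucleus=entry.nucleus.value,
                series=series,
                variant=entry.variant.value,
            )
        )
    return tracks


def simulate_two_state(
    model: EnsembleModel,
    config: SimulationConfig,
    nucleus: Union[Nucleus, str] = Nucleus.N15,
    rng: Optional[np.random.Generator] = None,
) -> PressureSeries:
    """Ensemble-model series on the config grid plus Gaussian noise."""
    nucleus = Nucleus.coerce(nucleus)
    if rng is None:
        rng = config.rng()
    grid = config.pressure_grid
    clean = np.asarray(ensemble_shift(model, grid), dtype=float)
    sd = config.noise_sd(nucleus)
    noisy = clean + rng.normal(0.0, sd, size=grid.shape) if sd > 0 else clean
    return PressureSeries(pressures=grid, shifts=noisy, nucleus=nucleus.value)
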