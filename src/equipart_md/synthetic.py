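"""Synthetic correlated time series and toy solute boxes.

Simulation logs (volumes, dipole moments, binding energies) are correlated
stationary series; a Gaussian AR(1) process is the minimal model with the
same qualitative structure, and its lag-1 coefficient phi maps to the
autocorrelation-threshold correlation length via n = ceil(ln 0.05/ln phi).
These generators give every estimator and free-energy stage a
fixture with analytically known ground truth, without running MD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .interactions import InteractionSpec, compute_energy_forces
from .models import Configuration, RNGStream, WaterModel, add_solute, build_water_lattice

__all__ = [
    "AR1Spec",
    "gen_ar1",
    "gen_dipole_series",
    "gen_binding_series",
    "gen_toy_ion_box",
]


@dataclass(frozen=True)
class AR1Spec:
    """Stationary Gaussian AR(1): mean, marginal SD, lag-1 coefficient."""

    mean: float = 0.0
    sd: float = 1.0
    phi: float = 0.0
    length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1.0:
            raise ValueError("|phi| must be < 1 for stationarity")
        if self.sd < 0.0 or self.length < 1:
            raise ValueError("sd must be >= 0 and length >= 1")

    @property
    def correlation_length(self) -> int:
        """Entries until the autocorrelation phi^k falls below 0.05."""
        if self.phi <= 0.0:
            return 1
        return math.ceil(math.log(0.05) / math.log(self.phi))


def gen_ar1(spec: AR1Spec) -> np.ndarray:
    """Stationary Gaussian AR(1) series with the specified marginal moments.

    x_t = mean + phi (x_{t-1} - mean) + sd sqrt(1 - phi^2) xi_t, with the
    first entry drawn from the marginal, so the series is stationary from
    entry 0 and reproducible by seed.
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(spec.seed)))
    xi = rng.standard_normal(spec.length)
    x = np.empty(spec.length)
    innov = spec.sd * math.sqrt(1.0 - spec.phi**2)
    x[0] = spec.sd * xi[0]
    for t in range(1, spec.length):
        x[t] = spec.phi * x[t - 1] + innov * xi[t]
    return spec.mean + x


def gen_dipole_series(
    per_component_sd: float, N: int, seed: int, phi: float = 0.0
) -> np.ndarray:
    """Zero-mean (N, 3) dipole series, one independent AR(1) per component."""
    cols = [
        gen_ar1(AR1Spec(0.0, per_component_sd, phi, N, seed * 3 + c))
        for c in range(3)
    ]
    return np.column_stack(cols)


def gen_binding_series(
    mean: float, sd: float, phi: float, N: int, seed: int
) -> np.ndarray:
    """Synthetic Gaussian solute binding-energy trace (kcal/mol)."""
    return gen_ar1(AR1Spec(mean, sd, phi, N, seed))


def gen_toy_ion_box(
    n_waters: int,
    model: WaterModel,
    ion_params: dict | None = None,
    seed: int = 0,
    density: float = 0.997,
    relax_steps: int = 50,
    interaction: InteractionSpec | None = None,
) -> Configuration:
    """Water box with one ion at the center at unchanged box volume.

    The ion is inserted assuming zero partial molar volume (the box is the
    pure-water box).  Overlaps are relaxed by steepest descent moving the
    ion only.  Default ion parameters are illustrative LJ values for a
    sodium-like sphere; override via ``ion_params`` (charge, sigma, eps,
    mass).
    """
    params = {"charge": 1.0, "sigma": 2.584, "eps": 0.1, "mass": 22.98977}
    if ion_params:
        params.update(ion_params)
    rng = RNGStream(seed)
    config = build_water_lattice(model, n_waters, density, rng)
    center = np.full(3, config.box_length / 2.0)
    # center of a lattice cell corner region: offset by half a spacing so the
    # ion starts between molecular lattice sites
    spacing = config.box_length / round(n_waters ** (1 / 3))
    config = add_solute(
        config,
        center + 0.5 * spacing,
        charge=params["charge"],
        sigma=params["sigma"],
        eps=params["eps"],
        mass=params["mass"],
    )
    if params["eps"] > 0.0 or params["charge"] != 0.0:
        _relax_ion(config, interaction or InteractionSpec(), relax_steps)
    return config


def _relax_ion(config: Configuration, ispec: InteractionSpec, n_steps: int) -> None:
    """Steepest descent on the ion position only (waters frozen)."""
    i = config.n_sites - 1
    gamma = 1e-3
    e_prev = None
    for _ in range(n_steps):
        rep = compute_energy_forces(config, ispec)
        if e_prev is not None and rep.e_total > e_prev:
            gamma *= 0.5
        else:
            gamma *= 1.2
        f = rep.forces[i]
        fnorm = float(np.linalg.norm(f))
        if fnorm < 1.0:
            break
        move = min(gamma * fnorm, 0.2)
        config.pos[i] += move * f / fnorm
        e_prev = rep.e_total
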