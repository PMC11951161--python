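"""Hydration free-energy components for charged and apolar solutes.

The electrostatic (charging) contribution is computed by thermodynamic
integration with the solute charges scaled linearly by lambda, so the TI
integrand is the full-charge solute-solvent electrostatic interaction
energy phi sampled in the lambda ensemble:

    mu_elec = sum_k w_k <phi>_{lambda_k}

evaluated on a three-point Gauss-Legendre schedule; the lambda = 0.5 node
alone is the linear-response estimate.  For a charged solute under periodic
boundary conditions with a neutralizing background, the Wigner
self-interaction correction (xi/2) sum q_i^2 with xi = -2.837297/L can be
added.  The van der Waals contribution uses the quasichemical
binding-energy route with the molecular envelope as the inner shell
(occupancy term dropped): Gaussian binding-energy statistics give
mu_vdW = <eps> + beta sigma^2/2, and the mean-field simplification keeps
only <eps>.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB, KB, XI_WIGNER
from .estimators import TimeSeriesEstimate, friedberg_cameron

__all__ = [
    "LambdaSchedule",
    "ChargingResult",
    "VdwResult",
    "gauss_legendre_3pt",
    "ti_charging",
    "charging_potential",
    "wigner_self_correction",
    "wigner_relative_correction",
    "vdw_from_binding_energies",
]


@dataclass(frozen=True)
class LambdaSchedule:
    """Quadrature nodes/weights on (0, 1) for charging TI."""

    nodes: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("quadrature weights must sum to 1")
        if any(b <= a for a, b in zip(self.nodes, self.nodes[1:])):
            raise ValueError("nodes must be strictly increasing")
        if self.nodes[0] <= 0.0 or self.nodes[-1] >= 1.0:
            raise ValueError("nodes must lie in the open interval (0, 1)")


@dataclass
class ChargingResult:
    """TI charging output: mu_elec and its pieces (kcal/mol)."""

    mu_elec: float
    stderr: float
    per_node: dict
    linear_response: float | None
    wigner_correction: float
    Q_net: float


@dataclass
class VdwResult:
    """Binding-energy statistics and the vdW free-energy estimates."""

    mean_binding: float
    mean_stderr: float
    variance: float
    mu_vdw_gaussian: float
    mu_vdw_gaussian_stderr: float
    mu_vdw_meanfield: float


def gauss_legendre_3pt() -> LambdaSchedule:
    """Three-point Gauss-Legendre rule mapped to (0, 1).

    Exact for polynomials up to degree 5; the middle node is exactly 0.5.
    """
    x, w = np.polynomial.legendre.leggauss(3)
    nodes = tuple(sorted((xi + 1.0) / 2.0 for xi in x))
    weights_by_node = sorted(zip((x + 1.0) / 2.0, w / 2.0))
    return LambdaSchedule(
        nodes=tuple(n for n, _ in weights_by_node),
        weights=tuple(wi for _, wi in weights_by_node),
    )


def ti_charging(
    engine_runs: dict,
    schedule: LambdaSchedule,
    Q: float,
    wigner: tuple | None = None,
) -> ChargingResult:
    """Charging free energy from per-lambda binding-potential series.

    ``engine_runs`` maps each node lambda_k to the sampled series of phi,
    the solute-solvent electrostatic interaction energy at FULL charges
    (linear charge scaling makes phi the TI integrand).  Uncertainties come
    from Friedberg-Cameron per node, propagated through the quadrature
    weights.  ``wigner = (charges, L)`` adds the self-interaction
    correction.  The lambda = 0.5 node, when present, is reported as the
    linear-response estimate.
    """
    mu = 0.0
    var = 0.0
    per_node = {}
    linear = None
    for lam, w in zip(schedule.nodes, schedule.weights):
        series = _lookup_node(engine_runs, lam)
        if series is None:
            raise ValueError(f"missing phi series for lambda={lam}")
        est = friedberg_cameron(series)
        per_node[lam] = est
        mu += w * est.mean
        var += (w * est.stderr) ** 2
        if abs(lam - 0.5) < 1e-9:
            linear = est.mean
    extra = [
        float(k) for k in engine_runs if not _lookup_node_key(schedule, float(k))
    ]
    if extra:
        raise ValueError(f"series supplied for non-schedule lambdas: {sorted(extra)}")
    correction = 0.0
    if wigner is not None:
        charges, L = wigner
        correction = wigner_self_correction(charges, L)
        mu += correction
    return ChargingResult(
        mu_elec=mu,
        stderr=float(np.sqrt(var)),
        per_node=per_node,
        linear_response=linear,
        wigner_correction=correction,
        Q_net=Q,
    )


def _lookup_node(engine_runs: dict, lam: float):
    for key, series in engine_runs.items():
        if abs(float(key) - lam) < 1e-9:
            return series
    return None


def _lookup_node_key(schedule: LambdaSchedule, lam: float) -> bool:
    return any(abs(n - lam) < 1e-9 for n in schedule.nodes)


def charging_potential(config, solute_site: int, interaction, lam: float) -> float:
    """TI integrand phi for a single-site ion, from a lambda-scaled frame.

    ``config`` carries the ion at its lambda-scaled charge q_lam; phi is
    the solute-solvent electrostatic interaction energy at FULL charges.
    With linear charge scaling the interaction is linear in lambda, so

        phi = [E_elec(q_lam) - E_elec(0) - (xi/2) q_lam^2 C / L] / lambda,

    where the subtracted term is the ion's own periodic self-interaction
    (its single-charge-plus-background Ewald energy), reported separately
    as the Wigner correction rather than folded into phi.
    """
    from .interactions import InteractionSpec, _ewald_part

    if lam <= 0.0:
        raise ValueError("lambda must be positive")
    espec = InteractionSpec(
        rcut_lj=0.0,
        rcut_real=interaction.rcut_real,
        ewald_tol=interaction.ewald_tol,
        tail_correction=False,
        kmax=interaction.kmax,
    )
    e_with = _ewald_part(config, espec, compute_forces=False).e_total
    neutral = config.copy()
    q_ion = float(neutral.charges[solute_site])
    neutral.charges[solute_site] = 0.0
    e_without = _ewald_part(neutral, espec, compute_forces=False).e_total
    self_term = wigner_self_correction([q_ion], config.box_length)
    return (e_with - e_without - self_term) / lam


def wigner_self_correction(charges, L: float) -> float:
    """Periodic self-interaction correction (xi/2) sum q_i^2, kcal/mol.

    xi = -2.837297/L is the lattice self-energy constant of a unit point
    charge in a cubic box with uniform neutralizing background.  An empty
    charge set returns 0.
    """
    if L <= 0.0:
        raise ValueError("box length must be positive")
    q = np.asarray(charges, dtype=float)
    if q.size == 0:
        return 0.0
    xi = XI_WIGNER / L
    return 0.5 * xi * float(q @ q) * COULOMB


def wigner_relative_correction(charges, L1: float, L2: float) -> float:
    """Wigner correction at L2 minus the one at L1 (kcal/mol)."""
    return wigner_self_correction(charges, L2) - wigner_self_correction(charges, L1)


def vdw_from_binding_energies(
    series_eps, T: float, mode: str = "gaussian"
) -> VdwResult:
    """Quasichemical vdW contribution from solute binding energies.

    With Gaussian binding-energy statistics P(eps) and the molecular
    envelope taken as the inner shell (p(n=0) = 1, packing term dropped):
    ``gaussian`` mode returns <eps> + beta sigma^2/2, ``meanfield`` only
    <eps>.  Uncertainties via Friedberg-Cameron on eps and on the squared
    fluctuations.
    """
    if mode not in ("gaussian", "meanfield"):
        raise ValueError("mode must be 'gaussian' or 'meanfield'")
    x = np.asarray(series_eps, dtype=float)
    if len(x) < 10:
        raise ValueError("binding-energy series too short (N >= 10)")
    if T <= 0.0:
        raise ValueError("temperature must be positive")
    est = friedberg_cameron(x)
    beta = 1.0 / (KB * T)
    dx2 = (x - x.mean()) ** 2
    var = float(dx2.mean())
    if np.ptp(x) == 0.0:
        var_stderr = 0.0
    else:
        var_stderr = friedberg_cameron(dx2).stderr
    mu_gauss = est.mean + 0.5 * beta * var
    gauss_stderr = float(np.sqrt(est.stderr**2 + (0.5 * beta * var_stderr) ** 2))
    return VdwResult(
        mean_binding=est.mean,
        mean_stderr=est.stderr,
        variance=var,
        mu_vdw_gaussian=mu_gauss,
        mu_vdw_gaussian_stderr=gauss_stderr,
        mu_vdw_meanfield=est.mean,
    )
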