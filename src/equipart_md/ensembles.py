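"""Thermostats, barostat, and the NVT/NpT driver.

The canonical stochastic velocity-rescaling (CSVR) thermostat applies one
global kinetic-energy rescale per step with exact canonical kinetic-energy
statistics; because the rescale is a single scalar it affects translational
and rotational kinetic energy by exactly the same factor each update.  The
Langevin thermostat applies a per-site Ornstein-Uhlenbeck kick after the
Verlet step (velocity constraints re-projected afterwards).  The Monte
Carlo barostat proposes ln-V moves that scale molecular centers of mass,
leaving rigid internal geometry untouched, and accepts with the Metropolis
criterion including the p*dV and (N_mol+1)*kB*T*ln(V'/V) Jacobian terms.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import BAR_A3_TO_KCAL_MOL, FORCE_TO_ACCEL, KB
from .dynamics import (
    IntegratorSpec,
    kinetic_energy,
    make_force_fn,
    project_velocities,
    step,
)
from .interactions import InteractionSpec, binding_energy, compute_energy_forces
from .models import Configuration, RNGStream, wrap_molecules

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleSpec",
    "SimulationLog",
    "csvr_rescale",
    "langevin_step",
    "mc_volume_move",
    "run_md",
    "n_degrees_of_freedom",
]


@dataclass
class EnsembleSpec:
    """Thermostat/barostat selection and targets.

    ``tau_csvr`` is the stochastic rescaling period in fs;
    ``gamma_langevin`` the friction in 1/ps; ``mc_every`` the barostat
    sampling frequency in steps; ``mc_dlnV_max`` the half-width of the
    uniform ln-V proposal.
    """

    thermostat: str = "csvr"  # csvr | langevin | none
    T_set: float = 298.15
    tau_csvr: float = 500.0
    gamma_langevin: float = 1.0
    barostat: str = "none"  # mc | none
    p_set: float = 1.0
    mc_every: int = 25
    mc_dlnV_max: float = 0.02

    def __post_init__(self) -> None:
        if self.T_set <= 0.0:
            raise ValueError("T_set must be positive")
        if self.tau_csvr <= 0.0:
            raise ValueError("tau_csvr must be positive")
        if self.mc_every < 1:
            raise ValueError("mc_every must be >= 1")
        if self.thermostat not in ("csvr", "langevin", "none"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.barostat not in ("mc", "none"):
            raise ValueError(f"unknown barostat {self.barostat!r}")


def n_degrees_of_freedom(config: Configuration, remove_com: bool = True) -> int:
    """Kinetic degrees of freedom: 6 per rigid water (3 translation +
    3 rotation), 3 per single-site solute; minus 3 when the total COM
    momentum is conserved at zero (not the case under a Langevin
    thermostat, whose random kicks re-thermalize the COM)."""
    n = 6 * config.n_waters + 3 * config.n_solute_sites
    return n - 3 if (remove_com and config.n_mol > 1) else n


# ---------------------------------------------------------------------------
# CSVR thermostat
# ---------------------------------------------------------------------------

def csvr_rescale(
    kinetic_energy_value: float,
    n_dof: int,
    dt: float,
    tau: float,
    T_set: float,
    rng: np.random.Generator | None = None,
    noise: tuple[float, float] | None = None,
) -> float:
    """One stochastic velocity-rescaling update; returns the factor alpha^2.

    The kinetic energy relaxes toward K_bar = n_dof*kB*T/2 with exponential
    memory exp(-dt/tau); the stochastic part uses one standard normal R1
    and one Gamma-distributed draw S ~ chi^2(n_dof - 1):

        alpha^2 = c + (1-c)(R1^2 + S) K_bar/(n_dof K)
                  + 2 R1 sqrt(c (1-c) K_bar/(n_dof K)),  c = exp(-dt/tau)

    ``noise`` is a test hook: pass (R1, R1^2 + S); the deterministic choice
    (0.0, n_dof) reduces the update to pure Berendsen-like relaxation with
    fixed point K = K_bar.
    """
    if kinetic_energy_value <= 0.0:
        raise ValueError("kinetic energy must be positive")
    if n_dof < 1:
        raise ValueError("n_dof must be >= 1")
    if dt <= 0.0 or tau <= 0.0 or T_set <= 0.0:
        raise ValueError("dt, tau and T_set must be positive")
    c = math.exp(-dt / tau)
    kbar = 0.5 * n_dof * KB * T_set
    if noise is None:
        if rng is None:
            raise ValueError("either rng or the noise hook must be given")
        r1 = rng.standard_normal()
        s = rng.gamma((n_dof - 1) / 2.0, 2.0) if n_dof > 1 else 0.0
        sum_sq = r1 * r1 + s
    else:
        r1, sum_sq = noise
    ratio = kbar / (n_dof * kinetic_energy_value)
    alpha2 = (
        c
        + (1.0 - c) * sum_sq * ratio
        + 2.0 * r1 * math.sqrt(c * (1.0 - c) * ratio)
    )
    return alpha2


# ---------------------------------------------------------------------------
# Langevin thermostat
# ---------------------------------------------------------------------------

def ou_kick(
    config: Configuration,
    gamma: float,
    T_set: float,
    dt: float,
    rng: np.random.Generator,
) -> None:
    """Per-site Ornstein-Uhlenbeck velocity update (the O step), in place.

    gamma in 1/ps, dt in fs.  Velocity constraints are NOT re-projected
    here; callers must do so for rigid molecules.
    """
    if gamma < 0.0:
        raise ValueError("gamma must be >= 0")
    if gamma == 0.0:
        return
    c1 = math.exp(-gamma * dt * 1.0e-3)
    sigma = np.sqrt(
        (1.0 - c1 * c1) * KB * T_set * FORCE_TO_ACCEL / config.masses
    )[:, None]
    config.vel *= c1
    config.vel += sigma * rng.standard_normal(size=config.vel.shape)


def langevin_step(
    config: Configuration,
    forces: np.ndarray,
    gamma: float,
    T_set: float,
    spec: IntegratorSpec,
    force_fn,
    rng: np.random.Generator,
):
    """One Verlet step followed by the OU kick and velocity re-projection.

    With gamma = 0 this is identical to a plain velocity-Verlet step.
    """
    report, prev = step(config, forces, spec, force_fn)
    if gamma > 0.0:
        ou_kick(config, gamma, T_set, spec.dt, rng)
        project_velocities(config, spec)
    return report, prev


# ---------------------------------------------------------------------------
# Monte Carlo barostat
# ---------------------------------------------------------------------------

def _scale_to_volume(config: Configuration, new_L: float) -> Configuration:
    """Return a copy with molecular COMs affinely scaled to the new box."""
    s = new_L / config.box_length
    out = config.copy()
    out.box_length = new_L
    nw = config.n_waters
    if nw:
        p = config.pos[: 3 * nw].reshape(nw, 3, 3)
        m = config.masses[: 3 * nw].reshape(nw, 3)
        com = (m[:, :, None] * p).sum(axis=1) / m.sum(axis=1)[:, None]
        out.pos[: 3 * nw] = (p + (s - 1.0) * com[:, None, :]).reshape(-1, 3)
    if config.n_solute_sites:
        out.pos[3 * nw :] = config.pos[3 * nw :] * s
    return out


def mc_volume_move(
    config: Configuration,
    energy_fn,
    p_set: float,
    dlnV_max: float,
    T_set: float,
    rng: np.random.Generator,
    current_energy: float | None = None,
):
    """Metropolis ln-V volume move; returns (configuration, accepted).

    Proposal: ln V' = ln V + U(-dlnV_max, +dlnV_max), molecular centers of
    mass scaled (rigid geometry untouched).  Acceptance:
    min{1, exp(-beta [dU + p dV - (N_mol + 1) kB T ln(V'/V)])}.
    On rejection (or an energy-function failure) the original configuration
    is returned untouched.
    """
    V = config.volume
    dln = rng.uniform(-dlnV_max, dlnV_max)
    V_new = math.exp(math.log(V) + dln)
    trial = _scale_to_volume(config, V_new ** (1.0 / 3.0))
    try:
        u_new = energy_fn(trial)
        if not math.isfinite(u_new):
            raise FloatingPointError("non-finite trial energy")
        u_old = energy_fn(config) if current_energy is None else current_energy
    except Exception as exc:  # noqa: BLE001 - reject and keep the state
        warnings.warn(f"volume move rejected: energy evaluation failed ({exc})")
        return config, False
    beta = 1.0 / (KB * T_set)
    n_mol = config.n_mol
    arg = -beta * (
        (u_new - u_old)
        + p_set * (V_new - V) * BAR_A3_TO_KCAL_MOL
        - (n_mol + 1) * KB * T_set * math.log(V_new / V)
    )
    if arg >= 0.0 or rng.uniform() < math.exp(arg):
        return trial, True
    return config, False


# ---------------------------------------------------------------------------
# NVT / NpT driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationLog:
    """Tabular time series from :func:`run_md` plus run metadata.

    ``data`` columns (units in names): step, time_fs, volume_A3, energy
    components (kcal/mol), T_trans_K, T_rot_K, dipole components (e*A) and
    optionally binding_kcal for a tagged solute.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)
    final_config: Configuration | None = None

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def run_md(
    config: Configuration,
    integrator: IntegratorSpec,
    ensemble: EnsembleSpec,
    n_steps: int,
    log_every: int = 25,
    rng: RNGStream | None = None,
    interaction: InteractionSpec | None = None,
    force_fn=None,
    tagged_molecule: int | None = None,
    binding_every: int | None = None,
    tune_barostat_until: int = 0,
    callback=None,
) -> SimulationLog:
    """Integrate ``n_steps`` with the requested thermostat/barostat.

    Returns time series of volume, energy components, translational and
    rotational temperatures, system dipole and (optionally) the binding
    energy of ``tagged_molecule``, sampled every ``log_every`` steps.  The
    configuration is advanced in place.  ``tune_barostat_until`` enables
    ln-V step-width tuning toward 40-50% acceptance during the first so
    many steps, after which the width is frozen.

    ``callback(istep, config)``, if given, may return a dict merged into
    each logged row (e.g. a charging potential sampled on the fly).

    Identical ``rng`` seeds and specs yield bit-identical logs.
    """
    from .estimators import trans_rot_temperatures

    rng = rng or RNGStream(0)
    interaction = interaction or InteractionSpec()
    if force_fn is None:
        force_fn = make_force_fn(interaction)
    energy_fn = None
    if ensemble.barostat == "mc":
        def energy_fn(c):
            return compute_energy_forces(c, interaction, compute_forces=False).e_total

    t_gen = rng.generator("thermostat")
    b_gen = rng.generator("barostat")
    n_dof = n_degrees_of_freedom(
        config, remove_com=ensemble.thermostat != "langevin"
    )
    report = force_fn(config)
    prev = None
    dlnv = ensemble.mc_dlnV_max
    mc_trials = 0
    mc_accepted = 0
    tune_trials = 0
    tune_accepted = 0
    rows = []
    has_binding = tagged_molecule is not None
    binding_every = binding_every or log_every

    for istep in range(1, n_steps + 1):
        if istep % 500 == 0:
            wrap_molecules(config)
        if ensemble.thermostat == "langevin":
            report, prev = langevin_step(
                config, report.forces, ensemble.gamma_langevin,
                ensemble.T_set, integrator, force_fn, t_gen,
            )
        else:
            report, prev = step(config, report.forces, integrator, force_fn, prev)
            if ensemble.thermostat == "csvr":
                ke = kinetic_energy(config)
                alpha2 = csvr_rescale(
                    ke, n_dof, integrator.dt, ensemble.tau_csvr,
                    ensemble.T_set, t_gen,
                )
                config.vel *= math.sqrt(alpha2)

        if ensemble.barostat == "mc" and istep % ensemble.mc_every == 0:
            new_config, accepted = mc_volume_move(
                config, energy_fn, ensemble.p_set, dlnv, ensemble.T_set,
                b_gen, current_energy=report.e_total,
            )
            mc_trials += 1
            mc_accepted += accepted
            if accepted:
                config.pos = new_config.pos
                config.box_length = new_config.box_length
                report = force_fn(config)
            if istep <= tune_barostat_until:
                tune_trials += 1
                tune_accepted += accepted
                if tune_trials == 20:
                    rate = tune_accepted / tune_trials
                    if rate < 0.40:
                        dlnv = max(dlnv * 0.7, 1.0e-5)
                    elif rate > 0.50:
                        dlnv = min(dlnv * 1.3, 0.5)
                    tune_trials = 0
                    tune_accepted = 0

        if istep % log_every == 0:
            t_trans, t_rot = trans_rot_temperatures(config)
            m = config.system_dipole()
            row = {
                "step": istep,
                "time_fs": config.time,
                "volume_A3": config.volume,
                "e_lj": report.e_lj,
                "e_lj_tail": report.e_lj_tail,
                "e_real": report.e_real,
                "e_recip": report.e_recip,
                "e_self_ewald": report.e_self_ewald,
                "e_intra_exclusion": report.e_intra_exclusion,
                "e_background": report.e_background,
                "e_potential": report.e_total,
                "e_kinetic": kinetic_energy(config),
                "T_trans_K": t_trans,
                "T_rot_K": t_rot,
                "Mx_eA": m[0],
                "My_eA": m[1],
                "Mz_eA": m[2],
            }
            if has_binding and istep % binding_every == 0:
                sites = np.where(config.mol_id == tagged_molecule)[0]
                row["binding_kcal"] = binding_energy(config, sites, interaction)
            if callback is not None:
                extra = callback(istep, config)
                if extra:
                    row.update(extra)
            rows.append(row)

    data = pd.DataFrame(rows)
    acc_rate = mc_accepted / mc_trials if mc_trials else float("nan")
    if mc_trials:
        logger.info(
            "MC barostat: %d/%d moves accepted (%.1f%%), final dlnV_max=%.4g",
            mc_accepted, mc_trials, 100 * acc_rate, dlnv,
        )
    meta = {
        "seed": rng.seed,
        "n_steps": n_steps,
        "dt_fs": integrator.dt,
        "scheme": integrator.scheme,
        "constraint": integrator.constraint,
        "thermostat": ensemble.thermostat,
        "barostat": ensemble.barostat,
        "T_set_K": ensemble.T_set,
        "p_set_bar": ensemble.p_set,
        "n_dof": n_dof,
        "n_waters": config.n_waters,
        "m_H_amu": float(config.masses[1]) if config.n_waters else None,
        "mc_acceptance": acc_rate,
        "mc_dlnV_max_final": dlnv,
    }
    return SimulationLog(data=data, meta=meta, final_config=config)
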