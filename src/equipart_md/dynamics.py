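"""Time integration of rigid molecules.

Velocity Verlet with holonomic constraints enforced either by the analytic
SETTLE solution for 3-site waters or by iterative RATTLE; the two solvers
cross-validate each other.  A standard Beeman predictor is available as an
alternative scheme.  Velocities are reported on-step as produced by the
integrator (no generalized-equipartition velocity refinement is applied:
the measured kinetic temperatures are exactly what the simulations see).

One full step is: half-kick, drift, position constraints (with the implied
velocity correction), force recompute, half-kick, velocity constraint
projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import FORCE_TO_ACCEL
from .interactions import EnergyReport, InteractionSpec, compute_energy_forces
from .models import Configuration

__all__ = [
    "IntegratorSpec",
    "step",
    "run_nve",
    "project_velocities",
    "apply_position_constraints",
    "kinetic_energy",
    "make_force_fn",
]


@dataclass
class IntegratorSpec:
    """Integration scheme, time-step (fs) and constraint solver."""

    scheme: str = "velocity_verlet"  # or "beeman"
    dt: float = 0.5
    constraint: str = "settle"  # or "rattle"
    rattle_tol: float = 1.0e-10
    rattle_maxiter: int = 500

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        if self.rattle_tol <= 0.0:
            raise ValueError("rattle_tol must be positive")
        if self.scheme not in ("velocity_verlet", "beeman"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.constraint not in ("settle", "rattle"):
            raise ValueError(f"unknown constraint solver {self.constraint!r}")


class ConstraintError(RuntimeError):
    """Raised when the constraint solver fails for a named molecule."""


# ---------------------------------------------------------------------------
# constraint kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _settle_pos(pos, pos_old, vel, n_w, m_o, m_h, ra, rb, rc, dt):
    """Analytic 3-site position constraint (Miyamoto-Kollman SETTLE).

    ``pos`` holds unconstrained drifted positions; ``pos_old`` the previous
    constrained positions.  Velocities receive the constraint correction
    (r_constrained - r_unconstrained)/dt.  Returns -1 or the index of the
    first failing molecule.
    """
    mtot = m_o + 2.0 * m_h
    for w in range(n_w):
        ia = 3 * w
        ib = ia + 1
        ic = ia + 2
        # old geometry relative to old oxygen
        xb0 = pos_old[ib] - pos_old[ia]
        xc0 = pos_old[ic] - pos_old[ia]
        # COM of unconstrained new positions
        com = (m_o * pos[ia] + m_h * pos[ib] + m_h * pos[ic]) / mtot
        a1 = pos[ia] - com
        b1 = pos[ib] - com
        c1 = pos[ic] - com
        # axes: z normal to old plane, a1 in the yz plane
        nz = np.cross(xb0, xc0)
        nx = np.cross(a1, nz)
        ny = np.cross(nz, nx)
        nz /= np.linalg.norm(nz)
        nx /= np.linalg.norm(nx)
        ny /= np.linalg.norm(ny)

        b0x = xb0 @ nx
        b0y = xb0 @ ny
        c0x = xc0 @ nx
        c0y = xc0 @ ny
        a1z = a1 @ nz
        b1x = b1 @ nx
        b1y = b1 @ ny
        b1z = b1 @ nz
        c1x = c1 @ nx
        c1y = c1 @ ny
        c1z = c1 @ nz

        sinphi = a1z / ra
        if sinphi > 1.0 or sinphi < -1.0:
            return w
        cosphi = math.sqrt(1.0 - sinphi * sinphi)
        sinpsi = (b1z - c1z) / (2.0 * rc * cosphi)
        if sinpsi > 1.0 or sinpsi < -1.0:
            return w
        cospsi = math.sqrt(1.0 - sinpsi * sinpsi)

        ya2 = ra * cosphi
        xb2 = -rc * cospsi
        yb2 = -rb * cosphi - rc * sinpsi * sinphi
        yc2 = -rb * cosphi + rc * sinpsi * sinphi

        alpha = xb2 * (b0x - c0x) + b0y * yb2 + c0y * yc2
        beta = xb2 * (c0y - b0y) + b0x * yb2 + c0x * yc2
        gamma = b0x * b1y - b1x * b0y + c0x * c1y - c1x * c0y
        al2be2 = alpha * alpha + beta * beta
        disc = al2be2 - gamma * gamma
        if disc < 0.0:
            return w
        sinthe = (alpha * gamma - beta * math.sqrt(disc)) / al2be2
        if sinthe > 1.0 or sinthe < -1.0:
            return w
        costhe = math.sqrt(1.0 - sinthe * sinthe)

        xa3 = -ya2 * sinthe
        ya3 = ya2 * costhe
        za3 = ra * sinphi
        xb3 = xb2 * costhe - yb2 * sinthe
        yb3 = xb2 * sinthe + yb2 * costhe
        zb3 = -rb * sinphi + rc * sinpsi * cosphi
        xc3 = -xb2 * costhe - yc2 * sinthe
        yc3 = -xb2 * sinthe + yc2 * costhe
        zc3 = -rb * sinphi - rc * sinpsi * cosphi

        for d in range(3):
            ra3d = com[d] + xa3 * nx[d] + ya3 * ny[d] + za3 * nz[d]
            rb3d = com[d] + xb3 * nx[d] + yb3 * ny[d] + zb3 * nz[d]
            rc3d = com[d] + xc3 * nx[d] + yc3 * ny[d] + zc3 * nz[d]
            vel[ia, d] += (ra3d - pos[ia, d]) / dt
            vel[ib, d] += (rb3d - pos[ib, d]) / dt
            vel[ic, d] += (rc3d - pos[ic, d]) / dt
            pos[ia, d] = ra3d
            pos[ib, d] = rb3d
            pos[ic, d] = rc3d
    return -1


@njit(cache=True)
def _settle_vel(pos, vel, n_w, m_o, m_h):
    """Exact velocity constraint for 3-site rigids: 3x3 solve per molecule.

    Impulses act along the current bond directions so that all constrained
    relative velocities vanish (the SETTLE velocity stage).
    """
    inv_a = 1.0 / m_o
    inv_b = 1.0 / m_h
    inv_c = 1.0 / m_h
    for w in range(n_w):
        ia = 3 * w
        ib = ia + 1
        ic = ia + 2
        eab = pos[ib] - pos[ia]
        ebc = pos[ic] - pos[ib]
        eca = pos[ia] - pos[ic]
        eab /= np.linalg.norm(eab)
        ebc /= np.linalg.norm(ebc)
        eca /= np.linalg.norm(eca)
        vab = (vel[ib] - vel[ia]) @ eab
        vbc = (vel[ic] - vel[ib]) @ ebc
        vca = (vel[ia] - vel[ic]) @ eca
        cosA = -(eab @ eca)
        cosB = -(ebc @ eab)
        cosC = -(eca @ ebc)
        # unknown impulses tau_ab, tau_bc, tau_ca; equations from
        # d/dt constraints = 0 after correction
        M = np.empty((3, 3))
        M[0, 0] = inv_a + inv_b
        M[0, 1] = inv_b * cosB
        M[0, 2] = inv_a * cosA
        M[1, 0] = inv_b * cosB
        M[1, 1] = inv_b + inv_c
        M[1, 2] = inv_c * cosC
        M[2, 0] = inv_a * cosA
        M[2, 1] = inv_c * cosC
        M[2, 2] = inv_c + inv_a
        rhs = np.empty(3)
        rhs[0] = vab
        rhs[1] = vbc
        rhs[2] = vca
        tau = np.linalg.solve(M, rhs)
        for d in range(3):
            vel[ia, d] += (tau[0] * eab[d] - tau[2] * eca[d]) * inv_a
            vel[ib, d] += (tau[1] * ebc[d] - tau[0] * eab[d]) * inv_b
            vel[ic, d] += (tau[2] * eca[d] - tau[1] * ebc[d]) * inv_c


@njit(cache=True)
def _rattle_pos(pos, pos_old, vel, n_w, m_o, m_h, d_oh, d_hh, tol, maxiter, dt):
    """Iterative SHAKE/RATTLE position stage.  Returns -1 or failing mol."""
    inv = np.empty(3)
    inv[0] = 1.0 / m_o
    inv[1] = 1.0 / m_h
    inv[2] = 1.0 / m_h
    d2 = np.empty(3)
    d2[0] = d_oh * d_oh
    d2[1] = d_oh * d_oh
    d2[2] = d_hh * d_hh
    pairs = np.empty((3, 2), dtype=np.int64)
    pairs[0, 0] = 0
    pairs[0, 1] = 1
    pairs[1, 0] = 0
    pairs[1, 1] = 2
    pairs[2, 0] = 1
    pairs[2, 1] = 2
    for w in range(n_w):
        base = 3 * w
        converged = False
        for _ in range(maxiter):
            maxdev = 0.0
            for k in range(3):
                i = base + pairs[k, 0]
                j = base + pairs[k, 1]
                rx = pos[i, 0] - pos[j, 0]
                ry = pos[i, 1] - pos[j, 1]
                rz = pos[i, 2] - pos[j, 2]
                r2 = rx * rx + ry * ry + rz * rz
                diff = r2 - d2[k]
                dev = abs(diff) / d2[k]
                if dev > maxdev:
                    maxdev = dev
                if dev > tol:
                    sx = pos_old[i, 0] - pos_old[j, 0]
                    sy = pos_old[i, 1] - pos_old[j, 1]
                    sz = pos_old[i, 2] - pos_old[j, 2]
                    rs = rx * sx + ry * sy + rz * sz
                    g = diff / (2.0 * rs * (inv[pairs[k, 0]] + inv[pairs[k, 1]]))
                    gi = g * inv[pairs[k, 0]]
                    gj = g * inv[pairs[k, 1]]
                    pos[i, 0] -= gi * sx
                    pos[i, 1] -= gi * sy
                    pos[i, 2] -= gi * sz
                    pos[j, 0] += gj * sx
                    pos[j, 1] += gj * sy
                    pos[j, 2] += gj * sz
                    vel[i, 0] -= gi * sx / dt
                    vel[i, 1] -= gi * sy / dt
                    vel[i, 2] -= gi * sz / dt
                    vel[j, 0] += gj * sx / dt
                    vel[j, 1] += gj * sy / dt
                    vel[j, 2] += gj * sz / dt
            if maxdev <= tol:
                converged = True
                break
        if not converged:
            return w
    return -1


@njit(cache=True)
def _rattle_vel(pos, vel, n_w, m_o, m_h, tol, maxiter):
    """Iterative RATTLE velocity stage.  Returns -1 or failing mol.

    Convergence criterion: bond-direction relative speeds below ``tol``
    in A/fs.
    """
    inv = np.empty(3)
    inv[0] = 1.0 / m_o
    inv[1] = 1.0 / m_h
    inv[2] = 1.0 / m_h
    pairs = np.empty((3, 2), dtype=np.int64)
    pairs[0, 0] = 0
    pairs[0, 1] = 1
    pairs[1, 0] = 0
    pairs[1, 1] = 2
    pairs[2, 0] = 1
    pairs[2, 1] = 2
    for w in range(n_w):
        base = 3 * w
        converged = False
        for _ in range(maxiter):
            maxdev = 0.0
            for k in range(3):
                i = base + pairs[k, 0]
                j = base + pairs[k, 1]
                rx = pos[i, 0] - pos[j, 0]
                ry = pos[i, 1] - pos[j, 1]
                rz = pos[i, 2] - pos[j, 2]
                r2 = rx * rx + ry * ry + rz * rz
                vx = vel[i, 0] - vel[j, 0]
                vy = vel[i, 1] - vel[j, 1]
                vz = vel[i, 2] - vel[j, 2]
                rv = rx * vx + ry * vy + rz * vz
                dev = abs(rv) / math.sqrt(r2)
                if dev > maxdev:
                    maxdev = dev
                if dev > tol:
                    kk = rv / (r2 * (inv[pairs[k, 0]] + inv[pairs[k, 1]]))
                    ki = kk * inv[pairs[k, 0]]
                    kj = kk * inv[pairs[k, 1]]
                    vel[i, 0] -= ki * rx
                    vel[i, 1] -= ki * ry
                    vel[i, 2] -= ki * rz
                    vel[j, 0] += kj * rx
                    vel[j, 1] += kj * ry
                    vel[j, 2] += kj * rz
            if maxdev <= tol:
                converged = True
                break
        if not converged:
            return w
    return -1


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _water_masses(config: Configuration) -> tuple[float, float]:
    if config.n_waters == 0:
        return 1.0, 1.0
    return float(config.masses[0]), float(config.masses[1])


def _settle_geometry(config: Configuration) -> tuple[float, float, float]:
    model = config.model
    if model is None:
        raise ValueError("configuration has no water model attached")
    m_o, m_h = _water_masses(config)
    rc = 0.5 * model.d_HH
    t = math.sqrt(model.d_OH**2 - rc**2)
    ra = 2.0 * m_h * t / (m_o + 2.0 * m_h)
    rb = t - ra
    return ra, rb, rc


def apply_position_constraints(
    config: Configuration, pos_old: np.ndarray, spec: IntegratorSpec
) -> None:
    """Restore rigid water geometry after an unconstrained drift (in place).

    Velocities receive the constraint correction (Delta r)/dt.
    """
    if config.n_waters == 0:
        return
    m_o, m_h = _water_masses(config)
    if spec.constraint == "settle":
        ra, rb, rc = _settle_geometry(config)
        fail = _settle_pos(
            config.pos, pos_old, config.vel, config.n_waters, m_o, m_h,
            ra, rb, rc, spec.dt,
        )
        if fail >= 0:
            raise ConstraintError(f"SETTLE failed for molecule {fail}")
    else:
        model = config.model
        fail = _rattle_pos(
            config.pos, pos_old, config.vel, config.n_waters, m_o, m_h,
            model.d_OH, model.d_HH, spec.rattle_tol, spec.rattle_maxiter,
            spec.dt,
        )
        if fail >= 0:
            raise ConstraintError(
                f"RATTLE did not converge in {spec.rattle_maxiter} iterations "
                f"for molecule {fail}"
            )


def project_velocities(
    config: Configuration, spec: IntegratorSpec | None = None
) -> None:
    """Remove velocity components along the rigid constraints (in place)."""
    if config.n_waters == 0:
        return
    m_o, m_h = _water_masses(config)
    if spec is not None and spec.constraint == "rattle":
        fail = _rattle_vel(
            config.pos, config.vel, config.n_waters, m_o, m_h,
            spec.rattle_tol, spec.rattle_maxiter,
        )
        if fail >= 0:
            raise ConstraintError(
                f"RATTLE velocity stage did not converge for molecule {fail}"
            )
    else:
        _settle_vel(config.pos, config.vel, config.n_waters, m_o, m_h)


def kinetic_energy(config: Configuration) -> float:
    """Total kinetic energy in kcal/mol."""
    v2 = (config.vel**2).sum(axis=1)
    return 0.5 * float(config.masses @ v2) / FORCE_TO_ACCEL


def make_force_fn(ispec: InteractionSpec):
    """Wrap an :class:`InteractionSpec` as a force provider for the drivers."""

    def force_fn(config: Configuration) -> EnergyReport:
        return compute_energy_forces(config, ispec)

    return force_fn


def step(
    config: Configuration,
    forces: np.ndarray,
    spec: IntegratorSpec,
    force_fn,
    prev_forces: np.ndarray | None = None,
):
    """Advance ``config`` by one step in place.

    ``forces`` must be consistent with the current positions (e.g. from the
    previous step's report).  Returns ``(report, prev_forces)`` where
    ``report`` is the :class:`EnergyReport` at the new positions and
    ``prev_forces`` feeds the next Beeman step (``None`` for velocity
    Verlet).
    """
    if spec.scheme == "beeman":
        return _beeman_step(config, forces, spec, force_fn, prev_forces)
    dt = spec.dt
    accel = forces * (FORCE_TO_ACCEL / config.masses[:, None])
    config.vel += 0.5 * dt * accel
    pos_old = config.pos.copy()
    config.pos = config.pos + dt * config.vel
    apply_position_constraints(config, pos_old, spec)
    report = force_fn(config)
    accel = report.forces * (FORCE_TO_ACCEL / config.masses[:, None])
    config.vel += 0.5 * dt * accel
    project_velocities(config, spec)
    config.time += dt
    return report, None


def _beeman_step(config, forces, spec, force_fn, prev_forces):
    """Standard Beeman predictor with the same constraint treatment."""
    dt = spec.dt
    inv_m = FORCE_TO_ACCEL / config.masses[:, None]
    if prev_forces is None:
        prev_forces = forces
    a_now = forces * inv_m
    a_prev = prev_forces * inv_m
    pos_old = config.pos.copy()
    config.pos = config.pos + dt * config.vel + dt * dt / 6.0 * (
        4.0 * a_now - a_prev
    )
    apply_position_constraints(config, pos_old, spec)
    report = force_fn(config)
    a_new = report.forces * inv_m
    config.vel += dt / 6.0 * (2.0 * a_new + 5.0 * a_now - a_prev)
    project_velocities(config, spec)
    config.time += dt
    return report, forces.copy()


def run_nve(
    config: Configuration,
    spec: IntegratorSpec,
    force_fn,
    n_steps: int,
    report_every: int = 10,
):
    """Microcanonical driver: no thermostat or barostat.

    Returns ``(frames, energies)`` where ``frames`` are archived copies of
    the configuration every ``report_every`` steps (including the start)
    and ``energies`` is a dict of numpy arrays with keys ``step``, ``time``,
    ``kinetic``, ``potential``, ``total`` (kcal/mol).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    report = force_fn(config)
    prev = None
    frames = [config.copy()]
    rows = [(0, config.time, kinetic_energy(config), report.e_total)]
    for istep in range(1, n_steps + 1):
        report, prev = step(config, report.forces, spec, force_fn, prev)
        if istep % report_every == 0 or istep == n_steps:
            frames.append(config.copy())
            rows.append((istep, config.time, kinetic_energy(config), report.e_total))
    arr = np.array(rows)
    energies = {
        "step": arr[:, 0],
        "time": arr[:, 1],
        "kinetic": arr[:, 2],
        "potential": arr[:, 3],
        "total": arr[:, 2] + arr[:, 3],
    }
    return frames, energies
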