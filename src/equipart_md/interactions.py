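"""Potential energy and forces: Lennard-Jones and plain Ewald electrostatics.

Lennard-Jones interactions use Lorentz-Berthelot mixing with either a sharp
cutoff plus an analytic long-range tail correction (bulk-water profile) or a
C1 switching window (the switched profile, no tail).  Electrostatics use a
full Ewald sum: real-space term screened by erfc with the splitting
parameter chosen from a relative tolerance at the real-space cutoff,
reciprocal sum truncated so the largest omitted Gaussian factor is below the
same tolerance, point self-energy, intramolecular exclusion corrections for
rigid charge groups, and the uniform-background term for non-neutral boxes.

Plain Ewald (not mesh-based PME) is used throughout: the boxes here are
small, and bit-for-bit reproducibility plus a simple brute-force oracle
matter more than asymptotic speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import erfcinv

from .constants import COULOMB
from .models import Configuration

__all__ = [
    "InteractionSpec",
    "EnergyReport",
    "lj_energy_forces",
    "ewald_energy_forces",
    "compute_energy_forces",
    "binding_energy",
    "select_molecules",
]


@dataclass
class InteractionSpec:
    """Cutoffs and Ewald controls, mirroring the bulk-water protocol.

    ``switch_window`` (r_on, r_off) replaces the sharp LJ cutoff by a C1
    switch; the tail correction only applies to the sharp-cutoff profile.
    ``ewald_tol`` is the relative real-space tolerance at ``rcut_real``;
    ``kmax`` overrides the automatic reciprocal-space truncation.
    """

    rcut_lj: float = 9.0
    rcut_real: float = 9.0
    ewald_tol: float = 1.0e-7
    tail_correction: bool = True
    switch_window: tuple[float, float] | None = None
    kmax: int | None = None

    def alpha(self) -> float:
        """Ewald splitting parameter: erfc(alpha*rcut)/rcut <= tol (1/A)."""
        if self.ewald_tol <= 0.0:
            raise ValueError("ewald_tol must be positive")
        return float(erfcinv(self.ewald_tol * self.rcut_real)) / self.rcut_real

    def nmax(self, L: float) -> int:
        """Integer reciprocal-space truncation for box length ``L``."""
        if self.kmax is not None:
            return int(self.kmax)
        return math.ceil(
            self.alpha() * L * math.sqrt(-math.log(self.ewald_tol)) / math.pi
        )


@dataclass
class EnergyReport:
    """Decomposed potential energy (kcal/mol) and forces (kcal/mol/A).

    ``e_total`` is always the plain sum of the six components plus the
    background term; the tail correction contributes no force.
    """

    e_lj: float = 0.0
    e_lj_tail: float = 0.0
    e_real: float = 0.0
    e_recip: float = 0.0
    e_self_ewald: float = 0.0
    e_intra_exclusion: float = 0.0
    e_background: float = 0.0
    forces: np.ndarray | None = None

    @property
    def e_total(self) -> float:
        return (
            self.e_lj
            + self.e_lj_tail
            + self.e_real
            + self.e_recip
            + self.e_self_ewald
            + self.e_intra_exclusion
            + self.e_background
        )

    def __add__(self, other: "EnergyReport") -> "EnergyReport":
        f = None
        if self.forces is not None and other.forces is not None:
            f = self.forces + other.forces
        elif self.forces is not None:
            f = self.forces.copy()
        elif other.forces is not None:
            f = other.forces.copy()
        return EnergyReport(
            self.e_lj + other.e_lj,
            self.e_lj_tail + other.e_lj_tail,
            self.e_real + other.e_real,
            self.e_recip + other.e_recip,
            self.e_self_ewald + other.e_self_ewald,
            self.e_intra_exclusion + other.e_intra_exclusion,
            self.e_background + other.e_background,
            f,
        )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _pair_kernel(
    pos,
    q,
    sig,
    eps,
    mol_id,
    L,
    rcut_lj,
    rcut_real,
    alpha,
    use_switch,
    r_on,
    use_real,
    compute_forces,
    forces,
):
    """Minimum-image pair loop: LJ (+switch) and real-space Ewald.

    Assumes every site-site separation is within 1.5 L per axis (the MD
    drivers wrap molecular COMs periodically to guarantee this), so a
    single conditional fold gives the minimum image.
    """
    n = pos.shape[0]
    halfL = 0.5 * L
    e_lj = 0.0
    e_real = 0.0
    rc_lj2 = rcut_lj * rcut_lj
    rc_re2 = rcut_real * rcut_real
    rmax2 = max(rc_lj2, rc_re2)
    ron2 = r_on * r_on
    denom = (rc_lj2 - ron2) ** 3 if use_switch else 1.0
    two_over_sqrt_pi = 2.0 / math.sqrt(math.pi)
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        qi = q[i]
        for j in range(i + 1, n):
            if mol_id[i] == mol_id[j]:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if dx > halfL:
                dx -= L
            elif dx < -halfL:
                dx += L
            if dy > halfL:
                dy -= L
            elif dy < -halfL:
                dy += L
            if dz > halfL:
                dz -= L
            elif dz < -halfL:
                dz += L
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rmax2:
                continue
            fscal = 0.0  # dE/dr / r (so f_i = -fscal * r_ij)
            if r2 < rc_lj2 and eps[i] > 0.0 and eps[j] > 0.0:
                s = 0.5 * (sig[i] + sig[j])
                e = math.sqrt(eps[i] * eps[j])
                s2 = s * s / r2
                s6 = s2 * s2 * s2
                u = 4.0 * e * s6 * (s6 - 1.0)
                dudr_r = -24.0 * e * s6 * (2.0 * s6 - 1.0) / r2  # (dU/dr)/r
                if use_switch and r2 > ron2:
                    a = rc_lj2 - r2
                    b = rc_lj2 + 2.0 * r2 - 3.0 * ron2
                    sw = a * a * b / denom
                    dsw_dr_r = 12.0 * a * (ron2 - r2) / denom  # (dS/dr)/r
                    fscal += dudr_r * sw + u * dsw_dr_r
                    e_lj += u * sw
                else:
                    fscal += dudr_r
                    e_lj += u
            if use_real and r2 < rc_re2:
                qq = qi * q[j]
                if qq != 0.0:
                    r = math.sqrt(r2)
                    ar = alpha * r
                    erfc_ar = math.erfc(ar)
                    epair = COULOMB * qq * erfc_ar / r
                    e_real += epair
                    # (dE/dr)/r for the screened Coulomb pair:
                    # -C qq [erfc/r + (2a/sqrt(pi)) exp(-a^2 r^2)] / r^2
                    fscal += (
                        -(
                            epair
                            + COULOMB
                            * qq
                            * two_over_sqrt_pi
                            * alpha
                            * math.exp(-ar * ar)
                        )
                        / r2
                    )
            if compute_forces and fscal != 0.0:
                fx = -fscal * dx
                fy = -fscal * dy
                fz = -fscal * dz
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
    return e_lj, e_real


@njit(cache=True, fastmath=True)
def _recip_kernel(pos, q, L, alpha, nvecs, nmax, compute_forces, forces):
    """Reciprocal-space Ewald sum over a half-space of integer k-vectors.

    ``nvecs`` must be lexicographically sorted on (nx, ny) so the partial
    phase product q_i * e^(i kx x) * e^(i ky y) can be reused across the
    inner nz run.
    """
    n = pos.shape[0]
    twopi_L = 2.0 * math.pi / L
    vol = L * L * L
    pref = 2.0 * math.pi * COULOMB / vol
    inv4a2 = 1.0 / (4.0 * alpha * alpha)

    eix = np.empty((n, nmax + 1), dtype=np.complex128)
    eiy = np.empty((n, 2 * nmax + 1), dtype=np.complex128)
    eiz = np.empty((n, 2 * nmax + 1), dtype=np.complex128)
    for i in range(n):
        ex = complex(math.cos(twopi_L * pos[i, 0]), math.sin(twopi_L * pos[i, 0]))
        ey = complex(math.cos(twopi_L * pos[i, 1]), math.sin(twopi_L * pos[i, 1]))
        ez = complex(math.cos(twopi_L * pos[i, 2]), math.sin(twopi_L * pos[i, 2]))
        eix[i, 0] = 1.0 + 0.0j
        eiy[i, nmax] = 1.0 + 0.0j
        eiz[i, nmax] = 1.0 + 0.0j
        for m in range(1, nmax + 1):
            eix[i, m] = eix[i, m - 1] * ex
            eiy[i, nmax + m] = eiy[i, nmax + m - 1] * ey
            eiz[i, nmax + m] = eiz[i, nmax + m - 1] * ez
            eiy[i, nmax - m] = eiy[i, nmax + m].conjugate()
            eiz[i, nmax - m] = eiz[i, nmax + m].conjugate()

    txy = np.empty(n, dtype=np.complex128)
    phase = np.empty(n, dtype=np.complex128)
    energy = 0.0
    last_nx = -(10 * nmax + 100)
    last_ny = last_nx
    for kidx in range(nvecs.shape[0]):
        nx = nvecs[kidx, 0]
        ny = nvecs[kidx, 1]
        nz = nvecs[kidx, 2]
        if nx != last_nx or ny != last_ny:
            for i in range(n):
                txy[i] = q[i] * eix[i, nx] * eiy[i, nmax + ny]
            last_nx = nx
            last_ny = ny
        kx = twopi_L * nx
        ky = twopi_L * ny
        kz = twopi_L * nz
        k2 = kx * kx + ky * ky + kz * kz
        a = math.exp(-k2 * inv4a2) / k2
        s_re = 0.0
        s_im = 0.0
        for i in range(n):
            ph = txy[i] * eiz[i, nmax + nz]
            phase[i] = ph
            s_re += ph.real
            s_im += ph.imag
        energy += 2.0 * pref * a * (s_re * s_re + s_im * s_im)
        if compute_forces:
            c = 4.0 * pref * a
            for i in range(n):
                # Im(S^* ph_i)
                im = s_re * phase[i].imag - s_im * phase[i].real
                forces[i, 0] += c * kx * im
                forces[i, 1] += c * ky * im
                forces[i, 2] += c * kz * im
    return energy


@njit(cache=True, fastmath=False)
def _exclusion_kernel(pos, q, n_waters, alpha, compute_forces, forces):
    """Subtract reciprocal-space contributions of intramolecular pairs.

    Rigid waters exclude their O-H and H-H charge pairs from real space;
    the reciprocal sum includes them, so -erf(alpha r)/r is added back.
    Uses true (unwrapped) intramolecular distances.
    """
    e = 0.0
    two_over_sqrt_pi = 2.0 / math.sqrt(math.pi)
    for w in range(n_waters):
        base = 3 * w
        for a in range(3):
            for b in range(a + 1, 3):
                i = base + a
                j = base + b
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                r = math.sqrt(r2)
                ar = alpha * r
                erf_ar = 1.0 - math.erfc(ar)
                qq = q[i] * q[j]
                e -= COULOMB * qq * erf_ar / r
                if compute_forces:
                    # E_pair = -C qq erf(ar)/r ; (dE/dr)/r =
                    # -C qq [(2a/sqrt(pi)) exp(-a^2 r^2) - erf/r] / r^2
                    dedr_r = (
                        -COULOMB
                        * qq
                        * (
                            two_over_sqrt_pi * alpha * math.exp(-ar * ar)
                            - erf_ar / r
                        )
                        / r2
                    )
                    fx = -dedr_r * dx
                    fy = -dedr_r * dy
                    fz = -dedr_r * dz
                    forces[i, 0] += fx
                    forces[i, 1] += fy
                    forces[i, 2] += fz
                    forces[j, 0] -= fx
                    forces[j, 1] -= fy
                    forces[j, 2] -= fz
    return e


def _half_space_nvecs(nmax: int) -> np.ndarray:
    """Integer k-vectors (nx,ny,nz) on a half-space with |n| <= nmax."""
    rng = np.arange(-nmax, nmax + 1)
    grid = np.array(np.meshgrid(np.arange(nmax + 1), rng, rng, indexing="ij"))
    pts = grid.reshape(3, -1).T
    norm2 = (pts**2).sum(axis=1)
    keep = (norm2 > 0) & (norm2 <= nmax * nmax)
    # half space: nx > 0, or nx == 0 and (ny > 0 or (ny == 0 and nz > 0))
    nx, ny, nz = pts[:, 0], pts[:, 1], pts[:, 2]
    half = (nx > 0) | ((nx == 0) & ((ny > 0) | ((ny == 0) & (nz > 0))))
    out = pts[keep & half]
    order = np.lexsort((out[:, 2], out[:, 1], out[:, 0]))
    return np.ascontiguousarray(out[order], dtype=np.int64)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _check_cutoff(rcut: float, L: float) -> None:
    if rcut >= L / 2.0:
        raise ValueError(
            f"cutoff {rcut} A >= L/2 = {L / 2.0:.3f} A: minimum image invalid"
        )


def lj_tail_correction(config: Configuration, rcut: float) -> float:
    """Analytic long-range LJ correction, summed over species pairs.

    Assumes g(r) = 1 beyond the cutoff:
    E = (8*pi/3V) * sum_ab N_a N_b eps_ab sigma_ab^3
        [ (1/3)(sigma/rc)^9 - (sigma/rc)^3 ].
    """
    active = config.lj_eps > 0.0
    if not active.any():
        return 0.0
    pairs = {}
    for s, e in zip(config.lj_sigma[active], config.lj_eps[active]):
        pairs[(s, e)] = pairs.get((s, e), 0) + 1
    species = list(pairs.items())
    total = 0.0
    for (sa, ea), na in species:
        for (sb, eb), nb in species:
            s = 0.5 * (sa + sb)
            e = math.sqrt(ea * eb)
            x = s / rcut
            total += na * nb * e * s**3 * (x**9 / 3.0 - x**3)
    return 8.0 * math.pi / (3.0 * config.volume) * total


def lj_energy_forces(
    config: Configuration,
    cutoff: float,
    switch_window: tuple[float, float] | None = None,
    tail_correction: bool = True,
) -> EnergyReport:
    """Pairwise minimum-image Lennard-Jones energy and forces.

    With ``switch_window = (r_on, r_off)`` the pair energy is multiplied by
    a C1 polynomial switch on [r_on, r_off] (the cutoff becomes r_off and
    the tail correction is dropped); otherwise a sharp cutoff with an
    optional analytic tail correction is used.
    """
    if switch_window is not None:
        r_on, r_off = switch_window
        if not 0.0 < r_on < r_off:
            raise ValueError("switch window must satisfy 0 < r_on < r_off")
        cutoff = r_off
        use_switch = True
        tail = 0.0
    else:
        r_on = cutoff
        use_switch = False
        tail = lj_tail_correction(config, cutoff) if tail_correction else 0.0
    _check_cutoff(cutoff, config.box_length)
    forces = np.zeros_like(config.pos)
    e_lj, _ = _pair_kernel(
        config.pos,
        config.charges,
        config.lj_sigma,
        config.lj_eps,
        config.mol_id,
        config.box_length,
        cutoff,
        0.0,
        1.0,
        use_switch,
        r_on,
        False,
        True,
        forces,
    )
    return EnergyReport(e_lj=e_lj, e_lj_tail=tail, forces=forces)


def ewald_energy_forces(
    config: Configuration,
    r_cut: float = 9.0,
    tolerance: float = 1.0e-7,
    kmax: int | None = None,
    compute_forces: bool = True,
) -> EnergyReport:
    """Full Ewald electrostatic energy and forces.

    Includes the real-space erfc sum, the reciprocal sum, the point
    self-energy, intramolecular exclusion corrections for rigid waters,
    and the uniform-background term for non-neutral systems.
    """
    spec = InteractionSpec(
        rcut_lj=0.0,
        rcut_real=r_cut,
        ewald_tol=tolerance,
        tail_correction=False,
        kmax=kmax,
    )
    return _ewald_part(config, spec, compute_forces)


def _ewald_part(
    config: Configuration, spec: InteractionSpec, compute_forces: bool
) -> EnergyReport:
    _check_cutoff(spec.rcut_real, config.box_length)
    alpha = spec.alpha()
    L = config.box_length
    q = config.charges
    forces = np.zeros_like(config.pos)
    _, e_real = _pair_kernel(
        config.pos,
        q,
        config.lj_sigma,
        config.lj_eps,
        config.mol_id,
        L,
        0.0,
        spec.rcut_real,
        alpha,
        False,
        0.0,
        True,
        compute_forces,
        forces,
    )
    nmax = spec.nmax(L)
    nvecs = _half_space_nvecs(nmax)
    e_recip = _recip_kernel(
        config.pos, q, L, alpha, nvecs, nmax, compute_forces, forces
    )
    e_self = -COULOMB * alpha / math.sqrt(math.pi) * float(q @ q)
    e_excl = _exclusion_kernel(
        config.pos, q, config.n_waters, alpha, compute_forces, forces
    )
    qtot = float(q.sum())
    e_bg = -COULOMB * math.pi / (2.0 * alpha**2 * config.volume) * qtot**2
    return EnergyReport(
        e_real=e_real,
        e_recip=e_recip,
        e_self_ewald=e_self,
        e_intra_exclusion=e_excl,
        e_background=e_bg,
        forces=forces if compute_forces else None,
    )


def compute_energy_forces(
    config: Configuration,
    spec: InteractionSpec,
    compute_forces: bool = True,
) -> EnergyReport:
    """Total potential energy (LJ + Ewald) in a single pass; engine path."""
    L = config.box_length
    if spec.switch_window is not None:
        r_on, r_off = spec.switch_window
        rcut_lj = r_off
        use_switch = True
        tail = 0.0
    else:
        r_on = spec.rcut_lj
        rcut_lj = spec.rcut_lj
        use_switch = False
        tail = (
            lj_tail_correction(config, rcut_lj) if spec.tail_correction else 0.0
        )
    _check_cutoff(max(rcut_lj, spec.rcut_real), L)
    alpha = spec.alpha()
    forces = np.zeros_like(config.pos)
    e_lj, e_real = _pair_kernel(
        config.pos,
        config.charges,
        config.lj_sigma,
        config.lj_eps,
        config.mol_id,
        L,
        rcut_lj,
        spec.rcut_real,
        alpha,
        use_switch,
        r_on,
        True,
        compute_forces,
        forces,
    )
    nmax = spec.nmax(L)
    nvecs = _half_space_nvecs(nmax)
    e_recip = _recip_kernel(
        config.pos, config.charges, L, alpha, nvecs, nmax, compute_forces, forces
    )
    q = config.charges
    e_self = -COULOMB * alpha / math.sqrt(math.pi) * float(q @ q)
    e_excl = _exclusion_kernel(
        config.pos, q, config.n_waters, alpha, compute_forces, forces
    )
    qtot = float(q.sum())
    e_bg = -COULOMB * math.pi / (2.0 * alpha**2 * config.volume) * qtot**2
    return EnergyReport(
        e_lj=e_lj,
        e_lj_tail=tail,
        e_real=e_real,
        e_recip=e_recip,
        e_self_ewald=e_self,
        e_intra_exclusion=e_excl,
        e_background=e_bg,
        forces=forces if compute_forces else None,
    )


def select_molecules(config: Configuration, mol_indices) -> Configuration:
    """Sub-configuration containing only the given molecules (same box)."""
    mol_indices = np.asarray(sorted(set(int(m) for m in mol_indices)))
    mask = np.isin(config.mol_id, mol_indices)
    if not mask.any():
        raise ValueError("no sites selected")
    n_w = int(sum(1 for m in mol_indices if m < config.n_waters))
    new_ids = np.searchsorted(mol_indices, config.mol_id[mask])
    return Configuration(
        pos=config.pos[mask].copy(),
        vel=config.vel[mask].copy(),
        box_length=config.box_length,
        n_waters=n_w,
        charges=config.charges[mask].copy(),
        masses=config.masses[mask].copy(),
        lj_sigma=config.lj_sigma[mask].copy(),
        lj_eps=config.lj_eps[mask].copy(),
        mol_id=new_ids.astype(int),
        model=config.model,
        time=config.time,
    )


def binding_energy(
    config: Configuration,
    solute_site_set,
    spec: InteractionSpec | None = None,
) -> float:
    """Solute-solvent interaction energy by deletion difference (kcal/mol).

    Returns U(full) - U(system minus solute) - U(solute alone), with the
    same cutoffs and Ewald splitting in all three evaluations, so for a
    tagged water it is exactly the molecule's binding energy under the
    engine's electrostatics.
    """
    spec = spec or InteractionSpec()
    sites = np.asarray(sorted(set(int(s) for s in solute_site_set)))
    if sites.size == 0:
        raise ValueError("solute site set is empty")
    if sites.min() < 0 or sites.max() >= config.n_sites:
        raise ValueError("solute site set out of range")
    mols = np.unique(config.mol_id[sites])
    all_sites_of_mols = np.where(np.isin(config.mol_id, mols))[0]
    if not np.array_equal(all_sites_of_mols, sites):
        raise ValueError("solute site set must consist of whole molecules")
    rest = [m for m in range(config.n_mol) if m not in set(mols.tolist())]
    if not rest:
        raise ValueError("solute set covers the whole system")
    e_full = compute_energy_forces(config, spec, compute_forces=False).e_total
    e_rest = compute_energy_forces(
        select_molecules(config, rest), spec, compute_forces=False
    ).e_total
    e_solo = compute_energy_forces(
        select_molecules(config, mols), spec, compute_forces=False
    ).e_total
    return e_full - e_rest - e_solo
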