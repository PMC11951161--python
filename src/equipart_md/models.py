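"""Rigid 3-site water models, periodic boxes, velocities, mass repartitioning.

A :class:`WaterModel` is an immutable parameter set (geometry, masses,
charges, Lennard-Jones).  A :class:`Configuration` is the evolving MD state:
site positions and velocities, the cubic box length, and the per-site
parameter arrays the interaction kernels consume.  Water sites always come
first, ordered O, H, H per molecule; optional solute sites (e.g. toy ions)
are appended afterwards, one molecule each.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .constants import AVOGADRO

__all__ = [
    "WaterModel",
    "Configuration",
    "RNGStream",
    "water_model",
    "available_models",
    "build_water_lattice",
    "replicate_box",
    "init_velocities",
    "repartition_hydrogen_mass",
    "add_solute",
    "wrap_molecules",
    "write_xyz",
    "write_trajectory",
    "read_xyz",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterModel:
    """Immutable rigid 3-site water parameter set.

    Lengths in A, angle in degrees, masses in amu, charges in e,
    ``eps_*`` in kcal/mol.
    """

    name: str
    d_OH: float
    theta_HOH: float
    m_O: float
    m_H: float
    q_O: float
    q_H: float
    sigma_O: float
    eps_O: float
    sigma_H: float = 0.0
    eps_H: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.q_O + 2.0 * self.q_H) > 1e-12:
            raise ValueError("water molecule must be neutral: q_O + 2 q_H = 0")
        if self.d_HH <= 0.0:
            raise ValueError("H-H distance must be positive")
        if self.m_O <= 0.0 or self.m_H <= 0.0:
            raise ValueError("masses must be positive")

    @property
    def d_HH(self) -> float:
        """H-H distance implied by d_OH and the HOH angle (A)."""
        return 2.0 * self.d_OH * math.sin(math.radians(self.theta_HOH) / 2.0)

    @property
    def total_mass(self) -> float:
        """Molecular mass (amu)."""
        return self.m_O + 2.0 * self.m_H

    def canonical_sites(self) -> np.ndarray:
        """Site coordinates (O, H, H) relative to the molecular COM.

        The molecule lies in the xy plane with the C2 axis along y and the
        oxygen on the positive-y side.
        """
        rc = 0.5 * self.d_HH
        t = math.sqrt(self.d_OH**2 - rc**2)  # O height above the HH line
        ra = 2.0 * self.m_H * t / self.total_mass  # COM -> O distance
        rb = t - ra
        return np.array(
            [[0.0, ra, 0.0], [-rc, -rb, 0.0], [rc, -rb, 0.0]], dtype=float
        )


@dataclass
class Configuration:
    """Positions/velocities of all sites plus the cubic periodic box.

    ``pos``/``vel`` are (n_sites, 3) arrays in A and A/fs.  The first
    ``3*n_waters`` sites are waters (O, H, H per molecule); solute sites
    follow, one molecule per site.  ``mol_id`` maps site -> molecule.
    """

    pos: np.ndarray
    vel: np.ndarray
    box_length: float
    n_waters: int
    charges: np.ndarray
    masses: np.ndarray
    lj_sigma: np.ndarray
    lj_eps: np.ndarray
    mol_id: np.ndarray
    model: WaterModel | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.box_length <= 0.0:
            raise ValueError("box length must be positive")
        n = self.pos.shape[0]
        if self.vel.shape != (n, 3):
            raise ValueError("vel must match pos shape")
        if n < 3 * self.n_waters:
            raise ValueError("fewer sites than 3*n_waters")

    @property
    def n_sites(self) -> int:
        return self.pos.shape[0]

    @property
    def n_solute_sites(self) -> int:
        return self.n_sites - 3 * self.n_waters

    @property
    def n_mol(self) -> int:
        return int(self.mol_id[-1]) + 1 if self.n_sites else 0

    @property
    def volume(self) -> float:
        """Box volume (A^3)."""
        return self.box_length**3

    def copy(self) -> "Configuration":
        return replace(
            self,
            pos=self.pos.copy(),
            vel=self.vel.copy(),
            charges=self.charges.copy(),
            masses=self.masses.copy(),
            lj_sigma=self.lj_sigma.copy(),
            lj_eps=self.lj_eps.copy(),
            mol_id=self.mol_id.copy(),
        )

    def system_dipole(self) -> np.ndarray:
        """Total dipole moment sum(q_i r_i) in e*A.

        Meaningful for a collection of neutral molecules with unwrapped
        coordinates (the engine never wraps sites, so molecular dipoles
        are image-independent).
        """
        return self.charges @ self.pos


class RNGStream:
    """Deterministic random-number plumbing with named substreams.

    A single integer seed fans out, via ``numpy.random.SeedSequence.spawn``,
    into independent persistent Philox generators for initialization,
    thermostat, barostat and solute placement, so e.g. changing how many
    thermostat draws happen never perturbs the barostat stream.
    """

    SUBSTREAMS = ("init", "thermostat", "barostat", "solute")

    def __init__(self, seed: int, algorithm: str = "philox"):
        if algorithm != "philox":
            raise ValueError("only the 'philox' bit generator is supported")
        self.seed = int(seed)
        self.algorithm = algorithm
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(self.SUBSTREAMS))
        self._gens = {
            name: np.random.Generator(np.random.Philox(ss))
            for name, ss in zip(self.SUBSTREAMS, children)
        }

    def generator(self, substream: str = "init") -> np.random.Generator:
        return self._gens[substream]


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

def _load_registry() -> dict:
    text = (
        importlib.resources.files("equipart_md")
        .joinpath("data/water_models.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


_REGISTRY_CACHE: dict | None = None


def available_models() -> list[str]:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        _REGISTRY_CACHE = _load_registry()
    return sorted(_REGISTRY_CACHE)


def water_model(name: str) -> WaterModel:
    """Load a bundled rigid water model ('spce' or 'tip3p') by name."""
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        _REGISTRY_CACHE = _load_registry()
    try:
        params = _REGISTRY_CACHE[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown water model {name!r}; available: {available_models()}"
        ) from None
    return WaterModel(name=name.lower(), **params)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def box_length_for_density(n_mol: int, molar_mass: float, density: float) -> float:
    """Cubic box length (A) for ``n_mol`` molecules at ``density`` (g/cm^3)."""
    volume_a3 = n_mol * molar_mass / (AVOGADRO * density) * 1.0e24
    return volume_a3 ** (1.0 / 3.0)


def build_water_lattice(
    model: WaterModel,
    n_mol: int,
    density: float,
    rng: RNGStream | None = None,
) -> Configuration:
    """Place ``n_mol`` rigid waters on a simple-cubic molecular lattice.

    The box length satisfies L^3 = n_mol*M_w/(N_A*density); molecular COMs
    sit on the lattice with uniformly random rigid orientations, so every
    intramolecular geometry is exactly at the model values.

    Raises ``ValueError`` if ``n_mol`` is not a perfect cube (the lattice
    cannot be filled) or if the resulting minimum-image O-O distance falls
    below 1.5 A (overlapping sites).
    """
    if density <= 0.0:
        raise ValueError("density must be positive")
    k = round(n_mol ** (1.0 / 3.0))
    if k**3 != n_mol or n_mol < 1:
        raise ValueError(
            f"n_mol={n_mol} is not lattice-fillable (must be a perfect cube)"
        )
    gen = (rng or RNGStream(0)).generator("init")
    L = box_length_for_density(n_mol, model.total_mass, density)
    spacing = L / k
    template = model.canonical_sites()

    pos = np.empty((3 * n_mol, 3))
    idx = 0
    for i in range(k):
        for j in range(k):
            for l in range(k):
                com = (np.array([i, j, l], dtype=float) + 0.5) * spacing
                R = _random_rotation(gen)
                pos[3 * idx : 3 * idx + 3] = template @ R.T + com
                idx += 1

    charges = np.tile([model.q_O, model.q_H, model.q_H], n_mol)
    masses = np.tile([model.m_O, model.m_H, model.m_H], n_mol)
    lj_sigma = np.tile([model.sigma_O, model.sigma_H, model.sigma_H], n_mol)
    lj_eps = np.tile([model.eps_O, model.eps_H, model.eps_H], n_mol)
    mol_id = np.repeat(np.arange(n_mol), 3)

    config = Configuration(
        pos=pos,
        vel=np.zeros_like(pos),
        box_length=L,
        n_waters=n_mol,
        charges=charges,
        masses=masses,
        lj_sigma=lj_sigma,
        lj_eps=lj_eps,
        mol_id=mol_id,
        model=model,
    )
    if n_mol > 1:
        d_min = _min_image_oo_distance(pos[::3], L)
        if d_min < 1.5:
            raise ValueError(
                f"overlapping sites: minimum-image O-O distance {d_min:.3f} A"
            )
    return config


def _min_image_oo_distance(opos: np.ndarray, L: float) -> float:
    d = opos[:, None, :] - opos[None, :, :]
    d -= L * np.rint(d / L)
    r = np.sqrt((d**2).sum(-1))
    np.fill_diagonal(r, np.inf)
    return float(r.min())


def replicate_box(config: Configuration, factors: tuple[int, int, int]) -> Configuration:
    """Periodically replicate a cubic box by integer factors per axis.

    Cubic boxes require equal factors; ``(1, 1, 1)`` is the identity.
    Velocities and geometry are copied into every image.
    """
    kx, ky, kz = (int(f) for f in factors)
    if min(kx, ky, kz) < 1:
        raise ValueError("replication factors must be >= 1")
    if not (kx == ky == kz):
        raise ValueError("cubic box requires equal replication factors")
    if kx == 1:
        return config.copy()
    if config.n_solute_sites:
        raise ValueError("replication of boxes with solutes is not supported")
    k = kx
    L = config.box_length
    shifts = np.array(
        [[i, j, l] for i in range(k) for j in range(k) for l in range(k)],
        dtype=float,
    ) * L
    n_img = len(shifts)
    pos = (config.pos[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    vel = np.tile(config.vel, (n_img, 1))
    n_mol = config.n_waters * n_img
    return Configuration(
        pos=pos,
        vel=vel,
        box_length=L * k,
        n_waters=n_mol,
        charges=np.tile(config.charges, n_img),
        masses=np.tile(config.masses, n_img),
        lj_sigma=np.tile(config.lj_sigma, n_img),
        lj_eps=np.tile(config.lj_eps, n_img),
        mol_id=np.repeat(np.arange(n_mol), 3),
        model=config.model,
        time=config.time,
    )


def init_velocities(
    config: Configuration, T: float, rng: RNGStream | None = None
) -> Configuration:
    """Draw Maxwell-Boltzmann site velocities at temperature ``T`` (K).

    The total linear momentum is zeroed, then the RATTLE velocity
    projection removes any velocity component along the rigid constraints,
    so constrained relative velocities vanish exactly.
    """
    from .constants import FORCE_TO_ACCEL, KB
    from .dynamics import project_velocities

    if T <= 0.0:
        raise ValueError("temperature must be positive")
    gen = (rng or RNGStream(0)).generator("init")
    out = config.copy()
    # sigma_v = sqrt(kB T / m) in A/fs; KB*T is kcal/mol so convert via
    # the same factor that maps (kcal/mol)/amu to (A/fs)^2.
    sigma = np.sqrt(KB * T * FORCE_TO_ACCEL / out.masses)[:, None]
    out.vel = gen.normal(size=out.pos.shape) * sigma
    ptot = (out.masses[:, None] * out.vel).sum(axis=0)
    out.vel -= ptot / out.masses.sum()
    project_velocities(out)
    return out


def repartition_hydrogen_mass(model: WaterModel, m_H_new: float) -> WaterModel:
    """Hydrogen mass repartitioning: move mass from O to H at fixed total.

    Charges and geometry are untouched; ``m_O`` becomes
    ``total_mass - 2*m_H_new``.  Raises if that would make ``m_O <= 0``.
    """
    total = model.total_mass
    if not 0.0 < m_H_new < total / 2.0:
        raise ValueError(
            f"m_H_new={m_H_new} amu would leave oxygen with non-positive mass"
        )
    return replace(model, m_H=m_H_new, m_O=total - 2.0 * m_H_new)


def wrap_molecules(config: Configuration) -> None:
    """Translate whole molecules so every COM lies in [0, L), in place.

    Whole-molecule translation by lattice vectors leaves energies, rigid
    geometry and molecular dipoles unchanged; the MD drivers call this
    periodically so site-site separations stay within the minimum-image
    fold of the interaction kernels.
    """
    L = config.box_length
    nw = config.n_waters
    if nw:
        p = config.pos[: 3 * nw].reshape(nw, 3, 3)
        m = config.masses[: 3 * nw].reshape(nw, 3)
        com = (m[:, :, None] * p).sum(axis=1) / m.sum(axis=1)[:, None]
        shift = np.floor(com / L) * L
        config.pos[: 3 * nw] = (p - shift[:, None, :]).reshape(-1, 3)
    if config.n_solute_sites:
        s = config.pos[3 * nw :]
        config.pos[3 * nw :] = s - np.floor(s / L) * L


def add_solute(
    config: Configuration,
    position: np.ndarray,
    charge: float = 0.0,
    sigma: float = 0.0,
    eps: float = 0.0,
    mass: float = 22.98977,
) -> Configuration:
    """Append a single-site solute (e.g. a toy LJ ion) as its own molecule."""
    out = config.copy()
    out.pos = np.vstack([out.pos, np.asarray(position, dtype=float)])
    out.vel = np.vstack([out.vel, np.zeros(3)])
    out.charges = np.append(out.charges, charge)
    out.masses = np.append(out.masses, mass)
    out.lj_sigma = np.append(out.lj_sigma, sigma)
    out.lj_eps = np.append(out.lj_eps, eps)
    out.mol_id = np.append(out.mol_id, out.mol_id[-1] + 1 if len(out.mol_id) else 0)
    return out


# ---------------------------------------------------------------------------
# extended-XYZ I/O
# ---------------------------------------------------------------------------

def write_xyz(config: Configuration, path, append: bool = False) -> None:
    """Write one extended-XYZ frame (element, x, y, z, vx, vy, vz).

    The comment line carries the box length and time.
    """
    elements = ["O", "H", "H"] * config.n_waters + ["X"] * config.n_solute_sites
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{config.n_sites}\n")
        fh.write(f"L={config.box_length:.10f} time={config.time:.6f}\n")
        for el, r, v in zip(elements, config.pos, config.vel):
            fh.write(
                f"{el} {r[0]:.10f} {r[1]:.10f} {r[2]:.10f} "
                f"{v[0]:.10e} {v[1]:.10e} {v[2]:.10e}\n"
            )


def write_trajectory(frames, path) -> None:
    """Write archived frames (e.g. from the NVE driver) as multi-frame XYZ."""
    for i, frame in enumerate(frames):
        write_xyz(frame, path, append=i > 0)


def read_xyz(path, model: WaterModel) -> Configuration:
    """Read the first extended-XYZ frame written by :func:`write_xyz`.

    Water parameters are rebuilt from ``model``; solute sites (element X)
    come back with zero charge/LJ and unit mass and must be re-dressed by
    the caller.
    """
    with open(path) as fh:
        n = int(fh.readline())
        comment = fh.readline().split()
        meta = dict(kv.split("=") for kv in comment)
        rows = [fh.readline().split() for _ in range(n)]
    elements = [r[0] for r in rows]
    data = np.array([[float(x) for x in r[1:7]] for r in rows])
    n_waters = elements.count("O")
    expected = ["O", "H", "H"] * n_waters
    if elements[: 3 * n_waters] != expected:
        raise ValueError("sites are not ordered O,H,H per water molecule")
    n_sol = n - 3 * n_waters
    charges = np.concatenate(
        [np.tile([model.q_O, model.q_H, model.q_H], n_waters), np.zeros(n_sol)]
    )
    masses = np.concatenate(
        [np.tile([model.m_O, model.m_H, model.m_H], n_waters), np.ones(n_sol)]
    )
    sig = np.concatenate(
        [np.tile([model.sigma_O, model.sigma_H, model.sigma_H], n_waters), np.zeros(n_sol)]
    )
    eps = np.concatenate(
        [np.tile([model.eps_O, model.eps_H, model.eps_H], n_waters), np.zeros(n_sol)]
    )
    mol_id = np.concatenate(
        [np.repeat(np.arange(n_waters), 3), n_waters + np.arange(n_sol)]
    ).astype(int)
    return Configuration(
        pos=data[:, :3].copy(),
        vel=data[:, 3:6].copy(),
        box_length=float(meta["L"]),
        n_waters=n_waters,
        charges=charges,
        masses=masses,
        lj_sigma=sig,
        lj_eps=eps,
        mol_id=mol_id,
        model=model,
        time=float(meta.get("time", 0.0)),
    )
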