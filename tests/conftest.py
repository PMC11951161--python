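"""Shared fixtures: small water boxes and the desk-scale simulation runs
used by the acceptance suite (session-scoped so several tests share one
trajectory)."""

from __future__ import annotations

import numpy as np
import pytest

from equipart_md.dynamics import IntegratorSpec
from equipart_md.ensembles import EnsembleSpec, run_md
from equipart_md.interactions import InteractionSpec
from equipart_md.models import (
    RNGStream,
    build_water_lattice,
    init_velocities,
    repartition_hydrogen_mass,
    water_model,
)

# Desk-scale protocol: the bulk-water study conditions (SPC/E, 298.15 K,
# 1 bar, CSVR tau = 0.5 ps, MC barostat every 25 steps) at reduced system
# size and run length.  Cutoffs are the largest that respect the
# minimum-image bound of each box.
T_SET = 298.15
ISPEC_125 = InteractionSpec(rcut_lj=7.0, rcut_real=7.0, ewald_tol=1e-5)
ISPEC_64 = InteractionSpec(rcut_lj=5.5, rcut_real=5.5, ewald_tol=1e-5)


@pytest.fixture(scope="session")
def spce():
    return water_model("spce")


@pytest.fixture(scope="session")
def tip3p():
    return water_model("tip3p")


@pytest.fixture(scope="session")
def water8(spce):
    """Dilute 8-water box (large enough for a 4.2 A cutoff)."""
    c = build_water_lattice(spce, 8, 0.35, RNGStream(3))
    return init_velocities(c, T_SET, RNGStream(3))


@pytest.fixture(scope="session")
def water27(spce):
    c = build_water_lattice(spce, 27, 0.997, RNGStream(5))
    return init_velocities(c, T_SET, RNGStream(5))


@pytest.fixture(scope="session")
def equilibrated_125(spce):
    """125 SPC/E waters melted from the lattice: 5 ps NVT at dt = 0.5 fs."""
    c = build_water_lattice(spce, 125, 0.997, RNGStream(42))
    c = init_velocities(c, T_SET, RNGStream(42))
    run_md(
        c,
        IntegratorSpec(dt=0.5),
        EnsembleSpec(thermostat="csvr", T_set=T_SET, tau_csvr=100.0),
        10000,
        log_every=2000,
        rng=RNGStream(43),
        interaction=ISPEC_125,
    )
    return c


def _gap_run(start, dt, seed, n_steps, hmr=False):
    """One NVT production run; returns (T_trans, T_rot) series tail."""
    cc = start.copy()
    if hmr:
        model = repartition_hydrogen_mass(cc.model, 3.024)
        cc.masses = np.tile([model.m_O, model.m_H, model.m_H], cc.n_waters)
        cc.model = model
    log = run_md(
        cc,
        IntegratorSpec(dt=dt),
        EnsembleSpec(thermostat="csvr", T_set=T_SET, tau_csvr=500.0),
        n_steps,
        log_every=10,
        rng=RNGStream(seed),
        interaction=ISPEC_125,
    )
    d = log.data
    q = len(d) // 6  # discard re-equilibration at the new dt (or masses)
    return d.T_trans_K.values[q:], d.T_rot_K.values[q:]


@pytest.fixture(scope="session")
def equipartition_runs(equilibrated_125):
    """Per-seed NVT temperature series at dt = 0.5 and 3.0 fs."""
    return {
        0.5: [_gap_run(equilibrated_125, 0.5, 100 + s, 12000) for s in range(4)],
        3.0: [_gap_run(equilibrated_125, 3.0, 200 + s, 12000) for s in range(6)],
    }


@pytest.fixture(scope="session")
def hmr_runs(equilibrated_125):
    """Paired dt = 2.0 fs runs, with and without repartitioned masses."""
    seeds = (300, 301)
    return {
        "plain": [_gap_run(equilibrated_125, 2.0, s, 10000) for s in seeds],
        "hmr": [_gap_run(equilibrated_125, 2.0, s, 10000, hmr=True) for s in seeds],
    }


@pytest.fixture(scope="session")
def npt_runs(equilibrated_125):
    """NpT (CSVR + MC barostat) volume traces at dt = 0.5 and 3.0 fs.

    125 waters from the shared melt; per dt: barostat-width tuning during
    a 10k-step equilibration, then 80k production steps logged every
    barostat period.
    """
    out = {}
    for dt in (0.5, 3.0):
        cc = equilibrated_125.copy()
        ens = EnsembleSpec(
            thermostat="csvr", T_set=T_SET, tau_csvr=500.0,
            barostat="mc", p_set=1.0, mc_every=25,
        )
        log_eq = run_md(
            cc, IntegratorSpec(dt=dt), ens, 10000, log_every=1000,
            rng=RNGStream(300 + int(10 * dt)), interaction=ISPEC_125,
            tune_barostat_until=6000,
        )
        ens_prod = EnsembleSpec(
            thermostat="csvr", T_set=T_SET, tau_csvr=500.0,
            barostat="mc", p_set=1.0, mc_every=25,
            mc_dlnV_max=log_eq.meta["mc_dlnV_max_final"],
        )
        log = run_md(
            cc, IntegratorSpec(dt=dt), ens_prod, 80000, log_every=25,
            rng=RNGStream(400 + int(10 * dt)), interaction=ISPEC_125,
        )
        out[dt] = log.data
    return out
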