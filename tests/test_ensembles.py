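"""Thermostats and barostat against closed-form stationary distributions."""

import math

import numpy as np
import pytest
from scipy import stats

from equipart_md.constants import BAR_A3_TO_KCAL_MOL, FORCE_TO_ACCEL, KB
from equipart_md.dynamics import IntegratorSpec, kinetic_energy, make_force_fn, step
from equipart_md.ensembles import (
    EnsembleSpec,
    csvr_rescale,
    langevin_step,
    mc_volume_move,
    n_degrees_of_freedom,
    ou_kick,
    run_md,
)
from equipart_md.estimators import friedberg_cameron, trans_rot_temperatures
from equipart_md.interactions import InteractionSpec
from equipart_md.models import Configuration, RNGStream, build_water_lattice, init_velocities

T_SET = 298.15
ISPEC64 = InteractionSpec(rcut_lj=5.5, rcut_real=5.5, ewald_tol=1e-5)


def ideal_gas(n, L=10.0, seed=0):
    rng = np.random.default_rng(seed)
    return Configuration(
        pos=rng.uniform(0, L, (n, 3)),
        vel=np.zeros((n, 3)),
        box_length=L,
        n_waters=0,
        charges=np.zeros(n),
        masses=np.ones(n),
        lj_sigma=np.zeros(n),
        lj_eps=np.zeros(n),
        mol_id=np.arange(n),
    )


class TestCSVR:
    def test_infinite_tau_is_noop(self):
        rng = np.random.default_rng(0)
        for k in (1.0, 50.0, 500.0):
            a2 = csvr_rescale(k, 300, dt=1.0, tau=1e15, T_set=T_SET, rng=rng)
            assert a2 == pytest.approx(1.0, abs=1e-7)

    def test_fixed_point_with_suppressed_noise(self):
        n_dof = 300
        kbar = 0.5 * n_dof * KB * T_SET
        a2 = csvr_rescale(kbar, n_dof, dt=1.0, tau=100.0, T_set=T_SET,
                          noise=(0.0, float(n_dof)))
        assert a2 == pytest.approx(1.0, abs=1e-12)

    def test_stationary_gamma_distribution(self):
        # the kinetic-energy Markov chain K -> alpha^2 K has the canonical
        # Gamma(n_dof/2, kB T) stationary law; KS test at 1%
        n_dof = 300
        rng = np.random.Generator(np.random.Philox(11))
        k = 0.5 * n_dof * KB * T_SET
        samples = []
        for i in range(100000):
            k *= csvr_rescale(k, n_dof, dt=1.0, tau=10.0, T_set=T_SET, rng=rng)
            if i % 30 == 0 and i > 3000:
                samples.append(k)
        _, p = stats.kstest(samples, "gamma", args=(n_dof / 2, 0, KB * T_SET))
        assert p > 0.01

    def test_global_rescale_preserves_trans_rot_ratio(self, water27):
        c = water27.copy()
        t0 = trans_rot_temperatures(c)
        c.vel *= math.sqrt(1.23)
        t1 = trans_rot_temperatures(c)
        assert t1[0] / t0[0] == pytest.approx(1.23, rel=1e-12)
        assert t1[1] / t0[1] == pytest.approx(1.23, rel=1e-12)

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            csvr_rescale(-1.0, 10, 1.0, 10.0, 300.0, rng)
        with pytest.raises(ValueError):
            csvr_rescale(1.0, 0, 1.0, 10.0, 300.0, rng)


class TestLangevin:
    def test_zero_friction_equals_verlet(self, water8):
        fn = make_force_fn(InteractionSpec(rcut_lj=4.2, rcut_real=4.2, ewald_tol=1e-6))
        spec = IntegratorSpec(dt=1.0)
        rng = np.random.default_rng(1)
        ca, cb = water8.copy(), water8.copy()
        ra, rb = fn(ca), fn(cb)
        for _ in range(10):
            ra, _ = langevin_step(ca, ra.forces, 0.0, T_SET, spec, fn, rng)
            rb, _ = step(cb, rb.forces, spec, fn)
        assert np.array_equal(ca.pos, cb.pos)
        assert np.array_equal(ca.vel, cb.vel)

    def test_ou_stationary_velocity_variance(self):
        # single free particle: <v^2> per component = kB T / m
        mass = 10.0
        c = ideal_gas(1)
        c.masses[:] = mass
        rng = np.random.Generator(np.random.Philox(7))
        gamma, dt = 5.0, 2.0  # 1/ps, fs
        vs = []
        for i in range(40000):
            ou_kick(c, gamma, T_SET, dt, rng)
            vs.append(c.vel[0, 0])
        vs = np.array(vs[2000:])
        target = KB * T_SET * FORCE_TO_ACCEL / mass
        c1 = math.exp(-gamma * dt * 1e-3)
        n_eff = len(vs) * (1 - c1) / (1 + c1)
        mc_sigma = target * math.sqrt(2.0 / n_eff)
        assert abs(vs.var() - target) < 3.0 * mc_sigma

    def test_water_kinetic_temperature(self, spce):
        c = build_water_lattice(spce, 64, 0.997, RNGStream(15))
        c = init_velocities(c, T_SET, RNGStream(15))
        ens = EnsembleSpec(thermostat="langevin", T_set=T_SET, gamma_langevin=2.0)
        log = run_md(c, IntegratorSpec(dt=1.0), ens, 8000, log_every=10,
                     rng=RNGStream(16), interaction=ISPEC64)
        n_dof = n_degrees_of_freedom(c, remove_com=False)
        t_kin = 2 * log.data.e_kinetic.values[200:] / (n_dof * KB)
        est = friedberg_cameron(t_kin)
        assert abs(est.mean - T_SET) < 3.0 * max(est.stderr, 1.0)


class TestMCBarostat:
    def test_null_move_always_accepted(self):
        c = ideal_gas(10)
        rng = np.random.default_rng(0)
        new, accepted = mc_volume_move(c, lambda x: 0.0, 1.0, 0.0, T_SET, rng)
        assert accepted
        assert new.volume == pytest.approx(c.volume)

    def test_ideal_gas_mean_volume(self):
        # ln-V proposals with the (N+1) Jacobian: <V> = (N+1) kB T / p
        n, p_set = 50, 1000.0
        c = ideal_gas(n, seed=1)
        rng = np.random.Generator(np.random.Philox(2))
        vols = []
        for i in range(60000):
            c, _ = mc_volume_move(c, lambda x: 0.0, p_set, 0.3, T_SET, rng,
                                  current_energy=0.0)
            vols.append(c.volume)
        vols = np.array(vols[5000:])
        target = (n + 1) * KB * T_SET / (p_set * BAR_A3_TO_KCAL_MOL)
        est = friedberg_cameron(vols)
        assert abs(est.mean - target) < 3.0 * est.stderr

    def test_ideal_gas_volume_histogram(self):
        # p(V) dV ~ V^N exp(-beta p V) dV: chi^2 test at 1%
        n, p_set = 20, 1000.0
        c = ideal_gas(n, seed=3)
        rng = np.random.Generator(np.random.Philox(5))
        vols = []
        for i in range(80000):
            c, _ = mc_volume_move(c, lambda x: 0.0, p_set, 0.5, T_SET, rng,
                                  current_energy=0.0)
            if i % 40 == 0 and i > 4000:
                vols.append(c.volume)
        vols = np.array(vols)
        scale = KB * T_SET / (p_set * BAR_A3_TO_KCAL_MOL)
        dist = stats.gamma(n + 1, scale=scale)
        edges = dist.ppf(np.linspace(0.001, 0.999, 16))
        observed, _ = np.histogram(vols, bins=edges)
        probs = np.diff(dist.cdf(edges))
        expected = probs / probs.sum() * observed.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=len(observed) - 1)
        assert p > 0.01

    def test_rigid_geometry_preserved(self, water27):
        rng = np.random.Generator(np.random.Philox(8))
        spec = InteractionSpec(rcut_lj=4.0, rcut_real=4.0, ewald_tol=1e-6)

        def efn(cfg):
            from equipart_md.interactions import compute_energy_forces

            return compute_energy_forces(cfg, spec, compute_forces=False).e_total

        accepted = False
        c = water27
        for _ in range(20):
            c, acc = mc_volume_move(c, efn, 1.0, 0.05, T_SET, rng)
            accepted = accepted or acc
        assert accepted
        d_oh = np.linalg.norm(c.pos[1] - c.pos[0])
        assert d_oh == pytest.approx(c.model.d_OH, abs=1e-12)

    def test_failing_energy_fn_rejects_with_warning(self, water27):
        rng = np.random.default_rng(0)

        def bad(cfg):
            raise RuntimeError("boom")

        with pytest.warns(UserWarning, match="rejected"):
            new, acc = mc_volume_move(water27, bad, 1.0, 0.1, T_SET, rng)
        assert not acc
        assert new is water27


class TestRunMD:
    def test_nvt_mean_temperature(self, spce):
        c = build_water_lattice(spce, 64, 0.997, RNGStream(23))
        c = init_velocities(c, T_SET, RNGStream(23))
        ens = EnsembleSpec(thermostat="csvr", T_set=T_SET, tau_csvr=500.0)
        log = run_md(c, IntegratorSpec(dt=0.5), ens, 8000, log_every=10,
                     rng=RNGStream(24), interaction=ISPEC64)
        d = log.data.iloc[100:]
        avg = friedberg_cameron(((d.T_trans_K + d.T_rot_K) / 2).values)
        # with COM momentum pinned at zero, the thermostatted average of
        # (T_trans + T_rot)/2 is T_set (1 - 1/(2N)) for N molecules
        expected = T_SET * (1.0 - 1.0 / (2 * 64))
        assert abs(avg.mean - expected) < 3.0 * max(avg.stderr, 0.5)

    def test_nvt_volume_constant(self, water27):
        c = water27.copy()
        ens = EnsembleSpec(thermostat="csvr", T_set=T_SET)
        spec = InteractionSpec(rcut_lj=4.0, rcut_real=4.0, ewald_tol=1e-6)
        log = run_md(c, IntegratorSpec(dt=0.5), ens, 200, log_every=20,
                     rng=RNGStream(1), interaction=spec)
        assert log.data.volume_A3.nunique() == 1

    def test_same_seed_bit_identical(self, water27):
        spec = InteractionSpec(rcut_lj=4.0, rcut_real=4.0, ewald_tol=1e-6)
        ens = EnsembleSpec(thermostat="csvr", T_set=T_SET, barostat="mc",
                           p_set=1.0, mc_every=10)
        logs = []
        for _ in range(2):
            c = water27.copy()
            logs.append(
                run_md(c, IntegratorSpec(dt=1.0), ens, 300, log_every=10,
                       rng=RNGStream(99), interaction=spec)
            )
        assert logs[0].data.equals(logs[1].data)

    def test_dipole_and_energy_columns(self, water27):
        spec = InteractionSpec(rcut_lj=4.0, rcut_real=4.0, ewald_tol=1e-6)
        ens = EnsembleSpec(thermostat="none", T_set=T_SET)
        log = run_md(water27.copy(), IntegratorSpec(dt=0.5), ens, 50,
                     log_every=10, rng=RNGStream(2), interaction=spec)
        d = log.data
        total = (d.e_lj + d.e_lj_tail + d.e_real + d.e_recip + d.e_self_ewald
                 + d.e_intra_exclusion + d.e_background)
        assert np.allclose(total, d.e_potential, rtol=1e-10)
        assert {"Mx_eA", "My_eA", "Mz_eA"} <= set(d.columns)
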