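"""Lennard-Jones and Ewald energies/forces against independent oracles."""

import math

import numpy as np
import pytest
from scipy import integrate

from equipart_md.constants import COULOMB
from equipart_md.interactions import (
    EnergyReport,
    InteractionSpec,
    binding_energy,
    compute_energy_forces,
    ewald_energy_forces,
    lj_energy_forces,
    lj_tail_correction,
    select_molecules,
)
from equipart_md.models import Configuration, RNGStream, add_solute, build_water_lattice


def point_config(positions, charges, L, sigma=None, eps=None):
    """Monatomic configuration: each site its own molecule."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    return Configuration(
        pos=pos,
        vel=np.zeros_like(pos),
        box_length=L,
        n_waters=0,
        charges=np.asarray(charges, dtype=float),
        masses=np.ones(n),
        lj_sigma=np.asarray(sigma if sigma is not None else np.zeros(n), dtype=float),
        lj_eps=np.asarray(eps if eps is not None else np.zeros(n), dtype=float),
        mol_id=np.arange(n),
    )


def lj_double_loop_oracle(config, cutoff):
    """Naive minimum-image LJ double loop (independent of the kernel)."""
    e = 0.0
    L = config.box_length
    for i in range(config.n_sites - 1):
        for j in range(i + 1, config.n_sites):
            if config.mol_id[i] == config.mol_id[j]:
                continue
            if config.lj_eps[i] == 0.0 or config.lj_eps[j] == 0.0:
                continue
            d = config.pos[i] - config.pos[j]
            d -= L * np.rint(d / L)
            r2 = float(d @ d)
            if r2 >= cutoff * cutoff:
                continue
            s = 0.5 * (config.lj_sigma[i] + config.lj_sigma[j])
            ep = math.sqrt(config.lj_eps[i] * config.lj_eps[j])
            s6 = (s * s / r2) ** 3
            e += 4 * ep * s6 * (s6 - 1.0)
    return e


class TestLennardJones:
    def test_zero_crossing_and_minimum(self):
        sigma, eps = 3.2, 0.2
        for r, e_ref, f_zero in [(sigma, 0.0, False), (2 ** (1 / 6) * sigma, -eps, True)]:
            c = point_config(
                [[0, 0, 0], [r, 0, 0]], [0, 0], 50.0,
                sigma=[sigma, sigma], eps=[eps, eps],
            )
            rep = lj_energy_forces(c, cutoff=20.0, tail_correction=False)
            assert rep.e_lj == pytest.approx(e_ref, abs=1e-12)
            if f_zero:
                assert np.abs(rep.forces).max() < 1e-10

    def test_against_double_loop_oracle(self, spce):
        c = build_water_lattice(spce, 125, 0.997, RNGStream(13))
        rep = lj_energy_forces(c, cutoff=7.0, tail_correction=False)
        assert rep.e_lj == pytest.approx(lj_double_loop_oracle(c, 7.0), rel=1e-9)

    def test_tail_correction_against_quadrature(self, spce):
        c = build_water_lattice(spce, 64, 0.997, RNGStream(2))
        rc = 5.5
        tail = lj_tail_correction(c, rc)
        s, e = spce.sigma_O, spce.eps_O

        def u(r):
            return 4 * e * ((s / r) ** 12 - (s / r) ** 6) * r * r

        integral, _ = integrate.quad(u, rc, np.inf)
        expected = 2 * math.pi * 64**2 / c.volume * integral
        assert tail == pytest.approx(expected, rel=1e-8)
        assert tail < 0  # attractive beyond the cutoff

    def test_switch_is_c1_and_matches_plain_inside(self):
        sigma, eps = 3.2, 0.2
        r_on, r_off = 6.0, 7.0

        def e_at(r, window):
            c = point_config([[0, 0, 0], [r, 0, 0]], [0, 0], 40.0,
                             sigma=[sigma] * 2, eps=[eps] * 2)
            return lj_energy_forces(c, cutoff=r_off, switch_window=window).e_lj

        # matches unswitched LJ below r_on
        assert e_at(4.0, (r_on, r_off)) == pytest.approx(
            4 * eps * ((sigma / 4) ** 12 - (sigma / 4) ** 6), rel=1e-12
        )
        # C1 across r_on and r_off: one-sided slopes agree, and the central
        # difference across the joint matches them (no value jump, which
        # would appear as a huge apparent slope)
        h = 1e-6
        for r0 in (r_on, r_off):
            vals = [e_at(r0 + k * h, (r_on, r_off)) for k in (-2, -1, 1, 2)]
            slope_lo = (vals[1] - vals[0]) / h
            slope_hi = (vals[3] - vals[2]) / h
            slope_mid = (vals[2] - vals[1]) / (2 * h)
            assert slope_lo == pytest.approx(slope_hi, abs=1e-4)
            assert slope_mid == pytest.approx(0.5 * (slope_lo + slope_hi), abs=1e-4)
        assert e_at(r_off + 0.01, (r_on, r_off)) == 0.0


class TestEwald:
    def test_madelung_rocksalt(self):
        a = 2.82
        pos, q = [], []
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    pos.append([i * a, j * a, k * a])
                    q.append(1.0 if (i + j + k) % 2 == 0 else -1.0)
        c = point_config(pos, q, 2 * a)
        rep = ewald_energy_forces(c, r_cut=2.8, tolerance=1e-7)
        madelung = rep.e_total / COULOMB * a / 4  # 4 ion pairs
        assert madelung == pytest.approx(-1.747565, abs=1e-5)

    def test_single_charge_with_background(self):
        L = 20.0
        c = point_config([[0.0, 0.0, 0.0]], [1.0], L)
        rep = ewald_energy_forces(c, r_cut=7.0, tolerance=1e-7)
        xi = 2.0 * rep.e_total * L / COULOMB
        assert xi == pytest.approx(-2.837297, abs=1e-5)

    def test_opposite_charges_coulomb_limit(self):
        # energy of a +/- pair at distance d tends to -C/d as L -> infinity;
        # the leading image correction decays as 1/L^3, so Richardson
        # extrapolation over L = 20, 40, 80 recovers the Coulomb limit
        d = 2.0
        energies = {}
        for L in (20.0, 40.0, 80.0):
            c = point_config([[0, 0, 0], [d, 0, 0]], [1.0, -1.0], L)
            energies[L] = ewald_energy_forces(c, r_cut=8.0, tolerance=1e-7).e_total
        e40, e80 = energies[40.0], energies[80.0]
        extrap = e80 + (e80 - e40) / 7.0
        assert extrap == pytest.approx(-COULOMB / d, rel=1e-3)

    def test_alpha_independence(self):
        # the converged sum must not depend on the real-space cutoff choice
        c = point_config([[1.0, 2.0, 3.0], [4.0, 3.5, 2.0]], [1.0, -1.0], 15.0)
        e1 = ewald_energy_forces(c, r_cut=5.0, tolerance=1e-7).e_total
        e2 = ewald_energy_forces(c, r_cut=7.0, tolerance=1e-7).e_total
        assert e1 == pytest.approx(e2, rel=1e-6)

    def test_kmax_robustness(self, water27):
        spec = InteractionSpec(rcut_lj=4.0, rcut_real=4.0, ewald_tol=1e-6)
        base = compute_energy_forces(water27, spec, compute_forces=False)
        bigger = InteractionSpec(
            rcut_lj=4.0, rcut_real=4.0, ewald_tol=1e-6,
            kmax=spec.nmax(water27.box_length) + 2,
        )
        more = compute_energy_forces(water27, bigger, compute_forces=False)
        # the tolerance is relative; the reciprocal sum is the term being
        # truncated, so its magnitude sets the scale
        assert abs(more.e_recip - base.e_recip) < 1e-6 * abs(base.e_recip)

    def test_invalid_inputs(self, water27):
        with pytest.raises(ValueError):
            ewald_energy_forces(water27, r_cut=water27.box_length, tolerance=1e-6)
        with pytest.raises(ValueError):
            ewald_energy_forces(water27, r_cut=4.0, tolerance=-1.0)


class TestTotalEnergy:
    def test_translational_invariance(self, water27):
        spec = InteractionSpec(rcut_lj=4.0, rcut_real=4.0, ewald_tol=1e-6)
        e0 = compute_energy_forces(water27, spec, compute_forces=False).e_total
        rng = np.random.default_rng(17)
        for _ in range(3):
            c = water27.copy()
            c.pos += rng.uniform(-5, 5, size=3)
            e = compute_energy_forces(c, spec, compute_forces=False).e_total
            assert e == pytest.approx(e0, rel=1e-9)

    def test_force_matches_numeric_gradient(self, water8):
        spec = InteractionSpec(rcut_lj=4.2, rcut_real=4.2, ewald_tol=1e-6)
        rep = compute_energy_forces(water8, spec)
        h = 1e-5
        rng = np.random.default_rng(3)
        for i in rng.choice(water8.n_sites, 4, replace=False):
            for d in range(3):
                cp = water8.copy()
                cp.pos[i, d] += h
                cm = water8.copy()
                cm.pos[i, d] -= h
                f_num = -(
                    compute_energy_forces(cp, spec, compute_forces=False).e_total
                    - compute_energy_forces(cm, spec, compute_forces=False).e_total
                ) / (2 * h)
                assert f_num == pytest.approx(rep.forces[i, d], rel=1e-6, abs=1e-6)

    def test_forces_sum_to_zero(self, water27):
        spec = InteractionSpec(rcut_lj=4.0, rcut_real=4.0, ewald_tol=1e-6)
        rep = compute_energy_forces(water27, spec)
        assert np.abs(rep.forces.sum(axis=0)).max() < 1e-8

    def test_report_components_sum(self, water27):
        spec = InteractionSpec(rcut_lj=4.0, rcut_real=4.0, ewald_tol=1e-6)
        rep = compute_energy_forces(water27, spec, compute_forces=False)
        total = (
            rep.e_lj + rep.e_lj_tail + rep.e_real + rep.e_recip
            + rep.e_self_ewald + rep.e_intra_exclusion + rep.e_background
        )
        assert rep.e_total == pytest.approx(total, rel=1e-10)
        combined = rep + EnergyReport(e_lj=1.0)
        assert combined.e_total == pytest.approx(rep.e_total + 1.0)


class TestBindingEnergy:
    SPEC = InteractionSpec(rcut_lj=4.0, rcut_real=4.0, ewald_tol=1e-6)

    def test_null_solute(self, water27):
        c = add_solute(water27, np.full(3, water27.box_length / 2 + 0.8))
        sites = [c.n_sites - 1]
        assert binding_energy(c, sites, self.SPEC) == pytest.approx(0.0, abs=1e-8)

    def test_isolated_pair_matches_direct_sum(self, spce):
        # two waters far from their images: binding energy equals the
        # direct 9-pair Coulomb + O-O LJ sum (independent oracle)
        # L large enough that the residual dipole-image interaction
        # (~ C mu^2/L^3, about 1e-3 kcal/mol at L = 60) is negligible
        L = 150.0
        c = build_water_lattice(spce, 8, 0.35, RNGStream(3))
        two = select_molecules(c, [0, 7])
        two.box_length = L
        # place the second molecule's oxygen 3 A from the first one's
        two.pos[3:] += two.pos[0] + np.array([3.0, 0.4, -0.2]) - two.pos[3]
        direct = 0.0
        for i in range(3):
            for j in range(3, 6):
                r = np.linalg.norm(two.pos[i] - two.pos[j])
                direct += COULOMB * two.charges[i] * two.charges[j] / r
                if two.lj_eps[i] > 0 and two.lj_eps[j] > 0:
                    s6 = (two.lj_sigma[i] / r) ** 6
                    direct += 4 * two.lj_eps[i] * s6 * (s6 - 1.0)
        spec = InteractionSpec(rcut_lj=25.0, rcut_real=25.0, ewald_tol=1e-7)
        be = binding_energy(two, [0, 1, 2], spec)
        assert be == pytest.approx(direct, rel=2e-4)

    def test_deletion_difference_identity(self, water27):
        # binding of a tagged water equals U(N) - U(N-1) - U(1) recomputed here
        sites = [0, 1, 2]
        be = binding_energy(water27, sites, self.SPEC)
        e_full = compute_energy_forces(water27, self.SPEC, compute_forces=False).e_total
        rest = select_molecules(water27, range(1, 27))
        solo = select_molecules(water27, [0])
        e_rest = compute_energy_forces(rest, self.SPEC, compute_forces=False).e_total
        e_solo = compute_energy_forces(solo, self.SPEC, compute_forces=False).e_total
        assert be == pytest.approx(e_full - e_rest - e_solo, rel=1e-10)

    def test_symmetric_molecules_equal(self, spce):
        c = build_water_lattice(spce, 8, 0.997, RNGStream(777))
        spec = InteractionSpec(rcut_lj=3.0, rcut_real=3.0, ewald_tol=1e-6)
        # same orientation at every lattice site (anchored at the COM,
        # which is what sits on the lattice) -> identical environments
        masses = c.masses[:3]
        com0 = masses @ c.pos[:3] / masses.sum()
        template = c.pos[:3] - com0
        for w in range(8):
            sites = c.pos[3 * w : 3 * w + 3]
            com_w = masses @ sites / masses.sum()
            c.pos[3 * w : 3 * w + 3] = template + com_w
        b0 = binding_energy(c, [0, 1, 2], spec)
        b1 = binding_energy(c, [3, 4, 5], spec)
        assert b0 == pytest.approx(b1, rel=1e-8)

    def test_partial_molecule_rejected(self, water27):
        with pytest.raises(ValueError, match="whole molecules"):
            binding_energy(water27, [0, 1], self.SPEC)
        with pytest.raises(ValueError):
            binding_energy(water27, [], self.SPEC)
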