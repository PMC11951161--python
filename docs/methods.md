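# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `equipart-md`. Everything quantitative stated here is
computed by the test suite or by the examples in the README.

## Units and constants

Å, fs, amu, elementary charge e, kcal/mol. Coulomb constant
332.0637 kcal·Å/(mol·e²); k_B = 0.0019872041 kcal/(mol·K); force→acceleration
conversion 4.184×10⁻⁴ (Å/fs²)/((kcal/mol/Å)/amu); 1 bar·Å³ =
1.43932×10⁻⁵ kcal/mol. All constants live in `equipart_md.constants`.

## Water models

Rigid 3-site SPC/E and (CHARMM-modified) TIP3P, loaded from a bundled YAML
file (`data/water_models.yaml`) that cites the original parameter
publications. Geometry, charges and Lennard-Jones parameters are immutable;
hydrogen-mass repartitioning moves mass from O to H at fixed total mass
(18.0154 amu), fixed charges and fixed geometry.

Boxes are cubic and built on a simple-cubic molecular lattice (COM on the
lattice point) with uniformly random rigid orientations drawn from random
unit quaternions. A lattice start is deterministic and overlap-free; the
melt at δt = 0.5 fs (5 ps, CSVR) erases it. Orientation assignment is a free
choice; any uniform scheme is acceptable and the quaternion route was chosen
for simplicity.

## Interactions

* **Lennard-Jones.** Lorentz–Berthelot mixing. Bulk-water profile: sharp
  cutoff with the analytic tail correction
  E_tail = (8π/3V) Σ_ab N_a N_b ε σ³ [⅓(σ/r_c)⁹ − (σ/r_c)³] (assumes
  g(r) = 1 beyond r_c, contributes no force). Switched profile (for the
  TIP3P-style protocol): the CHARMM C¹ polynomial switch
  S = (r_off²−r²)²(r_off²+2r²−3r_on²)/(r_off²−r_on²)³ on [r_on, r_off], no
  tail. The exact switching polynomial is a documented choice; any C¹
  switch is equivalent at the level tested.
* **Electrostatics: plain Ewald,** not mesh-based. The boxes here are small
  and an exactly summable, bit-reproducible reference matters more than
  asymptotic speed. The splitting parameter solves
  erfc(α r_c)/r_c = tol (1/Å scale); the reciprocal sum keeps integer
  vectors up to n_max = ⌈αL√(−ln tol)/π⌉, so the largest omitted Gaussian
  factor is below tol. Components: real-space erfc sum, reciprocal sum,
  point self-energy, intramolecular exclusion correction (−q_iq_j erf(αr)/r
  for the three rigid-water charge pairs, which must carry no net force),
  and the uniform-background term −πC(Σq)²/(2α²V) for non-neutral boxes.
  Oracles: Madelung constant of rock salt to 10⁻⁵; the single-charge
  lattice constant ξL = −2.837297 to 10⁻⁶; α-independence; forces vs
  central differences to 10⁻⁶.
* **Tolerances.** Static/reference evaluations use tol = 10⁻⁷. The MD
  drivers default to 10⁻⁵, the package's accuracy/throughput trade-off for
  desk-scale runs; a two-seed comparison at 10⁻⁷ showed no detectable
  change in the equipartition observables.
* **Binding energies** are deletion differences
  U(full) − U(minus solute) − U(solute alone) with identical cutoffs and
  splitting in all three evaluations — exact by construction, ~3× the cost
  of one energy call, used only at sampling points.

## Integration and constraints

Velocity Verlet: half-kick, drift, position constraints (velocity
correction Δr/δt), force recompute, half-kick, velocity constraint
projection. SETTLE is the analytic 3-site solution (rotation-angle
construction); RATTLE is the iterative solver (default tolerance 10⁻¹⁰,
500 iterations, failure names the molecule). The two solvers agree to
10⁻⁶ Å over 100 steps and both restore geometry to ≤10⁻¹⁰ relative;
time-reversibility and momentum conservation are asserted in tests. The
velocity projection solves the exact 3×3 impulse system per molecule.
Beeman (standard predictor, velocities from (2a₊ + 5a₀ − a₋)δt/6) is
provided for cross-checks on the CPU path and excluded from the headline
claims. Velocities are reported on-step exactly as the integrator produces
them — deliberately, since the δt artifacts under study live in those
on-step velocities; no generalized-equipartition refinement is applied.

Minimum images use a single conditional fold, valid while site separations
stay within 1.5 L per axis; the MD drivers re-wrap whole molecules (COM
into [0, L)) every 500 steps, which changes no energy, no rigid geometry
and no molecular dipole.

## Ensembles

* **CSVR** (canonical stochastic velocity rescaling): one global rescale
  per step, α² = c + (1−c)(R₁²+S)K̄/(n_dof K) + 2R₁√(c(1−c)K̄/(n_dof K)),
  c = e^(−δt/τ), S ~ χ²(n_dof−1), K̄ = ½n_dof k_B T. Default τ = 0.5 ps.
  The kinetic-energy chain is verified against the canonical Gamma law
  (KS test). Being a single scalar, the rescale cannot move energy between
  translation and rotation — the measured gap is produced by the dynamics.
* **Langevin**: per-site OU kick after the Verlet step
  (c₁ = e^(−γδt), noise √((1−c₁²)k_BT/m)), velocity constraints
  re-projected. γ = 0 reduces exactly to velocity Verlet.
* **Monte Carlo barostat**: ln V proposals of half-width dlnV_max,
  molecular COMs scaled (rigid geometry untouched), Metropolis acceptance
  exp(−β[ΔU + pΔV − (N_mol+1)k_BT ln(V′/V)]). The ln-V proposal form and
  its (N+1) Jacobian are a documented choice, verified against the
  ideal-gas closed forms ⟨V⟩ = (N+1)k_BT/p and p(V) ∝ V^N e^(−βpV).
  Default sampling period 25 steps; dlnV_max is tuned to 40–50% acceptance
  during equilibration, then frozen for production.
* **Degrees of freedom**: 6 per rigid water, 3 per single-site solute,
  minus 3 when total momentum is pinned at zero (CSVR/NVE; not Langevin,
  whose kicks re-thermalize the COM).

## Estimators

* **Friedberg–Cameron**: g = 1 + 2Σρ_k truncated at the first non-positive
  autocorrelation (a documented truncation choice); stderr = s√(g/N). If
  correlations persist beyond a tenth of the series a non-stationarity
  warning is raised. AR(1) oracle: g = (1+φ)/(1−φ).
* **Compressibility**: κ_T = σ²_V/(⟨V⟩k_BT). Correlation length n = first
  lag at which the normalized autocorrelation of δV falls below 0.05
  (first crossing, a documented choice). The trace is split into the n
  shifted stride-n subsamples; each subsample's second moment uses the
  χ²-motivated minimum-MSE normalization Σδx²/(N+1); the mean over
  subsamples is reported, with the spread across subsamples as the quoted
  uncertainty. Because shifted subsamples interleave one trajectory, that
  quoted uncertainty can understate the true sampling error of a variance
  (≈ σ²√(2(1+φ²)/((1−φ²)N)) for AR(1)); tests therefore check recovery
  against the analytic sampling error, and users should treat the quoted
  κ_T error bars as optimistic.
* **Dielectric constant** (NVT, conducting boundaries):
  ε = 1 + 4π(⟨M²⟩−⟨M⟩²)/(3Vk_BT), each Cartesian dipole component
  subsampled exactly as above. The k_BT is converted to e²/Å via the
  Coulomb constant so ε is dimensionless.
* **Kinetic temperatures**: T_trans from COM motion over 3N dof, T_rot
  from motion relative to the COM over 3N dof (all internal motion of a
  rigid molecule is rotation). With total momentum pinned, translation
  carries only 3(N−1) dof, so T_trans is biased low by exactly T/N —
  2.4 K at N = 125. `com_corrected_t_trans` multiplies by N/(N−1); the
  experiments report both raw and corrected gaps. This matters only at
  desk scale; at thousands of molecules the distinction vanishes.

## Free energies

Charging by thermodynamic integration with linear charge scaling: the
integrand is the full-charge solute–solvent electrostatic energy φ sampled
in the λ-scaled ensemble, μ_elec = Σ w_λ⟨φ⟩_λ on the 3-point Gauss–Legendre
schedule mapped to (0,1); the λ = 0.5 node alone is the linear-response
estimate (exact when the solvent response is linear — asserted). The ion's
own periodic self-interaction, (ξ/2)q²C/L with ξ = −2.837297/L, is excluded
from φ and reported separately as the Wigner correction (cross-checked
against the single-charge Ewald energy to 10⁻⁴). Higher-order finite-size
corrections ∝ (R/L)²/L are omitted, matching the protocol the package
emulates. The vdW contribution uses the quasichemical binding-energy route
with the molecular envelope as the inner shell, i.e. occupancy p(n=0) = 1
and no packing term: μ_vdW = ⟨ε⟩ + βσ²/2 for Gaussian P(ε), or the
mean-field ⟨ε⟩; differences between conditions are insensitive to the
fluctuation term (asserted as shift invariance). Toy-ion LJ parameters are
bundled as illustrative values, not fitted ones.

## Synthetic data

Stationary Gaussian AR(1) series stand in for simulation logs wherever an
estimator needs input with analytically known truth: marginal mean/SD are
specified exactly, the lag-1 coefficient φ maps to the correlation length
via n = ⌈ln 0.05/ln φ⌉, and dipole series are three independent zero-mean
components. What AR(1) does **not** emulate: non-Gaussian tails, slow
drifts, or the coupling between volume and energy in real NpT logs — so
estimator tests on synthetic data validate the statistics, while the
engine-driven tests validate the physics.

## Desk-scale study conditions and statistical power

The reference protocol (thousands of waters, 10⁷ steps) is scaled down ~30×
in particles and ~10³ in steps so the whole suite runs on one CPU in
minutes. Conditions used by the simulation tests:

* Equipartition: 125 SPC/E waters, 7 Å cutoffs, NVT CSVR (τ = 0.5 ps),
  5 ps melt at δt = 0.5 fs, then 12 000-step productions; 4 seeds at
  δt = 0.5 fs and 6 seeds at 3.0 fs, seed-scatter standard errors. Measured
  effect in this engine: corrected gap ≈ +7 K at δt = 3.0 fs, ≈ +8 K at
  4.0 fs, ≲ +2 K at 2.0 fs, 0 within error at 0.5 fs — consistent with the
  (ωδt/2)² on-step bias of a ~500 cm⁻¹ librational band. Per-run gap noise
  is σ ≈ 4.7 K per 30 ps at this system size.
* HMR: same protocol at δt = 2.0 fs with m_H = 3.024 amu. Repartitioning
  lowers the libration frequency by √3, so the expected gap reduction is
  ~⅔ of a ≈1–2 K effect — *below* the ≈2 K seed noise at affordable run
  lengths. The comparison is reported but is at (beyond) the edge of
  desk-scale resolution; resolving it to 2σ needs ~100× more sampling.
* NpT: 125 waters, 7 Å cutoffs, CSVR + MC barostat at 1 bar; 10 000-step
  tuned equilibration and 80 000-step production per δt. System size
  matters here: a fixed-volume virial-pressure diagnostic gave
  p(δt=3.0) − p(δt=0.5) ≈ +100 ± 150 bar at 125 waters/7 Å (the expected
  sign) but a *negative* shift at 64 waters/5.5 Å, and the 64-water box
  also sits ~0.6% below the reference density — so the NpT checks use the
  larger box. The volume trend between δt = 0.5 and 3.0 fs implied by that
  pressure shift is ~0.4% of V against per-run mean-volume errors of
  ~0.4%, i.e. sign-consistent but at the edge of 2σ resolution within this
  budget (full resolution is a multi-hour computation at these settings;
  a paired-seed variance reduction was measured and does not close the
  gap).
* Charging: 27–64 water boxes with one toy LJ ion at the λ = 0.5 node;
  βΔμ/q² across q = 2e, 3e agrees within run noise.

These problem sizes are the package's own choices for a desk-scale
artifact; the physics claims that survive them (equipartition breakdown
and its δt dependence, estimator correctness, charging identities) are
tested at fixed significance, and the two that do not (HMR gap shrinkage,
NpT volume trend at 2σ) are retained as honest, possibly-failing checks
rather than weakened.

## Known limitations

* Plain Ewald is O(N²)-ish; system sizes beyond ~10³ molecules are out of
  scope by design.
* The quoted κ_T/ε uncertainties follow the subsample-spread convention and
  can be optimistic (see above).
* No flexible water, no protein force fields, no PME, no r-RESPA, no
  replica exchange; the Langevin *piston* barostat is not implemented (NpT
  claims use CSVR + MC barostat, the least dynamics-intrusive pairing).
* Beeman shares the constraint machinery rather than using a
  scheme-specific constraint formulation; it is a cross-check, not a
  headline path.
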