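"""Unit system and physical constants.

The package works in conventional biomolecular-MD units:

* length: Angstrom (A)
* time: femtosecond (fs)
* mass: atomic mass unit (amu)
* charge: elementary charge (e)
* energy: kcal/mol

All other constants below are derived conversions within that system.
"""

#: Coulomb constant, kcal*A/(mol*e^2): E = COULOMB * q1*q2 / r.
COULOMB = 332.0637

#: Boltzmann constant, kcal/(mol*K).
KB = 0.0019872041

#: Converts (kcal/mol/A)/amu to acceleration in A/fs^2.
FORCE_TO_ACCEL = 4.184e-4

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: 1 bar*A^3 expressed in kcal/mol (used in the p*dV barostat term).
BAR_A3_TO_KCAL_MOL = 1.0e5 * 1.0e-30 * AVOGADRO / 4184.0

#: Boltzmann constant in bar*A^3/K (volume-fluctuation estimators).
KB_BAR_A3 = KB / BAR_A3_TO_KCAL_MOL

#: Self-energy constant of a unit point charge on a cubic lattice with
#: neutralizing background: E_self = XI_WIGNER/L * q^2/2 (times COULOMB).
XI_WIGNER = -2.837297


def ml_per_mol_to_A3(volume_ml_per_mol: float) -> float:
    """Molar volume in ml/mol to per-molecule volume in A^3.

    1 ml/mol = 1 cm^3/mol = 1e24 A^3 / N_A per molecule.
    """
    return volume_ml_per_mol * 1.0e24 / AVOGADRO
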