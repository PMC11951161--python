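# Rigid 3-site water model parameters.
#
# Sources:
#   spce  -- Berendsen, Grigera & Straatsma, J. Phys. Chem. 91, 6269 (1987).
#   tip3p -- Jorgensen et al., J. Chem. Phys. 79, 926 (1983), with the
#            CHARMM modification that puts a small LJ site on the hydrogens
#            (MacKerell et al., J. Phys. Chem. B 102, 3586 (1998)).
#
# Units: lengths in Angstrom, angles in degrees, masses in amu,
# charges in elementary charge e, epsilon in kcal/mol.
spce:
  d_OH: 1.0
  theta_HOH: 109.47
  m_O: 15.9994
  m_H: 1.008
  q_O: -0.8476
  q_H: 0.4238
  sigma_O: 3.166
  eps_O: 0.1553
  sigma_H: 0.0
  eps_H: 0.0
tip3p:
  d_OH: 0.9572
  theta_HOH: 104.52
  m_O: 15.9994
  m_H: 1.008
  q_O: -0.834
  q_H: 0.417
  sigma_O: 3.150665
  eps_O: 0.1521
  sigma_H: 0.400014
  eps_H: 0.046
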