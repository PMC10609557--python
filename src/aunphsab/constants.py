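"""Physical constants and unit-conversion factors (CODATA 2018 values)."""

#: kcal/mol per eV.
KCAL_PER_EV = 23.060548

#: eV per hartree.
EV_PER_HARTREE = 27.211386

#: Coulomb constant e^2/(4*pi*eps0) in eV*Angstrom.
COULOMB_EV_ANGSTROM = 14.3996454

#: Empirical chemical potential of bulk gold, eV.
MU_GOLD_EV = -5.77

#: Closest Au-Au distance in the Au(111) plane, Angstrom; the default
#: "nanoparticle contact" radius.
R_CONTACT_ANGSTROM = 2.88
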