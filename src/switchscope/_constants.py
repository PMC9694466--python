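"""Physical constants and unit conversions used across the package.

Energies are kcal/mol, distances Å, masses amu, temperatures K throughout.
"""

#: Coulomb constant so that q1*q2/r with e-charges and Å gives kcal/mol.
COULOMB_KCAL = 332.0637

#: Generalized-Born prefactor (half the Coulomb constant).
GB_PREFACTOR = 166.03

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872e-3

#: Boltzmann constant in kcal/(mol K) (same numerical value as R in molar units).
KB_KCAL = R_KCAL

#: Default simulation temperature (K).
T_DEFAULT = 310.0

#: Exterior (solvent) dielectric constant.
EPS_SOLVENT = 78.5

#: Water probe radius for SASA (Å).
PROBE_RADIUS = 1.4

#: Surface tension coefficient for the nonpolar solvation term, kcal/(mol Å^2).
SURFACE_TENSION = 0.0072

#: Conversion of Hessian eigenvalues from kcal/mol/(Å^2 amu) to (rad/s)^2.
#: 1 kcal/mol = 4184 J/mol; 1 Å^2 = 1e-20 m^2; 1 amu = 1e-3 kg/mol.
OMEGA2_PER_EIGVAL = 4184.0 / (1e-20 * 1e-3)

#: Planck constant (J s) and Boltzmann constant (J/K) for vibrational entropy.
H_PLANCK = 6.62607015e-34
KB_J = 1.380649e-23

#: Atomic masses (amu) for the elements the toy systems use.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "MG": 24.305,
}
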