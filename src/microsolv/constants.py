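"""Physical constants and small element tables used across the package.

Energies cross the API boundary in hartree (quantum-chemistry convention)
and are reported in kcal/mol everywhere else; the conversion factor and the
gas constant below are pinned so that results are bit-reproducible across
environments.
"""

from scipy import constants as _sc

# Pinned conversions (CODATA-derived); kcal is the thermochemical calorie.
HARTREE_TO_KCAL_MOL = 627.509474
R_KCAL = 1.98720425864083e-3  # gas constant, kcal mol^-1 K^-1
R_CAL = R_KCAL * 1000.0       # cal mol^-1 K^-1

# CODATA SI constants via scipy.
H_PLANCK = _sc.h          # J s
C_LIGHT = _sc.c           # m s^-1
K_BOLTZMANN = _sc.k       # J K^-1
N_AVOGADRO = _sc.N_A      # mol^-1
AMU_KG = _sc.atomic_mass  # kg
ATM_PA = _sc.atm          # Pa
J_PER_KCAL = _sc.calorie * 1000.0  # 4184 J

# 1 cm^-1 of a harmonic mode, as molar energy in kcal/mol.
WAVENUMBER_TO_KCAL_MOL = H_PLANCK * C_LIGHT * 100.0 * N_AVOGADRO / J_PER_KCAL

# Molar volume of an ideal gas at 1 atm, 298.15 K, in litres (for the
# optional 1 atm -> 1 mol/L standard-state shift).
MOLAR_VOLUME_298_L = 24.46

# Most-abundant-isotope masses in amu (bundled so results do not depend on
# environment lookups).
ATOMIC_MASSES = {
    "H": 1.00782503207,
    "He": 4.00260325415,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Ne": 19.9924401754,
    "Na": 22.9897692809,
    "Mg": 23.9850417,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Ar": 39.9623831225,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Br": 78.9183371,
    "I": 126.904473,
}

# Cordero covalent radii in angstrom, for connectivity perception.
COVALENT_RADII = {
    "H": 0.31,
    "He": 0.28,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "Mg": 1.41,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "K": 2.03,
    "Ca": 1.76,
    "Br": 1.20,
    "I": 1.39,
}
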