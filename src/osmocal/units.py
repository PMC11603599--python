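"""Unit conventions used throughout the package.

Distances are in nanometres, energies in kJ/mol, times in microseconds,
concentrations in mol/L (M).  Second virial coefficients are reported in
L/mol (identically M^-1): a volume of 1 nm^3 per molecule corresponds to
``N_A * 1e-24`` L/mol.
"""

from scipy.constants import Avogadro

#: Avogadro constant, 1/mol.
N_AVOGADRO = Avogadro

#: Conversion factor nm^3 -> L/mol (about 0.602214 L/mol per nm^3).
NM3_TO_L_PER_MOL = Avogadro * 1e-24

#: kT at 300 K in kJ/mol; beta = 1/kT is the default inverse temperature.
KT_300K_KJ_PER_MOL = 8.31446261815324e-3 * 300.0

#: Default inverse temperature beta in mol/kJ (300 K).
DEFAULT_BETA = 1.0 / KT_300K_KJ_PER_MOL
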