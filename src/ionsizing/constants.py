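"""Physical constants and laboratory reference conditions (SI unless noted)."""

ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
FARADAY = 96485.33212  # C/mol
EPSILON_0 = 8.8541878128e-12  # F/m

# Reference conditions: all activity constants below assume 25 degC.
T_REF = 298.15  # K
ETA_WATER = 0.89e-3  # Pa s, water at 25 degC
EPSILON_R_WATER = 78.4  # relative permittivity of water at 25 degC

# Extended Debye-Hueckel constants at 25 degC.  B is used with the hydrated-size
# parameter a0 expressed in Angstrom (the conventional pairing B*a0 ~ O(1) M^-1/2).
A_DEBYE_HUCKEL = 0.5085  # M^-1/2
B_DEBYE_HUCKEL = 0.3281  # 1/(Angstrom M^1/2)

PA_PER_A = 1e12
NM_PER_M = 1e9
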