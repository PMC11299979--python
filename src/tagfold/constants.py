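"""Physical constants shared across the package.

Energies are in kcal/mol throughout; temperatures in kelvin unless a
function explicitly works in degrees Celsius (thermal melts are acquired
on a Celsius grid).
"""

# Gas constant / Boltzmann constant in kcal mol^-1 K^-1
R_KCAL = 1.987e-3
KB_KCAL = R_KCAL

# Default experiment temperature (25 degC) for chemical denaturation and
# native-state proteolysis.
DEFAULT_TEMPERATURE_K = 298.0

# Thermolysin reference specificity constant for fully unfolded substrates,
# used to place the open-state equilibrium on an absolute free-energy scale.
THERMOLYSIN_KCAT_KM = 99_000.0  # M^-1 s^-1
THERMOLYSIN_MW = 34_600.0  # g/mol

# 15N backbone amide relaxation constants (SI units).
MU0 = 4.0e-7 * 3.141592653589793  # T m / A
HBAR = 1.054571817e-34  # J s
GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1
GAMMA_N = -2.7126e7  # rad s^-1 T^-1 (signed)
R_NH = 1.02e-10  # m, N-H bond length
CSA_N = -160.0e-6  # 15N chemical shift anisotropy
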