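"""Physical constants in the package-wide unit system.

Units everywhere: length Å, energy kcal·mol⁻¹, mass amu, time ps, charge e,
temperature K.  Avogadro's number, the vacuum permittivity, the elementary
charge and Planck's constant never appear explicitly — they are absorbed into
the four conversion constants below, which keeps every formula dimensionally
closed in this one system.
"""

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹.
K_B = 1.987204e-3

#: Electrostatic conversion (Coulomb prefactor), kcal·Å·mol⁻¹·e⁻².
#: U = K_E·q₁q₂/r gives kcal·mol⁻¹ for charges in e and r in Å.
K_E = 332.0636

#: Reduced Planck constant, kcal·ps·mol⁻¹.
HBAR = 1.5179e-2

#: 1 kcal·mol⁻¹ expressed in amu·Å²·ps⁻².
KCAL_TO_AMU_A2_PS2 = 418.4

#: Avogadro's number, mol⁻¹ (only used to convert mol·L⁻¹ → Å⁻³).
N_AVOGADRO = 6.02214076e23

#: mol·L⁻¹ → number density in Å⁻³  (1 L = 10²⁷ Å³).
MOLAR_TO_PER_A3 = N_AVOGADRO / 1e27
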