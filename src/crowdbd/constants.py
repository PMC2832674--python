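"""Physical constants and the package-wide unit contract.

Units everywhere: length Å, time ps, energy kcal/mol, temperature K,
charge in elementary charges, mass kDa, concentration g/l,
viscosity cP where stated.
"""

#: Boltzmann constant, kcal/(mol·K)
KB = 0.0019872041

#: Default temperature, K
TEMPERATURE = 298.15

#: kT at 298.15 K, kcal/mol
KT_298 = KB * TEMPERATURE  # 0.59248...

#: Coulomb constant, kcal·Å/(mol·e²)
COULOMB = 332.06

#: Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23

#: Gas constant, kcal/(mol·K) (identical to KB in molar units)
R_GAS = KB


def kt(temperature: float = TEMPERATURE) -> float:
    """Thermal energy kT in kcal/mol at the given temperature."""
    return KB * temperature


def debye_kappa(ionic_strength: float, solvent_dielectric: float = 78.0,
                temperature: float = TEMPERATURE) -> float:
    """Inverse Debye screening length, 1/Å, for a 1:1 electrolyte.

    Parameters
    ----------
    ionic_strength : molar (mol/l).
    solvent_dielectric : relative permittivity of the solvent.
    temperature : K.

    At 150 mM, 78.0, 298.15 K the screening length 1/kappa is ~7.8 Å.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0.0:
        return 0.0
    bjerrum = COULOMB / (solvent_dielectric * kt(temperature))  # Å
    # ion number density of a 1:1 salt, per Å^3 (both species)
    n_ions = 2.0 * ionic_strength * N_AVOGADRO * 1e-27
    return float((4.0 * 3.141592653589793 * bjerrum * n_ions) ** 0.5)
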