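"""Physical constants and unit conversions.

Internal conventions: energies in kcal/mol, lengths in Å, angles in degrees
at API boundaries (radians internally where noted), temperature in K.
"""

#: Boltzmann constant / gas constant, kcal/(mol·K)
KB_KCAL = 0.0019872041

#: exact thermochemical calorie conversion
KJ_PER_KCAL = 4.184

#: Coulomb constant e²/(4πε₀), kcal·Å/(mol·e²)
COULOMB_KCAL_A = 332.06371

#: standard-state volume per molecule at 1 M, Å³
STANDARD_VOLUME_A3 = 1660.0

#: cubic-lattice (Wigner) self-energy constant for periodic point charges
XI_LS = -2.837297


def kt(temperature: float) -> float:
    """Thermal energy RT in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature


def kj_to_kcal(x):
    return x / KJ_PER_KCAL


def kcal_to_kj(x):
    return x * KJ_PER_KCAL


def kj_nm2_to_kcal_A2(k):
    """Convert a force constant from kJ/mol/nm² to kcal/mol/Å²."""
    return k / KJ_PER_KCAL / 100.0
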