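"""Physical constants used throughout the package.

All core computations are carried out in SI units (joules, kelvin, moles).
The pseudo-stoichiometric coefficient xi_w scales inversely with the molar
heat capacity of liquid water, so that value is exposed explicitly rather
than buried in the fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ThermoConstants:
    """Bundle of physical constants for hydration thermodynamics.

    Parameters
    ----------
    gas_constant_R : float
        Molar gas constant, J·K⁻¹·mol⁻¹.
    water_heat_capacity_Cpw : float
        Molar isobaric heat capacity of liquid water near 298 K,
        J·K⁻¹·mol⁻¹.  The water count n_w is dCp_hydr / Cpw, so changing
        this value rescales every reported xi_w.
    avogadro_N : float
        Avogadro number, mol⁻¹.
    reference_T : float
        Default reference temperature (K) for Gibbs-energy evaluations.
    """

    gas_constant_R: float = 8.3145
    water_heat_capacity_Cpw: float = 75.3
    avogadro_N: float = 6.02214e23
    reference_T: float = 298.0

    def __post_init__(self) -> None:
        for name in (
            "gas_constant_R",
            "water_heat_capacity_Cpw",
            "avogadro_N",
            "reference_T",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


#: Module-level default constant set (SI units, 298 K reference).
DEFAULT_CONSTANTS = ThermoConstants()
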