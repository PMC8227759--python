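"""Worked-quantity helpers: iceberg free-energy lines, hydrophobic-bond
free energy, dilution entropy, ergodic activities and quasi-chemical
constants.

Unlike the SI-joule core, this module speaks the kJ convention of the
published vector arithmetic: unitary enthalpies in kJ·mol⁻¹·xi_w⁻¹ and
unitary entropies in kJ·K⁻¹·mol⁻¹·xi_w⁻¹.  ``kj`` / ``to_si`` convert
between the two conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import DEFAULT_CONSTANTS, ThermoConstants
from .exceptions import DomainError

__all__ = [
    "FreeEnergyLine",
    "EntropyDilution",
    "ErgodicActivity",
    "free_energy_line",
    "gibbs_at",
    "molar_fraction_from_entropy",
    "ergodic_activity",
    "quasichemical_constant",
    "eq7_thermal_term",
    "kj",
    "to_si",
]


def kj(value_si: float) -> float:
    """J -> kJ (core convention to this module's convention)."""
    return value_si / 1e3


def to_si(value_kj: float) -> float:
    """kJ -> J (this module's convention to the core convention)."""
    return value_kj * 1e3


@dataclass
class FreeEnergyLine:
    """Iceberg free energy as a straight line in T:
    ΔG(T) = intercept + slope·T with intercept = xi_w·Δh (kJ·mol⁻¹) and
    slope = −xi_w·Δs (kJ·mol⁻¹·K⁻¹)."""

    intercept: float
    slope: float
    class_label: str = ""

    def at(self, T: float) -> float:
        return self.intercept + self.slope * T


def free_energy_line(
    xi_w: float, unitary_h: float, unitary_s: float, class_label: str = ""
) -> FreeEnergyLine:
    """Compose the iceberg free-energy line from unitary terms.

    ``unitary_h`` in kJ·mol⁻¹·xi_w⁻¹, ``unitary_s`` in kJ·K⁻¹·mol⁻¹·xi_w⁻¹.
    Negative unitary terms (formation) give a line rising with T; positive
    (reduction) a falling one.
    """
    if xi_w < 0:
        raise DomainError("xi_w must be non-negative")
    return FreeEnergyLine(xi_w * unitary_h, -xi_w * unitary_s, class_label)


def gibbs_at(xi_w: float, unitary_h: float, unitary_s: float, T: float) -> float:
    """Iceberg free energy xi_w·(Δh − T·Δs) at temperature T (kJ·mol⁻¹)."""
    if T < 0:
        raise DomainError("temperature must be non-negative")
    return xi_w * (unitary_h - T * unitary_s)


@dataclass
class EntropyDilution:
    """Unitary molecule count and mole fraction implied by a configurational
    entropy change via ΔS/R = ln(N) and x = N / N_Avo."""

    delta_S: float
    N_unitary: float
    mole_fraction: float
    exceeds_unity: bool = field(init=False)

    def __post_init__(self) -> None:
        self.exceeds_unity = self.mole_fraction > 1.0


def molar_fraction_from_entropy(
    delta_S: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> EntropyDilution:
    """Convert an entropy change (J·K⁻¹·mol⁻¹) into an equivalent dilution.

    N_unitary = exp(ΔS/R); mole_fraction = N_unitary / N_Avo.  Mole
    fractions above 1 are flagged, not clipped.  Arguments whose exponent
    would overflow a double raise a structured error.
    """
    z = delta_S / constants.gas_constant_R
    if z > 700.0:  # exp overflow threshold for float64
        raise DomainError(f"delta_S = {delta_S:g} overflows exp({z:g})")
    n_unitary = math.exp(z)
    return EntropyDilution(delta_S, n_unitary, n_unitary / constants.avogadro_N)


@dataclass
class ErgodicActivity:
    """Ergodic activity a = Φ·x with thermal factor Φ = T^(−Cp/R)."""

    mole_fraction_x: float
    thermal_factor_phi: float
    activity_a: float
    Cp_A: float
    temperature: float


def ergodic_activity(
    x: float,
    Cp_A: float,
    T: float,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> ErgodicActivity:
    """Scale a mole fraction by the ergodicity-preserving thermal factor.

    ``x`` must lie in (0, 1]; ``Cp_A`` is the species heat capacity
    (J·K⁻¹·mol⁻¹).  Φ = T^(−Cp_A/R) equals 1 at T = 1 K or Cp_A = 0, and
    for T > 1 decreases as Cp_A grows.
    """
    if not 0 < x <= 1:
        raise DomainError("mole fraction x must lie in (0, 1]")
    if not T > 0:
        raise DomainError("temperature must be strictly positive")
    phi = T ** (-Cp_A / constants.gas_constant_R)
    return ErgodicActivity(x, phi, phi * x, Cp_A, T)


def quasichemical_constant(
    a_A: float, a_B: float, a_WII: float, xi_w: float, mode: str
) -> float:
    """Quasi-chemical equilibrium constant from ergodic activities.

    ``dissociation``: K = a_A · a_B⁻¹ · a_WII^(+xi_w);
    ``association``:  K = a_A · a_B⁻¹ · a_WII^(−xi_w).
    The mode mirrors the sign of the experimentally determined ±xi_w.
    """
    if min(a_A, a_B, a_WII) <= 0:
        raise DomainError("activities must be strictly positive")
    if mode == "dissociation":
        expo = xi_w
    elif mode == "association":
        expo = -xi_w
    else:
        raise ValueError(f"mode must be 'dissociation' or 'association', got {mode!r}")
    return a_A / a_B * a_WII**expo


def eq7_thermal_term(dCp_hydr: float, T: float, T_d: float) -> float:
    """Diagnostic evaluation of the textbook thermal free-energy expression
    −(ΔCp/T)·{(T_d − T) + T·ln(T/T_d)}.

    This expression is evaluated verbatim for comparison purposes only and
    is never used by the fitting pipeline: the model's position is that the
    thermal (compensative) functions contribute exactly zero free energy,
    ΔG_th/T = ΔH_th/T − ΔS_th = 0.  Note the verbatim form equals
    (1/T)·∫ ΔCp·(1 − T/T') dT' taken from T_d to T.
    """
    if T <= 0 or T_d <= 0:
        raise DomainError("temperatures must be strictly positive")
    return -(dCp_hydr / T) * ((T_d - T) + T * math.log(T / T_d))
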