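"""Seeded synthetic-data generation for the hydration-analysis pipeline.

The generator is the forward model of the analysis: per-compound lnK(T)
series follow the dual binding-potential function with iid Gaussian noise
on lnK, and families of compounds draw their motive functions from linear
laws in xi_w with compound-level Gaussian scatter.  Preset coefficient
sets emulate the published families (gas and liquid dissolution, protein
denaturation/folding, carboxylic-acid protonation, micelle formation)
with their characteristic xi_w ranges, so every pipeline stage can be
exercised, and its estimates checked against known truth, without any
external dataset.

Seeds are mandatory for every stochastic call; there is no hidden global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DEFAULT_CONSTANTS, ThermoConstants
from .data import CompoundSeries, FamilyRecord
from .exceptions import ConfigurationError, DomainError, UnknownPresetError

__all__ = [
    "CompoundTruth",
    "FamilyTruth",
    "generate_compound",
    "generate_family",
    "preset_scenarios",
    "default_T_grid",
    "PRESET_NAMES",
]


def default_T_grid() -> np.ndarray:
    """273.15–373.15 K in 10 K steps (11 points): liquid-water range."""
    return np.arange(273.15, 373.16, 10.0)


@dataclass
class CompoundTruth:
    """Ground-truth parameters for one synthetic compound."""

    dH_mot: float                 # J·mol⁻¹
    dS_mot: float                 # J·K⁻¹·mol⁻¹
    n_w: float                    # signed water count (dCp = n_w·Cp_w)
    noise_sd_lnK: float = 0.02
    T_grid: np.ndarray = field(default_factory=default_T_grid)

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        if np.any(self.T_grid <= 0):
            raise DomainError("T_grid must be strictly positive")
        if self.noise_sd_lnK < 0:
            raise DomainError("noise_sd_lnK must be non-negative")


@dataclass
class FamilyTruth:
    """Ground-truth family laws dX_mot = intercept + slope·xi_w.

    Class A requires both slopes negative (iceberg formation), Class B
    both positive (iceberg reduction); a mismatch is a configuration
    error, caught at generation time.
    """

    name: str
    class_label: str              # "A" or "B"
    intercept_H: float            # J·mol⁻¹
    slope_H: float                # J·mol⁻¹ per xi_w
    intercept_S: float            # J·K⁻¹·mol⁻¹
    slope_S: float                # J·K⁻¹·mol⁻¹ per xi_w
    xi_w_values: tuple = ()
    scatter_sd_H: float = 2.0e3   # compound-level scatter, J·mol⁻¹
    scatter_sd_S: float = 15.0    # compound-level scatter, J·K⁻¹·mol⁻¹

    def validate(self) -> None:
        if self.class_label == "A":
            ok = self.slope_H < 0 and self.slope_S < 0
        elif self.class_label == "B":
            ok = self.slope_H > 0 and self.slope_S > 0
        else:
            raise ConfigurationError(f"unknown class label {self.class_label!r}")
        if not ok:
            raise ConfigurationError(
                f"family {self.name!r}: class {self.class_label} is inconsistent "
                f"with slopes (H: {self.slope_H:g}, S: {self.slope_S:g})"
            )
        if len(self.xi_w_values) < 2:
            raise ConfigurationError("a family needs >= 2 xi_w values")


def model_ln_k(
    truth: CompoundTruth, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Noise-free lnK(T) on the truth's grid (the forward model)."""
    T = truth.T_grid
    dCp = truth.n_w * constants.water_heat_capacity_Cpw
    return (
        -truth.dH_mot / T + (truth.dS_mot - dCp) + dCp * np.log(T)
    ) / constants.gas_constant_R


def generate_compound(
    truth: CompoundTruth,
    seed: int,
    *,
    family_id: str = "synthetic",
    compound_id: str = "c0",
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> CompoundSeries:
    """Draw one lnK(T) series from the forward model, reproducibly."""
    rng = np.random.default_rng(seed)
    ln_k = model_ln_k(truth, constants)
    if truth.noise_sd_lnK > 0:
        ln_k = ln_k + rng.normal(0.0, truth.noise_sd_lnK, size=ln_k.size)
    return CompoundSeries(family_id, compound_id, truth.T_grid.copy(), ln_k)


def generate_family(
    truth: FamilyTruth,
    seed: int,
    *,
    T_grid=None,
    noise_sd_lnK: float = 0.02,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> tuple[list[CompoundSeries], list[FamilyRecord]]:
    """Draw a family of compound series plus its ground-truth records.

    For each xi_w, the compound's (dH_mot, dS_mot) are the family-line
    values plus Gaussian scatter; n_w = +xi_w in Class A, −xi_w in Class
    B.  Returns the series and matching FamilyRecord ground truth (the
    oracle for recovery tests).
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    T_grid = default_T_grid() if T_grid is None else np.asarray(T_grid, float)
    sign = 1.0 if truth.class_label == "A" else -1.0

    series_list: list[CompoundSeries] = []
    records: list[FamilyRecord] = []
    for i, xi in enumerate(truth.xi_w_values):
        dH = truth.intercept_H + truth.slope_H * xi
        dS = truth.intercept_S + truth.slope_S * xi
        if truth.scatter_sd_H > 0:
            dH += rng.normal(0.0, truth.scatter_sd_H)
        if truth.scatter_sd_S > 0:
            dS += rng.normal(0.0, truth.scatter_sd_S)
        ct = CompoundTruth(dH, dS, sign * xi, noise_sd_lnK, T_grid)
        cid = f"{truth.name}_{i:02d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        series_list.append(
            generate_compound(
                ct, sub_seed, family_id=truth.name, compound_id=cid,
                constants=constants,
            )
        )
        records.append(
            FamilyRecord(
                family_id=truth.name, compound_id=cid, xi_w=float(xi),
                dH_mot=dH, dS_mot=dS, n_w=sign * xi,
            )
        )
    return series_list, records


# ---------------------------------------------------------------------------
# Preset coefficient sets (kJ converted to J) with published-scale xi_w
# ranges: gases 2–6, liquids 2.7–5.4, protein denaturation 80–140,
# carboxylic protonation 1.8–2.3, micelles 4–19.
# ---------------------------------------------------------------------------
_PRESETS: dict[str, FamilyTruth] = {
    "gases_A": FamilyTruth(
        "gases_A", "A",
        intercept_H=-17.7e3, slope_H=-21.6e3,
        intercept_S=-86.4, slope_S=-445.4,
        xi_w_values=(2.0, 3.0, 4.0, 5.0, 6.0),
    ),
    "liquids_A": FamilyTruth(
        "liquids_A", "A",
        intercept_H=4.6e3, slope_H=-23.3e3,
        intercept_S=-0.5, slope_S=-447.0,
        xi_w_values=(2.7, 3.2, 3.8, 4.3, 4.9, 5.4),
    ),
    "protein_denaturation_A": FamilyTruth(
        "protein_denaturation_A", "A",
        intercept_H=211.82e3, slope_H=-22.5e3,
        intercept_S=415.0, slope_S=-428.5,
        xi_w_values=(80.0, 95.0, 110.0, 125.0, 140.0),
    ),
    "carboxylic_protonation_A": FamilyTruth(
        "carboxylic_protonation_A", "A",
        intercept_H=0.1e3, slope_H=-21.8e3,
        intercept_S=104.0, slope_S=-442.6,
        xi_w_values=(1.8, 1.9, 2.0, 2.1, 2.2, 2.3),
    ),
    "micelles_B": FamilyTruth(
        "micelles_B", "B",
        intercept_H=-3.97e3, slope_H=23.13e3,
        intercept_S=10.2, slope_S=428.0,
        xi_w_values=(4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 19.0),
    ),
    "protein_folding_B": FamilyTruth(
        "protein_folding_B", "B",
        intercept_H=-211.82e3, slope_H=22.5e3,
        intercept_S=-415.8, slope_S=424.2,
        xi_w_values=(80.0, 95.0, 110.0, 125.0, 140.0),
    ),
    # deprotonation is the sign-reversed protonation family (Class B);
    # slope signs follow the class convention
    "deprotonation_B": FamilyTruth(
        "deprotonation_B", "B",
        intercept_H=-0.1e3, slope_H=21.8e3,
        intercept_S=-104.0, slope_S=442.6,
        xi_w_values=(1.8, 1.9, 2.0, 2.1, 2.2, 2.3),
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset_scenarios(name: str) -> FamilyTruth:
    """Return a copy of a named family scenario.

    Raises ``UnknownPresetError`` listing the available names when ``name``
    is not registered.
    """
    try:
        return replace(_PRESETS[name])
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
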