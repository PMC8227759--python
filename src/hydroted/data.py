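"""In-memory containers for measurement series and family records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError


@dataclass
class CompoundSeries:
    """One compound's equilibrium-constant-versus-temperature series.

    Temperatures are kelvin; ``ln_k`` holds natural-log equilibrium
    constants.  On construction the points are sorted by temperature and
    validated: at least two points, strictly positive temperatures, no
    duplicated temperature.
    """

    family_id: str
    compound_id: str
    temperatures: np.ndarray
    ln_k: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        y = np.asarray(self.ln_k, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise DomainError(
                "temperatures and ln_k must be 1-d arrays of equal length"
            )
        if t.size < 2:
            raise DomainError("a series needs at least 2 points")
        if not np.all(t > 0):
            raise DomainError("temperatures must be strictly positive (kelvin)")
        order = np.argsort(t)
        t, y = t[order], y[order]
        if np.any(np.diff(t) == 0):
            raise DomainError("duplicate temperatures in series")
        self.temperatures = t
        self.ln_k = y

    def __len__(self) -> int:
        return int(self.temperatures.size)

    @classmethod
    def from_K(cls, family_id, compound_id, temperatures, K) -> "CompoundSeries":
        """Build a series from raw equilibrium constants (must be > 0)."""
        K = np.asarray(K, dtype=float)
        if np.any(K <= 0):
            raise DomainError("equilibrium constants K must be strictly positive")
        return cls(family_id, compound_id, temperatures, np.log(K))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family_id": self.family_id,
                "compound_id": self.compound_id,
                "temperature_K": self.temperatures,
                "lnK": self.ln_k,
            }
        )


@dataclass
class FamilyRecord:
    """Per-compound motive functions with the TED-determined water count.

    ``xi_w`` is the non-negative pseudo-stoichiometric coefficient; the
    signed value ``n_w`` (positive Class A, negative Class B) is retained
    alongside.  Enthalpy in J·mol⁻¹, entropy in J·K⁻¹·mol⁻¹.
    """

    family_id: str
    compound_id: str
    xi_w: float
    dH_mot: float
    dS_mot: float
    n_w: float | None = None
    dH_mot_se: float | None = None
    dS_mot_se: float | None = None

    def __post_init__(self) -> None:
        if self.xi_w < 0:
            raise DomainError("xi_w must be non-negative")
        if self.n_w is None:
            self.n_w = self.xi_w


def records_to_frame(records: list[FamilyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family_id": [r.family_id for r in records],
            "compound_id": [r.compound_id for r in records],
            "xi_w": [r.xi_w for r in records],
            "dH_mot": [r.dH_mot for r in records],
            "dS_mot": [r.dS_mot for r in records],
        }
    )
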