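"""Curved van't Hoff (dual binding-potential) fitting and TED analysis.

The hydrophobic-hydration model represents the observed ("dual")
equilibrium constant of a process with a temperature-independent
hydrophobic heat capacity dCp_hydr:

    R·lnK(T) = -dH_mot/T + (dS_mot - dCp_hydr) + dCp_hydr·lnT

which is linear in the three parameters (dH_mot, dS_mot, dCp_hydr).  The
motive enthalpy is the T -> 0 extrapolation of the dual enthalpy and the
motive entropy the lnT -> 0 (T = 1 K) extrapolation of the dual entropy;
the residual temperature dependence, dH_th = dCp·T and dS_th = dCp·lnT,
is the compensative "thermal" part attributed to the implicit solvent.

Thermal Equivalent Dilution (TED) converts the fitted curvature into a
pseudo-stoichiometric water count: n_w = dCp_hydr / Cp_w (signed),
xi_w = |n_w|.  Processes with dCp_hydr significantly positive are Class A
(convex binding function, iceberg formation); significantly negative,
Class B (concave, iceberg reduction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .constants import DEFAULT_CONSTANTS, ThermoConstants
from .data import CompoundSeries
from .exceptions import DomainError, InsufficientDataError, SingularFitError

__all__ = [
    "DualBindingModel",
    "DualBindingResults",
    "Decomposition",
    "ResidualSeries",
    "classify_ted",
    "binding_potential",
    "iceberg_residual",
]

#: condition-number ceiling (on the column-normalised design) beyond which
#: the temperature grid is treated as numerically collinear
_COND_LIMIT = 1e10


def classify_ted(
    dCp_hydr: float,
    dCp_se: float,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    significance_k: float = 2.0,
) -> tuple[float, float, str]:
    """Thermal-equivalent-dilution classification of a fitted heat capacity.

    Returns ``(n_w, xi_w, hydration_class)`` where ``n_w = dCp_hydr / Cp_w``
    is the signed, continuous (never rounded) pseudo-stoichiometric water
    count, ``xi_w = |n_w|`` and the class is ``"A"`` if dCp_hydr exceeds
    ``+significance_k`` standard errors, ``"B"`` below
    ``-significance_k`` standard errors, else ``"indeterminate"``.
    """
    cpw = constants.water_heat_capacity_Cpw
    if not cpw > 0:
        raise DomainError("water_heat_capacity_Cpw must be positive")
    n_w = dCp_hydr / cpw
    xi_w = abs(n_w)
    se = 0.0 if dCp_se is None or not np.isfinite(dCp_se) else float(dCp_se)
    if dCp_hydr > significance_k * se and dCp_hydr > 0:
        cls = "A"
    elif dCp_hydr < -significance_k * se and dCp_hydr < 0:
        cls = "B"
    else:
        cls = "indeterminate"
    return n_w, xi_w, cls


def binding_potential(
    dH_mot: float,
    dS_mot: float,
    dCp_hydr: float,
    T,
    form: Literal["alpha", "beta"] = "alpha",
    constants: ThermoConstants = DEFAULT_CONSTANTS,
):
    """Evaluate the binding potential function at temperature(s) T.

    ``alpha`` returns R·lnK(T) = -ΔG_dual/T (J·K⁻¹·mol⁻¹); ``beta``
    returns RT·lnK(T) = -ΔG_dual (J·mol⁻¹).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("temperature must be strictly positive")
    alpha = -dH_mot / T + (dS_mot - dCp_hydr) + dCp_hydr * np.log(T)
    if form == "alpha":
        out = alpha
    elif form == "beta":
        out = T * alpha
    else:
        raise ValueError(f"unknown form {form!r}; expected 'alpha' or 'beta'")
    return out if out.ndim else float(out)


@dataclass
class Decomposition:
    """Dual = motive + thermal split of H, S and G at one temperature.

    The identities dH_dual = dH_mot + dH_th and dS_dual = dS_mot + dS_th
    hold by construction; ``dG_th_algebraic = dH_th - T·dS_th`` is reported
    purely as a diagnostic — the model's contract is that the thermal
    (implicit-solvent) part contributes zero free energy, all free energy
    residing in dG_mot = dH_mot - T·dS_mot.
    """

    temperature: float
    dH_dual: float
    dH_mot: float
    dH_th: float
    dS_dual: float
    dS_mot: float
    dS_th: float
    dG_dual: float
    dG_mot: float
    dG_th_algebraic: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ResidualSeries:
    """Log-constants after subtracting an iceberg contribution, with the
    straight-line (lnK_x versus 1/T) fit diagnostics."""

    temperatures: np.ndarray
    ln_K_x: np.ndarray
    slope: float       # coefficient of 1/T, equals -dH_x/R
    intercept: float
    r_squared: float


class DualBindingModel:
    """Per-compound model of R·lnK(T) with constant hydrophobic heat capacity.

    Parameters
    ----------
    temperatures, ln_k : array-like
        Measurement series (kelvin / natural-log equilibrium constants).
    family_id, compound_id : str
        Labels carried through to the results.
    constants : ThermoConstants
        Physical constants (R enters the response scaling, Cp_w the TED
        conversion).
    weights : array-like, optional
        Per-point weights for weighted least squares; default unweighted.

    Examples
    --------
    >>> model = DualBindingModel([273.15, 283.15, 293.15, 303.15, 313.15],
    ...                          [1.2, 1.1, 1.05, 1.03, 1.04])
    >>> res = model.fit()
    >>> res.hydration_class in {"A", "B", "indeterminate"}
    True
    """

    def __init__(
        self,
        temperatures,
        ln_k,
        *,
        family_id: str = "",
        compound_id: str = "",
        constants: ThermoConstants = DEFAULT_CONSTANTS,
        weights=None,
    ):
        series = CompoundSeries(family_id, compound_id, temperatures, ln_k)
        self.series = series
        self.constants = constants
        self.weights = None if weights is None else np.asarray(weights, float)
        if self.weights is not None and self.weights.size != len(series):
            raise DomainError("weights length must match the series")

    @classmethod
    def from_series(
        cls, series: CompoundSeries, constants: ThermoConstants = DEFAULT_CONSTANTS
    ) -> "DualBindingModel":
        return cls(
            series.temperatures,
            series.ln_k,
            family_id=series.family_id,
            compound_id=series.compound_id,
            constants=constants,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        temperature_col: str = "temperature_K",
        lnk_col: str = "lnK",
        constants: ThermoConstants = DEFAULT_CONSTANTS,
    ) -> "DualBindingModel":
        """Build a model from a single-compound tidy frame."""
        fam = str(df["family_id"].iloc[0]) if "family_id" in df else ""
        cid = str(df["compound_id"].iloc[0]) if "compound_id" in df else ""
        return cls(
            df[temperature_col].to_numpy(float),
            df[lnk_col].to_numpy(float),
            family_id=fam,
            compound_id=cid,
            constants=constants,
        )

    # -- design ---------------------------------------------------------
    def _design(self) -> tuple[np.ndarray, np.ndarray]:
        T = self.series.temperatures
        X = np.column_stack([1.0 / T, np.ones_like(T), np.log(T)])
        y = self.constants.gas_constant_R * self.series.ln_k
        return X, y

    def fit(self, significance_k: float = 2.0) -> "DualBindingResults":
        """Ordinary (or weighted) least squares of R·lnK on {1/T, 1, lnT}.

        Raises
        ------
        InsufficientDataError
            Fewer than 4 distinct temperatures (3 parameters need >= 1 df).
        SingularFitError
            Numerically collinear temperature grid.
        """
        n = len(self.series)
        if n < 4:
            raise InsufficientDataError(
                f"dual fit needs >= 4 distinct temperatures, got {n}"
            )
        X, y = self._design()
        scale = np.linalg.norm(X, axis=0)
        if np.linalg.cond(X / scale) > _COND_LIMIT:
            raise SingularFitError("temperature grid is numerically collinear")
        if self.weights is None:
            ols = sm.OLS(y, X).fit()
        else:
            ols = sm.WLS(y, X, weights=self.weights).fit()
        return DualBindingResults(self, ols, significance_k)


class DualBindingResults:
    """Fitted dual binding-potential function for one compound.

    Exposes the three structural parameters (``dH_mot`` J·mol⁻¹,
    ``dS_mot`` J·K⁻¹·mol⁻¹, ``dCp_hydr`` J·K⁻¹·mol⁻¹) with standard
    errors, the TED outputs (``n_w``, ``xi_w``, ``hydration_class``), and
    evaluation/decomposition methods.
    """

    _PARAM_INDEX = pd.Index(["dH_mot", "dS_mot", "dCp_hydr"])

    def __init__(self, model: DualBindingModel, ols_results, significance_k: float):
        self.model = model
        self.constants = model.constants
        self._ols = ols_results
        self.significance_k = float(significance_k)

        b = np.asarray(ols_results.params, float)
        cov = np.asarray(ols_results.cov_params(), float)
        # map basis coefficients (b0/u + b1 + b2·lnT) to structural params
        self.dH_mot = -b[0]
        self.dCp_hydr = b[2]
        self.dS_mot = b[1] + b[2]
        se_dH = np.sqrt(max(cov[0, 0], 0.0))
        se_dCp = np.sqrt(max(cov[2, 2], 0.0))
        se_dS = np.sqrt(max(cov[1, 1] + cov[2, 2] + 2.0 * cov[1, 2], 0.0))
        self.params = pd.Series(
            [self.dH_mot, self.dS_mot, self.dCp_hydr], index=self._PARAM_INDEX
        )
        self.bse = pd.Series([se_dH, se_dS, se_dCp], index=self._PARAM_INDEX)

        self.nobs = int(ols_results.nobs)
        self.df_resid = int(ols_results.df_resid)
        self.low_df = self.df_resid <= 1
        resid = np.asarray(ols_results.resid, float)
        ssr = float(resid @ resid)
        y = np.asarray(ols_results.model.endog, float)
        sst = float(np.sum((y - y.mean()) ** 2))
        # scale-aware zero test: a constant response is a perfect fit
        tiny = 1e-14 * y.size * max(1.0, float(np.mean(np.abs(y)))) ** 2
        if sst > tiny:
            self.r_squared = 1.0 - ssr / sst
        else:
            self.r_squared = 1.0 if ssr <= tiny else 0.0
        self.residual_sd = float(np.sqrt(ssr / self.df_resid)) if self.df_resid else 0.0

        self.n_w, self.xi_w, self.hydration_class = classify_ted(
            self.dCp_hydr, se_dCp, self.constants, significance_k
        )

    # -- evaluation ------------------------------------------------------
    def predict(self, T, form: Literal["alpha", "beta"] = "alpha"):
        """Binding potential at T: ``alpha`` = R·lnK, ``beta`` = RT·lnK."""
        return binding_potential(
            self.dH_mot, self.dS_mot, self.dCp_hydr, T, form, self.constants
        )

    def ln_k(self, T):
        """Model lnK at temperature(s) T."""
        return self.predict(T, "alpha") / self.constants.gas_constant_R

    def decompose(self, T: float) -> Decomposition:
        """Split the dual thermodynamic functions at T into motive and
        thermal parts (thermal terms carry the sign of n_w)."""
        if not T > 0:
            raise DomainError("temperature must be strictly positive")
        dCp = self.dCp_hydr
        dH_th = dCp * T
        dS_th = dCp * np.log(T)
        dH_dual = self.dH_mot + dH_th
        dS_dual = self.dS_mot + dS_th
        dG_mot = self.dH_mot - T * self.dS_mot
        return Decomposition(
            temperature=float(T),
            dH_dual=dH_dual,
            dH_mot=self.dH_mot,
            dH_th=dH_th,
            dS_dual=dS_dual,
            dS_mot=self.dS_mot,
            dS_th=dS_th,
            dG_dual=dH_dual - T * dS_dual,
            dG_mot=dG_mot,
            dG_th_algebraic=dH_th - T * dS_th,
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """t-based confidence intervals for the structural parameters."""
        if self.df_resid <= 0:
            half = pd.Series(0.0, index=self._PARAM_INDEX)
        else:
            tcrit = scipy.stats.t.ppf(1 - alpha / 2, self.df_resid)
            half = tcrit * self.bse
        return pd.DataFrame(
            {"lower": self.params - half, "upper": self.params + half}
        )

    def to_dict(self) -> dict:
        """All fitted quantities in SI units plus kJ-scaled twins."""
        return {
            "family_id": self.model.series.family_id,
            "compound_id": self.model.series.compound_id,
            "dH_mot_J_per_mol": self.dH_mot,
            "dS_mot_J_per_K_mol": self.dS_mot,
            "dCp_hydr_J_per_K_mol": self.dCp_hydr,
            "dH_mot_se": float(self.bse["dH_mot"]),
            "dS_mot_se": float(self.bse["dS_mot"]),
            "dCp_hydr_se": float(self.bse["dCp_hydr"]),
            "dH_mot_kJ_per_mol": self.dH_mot / 1e3,
            "dS_mot_kJ_per_K_mol": self.dS_mot / 1e3,
            "n_w": self.n_w,
            "xi_w": self.xi_w,
            "hydration_class": self.hydration_class,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "n_points": self.nobs,
            "low_df": self.low_df,
        }

    def plot(self, ax=None, form: Literal["alpha", "beta"] = "alpha"):
        """Diagnostic plot: measured binding potential versus 1/T with the
        fitted curve overlaid.  Returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        T = s.temperatures
        scale = 1.0 if form == "alpha" else T
        ax.plot(1.0 / T, scale * self.constants.gas_constant_R * s.ln_k,
                "o", label="data")
        T_fine = np.linspace(T.min(), T.max(), 200)
        ax.plot(1.0 / T_fine, self.predict(T_fine, form), "-",
                label=f"fit (class {self.hydration_class})")
        ax.set_xlabel("1/T (K⁻¹)")
        ax.set_ylabel("R·lnK (J·K⁻¹·mol⁻¹)" if form == "alpha"
                      else "RT·lnK (J·mol⁻¹)")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Human-readable fit report."""
        s = self.model.series
        lines = [
            "Dual binding-potential fit "
            f"[{s.family_id or '-'} / {s.compound_id or '-'}]",
            f"  n = {self.nobs} points, T = {s.temperatures.min():.2f}.."
            f"{s.temperatures.max():.2f} K, R² = {self.r_squared:.6f}, "
            f"residual sd = {self.residual_sd:.4g} J·K⁻¹·mol⁻¹",
            f"  dH_mot   = {self.dH_mot:14.4g} ± {self.bse['dH_mot']:.3g}  J·mol⁻¹",
            f"  dS_mot   = {self.dS_mot:14.4g} ± {self.bse['dS_mot']:.3g}  J·K⁻¹·mol⁻¹",
            f"  dCp_hydr = {self.dCp_hydr:14.4g} ± {self.bse['dCp_hydr']:.3g}  J·K⁻¹·mol⁻¹",
            f"  TED: n_w = {self.n_w:.4g}, xi_w = {self.xi_w:.4g}, "
            f"class {self.hydration_class} (k = {self.significance_k:g})",
        ]
        if self.low_df:
            lines.append("  warning: low residual degrees of freedom")
        return "\n".join(lines)


def iceberg_residual(
    series: CompoundSeries,
    xi_w: float,
    unitary_h: float,
    unitary_s: float,
    dCp_hydr: float,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> ResidualSeries:
    """Subtract the iceberg (formation/reduction) contribution from lnK.

    With ``unitary_h``/``unitary_s`` the per-xi_w enthalpy (J·mol⁻¹) and
    entropy (J·K⁻¹·mol⁻¹) of the iceberg step, the subtracted term is the
    model lnK of a process with dH = xi_w·unitary_h, dS = xi_w·unitary_s
    and heat capacity dCp_hydr.  When those match the true iceberg terms
    the residual lnK_x is exactly linear in 1/T (a classical van't Hoff
    plot), which is the linearisation diagnostic of the model.
    """
    if xi_w < 0:
        raise DomainError("xi_w must be non-negative")
    R = constants.gas_constant_R
    T = series.temperatures
    iceberg = (
        -xi_w * unitary_h / T + xi_w * unitary_s - dCp_hydr + dCp_hydr * np.log(T)
    ) / R
    ln_K_x = series.ln_k - iceberg

    u = 1.0 / T
    slope, intercept = np.polyfit(u, ln_K_x, 1)
    fitted = slope * u + intercept
    ss_res = float(np.sum((ln_K_x - fitted) ** 2))
    ss_tot = float(np.sum((ln_K_x - ln_K_x.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    return ResidualSeries(T, ln_K_x, float(slope), float(intercept), r2)
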