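"""Family-level disaggregation of motive functions and class comparison.

Within a family of related compounds (noble gases, carboxylic acids,
homologous surfactants, lysozyme-like proteins, ...) the motive enthalpy
and entropy are modelled as linear in the water count xi_w:

    dH_mot = dH0 + xi_w * dh        dS_mot = dS0 + xi_w * ds

The intercepts are the "null-iceberg" parts of the process (the reaction
with no ordered water sheath involved) and the slopes are the *unitary*
functions — the enthalpy/entropy of forming (Class A, negative slopes) or
reducing (Class B, positive slopes) one iceberg unit.

The class-comparison statistic reproduced here is the half-difference of
the absolute class means divided by the root-sum-square of the class
standard deviations; a conventional Welch t statistic is provided as a
clearly separate cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .data import FamilyRecord, records_to_frame
from .exceptions import DomainError, SingularFitError, SignConventionWarning

__all__ = [
    "FamilyDisaggregation",
    "FamilyDisaggregationResults",
    "UnitarySummary",
    "ClassComparison",
    "summarize_unitary",
    "compare_classes",
    "welch_t_statistic",
    "pool_unitary",
    "relative_error_percent",
]


def relative_error_percent(mean: float, sd: float) -> float:
    """Relative error (%) of a unitary mean: 100·sd/|mean|."""
    if mean == 0:
        return 0.0 if sd == 0 else math.inf
    return 100.0 * sd / abs(mean)


class FamilyDisaggregation:
    """OLS disaggregation of per-compound motive functions against xi_w.

    Parameters
    ----------
    records : list[FamilyRecord]
        One record per compound; at least two distinct xi_w values are
        required (three for standard errors).
    """

    def __init__(self, records: list[FamilyRecord]):
        if len(records) < 2:
            raise DomainError("family regression needs >= 2 compounds")
        self.records = list(records)
        self.family_id = records[0].family_id
        self.xi_w = np.array([r.xi_w for r in records], float)
        self.dH_mot = np.array([r.dH_mot for r in records], float)
        self.dS_mot = np.array([r.dS_mot for r in records], float)
        if np.ptp(self.xi_w) == 0:
            raise SingularFitError(
                f"family {self.family_id!r}: all compounds share xi_w = "
                f"{self.xi_w[0]:g}; the slope is unidentifiable"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FamilyDisaggregation":
        records = [
            FamilyRecord(
                family_id=str(row.get("family_id", "")),
                compound_id=str(row.get("compound_id", "")),
                xi_w=float(row["xi_w"]),
                dH_mot=float(row["dH_mot"]),
                dS_mot=float(row["dS_mot"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(records)

    def fit(self, reference_T: float = 298.0) -> "FamilyDisaggregationResults":
        X = sm.add_constant(self.xi_w)
        res_H = sm.OLS(self.dH_mot, X).fit()
        res_S = sm.OLS(self.dS_mot, X).fit()
        return FamilyDisaggregationResults(self, res_H, res_S, reference_T)


def _r_squared(ols) -> float:
    resid = np.asarray(ols.resid, float)
    ssr = float(resid @ resid)
    y = np.asarray(ols.model.endog, float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst > 0:
        return 1.0 - ssr / sst
    return 1.0 if ssr < 1e-20 else 0.0


class FamilyDisaggregationResults:
    """Null-iceberg intercepts, unitary slopes and diagnostics for a family.

    Attributes
    ----------
    intercept_H, slope_H : float
        dH_mot = intercept_H + xi_w·slope_H (J·mol⁻¹).
    intercept_S, slope_S : float
        dS_mot = intercept_S + xi_w·slope_S (J·K⁻¹·mol⁻¹).
    dG0_at_reference_T : float
        Null-iceberg free energy intercept_H − T·intercept_S (J·mol⁻¹).
    hydration_class : str
        "A" when both slopes are negative, "B" when both positive,
        "indeterminate" otherwise (a structured warning is emitted —
        mixed-sign slopes are never silently relabelled).
    """

    def __init__(self, model, res_H, res_S, reference_T):
        self.model = model
        self.family_id = model.family_id
        self.n_compounds = int(model.xi_w.size)
        self.reference_T = float(reference_T)

        bH, bS = res_H.params, res_S.params
        self.intercept_H, self.slope_H = float(bH[0]), float(bH[1])
        self.intercept_S, self.slope_S = float(bS[0]), float(bS[1])
        if self.n_compounds >= 3:
            self.intercept_H_se, self.slope_H_se = (float(v) for v in res_H.bse)
            self.intercept_S_se, self.slope_S_se = (float(v) for v in res_S.bse)
        else:  # exact two-point interpolation: no residual df
            self.intercept_H_se = self.slope_H_se = math.nan
            self.intercept_S_se = self.slope_S_se = math.nan
        self.r_squared_H = _r_squared(res_H)
        self.r_squared_S = _r_squared(res_S)
        self.dG0_at_reference_T = self.intercept_H - reference_T * self.intercept_S

        self.sign_consistent = True
        if self.slope_H < 0 and self.slope_S < 0:
            self.hydration_class = "A"
        elif self.slope_H > 0 and self.slope_S > 0:
            self.hydration_class = "B"
        else:
            self.hydration_class = "indeterminate"
            self.sign_consistent = False
            warnings.warn(
                f"family {self.family_id!r}: unitary slopes have mixed signs "
                f"(slope_H = {self.slope_H:.4g}, slope_S = {self.slope_S:.4g}); "
                "no hydration class assigned",
                SignConventionWarning,
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "n_compounds": self.n_compounds,
            "intercept_H_J_per_mol": self.intercept_H,
            "slope_H_J_per_mol_per_xi": self.slope_H,
            "intercept_S_J_per_K_mol": self.intercept_S,
            "slope_S_J_per_K_mol_per_xi": self.slope_S,
            "intercept_H_se": self.intercept_H_se,
            "slope_H_se": self.slope_H_se,
            "intercept_S_se": self.intercept_S_se,
            "slope_S_se": self.slope_S_se,
            "r_squared_H": self.r_squared_H,
            "r_squared_S": self.r_squared_S,
            "hydration_class": self.hydration_class,
            "sign_consistent": self.sign_consistent,
            "reference_T": self.reference_T,
            "dG0_at_reference_T_J_per_mol": self.dG0_at_reference_T,
            "slope_H_kJ": self.slope_H / 1e3,
            "intercept_H_kJ": self.intercept_H / 1e3,
            "dG0_at_reference_T_kJ": self.dG0_at_reference_T / 1e3,
        }

    def summary(self) -> str:
        d = self.to_dict()
        return (
            f"Family {self.family_id!r} ({self.n_compounds} compounds), "
            f"class {self.hydration_class}\n"
            f"  dH_mot = {d['intercept_H_kJ']:.4g} + xi_w * "
            f"{d['slope_H_kJ']:.4g} kJ·mol⁻¹   (R² = {self.r_squared_H:.4f})\n"
            f"  dS_mot = {self.intercept_S:.4g} + xi_w * "
            f"{self.slope_S:.4g} J·K⁻¹·mol⁻¹   (R² = {self.r_squared_S:.4f})\n"
            f"  dG0(xi_w=0, T={self.reference_T:g} K) = "
            f"{d['dG0_at_reference_T_kJ']:.4g} kJ·mol⁻¹"
        )


@dataclass
class UnitarySummary:
    """Pooled statistics of per-family unitary slopes for one class."""

    class_label: str
    quantity: str                 # "enthalpy" or "entropy"
    values: list[float]
    mean: float = field(init=False)
    sd: float = field(init=False)
    relative_error_percent: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise DomainError("summarize_unitary needs at least one value")
        v = np.asarray(self.values, float)
        self.mean = float(v.mean())
        self.sd = float(v.std(ddof=1)) if v.size >= 2 else 0.0
        self.relative_error_percent = (
            100.0 * self.sd / abs(self.mean) if self.mean != 0 else 0.0
        )

    def to_dict(self) -> dict:
        return {
            "class": self.class_label,
            "quantity": self.quantity,
            "n_families": len(self.values),
            "mean": self.mean,
            "sd": self.sd,
            "relative_error_percent": self.relative_error_percent,
            "relative_error_percent_display": round(self.relative_error_percent, 1),
        }


def summarize_unitary(
    values, class_label: str = "", quantity: str = ""
) -> UnitarySummary:
    """Mean, sample sd (n−1 denominator) and relative error (%) of a set of
    per-family unitary values."""
    return UnitarySummary(class_label, quantity, [float(v) for v in values])


@dataclass
class ClassComparison:
    """Equal-magnitude test between Class A and Class B unitary means.

    ``students_ratio`` is ||mean_A| − |mean_B||/2 divided by
    sqrt(sd_A² + sd_B²); the equal-magnitude hypothesis is accepted when
    the ratio is below ``threshold``.
    """

    mean_A: float
    sd_A: float
    mean_B: float
    sd_B: float
    threshold: float
    mean_abs: float = field(init=False)
    half_range: float = field(init=False)
    pooled_sd: float = field(init=False)
    students_ratio: float = field(init=False)
    decision: str = field(init=False)

    def __post_init__(self) -> None:
        if self.sd_A < 0 or self.sd_B < 0:
            raise DomainError("standard deviations must be non-negative")
        a, b = abs(self.mean_A), abs(self.mean_B)
        self.mean_abs = (a + b) / 2.0
        self.half_range = abs(a - b) / 2.0
        self.pooled_sd = math.hypot(self.sd_A, self.sd_B)
        if self.pooled_sd == 0:
            self.students_ratio = 0.0 if self.half_range == 0 else math.inf
        else:
            self.students_ratio = self.half_range / self.pooled_sd
        self.decision = (
            "accepted" if self.students_ratio < self.threshold else "rejected"
        )

    def to_dict(self) -> dict:
        return {
            "mean_A": self.mean_A,
            "sd_A": self.sd_A,
            "mean_B": self.mean_B,
            "sd_B": self.sd_B,
            "mean_abs": self.mean_abs,
            "half_range": self.half_range,
            "pooled_sd": self.pooled_sd,
            "students_ratio": self.students_ratio,
            "students_ratio_display": round(self.students_ratio, 3),
            "threshold": self.threshold,
            "decision": self.decision,
        }


def compare_classes(
    summary_A: tuple[float, float],
    summary_B: tuple[float, float],
    threshold: float = 2.0,
) -> ClassComparison:
    """Compare the (mean, sd) unitary summaries of the two hydration classes.

    Symmetric in its arguments and invariant to a simultaneous sign flip of
    both means.
    """
    mean_A, sd_A = summary_A
    mean_B, sd_B = summary_B
    return ClassComparison(mean_A, sd_A, mean_B, sd_B, threshold)


def welch_t_statistic(
    mean_A: float, sd_A: float, n_A: int, mean_B: float, sd_B: float, n_B: int
) -> dict:
    """Conventional Welch two-sample t test on |mean_A| vs |mean_B|.

    Provided as a labelled cross-check of the ratio statistic above; it is
    NOT the decision rule of the pipeline.  Uses the summary-statistics
    form (scipy ``ttest_ind_from_stats`` with equal_var=False) on the
    absolute means.
    """
    res = scipy.stats.ttest_ind_from_stats(
        abs(mean_A), sd_A, n_A, abs(mean_B), sd_B, n_B, equal_var=False
    )
    return {"t": float(res.statistic), "p_value": float(res.pvalue)}


def pool_unitary(values, standard_errors=None) -> dict:
    """Simple and inverse-variance-weighted pooled means of unitary values.

    The weighting used for the published class means is unstated, so both
    poolings are reported side by side.
    """
    v = np.asarray(list(values), float)
    out = {"simple_mean": float(v.mean()), "n": int(v.size)}
    out["simple_sd"] = float(v.std(ddof=1)) if v.size >= 2 else 0.0
    if standard_errors is not None:
        se = np.asarray(list(standard_errors), float)
        if se.size != v.size or np.any(se <= 0):
            raise DomainError("standard errors must be positive, one per value")
        w = 1.0 / se**2
        out["weighted_mean"] = float(np.sum(w * v) / np.sum(w))
        out["weighted_se"] = float(np.sqrt(1.0 / np.sum(w)))
    return out
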