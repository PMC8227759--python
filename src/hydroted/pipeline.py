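"""End-to-end pipeline: per-compound fits -> family disaggregation ->
unitary statistics -> class comparison, with a partial-failure contract
(every input compound appears in the report, fitted or errored)."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .constants import DEFAULT_CONSTANTS, ThermoConstants
from .data import CompoundSeries, FamilyRecord
from .dualfit import DualBindingModel
from .exceptions import HydrotedError
from .family import FamilyDisaggregation, compare_classes, summarize_unitary

logger = logging.getLogger("hydroted")

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """Validated pipeline settings; every default is echoed at run start."""

    gas_constant_R: float = DEFAULT_CONSTANTS.gas_constant_R
    water_heat_capacity_Cpw: float = DEFAULT_CONSTANTS.water_heat_capacity_Cpw
    avogadro_N: float = DEFAULT_CONSTANTS.avogadro_N
    reference_T: float = DEFAULT_CONSTANTS.reference_T
    significance_k: float = 2.0
    ratio_threshold: float = 2.0
    celsius_input: bool = False
    input_path: str | None = None
    output_path: str | None = None
    verbosity: int = 0

    def constants(self) -> ThermoConstants:
        return ThermoConstants(
            self.gas_constant_R,
            self.water_heat_capacity_Cpw,
            self.avogadro_N,
            self.reference_T,
        )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(mapping) - known
        if unknown:
            raise HydrotedError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


def run_pipeline(
    series_list: list[CompoundSeries],
    config: PipelineConfig | None = None,
    *,
    seed: int | None = None,
) -> dict:
    """Run every analysis stage over the given series and assemble a report.

    Per-compound or per-family failures are recorded in the report (with
    the offending id) without aborting the remaining stages.  Deterministic
    for fixed inputs and config.
    """
    config = config or PipelineConfig()
    constants = config.constants()
    logger.info(
        "pipeline start: R=%g, Cp_w=%g, N_Avo=%g, reference_T=%g, "
        "significance_k=%g, ratio_threshold=%g",
        constants.gas_constant_R, constants.water_heat_capacity_Cpw,
        constants.avogadro_N, constants.reference_T,
        config.significance_k, config.ratio_threshold,
    )

    report: dict = {
        "provenance": {
            "package": "hydroted",
            "version": __version__,
            "config": asdict(config),
            "config_hash": config.digest(),
            "seed": seed,
        },
        "compounds": [],
        "families": [],
        "classes": {},
        "comparison": {},
        "errors": [],
    }

    # stage 1: per-compound dual fits
    records_by_family: dict[str, list[FamilyRecord]] = {}
    for s in series_list:
        try:
            res = DualBindingModel.from_series(s, constants).fit(
                config.significance_k
            )
        except HydrotedError as exc:
            entry = {
                "family_id": s.family_id,
                "compound_id": s.compound_id,
                "error": str(exc),
            }
            report["compounds"].append(entry)
            report["errors"].append(entry)
            continue
        report["compounds"].append(res.to_dict())
        records_by_family.setdefault(s.family_id, []).append(
            FamilyRecord(
                family_id=s.family_id,
                compound_id=s.compound_id,
                xi_w=res.xi_w,
                dH_mot=res.dH_mot,
                dS_mot=res.dS_mot,
                n_w=res.n_w,
                dH_mot_se=float(res.bse["dH_mot"]),
                dS_mot_se=float(res.bse["dS_mot"]),
            )
        )

    # stage 2: family disaggregation against xi_w
    slopes_by_class: dict[str, dict[str, list[float]]] = {}
    for fam_id, records in sorted(records_by_family.items()):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fam_res = FamilyDisaggregation(records).fit(config.reference_T)
            fam_dict = fam_res.to_dict()
            if caught:
                fam_dict["warnings"] = [str(w.message) for w in caught]
        except HydrotedError as exc:
            entry = {"family_id": fam_id, "error": str(exc)}
            report["families"].append(entry)
            report["errors"].append(entry)
            continue
        report["families"].append(fam_dict)
        cls = fam_res.hydration_class
        if cls in ("A", "B"):
            bucket = slopes_by_class.setdefault(
                cls, {"enthalpy_kJ": [], "entropy_J_per_K": []}
            )
            bucket["enthalpy_kJ"].append(fam_res.slope_H / 1e3)
            bucket["entropy_J_per_K"].append(fam_res.slope_S)

    # stage 3: unitary statistics per class
    summaries: dict[str, dict[str, dict]] = {}
    for cls, bucket in sorted(slopes_by_class.items()):
        summaries[cls] = {
            "enthalpy": summarize_unitary(
                bucket["enthalpy_kJ"], cls, "enthalpy"
            ).to_dict(),
            "entropy": summarize_unitary(
                bucket["entropy_J_per_K"], cls, "entropy"
            ).to_dict(),
        }
    report["classes"] = summaries

    # stage 4: A/B comparison (only when both classes are represented)
    if "A" in summaries and "B" in summaries:
        for qty in ("enthalpy", "entropy"):
            sa, sb = summaries["A"][qty], summaries["B"][qty]
            report["comparison"][qty] = compare_classes(
                (sa["mean"], sa["sd"]),
                (sb["mean"], sb["sd"]),
                config.ratio_threshold,
            ).to_dict()

    return report


def _fmt(x, nd=4):
    if isinstance(x, float):
        return f"{x:.{nd}g}"
    return str(x)


def render_report(report: dict) -> str:
    """Plain-text rendering of a pipeline report (families / classes /
    comparison blocks)."""
    out = []
    prov = report.get("provenance", {})
    out.append(
        f"hydroted {prov.get('version', '?')} report "
        f"(config {prov.get('config_hash', '?')})"
    )
    out.append(f"\nCompounds fitted: "
               f"{sum(1 for c in report['compounds'] if 'error' not in c)}"
               f" / {len(report['compounds'])}")
    for c in report["compounds"]:
        if "error" in c:
            out.append(f"  {c['family_id']}/{c['compound_id']}: "
                       f"ERROR {c['error']}")
        else:
            out.append(
                f"  {c['family_id']}/{c['compound_id']}: "
                f"xi_w={_fmt(c['xi_w'])} class={c['hydration_class']} "
                f"dH_mot={_fmt(c['dH_mot_kJ_per_mol'])} kJ "
                f"dS_mot={_fmt(c['dS_mot_J_per_K_mol'])} J/K "
                f"R²={_fmt(c['r_squared'], 6)}"
            )
    if report["families"]:
        out.append("\nFamily disaggregation (dX_mot = intercept + slope·xi_w):")
        for f in report["families"]:
            if "error" in f:
                out.append(f"  {f['family_id']}: ERROR {f['error']}")
                continue
            out.append(
                f"  {f['family_id']} [class {f['hydration_class']}]: "
                f"dH_mot = {_fmt(f['intercept_H_kJ'])} "
                f"{'+' if f['slope_H_kJ'] >= 0 else '-'} "
                f"{_fmt(abs(f['slope_H_kJ']))}·xi_w kJ·mol⁻¹ "
                f"(R²={_fmt(f['r_squared_H'], 6)}); "
                f"dS_mot = {_fmt(f['intercept_S_J_per_K_mol'])} "
                f"{'+' if f['slope_S_J_per_K_mol_per_xi'] >= 0 else '-'} "
                f"{_fmt(abs(f['slope_S_J_per_K_mol_per_xi']))}·xi_w J·K⁻¹·mol⁻¹ "
                f"(R²={_fmt(f['r_squared_S'], 6)}); "
                f"dG0({_fmt(f['reference_T'])} K) = "
                f"{_fmt(f['dG0_at_reference_T_kJ'])} kJ·mol⁻¹"
            )
    if report["classes"]:
        out.append("\nUnitary statistics by class:")
        for cls, block in report["classes"].items():
            for qty, s in block.items():
                out.append(
                    f"  class {cls} {qty}: mean={_fmt(s['mean'])} "
                    f"sd={_fmt(s['sd'])} "
                    f"rel.err={s['relative_error_percent_display']}% "
                    f"(n={s['n_families']})"
                )
    if report["comparison"]:
        out.append("\nClass A vs B equal-magnitude comparison:")
        for qty, c in report["comparison"].items():
            out.append(
                f"  {qty}: |mean| midpoint={_fmt(c['mean_abs'])} "
                f"half-range={_fmt(c['half_range'])} "
                f"pooled sd={_fmt(c['pooled_sd'])} "
                f"ratio={c['students_ratio_display']} -> {c['decision']} "
                f"(threshold {c['threshold']})"
            )
    return "\n".join(out)
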