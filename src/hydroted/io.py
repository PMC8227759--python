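"""Table readers/writers for measurement series and family records.

The on-disk format is delimiter-separated text (comma by default, sniffed
otherwise) with a header row.  Series tables carry ``family_id``,
``compound_id``, ``temperature_K`` and exactly one of ``K`` or ``lnK``;
raw constants are converted with the natural logarithm on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CompoundSeries, FamilyRecord
from .exceptions import ParseError

__all__ = [
    "read_series_table",
    "write_series_table",
    "read_family_records",
    "write_report",
]

_REQUIRED = ["family_id", "compound_id", "temperature_K"]


def _load_frame(path, delimiter) -> pd.DataFrame:
    try:
        if delimiter is None:
            return pd.read_csv(path, sep=None, engine="python")
        return pd.read_csv(path, sep=delimiter)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc


def read_series_table(
    path,
    delimiter: str | None = None,
    *,
    celsius: bool = False,
) -> list[CompoundSeries]:
    """Parse a series table into per-compound series.

    Rows are grouped by (family_id, compound_id) and sorted by
    temperature.  ``celsius=True`` converts the temperature column from
    °C to K on read.  Structural problems (missing or ambiguous K/lnK
    columns, non-numeric cells, K <= 0, duplicated temperatures within a
    compound) raise :class:`ParseError` carrying 1-based data row numbers.
    """
    df = _load_frame(path, delimiter)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    has_k, has_lnk = "K" in df.columns, "lnK" in df.columns
    if has_k and has_lnk:
        raise ParseError(f"{path}: both K and lnK present; provide exactly one")
    if not (has_k or has_lnk):
        raise ParseError(f"{path}: neither K nor lnK column present")
    value_col = "K" if has_k else "lnK"

    rows = np.arange(1, len(df) + 1)  # 1-based, excluding header
    tnum = pd.to_numeric(df["temperature_K"], errors="coerce")
    vnum = pd.to_numeric(df[value_col], errors="coerce")
    bad = rows[tnum.isna().to_numpy() | vnum.isna().to_numpy()]
    if bad.size:
        raise ParseError(f"{path}: non-numeric cells", list(map(int, bad)))
    if celsius:
        tnum = tnum + 273.15
    if has_k:
        bad = rows[(vnum <= 0).to_numpy()]
        if bad.size:
            raise ParseError(f"{path}: K must be > 0", list(map(int, bad)))
        vnum = np.log(vnum)

    work = pd.DataFrame(
        {
            "family_id": df["family_id"].astype(str),
            "compound_id": df["compound_id"].astype(str),
            "T": tnum.to_numpy(float),
            "lnK": vnum.to_numpy(float),
            "row": rows,
        }
    )
    dup = work.duplicated(subset=["family_id", "compound_id", "T"], keep=False)
    if dup.any():
        raise ParseError(
            f"{path}: duplicate (compound, temperature) rows",
            list(map(int, work.loc[dup, "row"])),
        )

    series: list[CompoundSeries] = []
    for (fam, cid), grp in work.groupby(["family_id", "compound_id"], sort=True):
        series.append(
            CompoundSeries(fam, cid, grp["T"].to_numpy(), grp["lnK"].to_numpy())
        )
    return series


def write_series_table(series_list: list[CompoundSeries], path) -> None:
    """Write series as a comma-separated table with a lnK column."""
    frames = [s.to_frame() for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_family_records(path, delimiter: str | None = None) -> list[FamilyRecord]:
    """Parse a family-record table (family_id, compound_id, xi_w,
    dH_mot_kJ, dS_mot_J_per_K); enthalpies are converted kJ -> J."""
    df = _load_frame(path, delimiter)
    needed = ["family_id", "compound_id", "xi_w", "dH_mot_kJ", "dS_mot_J_per_K"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                FamilyRecord(
                    family_id=str(row["family_id"]),
                    compound_id=str(row["compound_id"]),
                    xi_w=float(row["xi_w"]),
                    dH_mot=float(row["dH_mot_kJ"]) * 1e3,
                    dS_mot=float(row["dS_mot_J_per_K"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: bad record: {exc}", [int(i) + 1]) from exc
    return records


def write_report(report: dict, path) -> None:
    """Serialise a pipeline report to JSON (full precision)."""
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
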