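"""Tidy-CSV readers and writers (RFC-4180, UTF-8, dot decimal).

Interchange units are fixed: time in hours, concentrations in mM-N, buoyant
density in g/mL, rates in mg N·day⁻¹·kg soil⁻¹. Writers prepend a
provenance comment block (``# key: value``) recording the package version,
seed and config hash; readers skip ``#`` lines.

Time-series schema: treatment, salinity, replicate, time_h, no2_mM, no3_mM.
Fraction schema: gradient_id, condition, isotope, replicate, fraction,
density_g_ml (or refractive_index), one column per target.
qPCR schema: target, sample, cq, role ∈ {standard, unknown}, log10_copies
(standards only).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .config import InputError, TREATMENTS, TreatmentSeries

__all__ = [
    "SchemaError",
    "config_hash",
    "write_csv",
    "read_csv",
    "write_timeseries",
    "read_timeseries",
    "write_fraction_table",
    "read_fraction_table",
]

TIMESERIES_COLUMNS = ["treatment", "salinity", "replicate", "time_h", "no2_mM", "no3_mM"]
FRACTION_KEY_COLUMNS = [
    "gradient_id",
    "condition",
    "isotope",
    "replicate",
    "fraction",
    "density_g_ml",
]


class SchemaError(InputError):
    """A file does not match the documented column schema."""


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable config mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance_block(provenance: Mapping[str, object] | None) -> str:
    items = {"package": f"nitripartition {__version__}"}
    if provenance:
        items.update({str(k): v for k, v in provenance.items()})
    return "".join(f"# {k}: {v}\n" for k, v in items.items())


def write_csv(
    frame: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> Path:
    """Write a DataFrame as CSV with a leading provenance comment block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    frame.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(_provenance_block(provenance) + buf.getvalue(), encoding="utf-8")
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _require_columns(frame: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s) {missing}")


def _require_numeric(frame: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    for col in columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad) > 0:
            raise SchemaError(
                f"{what}: non-numeric value {frame.loc[bad[0], col]!r} in column "
                f"{col!r} (row {int(bad[0]) + 2} of the file)"
            )
        if coerced.isna().any():
            row = int(frame.index[coerced.isna()][0]) + 2
            raise SchemaError(f"{what}: missing value in column {col!r} (row {row})")
        frame[col] = coerced


def write_timeseries(
    series_list: Sequence[TreatmentSeries],
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> Path:
    rows = [
        {
            "treatment": s.treatment,
            "salinity": s.salinity,
            "replicate": s.replicate,
            "time_h": t,
            "no2_mM": n2,
            "no3_mM": n3,
        }
        for s in series_list
        for t, n2, n3 in zip(s.times, s.no2, s.no3)
    ]
    return write_csv(pd.DataFrame(rows, columns=TIMESERIES_COLUMNS), path, provenance)


def read_timeseries(path: str | Path) -> list[TreatmentSeries]:
    """Read, validate and canonicalize microcosm time series.

    Rows are grouped by (treatment, salinity, replicate) and sorted by time
    within each series; schema violations name the offending value and row.
    """
    frame = read_csv(path)
    _require_columns(frame, TIMESERIES_COLUMNS, "time-series file")
    _require_numeric(frame, ["salinity", "replicate", "time_h", "no2_mM", "no3_mM"],
                     "time-series file")
    bad = frame.loc[~frame["treatment"].isin(TREATMENTS), "treatment"]
    if len(bad) > 0:
        raise SchemaError(
            f"time-series file: invalid treatment {bad.iloc[0]!r} "
            f"(row {int(bad.index[0]) + 2}); expected one of {TREATMENTS}"
        )
    if (frame[["no2_mM", "no3_mM"]] < 0).any().any():
        row = int(frame.index[(frame[["no2_mM", "no3_mM"]] < 0).any(axis=1)][0]) + 2
        raise SchemaError(f"time-series file: negative concentration (row {row})")

    out: list[TreatmentSeries] = []
    for (treatment, salinity, replicate), group in frame.groupby(
        ["treatment", "salinity", "replicate"], sort=True
    ):
        group = group.sort_values("time_h")
        out.append(
            TreatmentSeries(
                treatment=str(treatment),
                salinity=float(salinity),
                replicate=int(replicate),
                times=tuple(group["time_h"].astype(float)),
                no2=tuple(group["no2_mM"].astype(float)),
                no3=tuple(group["no3_mM"].astype(float)),
            )
        )
    return out


def write_fraction_table(
    table: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> Path:
    _require_columns(table, FRACTION_KEY_COLUMNS, "fraction table")
    return write_csv(table, path, provenance)


def read_fraction_table(path: str | Path) -> pd.DataFrame:
    """Read a gradient fraction table; converts refractive index to density
    when only ``refractive_index`` is present, and restores the heavy =
    low-index ordering."""
    from .sip import fit_ri_calibration, ri_to_density

    frame = read_csv(path)
    if "density_g_ml" not in frame.columns:
        if "refractive_index" not in frame.columns:
            raise SchemaError(
                "fraction table needs a density_g_ml or refractive_index column"
            )
        frame["density_g_ml"] = ri_to_density(
            frame["refractive_index"].to_numpy(dtype=float), fit_ri_calibration()
        )
    _require_columns(frame, FRACTION_KEY_COLUMNS, "fraction table")
    target_cols = [c for c in frame.columns
                   if c not in FRACTION_KEY_COLUMNS + ["refractive_index"]]
    _require_numeric(frame, ["fraction", "density_g_ml"] + target_cols, "fraction table")
    return frame.sort_values(
        ["gradient_id", "isotope", "replicate", "fraction"]
    ).reset_index(drop=True)
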