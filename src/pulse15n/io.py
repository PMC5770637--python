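"""CSV reading/writing with the pipeline's fixed schemas.

All files are UTF-8 CSV with a header row, "." decimal separator and empty
fields for missing values.  Report writers prepend ``#`` comment lines
stating column units and the seed, so results never interleave with logs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .pools import LeachateRecord
from .recovery import MEASUREMENT_COLUMNS

__all__ = [
    "SchemaError",
    "read_measurements",
    "read_pools",
    "read_leachate",
    "write_report",
]

POOL_COLUMNS = ("compartment", "year", "m_pool_gN_m2")
LEACHATE_COLUMNS = (
    "start_date",
    "end_date",
    "volume_L_m2",
    "n_inorg_mg_L",
    "don_mg_L",
    "delta15N_permil",
)


class SchemaError(ValueError):
    """An input CSV does not match the expected schema."""


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} (header line 1)")


def read_measurements(path) -> pd.DataFrame:
    """Long-format paired-subplot δ¹⁵N measurements."""
    frame = pd.read_csv(path, comment="#")
    _require_columns(frame, [c for c in MEASUREMENT_COLUMNS if c != "n_content_fraction"], path)
    bad = ~frame["role"].isin(["labelled", "reference"])
    if bad.any():
        lines = (frame.index[bad] + 2).tolist()
        raise SchemaError(f"{path}: invalid role values on data lines {lines[:10]}")
    return frame


def read_pools(path) -> pd.DataFrame:
    """Compartment × year N pool masses (g N m⁻²)."""
    frame = pd.read_csv(path, comment="#")
    _require_columns(frame, POOL_COLUMNS, path)
    bad = frame["m_pool_gN_m2"] < 0
    if bad.any():
        lines = (frame.index[bad] + 2).tolist()
        raise SchemaError(f"{path}: negative pool masses on data lines {lines[:10]}")
    return frame


def read_leachate(path) -> list[LeachateRecord]:
    """Lysimeter collection intervals (ISO-8601 dates)."""
    frame = pd.read_csv(path, comment="#")
    _require_columns(frame, LEACHATE_COLUMNS[:5], path)
    records = []
    for i, r in frame.iterrows():
        try:
            records.append(
                LeachateRecord(
                    start_date=str(r["start_date"]),
                    end_date=str(r["end_date"]),
                    volume_l_m2=float(r["volume_L_m2"]),
                    n_inorg_mg_l=float(r["n_inorg_mg_L"]),
                    don_mg_l=float(r["don_mg_L"]),
                    delta15n=float(r["delta15N_permil"]) if "delta15N_permil" in frame else None,
                )
            )
        except ValueError as err:
            raise SchemaError(f"{path}: data line {i + 2}: {err}") from err
    return records


def write_report(
    frame: pd.DataFrame,
    path,
    units: dict[str, str] | None = None,
    seed: int | None = None,
    round_decimals: int | None = 2,
) -> Path:
    """Write a result table with unit/seed comment headers.

    Numeric columns are rounded (default two decimals) in the written file
    only; in-memory tables keep full precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = frame.copy()
    if round_decimals is not None:
        num = out.select_dtypes("number").columns
        out[num] = out[num].round(round_decimals)
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        for col, unit in (units or {}).items():
            fh.write(f"# {col}: {unit}\n")
        out.to_csv(fh, index=False)
    return path
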