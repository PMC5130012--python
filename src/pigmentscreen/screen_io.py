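"""Reading and writing of plate layouts, well readings and result tables.

All tables are pandas DataFrames in stable CSV dialects: comma separator,
UTF-8, ``.`` decimal, doses always in micromolar.  Well addresses are parsed
case-insensitively and stored uppercase.  Floats are written with 6
significant digits so repeated writes of the same table are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError

#: Closed vocabulary of well roles.
ROLES = frozenset(
    {
        "casper",          # pigment-free background control (eye melanin only)
        "wt",              # wild-type larvae
        "v12ras_dmso",     # untreated (vehicle-only) transgenic control
        "compound",        # library compound alone
        "compound_plus_mek",   # compound + MEK-inhibitor backbone
        "compound_plus_pi3k",  # compound + PI3K/mTOR-inhibitor backbone
    }
)

#: Roles that carry a library compound and hence need a compound_id.
COMPOUND_ROLES = frozenset({"compound", "compound_plus_mek", "compound_plus_pi3k"})

#: Canonical column order of a well-record table.
WELL_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "compound_id",
    "dose_um",
    "raw_absorbance",
    "wavelength_nm",
    "embryos_in",
    "embryos_alive",
]

LAYOUT_COLUMNS = ["plate_id", "well", "role", "compound_id", "dose_um"]


@dataclass
class PlateLayout:
    """Declared layout of a single plate: which well holds which role."""

    plate_id: str
    wells: list[tuple[str, str, str, float]] = field(default_factory=list)
    # each entry: (well_address, role, compound_id, dose_um); compound_id may
    # be "" and dose_um may be nan for control wells

    def roles(self) -> set[str]:
        return {w[1] for w in self.wells}

    def validate(self, require_controls: bool = True) -> None:
        seen: set[str] = set()
        for addr, role, compound_id, _dose in self.wells:
            if role not in ROLES:
                raise ConfigurationError(
                    f"plate {self.plate_id}: unknown role {role!r} in well {addr}"
                )
            if addr in seen:
                raise ConfigurationError(
                    f"plate {self.plate_id}: duplicate well address {addr}"
                )
            seen.add(addr)
            if role in COMPOUND_ROLES and not compound_id:
                raise ConfigurationError(
                    f"plate {self.plate_id}: well {addr} has role {role} "
                    "but no compound_id"
                )
        if require_controls:
            for needed in ("casper", "v12ras_dmso"):
                if needed not in self.roles():
                    raise ConfigurationError(
                        f"plate {self.plate_id}: missing required control "
                        f"role {needed!r}"
                    )


def _norm_well(addr: str) -> str:
    return str(addr).strip().upper()


def _well_sort_key(addr: str) -> tuple[str, int]:
    row = addr[0]
    try:
        col = int(addr[1:])
    except ValueError:
        col = 0
    return row, col


def read_layouts(path: str | Path) -> list[PlateLayout]:
    """Read a plate-layout CSV (plate_id, well, role, compound_id, dose_um)."""
    path = Path(path)
    df = _read_csv(path, LAYOUT_COLUMNS, numeric=["dose_um"])
    layouts: list[PlateLayout] = []
    for plate_id, grp in df.groupby("plate_id", sort=True):
        wells = [
            (r.well, r.role, r.compound_id, r.dose_um)
            for r in grp.itertuples()
        ]
        layout = PlateLayout(plate_id=str(plate_id), wells=wells)
        try:
            layout.validate(require_controls=False)
        except ConfigurationError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        layouts.append(layout)
    return layouts


def read_plates(paths: Sequence[str | Path]) -> tuple[list[PlateLayout], pd.DataFrame]:
    """Read well-record CSVs; return the implied layouts and the typed table.

    Validation errors cite ``file:line`` (line numbers count the header as
    line 1, matching what an editor shows).
    """
    frames = []
    for path in paths:
        path = Path(path)
        df = _read_csv(
            path,
            WELL_COLUMNS,
            numeric=["dose_um", "raw_absorbance", "wavelength_nm",
                     "embryos_in", "embryos_alive"],
        )
        _validate_wells(df, path)
        frames.append(df)
    wells = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=WELL_COLUMNS
    )
    wells = sort_wells(wells)
    layouts = []
    for plate_id, grp in wells.groupby("plate_id", sort=True):
        layouts.append(
            PlateLayout(
                plate_id=str(plate_id),
                wells=[
                    (r.well, r.role, r.compound_id, r.dose_um)
                    for r in grp.itertuples()
                ],
            )
        )
    return layouts, wells


def _read_csv(path: Path, columns: list[str], numeric: Iterable[str]) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df[columns].copy()
    df["well"] = df["well"].map(_norm_well)
    for col in numeric:
        converted = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}:{i + 2}: non-numeric value {df[col].iloc[i]!r} "
                f"in column {col}"
            )
        df[col] = converted
    return df


def _validate_wells(df: pd.DataFrame, path: Path) -> None:
    for i, row in enumerate(df.itertuples()):
        line = i + 2
        if row.role not in ROLES:
            raise ParseError(f"{path}:{line}: unknown role {row.role!r}")
        if row.role in COMPOUND_ROLES and not row.compound_id:
            raise ParseError(
                f"{path}:{line}: role {row.role} requires a compound_id"
            )
        if not np.isnan(row.raw_absorbance) and row.raw_absorbance < 0:
            raise ParseError(f"{path}:{line}: negative raw_absorbance")
        if row.embryos_alive > row.embryos_in:
            raise ParseError(
                f"{path}:{line}: embryos_alive exceeds embryos_in"
            )
    dupes = df.duplicated(subset=["plate_id", "well"])
    if dupes.any():
        r = df[dupes].iloc[0]
        raise ParseError(
            f"{path}: duplicate well {r['well']} on plate {r['plate_id']}"
        )


def sort_wells(df: pd.DataFrame) -> pd.DataFrame:
    """Stable ordering independent of input row order: by plate, then well."""
    if df.empty:
        return df.reset_index(drop=True)
    key = df["well"].map(_well_sort_key)
    out = df.assign(_row=key.map(lambda k: k[0]), _col=key.map(lambda k: k[1]))
    out = out.sort_values(["plate_id", "_row", "_col"], kind="mergesort")
    return out.drop(columns=["_row", "_col"]).reset_index(drop=True)


def _format_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return ""
        if float(v).is_integer() and abs(v) < 1e15:
            return str(int(v))
        return format(float(v), ".6g")
    return str(v)


def write_table(df: pd.DataFrame, path: str | Path) -> int:
    """Write one table with deterministic formatting; return the row count."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [",".join(map(str, df.columns))]
    for row in df.itertuples(index=False):
        lines.append(",".join(_format_value(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return len(df)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict:
    """Write named tables as ``<name>.csv`` plus a manifest JSON.

    Returns the manifest: ``{"files": [{"name", "path", "rows"}, ...]}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"files": []}
    for name in sorted(tables):
        fname = f"{name}.csv"
        rows = write_table(tables[name], out_dir / fname)
        manifest["files"].append({"name": name, "path": fname, "rows": rows})
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
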