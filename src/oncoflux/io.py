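"""Table ingestion with schema validation.

CSV dialect: comma-separated, UTF-8, header row required, ``.`` decimal.
Cycle indices and mass shifts are 0-based throughout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .flux import FluxPlate, InjectionProtocol, NormalizationTable

__all__ = [
    "SchemaError",
    "IntegrityError",
    "read_table",
    "read_flux_plate",
    "read_od_table",
    "read_protocol",
    "SCHEMAS",
]


class SchemaError(ValueError):
    """A required column is missing or a cell fails to parse."""


class IntegrityError(ValueError):
    """Duplicate keys or inconsistent structure within a table."""


SCHEMAS: dict[str, dict] = {
    "flux_trace": {
        "columns": ["well_id", "group", "condition", "cycle_index", "time_min", "ocr", "ecar"],
        "numeric": ["cycle_index", "time_min", "ocr", "ecar"],
        "key": ["well_id", "cycle_index"],
    },
    "od": {
        "columns": ["well_id", "od595"],
        "numeric": ["od595"],
        "key": ["well_id"],
    },
    "intensities": {
        "columns": ["metabolite", "sample", "mass_shift", "intensity"],
        "numeric": ["mass_shift", "intensity"],
        "key": ["metabolite", "sample", "mass_shift"],
    },
    "proteome": {"columns": [], "numeric": [], "key": []},  # wide: validated separately
    "sample_sheet": {
        "columns": ["sample", "group"],
        "numeric": [],
        "key": ["sample"],
    },
    "growth": {
        "columns": ["well", "time", "confluence"],
        "numeric": ["time", "confluence"],
        "key": ["well", "time"],
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises :class:`SchemaError` for missing columns or non-numeric cells in
    numeric columns (with location), :class:`IntegrityError` for duplicate
    keys.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    df = pd.read_csv(path)

    if schema == "proteome":
        if df.shape[1] < 3:
            raise SchemaError(f"{path.name}: proteome table needs an id column plus >=2 samples")
        df = df.set_index(df.columns[0])
        bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            raise SchemaError(f"{path.name}: non-numeric abundance in sample column(s) {list(bad)}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise IntegrityError(f"{path.name}: duplicate protein accession {dup!r}")
        return df.astype(float)

    spec = SCHEMAS[schema]
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    for col in spec["numeric"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[coerced.isna() & df[col].notna()]
        if len(bad_rows):
            r = bad_rows[0]
            raise SchemaError(
                f"{path.name}: non-numeric value {df.loc[r, col]!r} in column "
                f"{col!r}, row {r + 2}"  # +2: header line and 1-based file rows
            )
        if coerced.isna().any():
            r = df.index[coerced.isna()][0]
            raise SchemaError(f"{path.name}: empty cell in column {col!r}, row {r + 2}")
        df[col] = coerced
    if spec["key"]:
        dup = df.duplicated(subset=spec["key"])
        if dup.any():
            key = tuple(df.loc[df.index[dup][0], spec["key"]])
            raise IntegrityError(f"{path.name}: duplicate key {key} on {spec['key']}")
    return df


def read_flux_plate(path: str | Path) -> FluxPlate:
    """Ingest a tidy flux-trace CSV into a validated plate object."""
    df = read_table(path, "flux_trace")
    cycle_idx = np.sort(df["cycle_index"].unique()).astype(int)
    if not np.array_equal(cycle_idx, np.arange(len(cycle_idx))):
        raise IntegrityError("cycle_index must be a contiguous 0-based grid")
    wide_ocr = df.pivot(index="well_id", columns="cycle_index", values="ocr")
    wide_ecar = df.pivot(index="well_id", columns="cycle_index", values="ecar")
    if wide_ocr.isna().any().any():
        well = wide_ocr.index[wide_ocr.isna().any(axis=1)][0]
        raise IntegrityError(f"well {well!r} is missing cycles")
    wells = (
        df[["well_id", "group", "condition"]]
        .drop_duplicates()
        .sort_values("well_id")
        .reset_index(drop=True)
    )
    if wells["well_id"].duplicated().any():
        w = wells.loc[wells["well_id"].duplicated(), "well_id"].iloc[0]
        raise IntegrityError(f"well {w!r} has conflicting group/condition labels")
    times = df.sort_values("cycle_index").groupby("cycle_index")["time_min"].first()
    order = wells["well_id"]
    return FluxPlate(
        wells=wells,
        cycles=times.to_numpy(),
        ocr=wide_ocr.loc[order].to_numpy(),
        ecar=wide_ecar.loc[order].to_numpy(),
        normalised=False,
    )


def read_od_table(path: str | Path) -> NormalizationTable:
    df = read_table(path, "od")
    return NormalizationTable(od595=dict(zip(df["well_id"], df["od595"])))


def read_protocol(path: str | Path) -> InjectionProtocol:
    """Read an injection protocol from YAML: list of {name, first_cycle_index}."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    events = tuple((e["name"], int(e["first_cycle_index"])) for e in raw["injections"])
    return InjectionProtocol(events=events)
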