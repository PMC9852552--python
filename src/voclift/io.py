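"""Shared table and parameter-file I/O with schema validation.

Inputs are CSV or TSV (delimiter auto-detected between comma and tab,
decimal point only); outputs are TSV with floats at 6 significant digits,
written atomically (temp file then rename) so interrupted runs never leave
truncated files.  Transport parameter files are YAML or JSON with an
optional ``units`` block; everything is converted on read to the package's
internal unit system (μM, μm, s).
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import AssayWell
from .emission import EmissionTimeSeries
from .transport import BoundaryConditions, CarrierParams

__all__ = [
    "SchemaError",
    "PLATE_SCHEMA", "SERIES_SCHEMA", "CUTICLE_SCHEMA", "COMPOUNDS_SCHEMA",
    "read_table", "write_table", "atomic_write_text",
    "load_transport_params", "plate_to_wells", "series_from_frame",
    "RunConfig",
]


class SchemaError(ValueError):
    """Raised when an input table does not match its expected schema."""


# column name -> required
PLATE_SCHEMA = {
    "ligand": False, "replicate": False, "ligand_concentration_uM": True,
    "f_mix_0": True, "f_tns_0": True, "f_mix_ligand": True,
    "f_tns_ligand": True, "f_mix_sol": True, "f_tns_sol": True,
}
SERIES_SCHEMA = {
    "sample_id": False, "genotype": False, "time_h": True,
    "emission_nmol_gFW_h": True, "pool_nmol_gFW": True,
}
CUTICLE_SCHEMA = {
    "sample_id": False, "compound": False, "hexane_pool": True,
    "total_pool": True, "wax_recovery": True,
}
COMPOUNDS_SCHEMA = {"name": False, "kd": True, "weight": True}

_NON_NUMERIC = {"ligand", "sample_id", "genotype", "compound", "name"}

_CONC_UM = {"M": 1e6, "mM": 1e3, "uM": 1.0, "µM": 1.0, "nM": 1e-3}
_LEN_UM = {"m": 1e6, "mm": 1e3, "um": 1.0, "µm": 1.0, "nm": 1e-3}
_DIFF_UM2_S = {"m2_per_s": 1e12, "cm2_per_s": 1e8, "um2_per_s": 1.0}


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_table(path: str | os.PathLike, schema: dict[str, bool],
               key_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV/TSV table and validate it against a column schema.

    Header matching is order-insensitive; required columns must be present
    and numeric columns fully parseable.  Errors name the offending row
    (1-based data row) and column.  ``key_columns`` present in the table
    must identify rows uniquely.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c, req in schema.items() if req and c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in df.columns:
        if col in schema and col not in _NON_NUMERIC:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise SchemaError(
                    f"{path.name}: non-numeric value in column {col!r}, "
                    f"row {int(bad[0]) + 1}")
            df[col] = coerced
    keys = [k for k in key_columns if k in df.columns]
    if keys:
        dup = df.duplicated(subset=keys)
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
            raise SchemaError(
                f"{path.name}: duplicate key {tuple(keys)} at row {row}")
    return df


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write text to ``path`` via a temp file + rename (atomic on POSIX)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a DataFrame as TSV, floats at 6 significant digits, atomically."""
    atomic_write_text(path, df.to_csv(sep="\t", index=False, float_format="%.6g"))


def load_transport_params(path: str | os.PathLike
                          ) -> tuple[CarrierParams, BoundaryConditions]:
    """Load a YAML/JSON transport parameter file.

    Expected keys: carrier_total_concentration, dissociation_constants
    (scalar or list of 1–2), free_diffusivity, complex_diffusivity,
    wall_thickness, s0, sL, and an optional ``units`` block with entries
    ``concentration`` (M/mM/uM/nM), ``length`` (m/mm/um/nm) and
    ``diffusivity`` (m2_per_s/cm2_per_s/um2_per_s).  Values are converted
    to μM / μm / μm²·s⁻¹.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"{path.name}: expected a mapping of parameters")
    units = data.get("units", {}) or {}
    cu = _CONC_UM[units.get("concentration", "uM")]
    lu = _LEN_UM[units.get("length", "um")]
    du = _DIFF_UM2_S[units.get("diffusivity", "um2_per_s")]
    try:
        kds = np.atleast_1d(np.asarray(data["dissociation_constants"], float)) * cu
        params = CarrierParams(
            carrier_total_concentration=float(data["carrier_total_concentration"]) * cu,
            dissociation_constants=tuple(kds),
            free_diffusivity=float(data["free_diffusivity"]) * du,
            complex_diffusivity=float(data["complex_diffusivity"]) * du,
            wall_thickness=float(data["wall_thickness"]) * lu,
        )
        bc = BoundaryConditions(s0=float(data["s0"]) * cu, sL=float(data["sL"]) * cu)
    except KeyError as exc:
        raise SchemaError(f"{path.name}: missing parameter {exc}") from exc
    return params, bc


def plate_to_wells(df: pd.DataFrame) -> list[AssayWell]:
    """Convert validated plate rows to :class:`AssayWell` records."""
    wells = []
    for _, row in df.iterrows():
        wells.append(AssayWell(
            ligand_concentration=float(row["ligand_concentration_uM"]),
            f_mix_0=float(row["f_mix_0"]), f_tns_0=float(row["f_tns_0"]),
            f_mix_ligand=float(row["f_mix_ligand"]),
            f_tns_ligand=float(row["f_tns_ligand"]),
            f_mix_sol=float(row["f_mix_sol"]), f_tns_sol=float(row["f_tns_sol"]),
            replicate_id=int(row["replicate"]) if "replicate" in row else 0,
        ))
    return wells


def series_from_frame(df: pd.DataFrame) -> list[EmissionTimeSeries]:
    """Group validated series rows into per-sample time series."""
    out = []
    if "sample_id" not in df.columns:
        df = df.assign(sample_id="sample")
    if "genotype" not in df.columns:
        df = df.assign(genotype="NA")
    for (sid, gt), grp in df.groupby(["sample_id", "genotype"], sort=False):
        grp = grp.sort_values("time_h")
        out.append(EmissionTimeSeries(
            sample_id=str(sid), genotype=str(gt),
            times=grp["time_h"].to_numpy(float),
            emission_rate=grp["emission_nmol_gFW_h"].to_numpy(float),
            internal_pool=grp["pool_nmol_gFW"].to_numpy(float)))
    return out


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level run options shared by CLI commands."""

    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
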