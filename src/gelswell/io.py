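"""Table and config I/O with unit conversion and validation.

CSV dialect: comma-separated, UTF-8, dot decimal, mandatory header row.
Laboratory-friendly units in files (kPa, mM, mm, s) are converted to SI
on read and back on write.  Each registered schema lists required and
optional columns; validation reports offending rows by file line number
(header = line 1).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .elasticity import ModulusSeries, StressStrainRecord
from .kinetics import SwellingCurve
from .thermo import IonicBath, IonSpecies

__all__ = [
    "SCHEMAS",
    "TableFormatError",
    "read_table",
    "write_table",
    "load_config",
    "load_compression",
    "load_modulus_series",
    "load_osmotic",
    "load_kinetics",
    "load_bath",
    "load_chi_table",
    "file_sha256",
    "round_sig",
    "json_dump",
]

KPA = 1e3  # kPa -> Pa
MM_CONC = 1.0  # mM -> mol/m^3 (numerically identical)
MM_LEN = 1e-3  # mm -> m


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    optional: tuple[str, ...] = ()
    #: SI conversion factor per column; absent = dimensionless/string
    scale: Mapping[str, float] = None
    #: columns allowed to hold non-numeric values
    text_columns: tuple[str, ...] = ()


SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in [
        TableSchema(
            "compression",
            required=("lam", "sigma_kPa"),
            optional=("sample_id",),
            scale={"sigma_kPa": KPA},
            text_columns=("sample_id",),
        ),
        TableSchema(
            "osmotic",
            required=("phi",),
            optional=("pi_tot_kPa", "pi_mix_kPa", "G_kPa"),
            scale={"pi_tot_kPa": KPA, "pi_mix_kPa": KPA, "G_kPa": KPA},
        ),
        TableSchema(
            "modulus_series",
            required=("phi", "G_kPa"),
            optional=("bath",),
            scale={"G_kPa": KPA},
            text_columns=("bath",),
        ),
        TableSchema(
            "kinetics",
            required=("bead_id", "t_s", "d_mm"),
            scale={"d_mm": MM_LEN},
            text_columns=("bead_id",),
        ),
        TableSchema(
            "bead_meta",
            required=("bead_id", "a_mm"),
            optional=("bath", "d0_mm", "d_inf_mm"),
            scale={"a_mm": MM_LEN, "d0_mm": MM_LEN, "d_inf_mm": MM_LEN},
            text_columns=("bead_id", "bath"),
        ),
        TableSchema(
            "bath",
            required=("species", "valence", "conc_mM"),
            scale={"conc_mM": MM_CONC},
            text_columns=("species",),
        ),
        TableSchema(
            "chi_table",
            required=("c_salt_mM", "chi0", "chi1"),
            scale={"c_salt_mM": MM_CONC},
        ),
        TableSchema(
            "transition",
            required=("c_salt_mM", "phi"),
            scale={"c_salt_mM": MM_CONC},
        ),
        TableSchema(
            "trajectory",
            required=("t_s", "d_mm", "front_r_mm", "total_Ca_nmol"),
            scale={"d_mm": MM_LEN, "front_r_mm": MM_LEN, "total_Ca_nmol": 1e-9},
        ),
        TableSchema(
            "master",
            required=("bead_id", "t_reduced", "d_reduced"),
            text_columns=("bead_id",),
        ),
    ]
}


class TableFormatError(ValueError):
    """Structured parse/validation failure for a tabular input."""


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a registered schema; convert to SI.

    Returns a DataFrame whose unit-suffixed columns are renamed to their
    SI base name (``sigma_kPa`` -> ``sigma`` in Pa, ``d_mm`` -> ``d`` in m,
    ``conc_mM`` -> ``conc`` in mol/m^3, ``t_s`` -> ``t``).
    """
    if schema_name not in SCHEMAS:
        raise TableFormatError(
            f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}"
        )
    schema = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"{path}: file not found")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {missing} for schema "
            f"{schema_name!r} (found {list(df.columns)})"
        )
    errors = []
    out = {}
    for col in df.columns:
        if col in schema.text_columns:
            out[col] = df[col].astype(str)
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].str.strip() != "")
        for i in np.nonzero(bad.to_numpy())[0]:
            errors.append(
                f"line {i + 2}: column {col!r} has non-numeric value "
                f"{df[col].iloc[i]!r}"
            )
        scale = (schema.scale or {}).get(col, 1.0)
        out[_si_name(col)] = vals.to_numpy(dtype=float) * scale
    if errors:
        raise TableFormatError(f"{path}: " + "; ".join(errors))
    return pd.DataFrame(out)


def _si_name(col: str) -> str:
    for suffix in ("_kPa", "_mM", "_mm", "_s", "_nmol"):
        if col.endswith(suffix):
            return col[: -len(suffix)]
    return col


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as the canonical CSV dialect."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# typed loaders


def load_compression(path: str | Path) -> list[StressStrainRecord]:
    """compression.csv -> one StressStrainRecord per sample_id."""
    df = read_table(path, "compression")
    if "sample_id" in df.columns:
        groups = df.groupby("sample_id", sort=True)
        return [
            StressStrainRecord(
                lam=g["lam"].to_numpy(), sigma=g["sigma"].to_numpy(), sample_id=str(k)
            )
            for k, g in groups
        ]
    return [StressStrainRecord(lam=df["lam"].to_numpy(), sigma=df["sigma"].to_numpy())]


def load_modulus_series(path: str | Path) -> ModulusSeries:
    df = read_table(path, "modulus_series")
    labels = df["bath"].tolist() if "bath" in df.columns else None
    return ModulusSeries(phi=df["phi"].to_numpy(), g=df["G"].to_numpy(), labels=labels)


def load_osmotic(path: str | Path) -> pd.DataFrame:
    """osmotic.csv in SI: columns phi and pi_tot/pi_mix/G as available."""
    return read_table(path, "osmotic")


def load_kinetics(
    path: str | Path, meta_path: str | Path | None = None
) -> list[SwellingCurve]:
    """kinetics.csv (+ optional per-bead metadata) -> SwellingCurve per bead."""
    df = read_table(path, "kinetics")
    radii, d0s, d_infs = {}, {}, {}
    if meta_path is not None:
        meta = read_table(meta_path, "bead_meta")
        radii = dict(zip(meta["bead_id"], meta["a"]))
        if "d0" in meta.columns:
            d0s = dict(zip(meta["bead_id"], meta["d0"]))
        if "d_inf" in meta.columns:
            d_infs = dict(zip(meta["bead_id"], meta["d_inf"]))
    curves = []
    for bead, g in df.groupby("bead_id", sort=True):
        g = g.sort_values("t")
        curves.append(
            SwellingCurve(
                t=g["t"].to_numpy(),
                d=g["d"].to_numpy(),
                # the pre-immersion diameter, if measured, beats the first
                # frame (fast modes have already relaxed by the first frame)
                d0=float(d0s.get(bead, g["d"].iloc[0])),
                d_inf=float(d_infs[bead]) if bead in d_infs else None,
                bead_id=str(bead),
                radius=float(radii[bead]) if bead in radii else None,
            )
        )
    return curves


def load_bath(path: str | Path) -> IonicBath:
    df = read_table(path, "bath")
    species = [
        IonSpecies(label=str(r.species), valence=int(r.valence), bath_concentration=float(r.conc))
        for r in df.itertuples()
    ]
    return IonicBath(species)


def load_chi_table(path: str | Path):
    """chi_vs_salt.csv -> (salt grid mol/m^3, chi_of_salt interpolator)."""
    from .thermo import FloryHugginsParams

    df = read_table(path, "chi_table").sort_values("c_salt")
    c = df["c_salt"].to_numpy()
    chi0 = df["chi0"].to_numpy()
    chi1 = df["chi1"].to_numpy()

    def chi_of_salt(cs: float) -> FloryHugginsParams:
        return FloryHugginsParams(
            chi0=float(np.interp(cs, c, chi0)), chi1=float(np.interp(cs, c, chi1))
        )

    return c, chi_of_salt


# --------------------------------------------------------------------------
# config and JSON output


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def round_sig(x, digits: int = 12):
    """Round floats (recursively through dict/list) to significant digits."""
    if isinstance(x, dict):
        return {k: round_sig(v, digits) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [round_sig(v, digits) for v in x]
    if isinstance(x, np.ndarray):
        return [round_sig(float(v), digits) for v in x.tolist()]
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (float, np.floating)):
        x = float(x)
        if x == 0 or not math.isfinite(x):
            return x
        return float(f"{x:.{digits}g}")
    return x


def json_dump(obj: dict, path: str | Path, digits: int = 12) -> None:
    """Serialize numeric output JSON with fixed significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(round_sig(obj, digits), indent=2) + "\n")
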