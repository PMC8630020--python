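"""Reading and writing the package's tabular and JSON formats.

Profile tables are plain CSV (comma, UTF-8) with the columns
``site, depth_m, species, value, unit, sd``; concentrations are converted
to mol m-3 on read (TOC stays in percent dry weight).  Values written as
``"<x"`` are below-detection records and are kept as left-censored rows.
Result bundles are JSON documents of plain lists and scalars.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .diagnostics import MEASURABLE
from .units import concentration_to_si

_SPECIES_ALIASES = {
    "O2": "O2",
    "NO3": "NO3",
    "NO3-": "NO3",
    "NH4": "NH4",
    "NH4+": "NH4",
    "MN": "Mn",
    "MN2+": "Mn",
    "MN(II)": "Mn",
    "DIC": "DIC",
    "TOC": "TOC",
}


def load_site_metadata() -> pd.DataFrame:
    """The packaged table of published core properties."""
    ref = resources.files("sedpower").joinpath("data/site_metadata.csv")
    with resources.as_file(ref) as fp:
        return pd.read_csv(fp, comment="#")


def read_profile_table(path) -> pd.DataFrame:
    """Read a measured-profile CSV into the internal representation.

    Returns a frame with ``site, depth_m, species, value, sd, censored``;
    values in mol m-3 except TOC (percent dry weight).  Unknown species
    or units raise with the offending row number.
    """
    raw = pd.read_csv(path, comment="#", dtype={"value": str}, float_precision="round_trip")
    required = {"site", "depth_m", "species", "value", "unit"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"profile table missing columns {sorted(missing)}")
    records = []
    for i, row in raw.iterrows():
        sp_key = str(row["species"]).strip().upper()
        species = _SPECIES_ALIASES.get(sp_key)
        if species is None or species not in MEASURABLE:
            raise ValueError(f"row {i}: unknown species {row['species']!r}")
        text = str(row["value"]).strip()
        censored = text.startswith("<")
        number = float(text[1:]) if censored else float(text)
        unit = str(row["unit"]).strip()
        if species == "TOC":
            if unit != "percent_dw":
                raise ValueError(f"row {i}: TOC must be in percent_dw, got {unit!r}")
            value = number
        else:
            try:
                value = float(concentration_to_si(number, unit))
            except ValueError as exc:
                raise ValueError(f"row {i}: {exc}") from None
        sd = row.get("sd", np.nan)
        records.append(
            {
                "site": row["site"],
                "depth_m": float(row["depth_m"]),
                "species": species,
                "value": value,
                "sd": float(sd) if pd.notna(sd) else np.nan,
                "censored": censored,
            }
        )
    return pd.DataFrame.from_records(records)


def write_profile_table(measured: pd.DataFrame, path) -> None:
    """Write the internal representation back to the CSV dialect.

    Solutes are written in mol/m3 so a read round-trips exactly.
    """
    out = []
    for _, row in measured.iterrows():
        unit = "percent_dw" if row["species"] == "TOC" else "mol/m3"
        value = repr(float(row["value"]))
        if row.get("censored", False):
            value = f"<{value}"
        out.append(
            {
                "site": row.get("site", ""),
                "depth_m": repr(float(row["depth_m"])),
                "species": row["species"],
                "value": value,
                "unit": unit,
                "sd": "" if pd.isna(row.get("sd", np.nan)) else repr(float(row["sd"])),
            }
        )
    pd.DataFrame(out).to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v  # JSON has no NaN
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_bundle(bundle: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonify(bundle), fh, indent=1)


def read_bundle(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
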