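"""Tabular I/O: species trait tables, FA composition tables, run manifests.

All tables are plain CSV.  The species table has one row per species with
columns ``species``, ``environment`` (terrestrial / semi_aquatic /
fully_aquatic), ``latitude`` (degrees, signed as sourced), and optionally
``hair_density`` (+ ``hair_density_secondary``, hairs/mm²),
``blubber_section``, ``pinniped``, ``delta9_di`` and ``dbi``.  The FA table
has one row per species and one column per FA label, values in wt%.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .fa import FAProfile, Section
from .models import ENV_LEVELS

__all__ = [
    "SpeciesTableError",
    "load_species_table",
    "load_fa_table",
    "write_table",
    "run_manifest",
]

_FLOAT_FMT = "%.6g"


class SpeciesTableError(ValueError):
    """A species trait table failed validation; message names the row."""


def load_species_table(
    path: str | Path, latitude_mode: str = "absolute"
) -> pd.DataFrame:
    """Load and validate a species trait table.

    ``latitude_mode``: "absolute" (default; latitude is a thermal proxy, so
    hemispheres fold together) or "signed".  Primary and secondary hair
    densities are summed when both are present; the log-transform used by the
    models is added as ``log_hair_density``.  Validation failures name the
    offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    required = {"species", "environment", "latitude"}
    missing = required - set(df.columns)
    if missing:
        raise SpeciesTableError(f"missing required columns: {', '.join(sorted(missing))}")
    if latitude_mode not in ("absolute", "signed"):
        raise SpeciesTableError(f"unknown latitude_mode {latitude_mode!r}")
    for i, row in df.iterrows():
        rownum = i + 1
        if pd.isna(row["species"]) or not str(row["species"]).strip():
            raise SpeciesTableError(f"row {rownum}: missing species name")
        if row["environment"] not in ENV_LEVELS:
            raise SpeciesTableError(
                f"row {rownum}: unknown environment {row['environment']!r}; "
                f"expected one of {', '.join(ENV_LEVELS)}"
            )
        if not np.isfinite(row["latitude"]) or abs(row["latitude"]) > 90:
            raise SpeciesTableError(
                f"row {rownum}: latitude {row['latitude']!r} outside [-90, 90]"
            )
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise SpeciesTableError(f"duplicate species: {', '.join(map(str, dupes))}")
    out = df.copy()
    if latitude_mode == "absolute":
        out["latitude"] = out["latitude"].abs()
    if "hair_density" in out.columns:
        hd = out["hair_density"].astype(float)
        if "hair_density_secondary" in out.columns:
            hd = hd.add(out["hair_density_secondary"].astype(float), fill_value=0.0)
        if (hd.dropna() <= 0).any():
            bad = out.loc[hd <= 0].index[0] + 1
            raise SpeciesTableError(f"row {bad}: hair density must be > 0")
        out["hair_density"] = hd
        out["log_hair_density"] = np.log(hd)
    else:
        out["hair_density"] = np.nan
        out["log_hair_density"] = np.nan
    if "blubber_section" not in out.columns:
        out["blubber_section"] = "unknown"
    out["blubber_section"] = out["blubber_section"].fillna("unknown")
    bad_sections = set(out["blubber_section"]) - {s.value for s in Section}
    if bad_sections:
        raise SpeciesTableError(f"unknown blubber_section values: {sorted(bad_sections)}")
    if "pinniped" not in out.columns:
        out["pinniped"] = False
    out["pinniped"] = out["pinniped"].astype(bool)
    return out


def load_fa_table(path: str | Path) -> list[FAProfile]:
    """Read a wide FA composition table into per-species profiles.

    First column (or a ``species`` column) names the species; an optional
    ``section`` column tags the tissue; every other column is an FA label
    with wt% values.  Blank cells count as absent (zero wt%).
    """
    df = pd.read_csv(path)
    species_col = "species" if "species" in df.columns else df.columns[0]
    fa_cols = [c for c in df.columns if c not in (species_col, "section")]
    profiles = []
    for _, row in df.iterrows():
        weights = {
            c: float(row[c]) for c in fa_cols if pd.notna(row[c])
        }
        profiles.append(
            FAProfile(
                species=str(row[species_col]),
                weights=weights,
                section=row.get("section", "unknown") if pd.notna(row.get("section", np.nan)) else "unknown",
            )
        )
    return profiles


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV writer with fixed float formatting for byte-stable output."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_manifest(
    inputs: dict[str, str | Path], config: dict, out_path: str | Path
) -> dict:
    """Write a machine-readable manifest of a run: config, seeds, checksums."""
    manifest = {
        "python": platform.python_version(),
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
            if Path(p).exists()
        },
    }
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
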