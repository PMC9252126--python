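"""Strict readers and writers for pipeline tables.

CSV dialect is fixed: comma delimiter, '.' decimal, UTF-8, mandatory header
row. Floats are written with repr-roundtrip precision so a write-then-read
cycle reproduces values exactly. Every write_outputs call drops a
``run_metadata.json`` sidecar carrying the config hash, seed and package
version (no timestamp, so identical runs are byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "read_table",
    "read_reach_table",
    "write_table",
    "write_outputs",
    "reach_geojson",
]

log = logging.getLogger(__name__)

_REQUIRED_REACH_COLS = ("reach_id", "lat", "lon")
_CSV_FLOAT_FORMAT = "%.17g"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV with exact float round-trip parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def read_reach_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a reach table CSV.

    Requires reach_id/lat/lon plus at least one complete
    ``<key>_month_1..12`` climatology block; reach_id must be unique and
    all monthly cells numeric (offending row/column named on failure).
    """
    df = read_table(path)
    missing = [c for c in _REQUIRED_REACH_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"reach table missing required columns: {missing}")
    dupes = df.loc[df["reach_id"].duplicated(), "reach_id"]
    if len(dupes):
        raise ValueError(f"duplicate reach_id: {sorted(set(dupes.astype(str)))}")

    month_cols = [c for c in df.columns if "_month_" in c]
    keys = sorted({c.rsplit("_month_", 1)[0] for c in month_cols})
    if not keys:
        raise ValueError("reach table has no <key>_month_1..12 climatology columns")
    for key in keys:
        cols = [f"{key}_month_{m}" for m in range(1, 13)]
        absent = [c for c in cols if c not in df.columns]
        if absent:
            raise ValueError(f"climatology {key!r} incomplete: missing {absent}")
        for col in cols:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric temperature in column {col!r}, "
                    f"row(s) {list(bad[:5])}"
                )
            df[col] = vals.astype(float)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as RFC-4180 CSV with full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT,
              lineterminator="\n", encoding="utf-8")
    return path


def reach_geojson(
    reach_table: pd.DataFrame, results: pd.DataFrame
) -> dict:
    """GeoJSON FeatureCollection of reach points carrying projection values.

    Coordinates are (lon, lat) per the GeoJSON standard; one feature per
    (reach, scenario) row.
    """
    coords = reach_table.set_index("reach_id")[["lon", "lat"]]
    features = []
    for _, row in results.iterrows():
        rid = row["reach_id"]
        lon, lat = (float(coords.loc[rid, "lon"]), float(coords.loc[rid, "lat"]))
        props = {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in row.items()
        }
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [lon, lat]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_outputs(
    out_dir: str | Path,
    tables: dict[str, pd.DataFrame],
    seed: int,
    config_text: str = "",
    geojson: dict | None = None,
) -> dict[str, Path]:
    """Write named tables (plus optional GeoJSON) and a metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        written[name] = write_table(df, out_dir / f"{name}.csv")
    if geojson is not None:
        p = out_dir / "reaches.geojson"
        p.write_text(json.dumps(geojson, sort_keys=True), encoding="utf-8")
        written["reaches_geojson"] = p
    meta = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": int(seed),
        "streambem_version": __version__,
        "outputs": sorted(p.name for p in written.values()),
    }
    mp = out_dir / "run_metadata.json"
    mp.write_text(json.dumps(meta, indent=2, sort_keys=True), encoding="utf-8")
    written["metadata"] = mp
    log.info("wrote %d output file(s) to %s", len(written), out_dir)
    return written
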