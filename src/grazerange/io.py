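"""File formats: relocation CSVs, site GeoJSON, hunt dates, YAML config."""

from __future__ import annotations

import json
import logging

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

logger = logging.getLogger(__name__)

RELOCATION_COLUMNS = ("animal_id", "timestamp", "x", "y", "sex", "dop_ok")


def read_relocations(path) -> pd.DataFrame:
    """Read a relocation CSV into a clean, per-animal time-sorted table.

    Rows failing the fix-quality flag (``dop_ok``) are dropped (count
    logged); duplicate (animal, timestamp) pairs are an error.  Timestamps
    are parsed as UTC; a row that fails to parse is reported by index.
    """
    df = pd.read_csv(path)
    missing = [c for c in RELOCATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"relocation file missing column(s): {missing}")
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce",
                        format="ISO8601")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        raise ValueError(
            f"unparseable timestamp at row index {int(bad.idxmax())}")
    df["timestamp"] = ts
    ok = df["dop_ok"].astype(bool)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d fixes failing the quality flag", n_dropped)
    df = df.loc[ok].copy()
    dup = df.duplicated(subset=["animal_id", "timestamp"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate fix for animal {row['animal_id']!r} at {row['timestamp']}")
    df = df.sort_values(["animal_id", "timestamp"], kind="stable")
    df["quality_ok"] = True
    return df.drop(columns=["dop_ok"]).reset_index(drop=True)


def write_relocations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["dop_ok"] = out.pop("quality_ok") if "quality_ok" in out else True
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_hunt_dates(path) -> list:
    df = pd.read_csv(path)
    if "date" not in df.columns:
        raise ValueError("hunt-date file needs a 'date' column")
    return [d.date() for d in pd.to_datetime(df["date"])]


def write_sites_geojson(sites: dict, groups: dict, path) -> None:
    features = [
        {"type": "Feature",
         "properties": {"site_id": sid, "group": groups.get(sid)},
         "geometry": mapping(poly)}
        for sid, poly in sites.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_sites_geojson(path):
    """Returns (site polygons, site groups) keyed by site_id."""
    with open(path) as fh:
        gj = json.load(fh)
    sites, groups = {}, {}
    for feat in gj["features"]:
        sid = feat["properties"]["site_id"]
        sites[sid] = shape(feat["geometry"])
        groups[sid] = feat["properties"].get("group")
    return sites, groups


def write_geojson_geometry(geom, path, properties=None) -> None:
    feature = {"type": "Feature", "properties": properties or {},
               "geometry": mapping(geom)}
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    return cfg
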