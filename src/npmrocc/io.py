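"""Plain-text I/O for survey tables, landscape bundles and model configs.

Formats are deliberately text-based and tool-agnostic:

* survey tables — CSV with a header, missing values as empty fields;
* stream lines and observation points — GeoJSON;
* rasters — ESRI ASCII grid (``.asc``), with class labels for
  categorical rasters in a JSON sidecar;
* models and search controls — YAML.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from .landscape import GridConfig, Raster
from .npmr import NPMRModel
from .search import SearchControls

__all__ = [
    "read_survey", "write_survey",
    "read_lines_geojson", "write_lines_geojson",
    "read_points_geojson", "write_points_geojson",
    "read_ascii_grid", "write_ascii_grid",
    "read_model_yaml", "write_model_yaml",
    "read_controls_yaml", "write_controls_yaml",
]

_NODATA = -9999.0


def write_survey(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_survey(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "occupancy" not in table.columns:
        raise ValueError("survey CSV must have an 'occupancy' column")
    return table


def write_lines_geojson(lines, path) -> None:
    features = []
    for line in lines:
        coords = np.asarray(getattr(line, "coords", line), dtype=float)
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": coords.tolist()},
            "properties": {},
        })
    pathlib.Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_lines_geojson(path) -> list[np.ndarray]:
    data = json.loads(pathlib.Path(path).read_text())
    return [np.asarray(f["geometry"]["coordinates"], dtype=float)
            for f in data["features"]
            if f["geometry"]["type"] == "LineString"]


def write_points_geojson(points_by_species: dict, path) -> None:
    features = []
    for species, pts in points_by_species.items():
        for x, y in np.asarray(pts, dtype=float).reshape(-1, 2):
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"species": species},
            })
    pathlib.Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_points_geojson(path) -> dict[str, np.ndarray]:
    data = json.loads(pathlib.Path(path).read_text())
    by_species: dict[str, list] = {}
    for f in data["features"]:
        if f["geometry"]["type"] != "Point":
            continue
        sp = f.get("properties", {}).get("species", "")
        by_species.setdefault(sp, []).append(f["geometry"]["coordinates"])
    return {sp: np.asarray(pts, dtype=float) for sp, pts in by_species.items()}


def write_ascii_grid(raster: Raster, path, labels=None) -> None:
    """ESRI ASCII grid; ASCII rows run north→south, so the value array
    (row 0 = south) is flipped on write.  Optional categorical labels go
    to ``<path>.classes.json``."""
    grid = raster.grid
    nrows, ncols = grid.shape
    vals = np.where(np.isfinite(raster.values), raster.values, _NODATA)
    header = (f"ncols {ncols}\nnrows {nrows}\n"
              f"xllcorner {grid.origin[0]}\nyllcorner {grid.origin[1]}\n"
              f"cellsize {grid.cell_size}\nNODATA_value {_NODATA}\n")
    body = "\n".join(" ".join(repr(float(v)) for v in row)
                     for row in vals[::-1])
    pathlib.Path(path).write_text(header + body + "\n")
    if labels is not None:
        pathlib.Path(str(path) + ".classes.json").write_text(
            json.dumps(list(labels)))


def read_ascii_grid(path, window_radius: float = 5.0) -> Raster:
    text = pathlib.Path(path).read_text().splitlines()
    meta = {}
    i = 0
    while i < len(text) and text[i].split()[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value"):
        key, val = text[i].split()
        meta[key.lower()] = float(val)
        i += 1
    vals = np.array([[float(v) for v in row.split()] for row in text[i:] if row])
    vals[vals == meta.get("nodata_value", _NODATA)] = np.nan
    grid = GridConfig(origin=(meta["xllcorner"], meta["yllcorner"]),
                      shape=(int(meta["nrows"]), int(meta["ncols"])),
                      cell_size=meta["cellsize"], window_radius=window_radius)
    return Raster(grid, vals[::-1])


def write_model_yaml(model: NPMRModel, path) -> None:
    pathlib.Path(path).write_text(yaml.safe_dump({
        "predictors": list(model.predictors),
        "tolerances": {k: float(v) for k, v in model.tolerances.items()},
        "min_neighborhood": float(model.min_neighborhood),
    }, sort_keys=True))


def read_model_yaml(path) -> NPMRModel:
    data = yaml.safe_load(pathlib.Path(path).read_text())
    return NPMRModel(predictors=tuple(data["predictors"]),
                     tolerances=dict(data.get("tolerances", {})),
                     min_neighborhood=data.get("min_neighborhood", 1.0))


def write_controls_yaml(controls: SearchControls, path) -> None:
    data = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in controls.__dict__.items()}
    pathlib.Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_controls_yaml(path) -> SearchControls:
    data = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    if "tolerance_grid_levels" in data:
        data["tolerance_grid_levels"] = tuple(data["tolerance_grid_levels"])
    return SearchControls(**data)
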