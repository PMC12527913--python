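"""Plain-text round-tripping for contours, tables and configs.

All numeric columns carry units in their names (``*_um``, ``*_um_inv``,
``*_deg``).  Files are written atomically (tmp + rename) so partially
written artifacts never appear under the final name.
"""

from __future__ import annotations

import json
import os
import tempfile
from typing import Iterable, Union

import numpy as np
import pandas as pd
import yaml

from .geometry import Contour


def _atomic_write(path, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_contours_csv(path, contours: dict) -> None:
    """``contours``: mapping id -> Contour."""
    rows = []
    for cid, c in contours.items():
        for i, (x, y) in enumerate(c.vertices):
            rows.append((cid, i, repr(float(x)), repr(float(y)), int(c.closed),
                         repr(float(c.pixel_size))))
    lines = ["id,vertex_index,x_um,y_um,closed,pixel_size_um"]
    lines += [",".join(map(str, r)) for r in rows]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_contours_csv(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for cid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("vertex_index")
        out[cid] = Contour(vertices=grp[["x_um", "y_um"]].to_numpy(),
                           closed=bool(grp["closed"].iloc[0]),
                           pixel_size=float(grp["pixel_size_um"].iloc[0]))
    return out


def write_contours_json(path, contours: dict) -> None:
    """GeoJSON-like polygon/linestring dump."""
    feats = []
    for cid, c in contours.items():
        coords = [[float(x), float(y)] for x, y in c.vertices]
        feats.append({
            "type": "Feature",
            "id": str(cid),
            "geometry": {"type": "Polygon" if c.closed else "LineString",
                         "coordinates": [coords] if c.closed else coords},
            "properties": {"pixel_size_um": float(c.pixel_size)},
        })
    _atomic_write(path, json.dumps(
        {"type": "FeatureCollection", "features": feats}, indent=1) + "\n")


def read_contours_json(path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    out = {}
    for feat in data["features"]:
        geom = feat["geometry"]
        closed = geom["type"] == "Polygon"
        coords = geom["coordinates"][0] if closed else geom["coordinates"]
        out[feat["id"]] = Contour(vertices=np.asarray(coords, dtype=float),
                                  closed=closed,
                                  pixel_size=float(
                                      feat["properties"]["pixel_size_um"]))
    return out


def write_table(path, df: pd.DataFrame) -> None:
    _atomic_write(path, df.to_csv(index=False))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config(path, cfg: dict) -> None:
    _atomic_write(path, yaml.safe_dump(cfg, sort_keys=True))


def read_config(path) -> dict:
    with open(path) as fh:
        text = fh.read()
    try:
        return json.loads(text)   # JSON accepted as a YAML subset shortcut
    except json.JSONDecodeError:
        return yaml.safe_load(text)


def write_mesh_vtk(path, nodes: np.ndarray, elems: np.ndarray,
                   region: np.ndarray) -> None:
    """Legacy-VTK (ASCII) quad mesh export with region labels."""
    lines = ["# vtk DataFile Version 3.0", "cell front mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(nodes)} double"]
    lines += [f"{x} {y} 0.0" for x, y in nodes]
    lines.append(f"CELLS {len(elems)} {5 * len(elems)}")
    lines += ["4 " + " ".join(map(str, e)) for e in elems]
    lines.append(f"CELL_TYPES {len(elems)}")
    lines += ["9"] * len(elems)
    lines.append(f"CELL_DATA {len(elems)}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(r)) for r in region]
    _atomic_write(path, "\n".join(lines) + "\n")
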