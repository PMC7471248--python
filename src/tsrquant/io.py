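"""Reading and writing the pipeline's on-disk artifacts.

Conventions:

* RGB canvases and label masks are PNG (masks single-channel, values 0/1/2
  with a palette so they are viewable directly);
* ROI polygons are GeoJSON ``Polygon`` features whose coordinates are
  ``[col, row]`` pairs (GeoJSON x/y order; rows increase downward);
* patch grids are CSV with one window per row (``row0,col0,row1,col1``);
* cohorts and result tables are CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .tiling import PatchGrid, Window

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_roi_geojson",
    "read_roi_geojson",
    "write_grid_csv",
    "read_grid_csv",
]

# Palette for 3-class masks: black background, blue-ish epithelium, pink stroma.
_MASK_PALETTE = [0, 0, 0, 70, 60, 160, 230, 140, 180] + [0] * (256 * 3 - 9)


def write_image(path: str | Path, rgb: np.ndarray) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path)


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    img = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    img.putpalette(_MASK_PALETTE)
    img.save(path)


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint8)


def write_roi_geojson(path: str | Path, polygon: Sequence[tuple[float, float]]) -> None:
    """Write a (row, col) polygon as a GeoJSON Polygon feature."""
    verts = [[float(c), float(r)] for r, c in polygon]
    if verts[0] != verts[-1]:
        verts.append(verts[0])  # GeoJSON rings are closed
    feature = {
        "type": "Feature",
        "properties": {"coordinate_order": "[col, row]"},
        "geometry": {"type": "Polygon", "coordinates": [verts]},
    }
    Path(path).write_text(json.dumps(feature, indent=1))


def read_roi_geojson(path: str | Path) -> np.ndarray:
    """Read a GeoJSON Polygon back into (row, col) vertices."""
    obj = json.loads(Path(path).read_text())
    geom = obj["geometry"] if obj.get("type") == "Feature" else obj
    if geom.get("type") != "Polygon":
        raise ValueError(f"expected a GeoJSON Polygon, got {geom.get('type')!r}")
    ring = geom["coordinates"][0]
    if ring[0] == ring[-1]:
        ring = ring[:-1]
    return np.array([[r, c] for c, r in ring], dtype=float)


def write_grid_csv(path: str | Path, grid: PatchGrid) -> None:
    frame = pd.DataFrame(grid.windows, columns=["row0", "col0", "row1", "col1"])
    frame.to_csv(path, index=False)


def read_grid_csv(
    path: str | Path,
    canvas_shape: tuple[int, int],
    tile_size: int,
    edge_policy: str = "pad",
) -> PatchGrid:
    frame = pd.read_csv(path)
    windows: tuple[Window, ...] = tuple(
        (int(r.row0), int(r.col0), int(r.row1), int(r.col1)) for r in frame.itertuples()
    )
    return PatchGrid(
        canvas_shape=canvas_shape, tile_size=tile_size,
        windows=windows, edge_policy=edge_policy,  # type: ignore[arg-type]
    )
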