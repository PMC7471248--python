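"""ROI rasterization and the non-overlapping patch grid.

Whole-mount slide images are processed as non-overlapping 512x512 windows
laid over the bounding box of the pathologist-delineated region of interest
(ROI).  This module owns the coordinate conventions used everywhere else in
the package: 0-based, row-major, half-open ``[row0, row1) x [col0, col1)``
windows.  Extraction and stitching are exact inverses on ROI pixels, so no
tissue area is ever lost or double counted between the patch and canvas
representations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import shapely

__all__ = [
    "ROIMask",
    "PatchGrid",
    "Patch",
    "rasterize_roi",
    "build_patch_grid",
    "extract_patches",
    "stitch",
]

Window = tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
EdgePolicy = Literal["pad", "drop"]

DEFAULT_TILE_SIZE = 512


@dataclass(frozen=True)
class ROIMask:
    """Boolean per-pixel inclusion map for a delineated region of interest."""

    mask: np.ndarray
    polygon: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("ROI mask must be a 2-D boolean array")
        if not m.any():
            raise ValueError("ROI mask contains no included pixels")
        object.__setattr__(self, "mask", m)

    @property
    def canvas_shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area(self) -> int:
        """Number of included pixels."""
        return int(self.mask.sum())

    def bounding_box(self) -> Window:
        """Tight half-open bounding box of the included pixels."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


@dataclass(frozen=True)
class PatchGrid:
    """Deterministic set of non-overlapping tile windows covering an ROI.

    Windows are anchored at the top-left corner of the ROI bounding box and
    step by ``tile_size``.  Under the ``pad`` edge policy boundary windows
    are clipped to the canvas (patches are later padded back to full tile
    size); under ``drop`` only windows fully inside the bounding box are
    kept.  Windows that do not touch a single ROI pixel are omitted.
    """

    canvas_shape: tuple[int, int]
    tile_size: int
    windows: tuple[Window, ...]
    edge_policy: EdgePolicy = "pad"

    def __post_init__(self) -> None:
        for r0, c0, r1, c1 in self.windows:
            if not (0 <= r0 < r1 <= self.canvas_shape[0] and 0 <= c0 < c1 <= self.canvas_shape[1]):
                raise ValueError(f"window {(r0, c0, r1, c1)} escapes canvas {self.canvas_shape}")
            if r1 - r0 > self.tile_size or c1 - c0 > self.tile_size:
                raise ValueError(f"window {(r0, c0, r1, c1)} exceeds tile size {self.tile_size}")

    def __len__(self) -> int:
        return len(self.windows)

    def covered_mask(self) -> np.ndarray:
        """Boolean canvas map of pixels lying inside some window."""
        cov = np.zeros(self.canvas_shape, dtype=bool)
        for r0, c0, r1, c1 in self.windows:
            cov[r0:r1, c0:c1] = True
        return cov


@dataclass(frozen=True)
class Patch:
    """A single extracted tile: pixel data plus provenance.

    ``pixels`` always has spatial shape ``(tile_size, tile_size)``; for
    windows clipped at the canvas edge the out-of-window region is filled
    with ``pad_value`` and flagged False in ``valid``.
    """

    window: Window
    pixels: np.ndarray
    valid: np.ndarray = field(repr=False)

    @property
    def is_padded(self) -> bool:
        return not bool(self.valid.all())


def rasterize_roi(polygon: Sequence[tuple[float, float]], canvas_shape: tuple[int, int]) -> ROIMask:
    """Rasterize a simple polygon into a per-pixel inclusion mask.

    A pixel ``(r, c)`` is included iff its center ``(r + 0.5, c + 0.5)``
    lies strictly inside the polygon (even-odd rule).  Vertices are
    ``(row, col)`` pairs in canvas coordinates.

    Raises
    ------
    ValueError
        If the polygon is degenerate (zero area) or no pixel center falls
        inside it on the given canvas.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon must be a sequence of >= 3 (row, col) vertices")
    # shapely works in (x, y); map col -> x, row -> y.
    poly = shapely.Polygon(verts[:, ::-1])
    if not poly.is_valid or poly.area == 0:
        raise ValueError("polygon is degenerate or self-intersecting")

    nrows, ncols = canvas_shape
    r0 = max(int(np.floor(verts[:, 0].min())), 0)
    r1 = min(int(np.ceil(verts[:, 0].max())) + 1, nrows)
    c0 = max(int(np.floor(verts[:, 1].min())), 0)
    c1 = min(int(np.ceil(verts[:, 1].max())) + 1, ncols)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("polygon lies entirely outside the canvas")

    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    inside = shapely.contains_xy(poly, cc.ravel() + 0.5, rr.ravel() + 0.5)
    mask = np.zeros((nrows, ncols), dtype=bool)
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    if not mask.any():
        raise ValueError("polygon covers no pixel center on the canvas")
    return ROIMask(mask=mask, polygon=verts)


def build_patch_grid(
    roi: ROIMask,
    tile_size: int = DEFAULT_TILE_SIZE,
    edge_policy: EdgePolicy = "pad",
) -> PatchGrid:
    """Lay a non-overlapping tile grid over the ROI bounding box.

    The grid is anchored at the bounding-box top-left and steps by
    ``tile_size`` in both axes.  Windows intersecting no ROI pixel are
    dropped regardless of policy.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if edge_policy not in ("pad", "drop"):
        raise ValueError(f"unknown edge policy: {edge_policy!r}")

    br0, bc0, br1, bc1 = roi.bounding_box()
    nrows, ncols = roi.canvas_shape
    windows: list[Window] = []
    for r in range(br0, br1, tile_size):
        for c in range(bc0, bc1, tile_size):
            r_end, c_end = r + tile_size, c + tile_size
            if edge_policy == "drop" and (r_end > br1 or c_end > bc1):
                continue
            w: Window = (r, c, min(r_end, nrows), min(c_end, ncols))
            if roi.mask[w[0] : w[2], w[1] : w[3]].any():
                windows.append(w)
    return PatchGrid(
        canvas_shape=(nrows, ncols),
        tile_size=tile_size,
        windows=tuple(windows),
        edge_policy=edge_policy,
    )


def extract_patches(image: np.ndarray, grid: PatchGrid, pad_value: int = 0) -> list[Patch]:
    """Cut the image into the grid's windows, in window order.

    Clipped boundary windows (pad policy) are padded with ``pad_value`` up
    to the full tile size; the padded region is flagged in ``Patch.valid``
    and never re-enters the canvas on stitching.
    """
    image = np.asarray(image)
    if image.shape[:2] != grid.canvas_shape:
        raise ValueError(
            f"image canvas {image.shape[:2]} does not match grid canvas {grid.canvas_shape}"
        )
    t = grid.tile_size
    patches = []
    for window in grid.windows:
        r0, c0, r1, c1 = window
        h, w = r1 - r0, c1 - c0
        shape = (t, t) + image.shape[2:]
        pixels = np.full(shape, pad_value, dtype=image.dtype)
        pixels[:h, :w] = image[r0:r1, c0:c1]
        valid = np.zeros((t, t), dtype=bool)
        valid[:h, :w] = True
        patches.append(Patch(window=window, pixels=pixels, valid=valid))
    return patches


def stitch(
    per_patch_masks: Sequence[np.ndarray | Patch],
    grid: PatchGrid,
    roi: ROIMask | None = None,
) -> np.ndarray:
    """Reassemble per-patch label masks onto the canvas.

    Windows are disjoint, so placement needs no blending.  Padded pixels are
    cropped away; canvas pixels outside every window are 0; if ``roi`` is
    given, pixels outside the ROI are forced to 0 as well.
    """
    if len(per_patch_masks) != len(grid.windows):
        raise ValueError(
            f"got {len(per_patch_masks)} masks for {len(grid.windows)} windows"
        )
    canvas = np.zeros(grid.canvas_shape, dtype=np.uint8)
    for item, window in zip(per_patch_masks, grid.windows):
        mask = item.pixels if isinstance(item, Patch) else np.asarray(item)
        r0, c0, r1, c1 = window
        h, w = r1 - r0, c1 - c0
        if mask.shape[0] < h or mask.shape[1] < w:
            raise ValueError(f"mask shape {mask.shape} too small for window {window}")
        canvas[r0:r1, c0:c1] = mask[:h, :w]
    if roi is not None:
        if roi.canvas_shape != grid.canvas_shape:
            raise ValueError("ROI canvas does not match grid canvas")
        canvas[~roi.mask] = 0
    return canvas
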