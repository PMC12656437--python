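"""Tile extraction and prediction stitching.

The segmentation model consumes 20x16-pixel tiles.  Training tiles are cut
with 50% overlap (stride 10x8); inference defaults to disjoint tiles for
speed.  The right/bottom remainder is handled by shifting the final tile
origin so the last tile ends exactly at the image border -- no padding, full
coverage, no fabricated spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube_io import Hypercube
from .taxonomy import UNANNOTATED

TILE_H = 20
TILE_W = 16


@dataclass(frozen=True)
class TileGrid:
    """Tiling geometry.  50% overlap corresponds to stride (10, 8)."""

    tile_h: int = TILE_H
    tile_w: int = TILE_W
    stride_h: int = TILE_H
    stride_w: int = TILE_W

    def __post_init__(self) -> None:
        for stride, tile in ((self.stride_h, self.tile_h), (self.stride_w, self.tile_w)):
            if not 1 <= stride <= tile:
                raise ValueError(f"stride {stride} must lie in 1..tile size {tile}")

    @staticmethod
    def overlapping() -> "TileGrid":
        return TileGrid(stride_h=TILE_H // 2, stride_w=TILE_W // 2)


@dataclass
class Tile:
    """One tile: (tile_h, tile_w, bands) data, optional label mask, and the
    (row, col) of its top-left corner in the parent cube."""

    data: np.ndarray
    origin: tuple[int, int]
    mask: np.ndarray | None = None


def _origins(extent: int, tile: int, stride: int) -> list[int]:
    """Start offsets along one axis; the final origin is clamped to the border."""
    if extent < tile:
        raise ValueError(f"image extent {extent} smaller than tile size {tile}")
    starts = list(range(0, extent - tile + 1, stride))
    if starts[-1] != extent - tile:
        starts.append(extent - tile)
    return starts


def tile_origins(shape: tuple[int, int], grid: TileGrid) -> list[tuple[int, int]]:
    rows = _origins(shape[0], grid.tile_h, grid.stride_h)
    cols = _origins(shape[1], grid.tile_w, grid.stride_w)
    return [(r, c) for r in rows for c in cols]


def extract_tiles(
    cube: Hypercube,
    mask: np.ndarray | None = None,
    grid: TileGrid | None = None,
    drop_unannotated: bool = False,
) -> list[Tile]:
    """Cut a normalized cube (and optional label mask) into tiles.

    ``drop_unannotated`` discards tiles whose mask is entirely 255, the
    typical choice when building a training set.
    """
    if cube.state != "normalized184":
        raise ValueError(f"tiling expects a normalized184 cube, got state {cube.state!r}")
    grid = grid or TileGrid()
    h, w, _ = cube.shape
    if mask is not None and mask.shape != (h, w):
        raise ValueError(f"mask shape {mask.shape} does not match cube spatial shape {(h, w)}")
    tiles = []
    for r, c in tile_origins((h, w), grid):
        sub_mask = None
        if mask is not None:
            sub_mask = mask[r : r + grid.tile_h, c : c + grid.tile_w]
            if drop_unannotated and np.all(sub_mask == UNANNOTATED):
                continue
        tiles.append(Tile(data=cube.data[r : r + grid.tile_h, c : c + grid.tile_w, :], origin=(r, c), mask=sub_mask))
    return tiles


def stitch_predictions(
    tiles: list[tuple[tuple[int, int], np.ndarray]],
    shape: tuple[int, int],
    combine: str = "mean_logits",
) -> np.ndarray:
    """Merge per-tile logits into a full-image class map.

    ``tiles`` is a list of ``(origin, logits)`` with logits of shape
    (tile_h, tile_w, n_classes).  Overlapping pixels are combined either by
    averaging logits before the argmax (default) or by majority vote over
    per-tile argmaxes.  Every pixel must be covered at least once.  Argmax
    ties resolve to the lowest class index.
    """
    if combine not in ("mean_logits", "majority_vote"):
        raise ValueError(f"unknown combine mode {combine!r}")
    if not tiles:
        raise ValueError("no tiles to stitch")
    n_classes = tiles[0][1].shape[2]
    acc = np.zeros(shape + (n_classes,), dtype=np.float64)
    cover = np.zeros(shape, dtype=np.int64)
    for (r, c), logits in tiles:
        th, tw, _ = logits.shape
        if r < 0 or c < 0 or r + th > shape[0] or c + tw > shape[1]:
            raise ValueError(f"tile at origin {(r, c)} exceeds image shape {shape}")
        if combine == "mean_logits":
            acc[r : r + th, c : c + tw] += logits
        else:
            votes = np.argmax(logits, axis=2)
            idx = np.indices((th, tw))
            acc[r + idx[0], c + idx[1], votes] += 1.0
        cover[r : r + th, c : c + tw] += 1
    if np.any(cover == 0):
        holes = np.argwhere(cover == 0)
        preview = ", ".join(map(str, map(tuple, holes[:5])))
        raise ValueError(f"{len(holes)} uncovered pixel(s), e.g. {preview}")
    return np.argmax(acc, axis=2).astype(np.uint8)
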