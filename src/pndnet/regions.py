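"""Region pooling and spatial pyramid pooling over backbone feature maps.

The backbone's final h x w x C activation map is bilinearly upsampled to
H x W, partitioned into a fixed grid of g x g non-overlapping tiles (each
averaged into one C-vector), and the g x g grid of region descriptors is
then adaptively pooled at two pyramid resolutions i x i and j x j. The
P = i^2 + j^2 pooled vectors, concatenated level i first in row-major bin
order, are the graph node features F_SPP (a P x C matrix).

Pooling the grid of region descriptors (rather than pooling inside each
region separately) is what lets the pyramid summarize inter-region
context at several scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import adaptive_bins, bilinear_matrix

__all__ = ["RegionConfig", "upsample_map", "partition_regions", "pyramid_pool",
           "node_features"]


@dataclass(frozen=True)
class RegionConfig:
    """Geometry of the region/pyramid stage.

    ``upsample_size`` H (= W) must be divisible by ``grid`` g; the pyramid
    levels (i, j) must not exceed g. Node count P = i^2 + j^2 (13 for the
    default (2, 3) pyramid).
    """

    upsample_size: int = 16
    grid: int = 4
    pyramid_levels: tuple[int, int] = (2, 3)
    pool_mode: str = "average"
    use_spp: bool = True         # False => nodes are the raw region descriptors

    def __post_init__(self):
        if self.upsample_size % self.grid:
            raise ValueError(
                f"upsample_size {self.upsample_size} not divisible by grid {self.grid}")
        i, j = self.pyramid_levels
        if i < 1 or j < 1:
            raise ValueError("pyramid levels must be >= 1")
        if max(i, j) > self.grid:
            raise ValueError(f"pyramid level {max(i, j)} exceeds region grid {self.grid}")
        if self.pool_mode not in ("average", "max"):
            raise ValueError(f"pool_mode must be 'average' or 'max', got {self.pool_mode!r}")

    @property
    def n_regions(self) -> int:
        return self.grid ** 2

    @property
    def n_nodes(self) -> int:
        if not self.use_spp:
            return self.n_regions
        i, j = self.pyramid_levels
        return i * i + j * j


def upsample_map(fm: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling of an h x w x C map to H x W x C (H >= h, W >= w)."""
    fm = np.asarray(fm, dtype=float)
    if fm.ndim != 3:
        raise ValueError(f"expected h x w x C map, got shape {fm.shape}")
    h, w, _ = fm.shape
    H, W = target
    if H < h or W < w:
        raise ValueError(f"target {target} smaller than source {(h, w)}")
    Rh, Rw = bilinear_matrix(H, h), bilinear_matrix(W, w)
    return np.einsum("th,hwc,uw->tuc", Rh, fm, Rw, optimize=True)


def partition_regions(fm: np.ndarray, g: int) -> np.ndarray:
    """Average each of the g x g non-overlapping tiles of an H x W x C map
    into a C-vector; returns the g x g x C region-descriptor grid
    (row-major tile order when flattened)."""
    fm = np.asarray(fm, dtype=float)
    H, W, C = fm.shape
    if H % g or W % g:
        raise ValueError(f"map size {(H, W)} not divisible by grid {g}")
    th, tw = H // g, W // g
    return fm.reshape(g, th, g, tw, C).mean(axis=(1, 3))


def pyramid_pool(grid: np.ndarray, levels: tuple[int, int] = (2, 3),
                 mode: str = "average") -> np.ndarray:
    """Adaptive two-level pyramid pooling of a g x g x C region grid.

    Bin b of n over size S spans [floor(b*S/n), ceil((b+1)*S/n)). Output is
    the (i^2 + j^2) x C node-feature matrix, level i first, bins row-major.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 3 or grid.shape[0] != grid.shape[1]:
        raise ValueError(f"expected g x g x C region grid, got shape {grid.shape}")
    g = grid.shape[0]
    if mode not in ("average", "max"):
        raise ValueError(f"mode must be 'average' or 'max', got {mode!r}")
    rows = []
    for n in levels:
        if n < 1 or n > g:
            raise ValueError(f"pyramid level {n} invalid for grid {g}")
        spans = adaptive_bins(n, g)
        for r0, r1 in spans:
            for c0, c1 in spans:
                tile = grid[r0:r1, c0:c1, :]
                rows.append(tile.mean(axis=(0, 1)) if mode == "average"
                            else tile.max(axis=(0, 1)))
    return np.stack(rows)


def node_features(fm: np.ndarray, cfg: RegionConfig) -> np.ndarray:
    """Full region stage on a single backbone map: upsample -> partition ->
    (optionally) pyramid pool. Returns the P x C node matrix."""
    up = upsample_map(fm, (cfg.upsample_size, cfg.upsample_size))
    grid = partition_regions(up, cfg.grid)
    if not cfg.use_spp:
        return grid.reshape(cfg.n_regions, -1)
    return pyramid_pool(grid, cfg.pyramid_levels, cfg.pool_mode)
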