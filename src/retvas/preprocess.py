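"""Fundus image container and pre-processing.

Vessels have their strongest contrast against the retinal background in the
green plane of an RGB fundus photograph, so the processing chain works on the
green channel, contrast-enhanced by contrast-limited adaptive histogram
equalization (CLAHE).  The field of view (FOV) — the illuminated circular
retinal area inside the rectangular frame — is detected by thresholding and
kept as a mask alongside the image.

Coordinate convention throughout the package: (row, col), 0-based, origin at
the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "FundusImage",
    "load_image",
    "save_image",
    "extract_green",
    "detect_fov",
    "adaptive_hist_eq",
    "FovNotFoundError",
]

#: Grey-level above which a pixel can belong to the illuminated field of view.
DEFAULT_FOV_THRESHOLD = 10

#: Default CLAHE tiling and clip limit (fraction of a tile's pixel count).
DEFAULT_TILE_GRID = (8, 8)
DEFAULT_CLIP_LIMIT = 0.01


class FovNotFoundError(ValueError):
    """No pixel in the frame exceeds the FOV threshold."""


@dataclass
class FundusImage:
    """An 8-bit RGB fundus photograph with its device label and FOV mask."""

    pixels: np.ndarray  # (H, W, 3) uint8
    device_label: str = ""
    fov_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def load_image(path, device_label: str = "") -> FundusImage:
    """Read an 8-bit RGB PNG/TIFF into a :class:`FundusImage`."""
    px = iio.imread(path)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[..., :3]
    return FundusImage(pixels=np.asarray(px, dtype=np.uint8), device_label=device_label)


def save_image(image: FundusImage, path) -> None:
    iio.imwrite(path, image.pixels)


def extract_green(image: FundusImage) -> np.ndarray:
    """Return the green plane of the photograph, unchanged.

    The green channel carries the best vessel/background contrast in colour
    fundus photography and is the working image for segmentation.
    """
    return image.pixels[..., 1].copy()


def detect_fov(image: FundusImage, threshold: int = DEFAULT_FOV_THRESHOLD) -> np.ndarray:
    """Detect the circular field of view as a single connected binary mask.

    A pixel is a FOV candidate when the maximum of its three channel values
    exceeds ``threshold``; the largest 8-connected candidate component is then
    morphologically closed and hole-filled so that dark vessels or the dark
    macula cannot punch holes in the mask.

    Raises
    ------
    FovNotFoundError
        If no pixel exceeds the threshold.
    """
    bright = image.pixels.max(axis=2) > threshold
    if not bright.any():
        raise FovNotFoundError("no field of view found")
    labels, n = ndi.label(bright, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndi.sum(bright, labels, index=np.arange(1, n + 1))
        bright = labels == (int(np.argmax(sizes)) + 1)
    closed = ndi.binary_closing(bright, structure=_disk(5), border_value=0)
    closed |= bright  # closing's erosion step must not shave frame borders
    return ndi.binary_fill_holes(closed)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def adaptive_hist_eq(
    grey: np.ndarray,
    tile_grid: tuple[int, int] = DEFAULT_TILE_GRID,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    fov: np.ndarray | None = None,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of an 8-bit raster.

    The frame is divided into ``tile_grid`` rectangular tiles; each tile's
    256-bin histogram is clipped at ``clip_limit`` times the tile pixel count
    (the clipped excess redistributed uniformly) and converted to a cumulative
    grey-level mapping.  Every pixel is remapped by bilinear interpolation
    between the mappings of the four nearest tile centres, which removes tile
    seams.

    When ``fov`` is given, tile histograms are accumulated from FOV pixels
    only, so the black surround cannot dominate the local statistics; the
    resulting mappings are still applied to every pixel of the frame.
    Tiles with no FOV pixel fall back to the global FOV histogram.
    """
    grey = np.asarray(grey)
    if grey.ndim != 2:
        raise ValueError("adaptive_hist_eq expects a single-plane raster")
    gr, gc = int(tile_grid[0]), int(tile_grid[1])
    if gr < 2 or gc < 2:
        raise ValueError("tile_grid must be at least (2, 2)")
    h, w = grey.shape
    if h // gr < 8 or w // gc < 8:
        raise ValueError("degenerate tile size: tiles must be at least 8 px on a side")

    g = grey.astype(np.uint8)
    row_edges = np.linspace(0, h, gr + 1).astype(int)
    col_edges = np.linspace(0, w, gc + 1).astype(int)

    histmask = np.ones((h, w), dtype=bool) if fov is None else np.asarray(fov, dtype=bool)
    global_hist = np.bincount(g[histmask].ravel(), minlength=256).astype(float)
    if global_hist.sum() == 0:
        global_hist = np.bincount(g.ravel(), minlength=256).astype(float)

    mappings = np.empty((gr, gc, 256), dtype=np.float64)
    for i in range(gr):
        for j in range(gc):
            tile = g[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            tmask = histmask[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            vals = tile[tmask]
            hist = (
                np.bincount(vals.ravel(), minlength=256).astype(float)
                if vals.size
                else global_hist.copy()
            )
            mappings[i, j] = _clipped_cdf_mapping(hist, clip_limit)

    # Bilinear blend between the four surrounding tile-centre mappings.
    centres_r = (row_edges[:-1] + row_edges[1:]) / 2.0
    centres_c = (col_edges[:-1] + col_edges[1:]) / 2.0
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    i1 = np.clip(np.searchsorted(centres_r, rows), 0, gr - 1)
    i0 = np.clip(i1 - 1, 0, gr - 1)
    j1 = np.clip(np.searchsorted(centres_c, cols), 0, gc - 1)
    j0 = np.clip(j1 - 1, 0, gc - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        wr = np.where(
            i1 > i0, (rows - centres_r[i0]) / (centres_r[i1] - centres_r[i0]), 0.0
        )
        wc = np.where(
            j1 > j0, (cols - centres_c[j0]) / (centres_c[j1] - centres_c[j0]), 0.0
        )
    wr = np.clip(wr, 0.0, 1.0)[:, None]
    wc = np.clip(wc, 0.0, 1.0)[None, :]

    gi = g.astype(np.intp)
    m00 = mappings[i0[:, None], j0[None, :], gi]
    m01 = mappings[i0[:, None], j1[None, :], gi]
    m10 = mappings[i1[:, None], j0[None, :], gi]
    m11 = mappings[i1[:, None], j1[None, :], gi]
    out = (1 - wr) * ((1 - wc) * m00 + wc * m01) + wr * ((1 - wc) * m10 + wc * m11)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _clipped_cdf_mapping(hist: np.ndarray, clip_limit: float) -> np.ndarray:
    """Clip a 256-bin histogram and return its cumulative grey-level mapping."""
    total = hist.sum()
    if total == 0:
        return np.arange(256, dtype=np.float64)
    limit = max(1.0, clip_limit * total)
    excess = np.maximum(hist - limit, 0.0).sum()
    clipped = np.minimum(hist, limit) + excess / 256.0
    cdf = np.cumsum(clipped)
    return cdf / cdf[-1] * 255.0
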