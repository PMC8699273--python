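"""Rasterize nodal reconstruction fields into SSIM-ready grayscale images.

The similarity metrics compare 8-bit (L = 255) images on a fixed square
pixel grid.  Reconstructed fields live on mesh nodes, so they are first
linearly interpolated onto the grid (barycentric interpolation within
triangles) and then quantized to gray levels with a scale *shared* between
the reference and test image — per-image min–max scaling would erase
exactly the contrast differences the metrics must detect.

The default grid is 160×160 (0.5 mm/pixel on the 80-mm domain).  The side
must be a multiple of 2^(K-1) = 16 so the K = 5 dyadic downsamplings of
the multiscale metrics are exact, and the coarsest scale (160/16 = 10 px)
must still admit a 9×9 analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.tri import LinearTriInterpolator, Triangulation
from PIL import Image

DEFAULT_GRID_SIZE = 160
GRAY_LEVELS = 255

__all__ = [
    "GrayImage",
    "DEFAULT_GRID_SIZE",
    "GRAY_LEVELS",
    "pixel_grid",
    "rasterize_field",
    "quantize_pair",
    "write_png",
    "read_png",
    "write_float_grid",
    "read_float_grid",
]


@dataclass
class GrayImage:
    """Quantized grayscale image on the fixed raster grid.

    pixels : float array of integer gray levels in [0, L]
    pitch  : physical pixel size, mm
    mask   : boolean in-domain (inside the disc) pixel mask
    """

    pixels: np.ndarray
    pitch: float = 0.0
    mask: np.ndarray | None = None
    L: int = GRAY_LEVELS

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("GrayImage must be square")
        if self.pixels.min() < 0 or self.pixels.max() > self.L:
            raise ValueError(f"gray levels must lie in [0, {self.L}]")

    @property
    def grid_size(self) -> int:
        return self.pixels.shape[0]


def pixel_grid(radius: float, grid_size: int):
    """Pixel-centre coordinates (x, y meshgrids) and in-disc mask."""
    pitch = 2.0 * radius / grid_size
    coords = -radius + (np.arange(grid_size) + 0.5) * pitch
    x, y = np.meshgrid(coords, coords)
    mask = x ** 2 + y ** 2 <= radius ** 2
    return x, y, mask, pitch


def rasterize_field(field: np.ndarray, mesh, grid_size: int = DEFAULT_GRID_SIZE,
                    fill: float | None = None) -> np.ndarray:
    """Linear barycentric interpolation of a nodal field onto the pixel grid.

    Pixels outside the mesh (including the thin sliver between the polygonal
    mesh boundary and the circle, and everything outside the disc) take the
    ``fill`` value — pass the background optical value; defaults to the mean
    of the field on the boundary nodes.
    """
    field = np.asarray(field, dtype=float)
    if len(field) != mesh.n_nodes:
        raise ValueError("field length must equal mesh node count")
    if fill is None:
        fill = float(field[mesh.boundary_nodes].mean())
    x, y, _, _ = pixel_grid(mesh.radius, grid_size)
    tri = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles)
    vals = LinearTriInterpolator(tri, field)(x, y)
    return np.asarray(vals.filled(fill))


def quantize_pair(reference_raw: np.ndarray, test_raw: np.ndarray,
                  L: int = GRAY_LEVELS,
                  value_range: tuple[float, float] | None = None,
                  pitch: float = 0.0,
                  mask: np.ndarray | None = None
                  ) -> tuple[GrayImage, GrayImage]:
    """Quantize a reference/test image pair with one shared affine scale.

    ``value_range`` fixes the (min, max) of the affine map; in a study it is
    the global range of that optical property over all study images of the
    case, computed once, so identical physical contrasts always map to
    identical gray differences.  When omitted, the joint range of the two
    images is used.  A degenerate range maps everything to mid-gray L/2.
    """
    ref = np.asarray(reference_raw, dtype=float)
    test = np.asarray(test_raw, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("reference and test images must share the grid")
    if value_range is None:
        lo = min(ref.min(), test.min())
        hi = max(ref.max(), test.max())
    else:
        lo, hi = value_range

    if hi <= lo:
        g_ref = np.full_like(ref, L / 2.0)
        g_test = np.full_like(test, L / 2.0)
    else:
        scale = L / (hi - lo)
        g_ref = np.clip(np.rint((ref - lo) * scale), 0, L)
        g_test = np.clip(np.rint((test - lo) * scale), 0, L)
    return (GrayImage(g_ref, pitch=pitch, mask=mask, L=L),
            GrayImage(g_test, pitch=pitch, mask=mask, L=L))


def write_png(image: GrayImage, path) -> None:
    Image.fromarray(image.pixels.astype(np.uint8), mode="L").save(path)


def read_png(path) -> GrayImage:
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    return GrayImage(arr)


def write_float_grid(raw: np.ndarray, path) -> None:
    """Lossless text sidecar for the raw (pre-quantization) field."""
    np.savetxt(path, np.asarray(raw, dtype=float), fmt="%.17g")


def read_float_grid(path) -> np.ndarray:
    return np.loadtxt(path, dtype=float)
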