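"""Image I/O and region-of-interest color extraction.

Mirrors the two-stage pellet selection of the companion phone app: the user
first taps near a pellet, the app shows a 200×200 px zoom for a refined
center tap, then averages the RGB values of the 20×20 px window around the
refined center. Here the taps become explicit (row, col) coordinates so the
whole flow is scriptable; :func:`crop_zoom` reproduces the zoom stage and
:func:`mean_rgb` the averaging stage.

Conventions: pixel coordinates are 0-based (row, col); a window of side w
centered at c covers the half-open range [c - w//2, c - w//2 + w) on each
axis, so an even 20-px window has an unambiguous 400-pixel footprint.
Windows are clipped at image edges rather than raising, with the surviving
pixel count reported. Means are computed in float64 over raw 8-bit sRGB
values, without gamma correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import GeometryError, InputError

__all__ = ["PelletColor", "load_image", "save_image", "crop_zoom", "mean_rgb"]

DEFAULT_WINDOW_SIDE = 20
DEFAULT_ZOOM_SIDE = 200


@dataclass(frozen=True)
class PelletColor:
    """Mean RGB of one pellet region of interest.

    ``rgb`` holds per-channel means on the 0–255 scale; ``n_pixels`` is the
    number of pixels that contributed (the full window area unless the
    window was clipped at an image edge); ``source`` is free-form
    provenance (image id, center, window side).
    """

    rgb: tuple[float, float, float]
    n_pixels: int
    source: str | None = None

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rgb, dtype=float)


def load_image(path: str | Path) -> np.ndarray:
    """Decode a PNG or JPEG into an (H, W, 3) uint8 RGB array.

    Alpha channels are discarded; grayscale images are promoted to three
    equal channels. Unreadable or truncated files raise :class:`InputError`
    naming the path.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            rgb = img.convert("RGB")
            return np.asarray(rgb, dtype=np.uint8)
    except (OSError, UnidentifiedImageError, SyntaxError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) uint8 array as a lossless PNG."""
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(
        Path(path), format="PNG"
    )


def _check_center(image: np.ndarray, center: tuple[int, int]) -> tuple[int, int]:
    height, width = image.shape[:2]
    row, col = int(center[0]), int(center[1])
    if not (0 <= row < height and 0 <= col < width):
        raise GeometryError(
            f"center {center} outside {height}x{width} image"
        )
    return row, col


def _window_bounds(c: int, side: int, size: int) -> tuple[int, int]:
    lo = c - side // 2
    hi = lo + side
    return max(lo, 0), min(hi, size)


def crop_zoom(
    image: np.ndarray,
    center: tuple[int, int],
    side: int = DEFAULT_ZOOM_SIDE,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Extract the side×side zoom region around a coarse center.

    Returns the cropped subimage and the (row, col) offset of its top-left
    pixel in the original image, so refined coordinates chosen in the crop
    map back to the original. Near an edge the region is clipped and may be
    smaller than side×side.
    """
    row, col = _check_center(image, center)
    height, width = image.shape[:2]
    r0, r1 = _window_bounds(row, side, height)
    c0, c1 = _window_bounds(col, side, width)
    return image[r0:r1, c0:c1], (r0, c0)


def mean_rgb(
    image: np.ndarray,
    center: tuple[int, int],
    window_side: int = DEFAULT_WINDOW_SIDE,
    source: str | None = None,
) -> PelletColor:
    """Per-channel mean over the window_side×window_side box at ``center``.

    The arithmetic mean is taken over the half-open window
    [c - w//2, c - w//2 + w) per axis, clipped at image edges; the number of
    contributing pixels is reported in ``n_pixels``.
    """
    row, col = _check_center(image, center)
    height, width = image.shape[:2]
    r0, r1 = _window_bounds(row, window_side, height)
    c0, c1 = _window_bounds(col, window_side, width)
    window = np.asarray(image[r0:r1, c0:c1], dtype=np.float64)
    n_pixels = window.shape[0] * window.shape[1]
    means = window.reshape(-1, window.shape[2]).mean(axis=0)
    return PelletColor(
        rgb=(float(means[0]), float(means[1]), float(means[2])),
        n_pixels=int(n_pixels),
        source=source,
    )
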