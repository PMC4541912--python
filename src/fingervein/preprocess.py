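"""Finger-region detection and size normalization.

The finger occupies a bright horizontal band on a dark background. The left
and right region bounds ``X_L``/``X_R`` are fixed per capture device (the
device hole constrains where the finger can sit); the upper and lower
boundaries are detected per column with a pair of 4x20 edge masks whose
response is maximal at a dark-to-bright (upper) or bright-to-dark (lower)
vertical transition. The detected region is linearly stretched to a 150x60
rectangle and sub-sampled by 3x3 block averaging to the 50x20 working image
on which enhancement and coding operate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ContractError, DetectionError

NORMALIZED_SHAPE = (60, 150)  # (height, width)
SUBSAMPLED_SHAPE = (20, 50)

#: Per-row weights of the boundary masks, top to bottom; each weight spans
#: the full mask width. Upper mask: dark above, bright below.
UPPER_MASK_WEIGHTS = (-1.0, -1.0, 1.0, 1.0)
LOWER_MASK_WEIGHTS = (1.0, 1.0, -1.0, -1.0)
MASK_WIDTH = 20

#: Fixed horizontal crop bounds per database quality, from the capture
#: devices' hole geometry (640x480 lab devices, 320x240 open database).
DATABASE_BOUNDS = {"good": (180, 480), "mid": (220, 470), "open": (20, 268)}


@dataclass(frozen=True)
class CropBounds:
    """Left/right finger-region bounds, half-open column range [X_L, X_R)."""

    x_left: int
    x_right: int

    def validate(self, width: int) -> None:
        if not (0 <= self.x_left < self.x_right <= width):
            raise ContractError(
                f"bounds [{self.x_left}, {self.x_right}) invalid for image width {width}"
            )

    @property
    def width(self) -> int:
        return self.x_right - self.x_left


@dataclass
class FingerRegion:
    """Detected finger region: crop bounds plus per-column boundary curves.

    ``upper`` / ``lower`` hold one y-position per column in [X_L, X_R);
    ``upper[c] < lower[c]`` for every column.
    """

    bounds: CropBounds
    upper: np.ndarray
    lower: np.ndarray


def _mask_response_maps(image: np.ndarray, mask_width: int = MASK_WIDTH) -> np.ndarray:
    """Upper-mask response at every (y, x); the lower-mask map is its negation.

    Response at (y, x) correlates the 4 x ``mask_width`` window spanning rows
    [y-2, y+2) and columns [x-w/2, x+w/2) with the row weights, replicating
    edge pixels where the window leaves the image.
    """
    img = np.asarray(image, dtype=np.float64)
    horiz = ndi.correlate1d(img, np.ones(mask_width), axis=1, mode="nearest")
    return ndi.correlate1d(horiz, np.asarray(UPPER_MASK_WEIGHTS), axis=0, mode="nearest")


def boundary_mask_response(
    image: np.ndarray, column: int, y: int, which: str, mask_width: int = MASK_WIDTH
) -> float:
    """Response of the upper/lower boundary mask centered at (column, y).

    The mask window spans rows [y-2, y+2) and ``mask_width`` columns centered
    at ``column`` (offsets -w/2 .. w/2-1), clamped at the image edges by
    replicate padding. ``which`` selects the row-weight pattern: ``"upper"``
    (-1,-1,+1,+1) peaks at dark-to-bright transitions, ``"lower"``
    (+1,+1,-1,-1) at bright-to-dark ones.
    """
    img = np.asarray(image, dtype=np.float64)
    height, width = img.shape
    if not 0 <= column < width:
        raise ContractError(f"column {column} outside image width {width}")
    if not 0 <= y < height:
        raise ContractError(f"row {y} outside image height {height}")
    if which == "upper":
        weights = UPPER_MASK_WEIGHTS
    elif which == "lower":
        weights = LOWER_MASK_WEIGHTS
    else:
        raise ContractError(f"which must be 'upper' or 'lower', got {which!r}")
    half = mask_width // 2
    padded = np.pad(img, ((2, 2), (half, half)), mode="edge")
    window = padded[y : y + 4, column : column + mask_width]
    return float(np.sum(np.asarray(weights)[:, None] * window))


def detect_finger_region(
    image: np.ndarray,
    bounds: CropBounds,
    median_window: int = 5,
    mask_width: int = MASK_WIDTH,
    upper_search: tuple[int, int] | None = None,
    lower_search: tuple[int, int] | None = None,
) -> FingerRegion:
    """Detect upper/lower finger boundaries for each column in [X_L, X_R).

    Per column the upper boundary is the argmax of the upper-mask response
    over rows ``upper_search`` (default [2, H/2)) and the lower boundary the
    argmax of the lower-mask response over ``lower_search`` (default
    [H/2, H-2)); the default half-split prevents the curves from crossing.
    Ties take the smallest y. Each curve is then median-filtered over
    ``median_window`` columns to suppress outliers; if a column still ends
    up with upper >= lower (possible only with overlapping custom search
    ranges) the image is rejected.
    """
    img = np.asarray(image, dtype=np.float64)
    height, width = img.shape
    bounds.validate(width)
    half_h = height // 2
    if half_h < 3 or height - 2 <= half_h:
        raise ContractError(f"image height {height} too small for boundary search")
    u0, u1 = upper_search if upper_search is not None else (2, half_h)
    l0, l1 = lower_search if lower_search is not None else (half_h, height - 2)
    if not (0 <= u0 < u1 <= height and 0 <= l0 < l1 <= height):
        raise ContractError("search ranges must be non-empty and inside the image")

    resp = _mask_response_maps(img, mask_width)[:, bounds.x_left : bounds.x_right]
    upper = u0 + np.argmax(resp[u0:u1], axis=0)
    lower = l0 + np.argmax(-resp[l0:l1], axis=0)
    if median_window > 1:
        upper = ndi.median_filter(upper, size=median_window, mode="nearest")
        lower = ndi.median_filter(lower, size=median_window, mode="nearest")
    if np.any(upper >= lower):
        bad = int(np.argmax(upper >= lower))
        raise DetectionError(
            f"finger boundary detection failed: upper >= lower at column {bounds.x_left + bad}"
        )
    return FingerRegion(bounds, upper.astype(np.int64), lower.astype(np.int64))


def stretch_to_rectangle(image: np.ndarray, region: FingerRegion) -> np.ndarray:
    """Linearly stretch the detected finger region to a 150x60 rectangle.

    Output column j samples source column ``X_L + j*(X_R-X_L)/150``; output
    row i samples the point a fraction ``i/60`` of the way from the (linearly
    interpolated) upper boundary to the lower boundary at that source column.
    Intensities are bilinearly interpolated and clipped to [0, 255].
    """
    img = np.asarray(image, dtype=np.float64)
    region.bounds.validate(img.shape[1])
    out_h, out_w = NORMALIZED_SHAPE
    j = np.arange(out_w)
    xs = region.bounds.x_left + j * (region.bounds.width / out_w)
    col_pos = xs - region.bounds.x_left  # fractional index into boundary arrays
    grid = np.arange(region.bounds.width, dtype=np.float64)
    up = np.interp(col_pos, grid, region.upper.astype(np.float64))
    low = np.interp(col_pos, grid, region.lower.astype(np.float64))
    i = np.arange(out_h, dtype=np.float64)[:, None]
    ys = up[None, :] + i * (low - up)[None, :] / out_h
    xg = np.broadcast_to(xs[None, :], (out_h, out_w))
    sampled = ndi.map_coordinates(img, [ys, xg], order=1, mode="nearest")
    return np.clip(sampled, 0.0, 255.0)


def subsample_3x3(image: np.ndarray) -> np.ndarray:
    """Average each 3x3 block of a 150x60 image, producing the 50x20 image.

    Intensities stay real-valued (no re-quantization) so the enhancement and
    coding stages see the full contrast.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape != NORMALIZED_SHAPE:
        raise ContractError(f"expected {NORMALIZED_SHAPE} input, got {img.shape}")
    h, w = SUBSAMPLED_SHAPE
    return img.reshape(h, 3, w, 3).mean(axis=(1, 3))


def preprocess_image(
    image: np.ndarray,
    bounds: CropBounds,
    median_window: int = 5,
    mask_width: int = MASK_WIDTH,
) -> np.ndarray:
    """Full preprocessing: detect region, stretch to 150x60, sub-sample to 50x20."""
    region = detect_finger_region(image, bounds, median_window, mask_width)
    return subsample_3x3(stretch_to_rectangle(image, region))
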