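"""Enrollment templates: shift compensation, image averaging, representative selection.

Misalignment between enrollment captures of the same finger is the dominant
error source; before averaging, every image after the first is registered to
the first by exhaustive integer-shift template matching (normalized
cross-correlation over the overlap, search window ±``max_shift`` pixels).
The compensated images are averaged per pixel and the average is enhanced
and coded into the enrollment template. ``select_representative`` implements
the common single-image baseline: enroll the image whose code has the
smallest summed Hamming distance to the other enrollment codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .gabor import GaborParams
from .veincode import VeinCode, extract_code, hamming

MAX_SHIFT_DEFAULT = 5


@dataclass
class EnrollmentTemplate:
    """Stored enrollment representation.

    ``shifts[i]`` is the (dx, dy) correction applied to contributing image i
    (the first image is the reference, so ``shifts[0] == (0, 0)``); e.g. an
    image measured as moved by (-2, -1) relative to the reference is shifted
    by (+2, +1) before averaging.
    """

    code: VeinCode
    n_images: int
    shifts: list[tuple[int, int]] = field(default_factory=lambda: [(0, 0)])
    average_image: np.ndarray | None = None
    source_index: int | None = None


def translate_image(image: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate by (dx, dy) pixels with replicate fill at exposed borders."""
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    ys = np.clip(np.arange(h) - dy, 0, h - 1)
    xs = np.clip(np.arange(w) - dx, 0, w - 1)
    return img[np.ix_(ys, xs)]


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-shape patches; 0 if either is flat."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom <= 0:
        return 0.0
    return float((a @ b) / denom)


def estimate_shift(
    reference: np.ndarray, moving: np.ndarray, max_shift: int = MAX_SHIFT_DEFAULT
) -> tuple[int, int]:
    """Integer (dx, dy) by which ``moving`` is translated relative to ``reference``.

    Maximizes normalized cross-correlation over the overlapping region across
    all shifts in [-max_shift, max_shift]^2; ties are broken by smallest
    |dx|+|dy|, then smallest dy, then smallest dx. The compensating move is
    the negation of the returned shift.
    """
    ref = np.asarray(reference, dtype=np.float64)
    mov = np.asarray(moving, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ContractError("reference and moving images must share a shape")
    if not 0 <= max_shift <= 5:
        raise ContractError(f"max_shift must lie in [0, 5], got {max_shift}")
    h, w = ref.shape
    candidates = sorted(
        (
            (dx, dy)
            for dx in range(-max_shift, max_shift + 1)
            for dy in range(-max_shift, max_shift + 1)
        ),
        key=lambda d: (abs(d[0]) + abs(d[1]), d[1], d[0]),
    )
    best, best_score = (0, 0), -np.inf
    for dx, dy in candidates:
        y0, y1 = max(0, dy), h + min(0, dy)
        x0, x1 = max(0, dx), w + min(0, dx)
        if y1 - y0 < 2 or x1 - x0 < 2:
            continue
        score = _ncc(ref[y0 - dy : y1 - dy, x0 - dx : x1 - dx], mov[y0:y1, x0:x1])
        if score > best_score:
            best, best_score = (dx, dy), score
    return best


def average_enrollment(
    images: list[np.ndarray],
    max_shift: int = MAX_SHIFT_DEFAULT,
    bank: list[GaborParams] | None = None,
    kernel_size: int | None = None,
    enhance: bool = True,
) -> EnrollmentTemplate:
    """Shift-compensated average of enrollment images, enhanced and coded.

    The first image is the reference; each later image is registered to it
    and moved by the negated measured shift (replicate fill), then the
    per-pixel arithmetic mean is enhanced (by default) and coded.
    """
    if len(images) == 0:
        raise ContractError("enrollment needs at least one image")
    if len(images) > 10:
        raise ContractError("enrollment supports at most 10 images")
    ref = np.asarray(images[0], dtype=np.float64)
    aligned = [ref]
    shifts: list[tuple[int, int]] = [(0, 0)]
    for img in images[1:]:
        dx, dy = estimate_shift(ref, np.asarray(img, dtype=np.float64), max_shift)
        aligned.append(translate_image(img, -dx, -dy))
        shifts.append((-dx, -dy))
    mean_image = np.mean(aligned, axis=0)
    code = _code_image(mean_image, bank, kernel_size, enhance)
    return EnrollmentTemplate(code, len(images), shifts, average_image=mean_image)


def select_representative(
    images: list[np.ndarray],
    bank: list[GaborParams] | None = None,
    kernel_size: int | None = None,
    enhance: bool = True,
) -> EnrollmentTemplate:
    """Enroll the single image whose code is closest to the other codes.

    Codes every image and picks the one minimizing the sum of Hamming
    distances to all others (earliest index on ties).
    """
    if len(images) == 0:
        raise ContractError("enrollment needs at least one image")
    codes = [_code_image(np.asarray(im, dtype=np.float64), bank, kernel_size, enhance) for im in images]
    sums = [
        sum(hamming(codes[i], codes[j]).hd for j in range(len(codes)) if j != i)
        for i in range(len(codes))
    ]
    idx = int(np.argmin(sums))
    return EnrollmentTemplate(
        codes[idx],
        n_images=1,
        shifts=[(0, 0)],
        average_image=np.asarray(images[idx], dtype=np.float64),
        source_index=idx,
    )


def _code_image(
    image: np.ndarray,
    bank: list[GaborParams] | None,
    kernel_size: int | None,
    enhance: bool,
) -> VeinCode:
    from .gabor import DEFAULT_KERNEL_SIZE, enhance_image

    if enhance:
        image = enhance_image(image, bank, kernel_size or DEFAULT_KERNEL_SIZE)
    return extract_code(image)
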