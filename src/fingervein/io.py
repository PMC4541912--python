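"""Image and dataset-manifest I/O.

Images are 8-bit single-channel grids (NIR finger images). A dataset is
described by a CSV manifest with columns ``path,person,hand,finger,trial``;
each row labels one image with the identity tuple
(person, hand, finger type, trial) that the evaluation designs group by.

Coordinate convention used throughout the package: ``x`` is the column
(horizontal), ``y`` the row (vertical), origin at the top-left, 0-based,
ranges half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import ManifestError, ValidationError

HANDS = ("L", "R")
FINGER_TYPES = ("index", "middle", "ring")

_HAND_ALIASES = {"l": "L", "left": "L", "r": "R", "right": "R"}


@dataclass(frozen=True, order=True)
class SampleLabel:
    """Identity label of one captured image.

    The 4-tuple (person, hand, finger type, trial) uniquely identifies an
    image within a manifest; a database of P people with T trials per finger
    contains P x 2 x 3 x T images.
    """

    person_id: int
    hand: str
    finger_type: str
    trial: int

    def __post_init__(self) -> None:
        if self.person_id < 0 or self.trial < 0:
            raise ValidationError(f"person_id and trial must be >= 0: {self}")
        if self.hand not in HANDS:
            raise ValidationError(f"unknown hand {self.hand!r}; expected one of {HANDS}")
        if self.finger_type not in FINGER_TYPES:
            raise ValidationError(
                f"unknown finger type {self.finger_type!r}; expected one of {FINGER_TYPES}"
            )

    @property
    def finger_key(self) -> tuple[int, str, str]:
        """Class key under the finest grouping: one class per physical finger."""
        return (self.person_id, self.hand, self.finger_type)


def normalize_hand(token: str) -> str:
    try:
        return _HAND_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise ManifestError(f"unknown hand token {token!r}; expected L/R") from None


def normalize_finger(token: str) -> str:
    t = str(token).strip().lower()
    if t not in FINGER_TYPES:
        raise ManifestError(f"unknown finger token {token!r}; expected one of {FINGER_TYPES}")
    return t


@dataclass
class DatasetManifest:
    """Ordered list of (image path, label) pairs describing one database."""

    entries: list[tuple[Path, SampleLabel]] = field(default_factory=list)
    quality_tag: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[SampleLabel]:
        return [lab for _, lab in self.entries]

    @property
    def paths(self) -> list[Path]:
        return [p for p, _ in self.entries]

    def validate(self) -> None:
        seen: dict[tuple, int] = {}
        dups = []
        for i, (_, lab) in enumerate(self.entries):
            key = (lab.person_id, lab.hand, lab.finger_type, lab.trial)
            if key in seen:
                dups.append(key)
            seen.setdefault(key, i)
        if dups:
            raise ManifestError(f"duplicate (person, hand, finger, trial) tuples: {sorted(set(dups))}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/BMP image as an 8-bit grayscale array (height x width).

    Multi-channel inputs are converted by ITU-R 601 luma weighting; 16-bit
    inputs are rescaled by an integer right-shift of 8 bits.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("I;16", "I;16B", "I;16L", "I"):
                arr = np.asarray(im, dtype=np.uint32)
                pixels = (arr >> 8).clip(0, 255).astype(np.uint8)
            elif im.mode == "L":
                pixels = np.asarray(im, dtype=np.uint8)
            else:
                pixels = np.asarray(im.convert("L"), dtype=np.uint8)
    except FileNotFoundError:
        raise
    except UnidentifiedImageError as exc:
        raise OSError(f"cannot decode image file {path}") from exc
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValidationError(f"image {path} is empty or not a 2-D grid")
    return pixels


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an 8-bit grayscale array to PNG/BMP (format from the extension)."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError("pixels must be a non-empty 2-D grid")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def load_manifest(path: str | Path, quality_tag: str = "") -> DatasetManifest:
    """Load a CSV manifest with columns ``path,person,hand,finger,trial``.

    Rows are kept in file order; image paths are resolved relative to the
    manifest's directory. An empty file yields an empty manifest.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return DatasetManifest([], quality_tag)
    missing = {"path", "person", "hand", "finger", "trial"} - set(df.columns)
    if missing:
        raise ManifestError(f"manifest {path} lacks columns {sorted(missing)}")
    base = path.parent
    entries = []
    for row in df.itertuples(index=False):
        label = SampleLabel(
            person_id=int(row.person),
            hand=normalize_hand(row.hand),
            finger_type=normalize_finger(row.finger),
            trial=int(row.trial),
        )
        img_path = Path(str(row.path))
        if not img_path.is_absolute():
            img_path = base / img_path
        entries.append((img_path, label))
    manifest = DatasetManifest(entries, quality_tag)
    manifest.validate()
    return manifest


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a manifest back to CSV; paths are stored relative to the CSV."""
    path = Path(path)
    base = path.parent
    rows = []
    for img_path, lab in manifest.entries:
        try:
            rel = img_path.relative_to(base)
        except ValueError:
            rel = img_path
        rows.append(
            {
                "path": str(rel),
                "person": lab.person_id,
                "hand": lab.hand,
                "finger": lab.finger_type,
                "trial": lab.trial,
            }
        )
    pd.DataFrame(rows, columns=["path", "person", "hand", "finger", "trial"]).to_csv(
        path, index=False
    )
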