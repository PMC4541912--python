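"""End-to-end wiring: raw image -> working image -> vein code.

Holds the run configuration (crop bounds plus every stage tunable) and the
convenience composers used by the CLI, the evaluation experiments and the
tests. Codes are extracted once per image and reused for all pairings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .gabor import DEFAULT_FREQUENCY, DEFAULT_KERNEL_SIZE, DEFAULT_SIGMA, default_bank, enhance_image
from .io import DatasetManifest, SampleLabel, read_image
from .preprocess import DATABASE_BOUNDS, CropBounds, preprocess_image
from .synthetic import SynthConfig, iter_database
from .veincode import VeinCode, extract_code


@dataclass
class PipelineConfig:
    """All tunables of the recognition pipeline, with the working defaults.

    ``enhance=False`` bypasses Gabor filtering so the LBP can be ablated on
    the raw sub-sampled image.
    """

    bounds: CropBounds = field(default_factory=lambda: CropBounds(*DATABASE_BOUNDS["good"]))
    gabor_frequency: float = DEFAULT_FREQUENCY
    gabor_sigma_x: float = DEFAULT_SIGMA
    gabor_sigma_y: float = DEFAULT_SIGMA
    kernel_size: int = DEFAULT_KERNEL_SIZE
    enhance: bool = True
    median_window: int = 5
    mask_width: int = 20
    max_shift: int = 5
    n_thresholds: int = 10_001

    def bank(self):
        return default_bank(self.gabor_frequency, self.gabor_sigma_x, self.gabor_sigma_y)

    @classmethod
    def for_database(cls, quality: str, **overrides) -> "PipelineConfig":
        return cls(bounds=CropBounds(*DATABASE_BOUNDS[quality]), **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "bounds" in data:
            data["bounds"] = CropBounds(*data["bounds"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "bounds": [self.bounds.x_left, self.bounds.x_right],
            "gabor_frequency": self.gabor_frequency,
            "gabor_sigma_x": self.gabor_sigma_x,
            "gabor_sigma_y": self.gabor_sigma_y,
            "kernel_size": self.kernel_size,
            "enhance": self.enhance,
            "median_window": self.median_window,
            "mask_width": self.mask_width,
            "max_shift": self.max_shift,
            "n_thresholds": self.n_thresholds,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def subsample_raw(image: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Raw image -> 20x50 working image (detection, stretching, sub-sampling)."""
    return preprocess_image(image, config.bounds, config.median_window, config.mask_width)


def code_subsampled(subsampled: np.ndarray, config: PipelineConfig) -> VeinCode:
    """20x50 working image -> vein code (optional Gabor enhancement, LBP)."""
    working = subsampled
    if config.enhance:
        working = enhance_image(subsampled, config.bank(), config.kernel_size)
    return extract_code(working)


def code_image(image: np.ndarray, config: PipelineConfig) -> VeinCode:
    """Full pipeline on one raw image."""
    return code_subsampled(subsample_raw(image, config), config)


def code_manifest(
    manifest: DatasetManifest, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Code every manifest image; returns (subsampled stack, bit matrix)."""
    subs, bits = [], []
    for path, _ in manifest.entries:
        sub = subsample_raw(read_image(path), config)
        subs.append(sub)
        bits.append(code_subsampled(sub, config).bits)
    return np.stack(subs), np.stack(bits)


def code_synthetic_database(
    synth: SynthConfig, config: PipelineConfig
) -> tuple[list[SampleLabel], np.ndarray, np.ndarray]:
    """Generate a synthetic database in memory and code every image.

    Streams the renders so only the 20x50 working images and the bit matrix
    stay resident. Returns (labels, subsampled stack, bit matrix).
    """
    labels, subs, bits = [], [], []
    for label, image, _ in iter_database(synth):
        sub = subsample_raw(image, config)
        labels.append(label)
        subs.append(sub)
        bits.append(code_subsampled(sub, config).bits)
    return labels, np.stack(subs), np.stack(bits)
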