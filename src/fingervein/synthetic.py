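"""Synthetic NIR-like finger-vein database generator.

Renders what a transillumination finger camera sees: a bright finger band
with smooth, slowly varying upper/lower boundaries on a dark background,
crossed by a handful of darker, smoothly curving vein lines (deoxyhemoglobin
absorbs the NIR light). Identity structure matches the real capture
protocol — people x 2 hands x 3 finger types, several trials per finger —
with one vein pattern per physical finger and a per-trial translation
jitter that emulates finger-placement misalignment, the dominant difference
between the good/mid/open capture setups. Vein patterns of different fingers
of one person are independent: empirically, two fingers of the same person
are nearly as dissimilar as fingers of different people, so no within-person
correlation is modelled. A mild cross-people regularity IS modelled: a few
of each finger's veins follow a per-finger-type archetype (index fingers
resemble other index fingers more than they resemble ring fingers), which is
what gives the finger-type class definition its small but real edge over the
hand class definition in verification accuracy.

All randomness flows from ``SynthConfig.seed`` through per-pattern and
per-trial ``numpy.random.SeedSequence`` streams (spawn keys
``(pattern_index,)`` and ``(pattern_index, trial + 1)``), so any single
image is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import FINGER_TYPES, HANDS, DatasetManifest, SampleLabel, save_manifest, write_image
from .preprocess import DATABASE_BOUNDS, CropBounds


@dataclass(frozen=True)
class SynthConfig:
    """Rendering and identity-structure parameters of one synthetic database.

    Intensities are 8-bit gray levels; lengths are pixels at the raw image
    scale. ``jitter_sigma`` is the standard deviation of the per-trial
    Gaussian translation of the whole finger (both axes); vertical jitter is
    largely cancelled by boundary normalization, horizontal jitter survives
    into the working image because the crop window is fixed.
    """

    n_people: int = 20
    n_trials: int = 10
    width: int = 640
    height: int = 480
    jitter_sigma: float = 2.0
    vein_count: tuple[int, int] = (5, 9)
    vein_width: tuple[float, float] = (6.0, 14.0)
    vein_contrast: float = 60.0
    background_level: float = 40.0
    finger_level: float = 160.0
    noise_sigma: float = 3.0
    shared_vein_count: int = 1
    archetype_jitter: float = 0.09
    seed: int = 0
    hands: tuple[str, ...] = HANDS
    finger_types: tuple[str, ...] = FINGER_TYPES

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0 or self.noise_sigma < 0:
            raise ValidationError("jitter_sigma and noise_sigma must be >= 0")
        if self.finger_level <= self.background_level:
            raise ValidationError("finger_level must exceed background_level")
        if self.vein_count[0] > self.vein_count[1] or self.vein_count[0] < 1:
            raise ValidationError(f"empty vein_count range {self.vein_count}")
        if self.vein_width[0] > self.vein_width[1] or self.vein_width[0] <= 0:
            raise ValidationError(f"empty vein_width range {self.vein_width}")
        if self.n_people < 1 or self.n_trials < 1 or self.width < 8 or self.height < 8:
            raise ValidationError("n_people/n_trials/size out of range")
        if not 0 <= self.shared_vein_count <= self.vein_count[0]:
            raise ValidationError("shared_vein_count must not exceed the minimum vein count")

    @property
    def n_patterns(self) -> int:
        return self.n_people * len(self.hands) * len(self.finger_types)

    @property
    def n_images(self) -> int:
        return self.n_patterns * self.n_trials


#: Quality presets emulating the three capture setups: a guiding-bar device
#: (good), the same optics without the bar (mid), and an open 320x240
#: database with more placement freedom and weaker contrast (open).
def preset_config(name: str, n_people: int | None = None, n_trials: int | None = None,
                  seed: int = 0) -> tuple[SynthConfig, CropBounds]:
    """A (SynthConfig, CropBounds) pair for the good/mid/open quality preset."""
    base = {
        "good": SynthConfig(n_people=20, n_trials=10, width=640, height=480, jitter_sigma=2.0),
        "mid": SynthConfig(n_people=33, n_trials=10, width=640, height=480, jitter_sigma=10.0),
        "open": SynthConfig(
            n_people=106, n_trials=6, width=320, height=240, jitter_sigma=12.0,
            vein_contrast=40.0, vein_width=(3.0, 7.0),
        ),
    }
    try:
        cfg = base[name]
    except KeyError:
        raise ValidationError(f"unknown preset {name!r}; expected good/mid/open") from None
    if n_people is not None:
        cfg = replace(cfg, n_people=n_people)
    if n_trials is not None:
        cfg = replace(cfg, n_trials=n_trials)
    cfg = replace(cfg, seed=seed)
    return cfg, CropBounds(*DATABASE_BOUNDS[name])


@dataclass
class VeinPattern:
    """Ground-truth geometry of one finger: boundary and vein polynomials.

    Polynomials are in the normalized finger-frame coordinate
    ``xi = (x - dx) / (width - 1)``; boundary values are absolute rows,
    vein centers are fractions of the band thickness.
    """

    upper_coeffs: np.ndarray  # ascending powers of xi, absolute rows
    lower_coeffs: np.ndarray
    vein_coeffs: list[np.ndarray]  # band-fraction cubics, ascending powers
    vein_widths: list[float]
    vein_contrasts: list[float]

    def boundaries_at(self, x: np.ndarray, width: int, dx: float = 0.0, dy: float = 0.0):
        xi = (np.asarray(x, dtype=np.float64) - dx) / (width - 1)
        up = np.polynomial.polynomial.polyval(xi, self.upper_coeffs) + dy
        low = np.polynomial.polynomial.polyval(xi, self.lower_coeffs) + dy
        return up, low

    def to_json(self) -> dict:
        return {
            "upper_coeffs": self.upper_coeffs.tolist(),
            "lower_coeffs": self.lower_coeffs.tolist(),
            "vein_coeffs": [c.tolist() for c in self.vein_coeffs],
            "vein_widths": self.vein_widths,
            "vein_contrasts": self.vein_contrasts,
        }


def _pattern_rng(config: SynthConfig, pattern_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(pattern_index,))
    )


def _trial_rng(config: SynthConfig, pattern_index: int, trial: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(pattern_index, trial + 1))
    )


_KNOTS_X = np.array([0.0, 1 / 3, 2 / 3, 1.0])


def _archetype_knots(config: SynthConfig, finger_type_index: int) -> np.ndarray:
    """Per-finger-type archetype vein tracks, shared across people and hands."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(999_000 + finger_type_index,))
    )
    return rng.uniform(0.2, 0.8, size=(config.shared_vein_count, _KNOTS_X.size))


def make_pattern(
    config: SynthConfig, pattern_index: int, finger_type_index: int = 0
) -> VeinPattern:
    """Draw the persistent geometry of one finger from its pattern stream.

    The first ``shared_vein_count`` veins perturb the finger-type archetype
    (same-type fingers of different people look mildly alike); the remainder
    are fully individual.
    """
    rng = _pattern_rng(config, pattern_index)
    h = config.height
    center = h * rng.uniform(0.47, 0.53)
    half = h * rng.uniform(0.22, 0.28)
    # gentle quadratic wobble of each boundary, a few pixels across the image
    def boundary(sign: float) -> np.ndarray:
        c0 = center + sign * half
        c1 = rng.uniform(-0.02, 0.02) * h
        c2 = rng.uniform(-0.02, 0.02) * h
        return np.array([c0 - (c1 / 2 + c2 / 3), c1, c2])  # zero-mean wobble

    upper = boundary(-1.0)
    lower = boundary(+1.0)
    n_veins = int(rng.integers(config.vein_count[0], config.vein_count[1] + 1))
    archetype = _archetype_knots(config, finger_type_index)
    vein_coeffs, widths, contrasts = [], [], []
    for v in range(n_veins):
        if v < config.shared_vein_count:
            knots_y = archetype[v] + rng.normal(0.0, config.archetype_jitter, _KNOTS_X.size)
            knots_y = np.clip(knots_y, 0.12, 0.88)
        else:
            knots_y = rng.uniform(0.15, 0.85, size=_KNOTS_X.size)
        coeffs = np.polynomial.polynomial.polyfit(_KNOTS_X, knots_y, 3)
        vein_coeffs.append(coeffs)
        widths.append(float(rng.uniform(*config.vein_width)))
        contrasts.append(float(config.vein_contrast * rng.uniform(0.7, 1.3)))
    return VeinPattern(upper, lower, vein_coeffs, widths, contrasts)


def render_finger(
    pattern: VeinPattern,
    config: SynthConfig,
    jitter: tuple[float, float] = (0.0, 0.0),
    noise_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one trial image: band + veins, translated by ``jitter``, plus noise.

    With zero jitter and no noise generator the render is a deterministic
    function of the pattern, so repeated trials are bit-identical.
    """
    dx, dy = jitter
    h, w = config.height, config.width
    x = np.arange(w, dtype=np.float64)
    up, low = pattern.boundaries_at(x, w, dx, dy)
    y = np.arange(h, dtype=np.float64)[:, None]
    edge = 1.5  # soft boundary ramp, px
    inside = np.clip((y - up[None, :]) / edge, 0.0, 1.0) * np.clip(
        (low[None, :] - y) / edge, 0.0, 1.0
    )
    img = config.background_level + (config.finger_level - config.background_level) * inside
    xi = (x - dx) / (w - 1)
    thickness = low - up
    for coeffs, width_px, contrast in zip(
        pattern.vein_coeffs, pattern.vein_widths, pattern.vein_contrasts
    ):
        frac = np.polynomial.polynomial.polyval(xi, coeffs)
        yc = up + frac * thickness
        t = (y - yc[None, :]) / (0.5 * width_px)
        img -= contrast * np.exp(-0.5 * t * t) * inside
    if noise_rng is not None and config.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, config.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def iter_database(config: SynthConfig):
    """Yield (SampleLabel, image, truth) for every image of the database.

    ``truth`` records the pattern index, the applied (dx, dy) jitter and the
    jittered boundary curves sampled per column, for validating the
    preprocessing stage against ground truth.
    """
    pattern_index = 0
    for person in range(config.n_people):
        for hand in config.hands:
            for type_index, finger in enumerate(config.finger_types):
                pattern = make_pattern(config, pattern_index, type_index)
                for trial in range(config.n_trials):
                    rng = _trial_rng(config, pattern_index, trial)
                    if config.jitter_sigma > 0:
                        dx, dy = rng.normal(0.0, config.jitter_sigma, size=2)
                    else:
                        dx, dy = 0.0, 0.0
                    image = render_finger(
                        pattern, config, (dx, dy), rng if config.noise_sigma > 0 else None
                    )
                    label = SampleLabel(person, hand, finger, trial)
                    truth = {
                        "pattern_index": pattern_index,
                        "dx": float(dx),
                        "dy": float(dy),
                        "pattern": pattern,
                    }
                    yield label, image, truth
                pattern_index += 1


def generate_database(
    config: SynthConfig, out_dir: str | Path, quality_tag: str = "synthetic"
) -> DatasetManifest:
    """Write all images, a CSV manifest and a ground-truth JSON to ``out_dir``.

    Returns the manifest; total image count is
    ``n_people x hands x finger_types x n_trials``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    entries = []
    truth_records = []
    patterns: dict[int, dict] = {}
    for label, image, truth in iter_database(config):
        name = f"p{label.person_id:03d}_{label.hand}_{label.finger_type}_t{label.trial:02d}.png"
        write_image(out / name, image)
        entries.append((out / name, label))
        patterns.setdefault(truth["pattern_index"], truth["pattern"].to_json())
        truth_records.append(
            {
                "path": name,
                "person": label.person_id,
                "hand": label.hand,
                "finger": label.finger_type,
                "trial": label.trial,
                "pattern_index": truth["pattern_index"],
                "dx": truth["dx"],
                "dy": truth["dy"],
            }
        )
    manifest = DatasetManifest(entries, quality_tag)
    save_manifest(manifest, out / "manifest.csv")
    ground_truth = {
        "seed": config.seed,
        "jitter_sigma": config.jitter_sigma,
        "patterns": patterns,
        "images": truth_records,
    }
    (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
    return manifest
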