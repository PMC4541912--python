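import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fingervein as fv

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def band_image():
    """Bright horizontal band (rows 100..400) on a dark background, 640x480."""
    img = np.full((480, 640), 10, dtype=np.uint8)
    img[100:400, :] = 200
    return img


@pytest.fixture(scope="session")
def textured_subsampled():
    """A deterministic, textured 20x50 working image (synthetic finger render)."""
    cfg, bounds = fv.preset_config("good", n_people=1, n_trials=1, seed=99)
    label, image, _ = next(fv.iter_database(cfg))
    return fv.subsample_raw(image, fv.PipelineConfig(bounds=bounds))


def _coded_db(preset: str, seed: int):
    cfg, bounds = fv.preset_config(preset, n_people=10, n_trials=10, seed=seed)
    pc = fv.PipelineConfig(bounds=bounds)
    labels, subs, bits = fv.code_synthetic_database(cfg, pc)
    return labels, subs, bits, fv.pairwise_hamming(bits)


@pytest.fixture(scope="session")
def coded_good_db():
    """10-person good-quality synthetic DB, fully coded (600 images)."""
    return _coded_db("good", seed=1)


@pytest.fixture(scope="session")
def coded_mid_db():
    """10-person mid-quality synthetic DB, fully coded (600 images)."""
    return _coded_db("mid", seed=1)


@pytest.fixture(scope="session")
def coded_open_db():
    """10-person open-quality synthetic DB, fully coded (600 images)."""
    return _coded_db("open", seed=1)
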