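import numpy as np
import pytest

from carrotmorph.pipeline import PipelineConfig, run_measure
from carrotmorph.synthetic import generate_population

STANDARD_SEED = 42  # seed of the standard 100-plant fixture


@pytest.fixture(scope="session")
def population100():
    """Standard seeded 100-plant synthetic population: (images, truth)."""
    return generate_population(100, seed=STANDARD_SEED)


@pytest.fixture(scope="session")
def measured100(population100, tmp_path_factory):
    """The standard population run through the measurement stage.

    Returns (out_dir, measurements, failures, truth).
    """
    images, truth = population100
    out = tmp_path_factory.mktemp("measured100")
    items = list(zip(truth["image_id"], images))
    config = PipelineConfig(px_per_cm=float(truth["px_per_cm"].iloc[0]))
    measurements, failures = run_measure(items, out, config)
    return out, measurements, failures, truth


def random_mask(rng, shape=(60, 80), p=0.3):
    """Random binary mask with at least one foreground pixel."""
    grid = (rng.random(shape) < p).astype(np.uint8)
    if not grid.any():
        grid[shape[0] // 2, shape[1] // 2] = 1
    return grid
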