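import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brduquant import synthgen

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_population():
    """Default ground-truth population at the study's per-experiment size."""
    pop = synthgen.PopulationParams(n_cells=10_000, seed=11)
    cyc = synthgen.CellCycleParams()
    return pop, cyc, synthgen.generate_population(pop, cyc)


@pytest.fixture(scope="session")
def rendered_scene():
    """200 placed nuclei rendered with default imaging noise."""
    pop = synthgen.PopulationParams(n_cells=200, seed=21)
    cyc = synthgen.CellCycleParams()
    truth = synthgen.generate_population(pop, cyc)
    img = synthgen.ImagingParams(seed=22)
    placed = synthgen.place_nuclei(truth, img)
    dapi, signal, labels = synthgen.render_images(placed, img)
    return placed, img, dapi, signal, labels


@pytest.fixture(scope="session")
def rendered_scene_noise_free():
    """Same geometry as rendered_scene but without acquisition noise."""
    pop = synthgen.PopulationParams(n_cells=200, seed=21)
    cyc = synthgen.CellCycleParams()
    truth = synthgen.generate_population(pop, cyc)
    img = synthgen.ImagingParams(gaussian_noise_sd=0.0, poisson_noise=False, seed=22)
    placed = synthgen.place_nuclei(truth, img)
    dapi, signal, labels = synthgen.render_images(placed, img)
    return placed, img, dapi, signal, labels
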