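import numpy as np
import pytest

from phasefit import (
    SegmentationParams,
    default_population_params,
    render_synthetic_image,
    simulate_cell_population,
)


@pytest.fixture(scope="session")
def sol_cells():
    return simulate_cell_population(default_population_params("SOL", 200, seed=11))


@pytest.fixture(scope="session")
def agg_cells():
    return simulate_cell_population(default_population_params("AGG", 200, seed=12))


@pytest.fixture(scope="session")
def clean_image(agg_cells):
    """Noise-free 100-cell frame with mixed foci and exact ground truth."""
    cells = agg_cells.head(100).copy()
    # keep every cell inside the detectable 8-50 um^2 window
    cells["area_um2"] = np.clip(cells["area_um2"], 10.0, 45.0)
    return render_synthetic_image(cells, background_sd=0.0, seed=21)


@pytest.fixture(scope="session")
def seg_params(clean_image):
    return SegmentationParams(pixel_scale=clean_image.pixel_scale)
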