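import numpy as np
import pytest

from glacier import (
    SpatialExpressionDataset,
    SyntheticTruth,
    make_spatial_field,
    simulate_expression,
)


@pytest.fixture
def tiny_dataset() -> SpatialExpressionDataset:
    """3 cells x 2 genes with known counts and coordinates."""
    return SpatialExpressionDataset(
        counts=np.array([[1, 0], [2, 3], [0, 1]]),
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
        gene_names=["TF1", "G1"],
    )


@pytest.fixture(scope="session")
def gradient_dataset():
    """400-cell grid where gene trends vary along x only."""
    coords, d, _ = make_spatial_field(400, layout="grid", seed=11)
    truth = SyntheticTruth(trend_scale=1.0, noise_sd=0.1)
    ds = simulate_expression(coords, d, truth, G=10, seed=11)
    return ds, coords, d
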