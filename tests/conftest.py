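"""Shared fixtures: tiny rasters, layouts, and cached synthetic experiments."""

import numpy as np
import pytest
from shapely.geometry import box

from uavfield.geometry import FieldLayout, PlotRecord
from uavfield.raster import RasterLayer
from uavfield.synthetic import (
    SyntheticConfig,
    generate_experiment,
    noiseless_config,
)


def make_layer(values, pixel_size=1.0, x_origin=0.0, y_origin=None, kind="index",
               mask=None):
    values = np.asarray(values, dtype=float)
    if y_origin is None:
        y_origin = values.shape[0] * pixel_size
    return RasterLayer(values=values, x_origin=x_origin, y_origin=y_origin,
                       pixel_size=pixel_size, kind=kind, mask=mask)


@pytest.fixture
def uniform_layer():
    def _make(value, shape=(10, 10), **kw):
        return make_layer(np.full(shape, float(value)), **kw)

    return _make


@pytest.fixture
def two_plot_layout():
    """Two adjacent 2 m x 4 m plots sharing a boundary inside a 10 x 10 field."""
    field = box(0, 0, 10, 10)
    plots = [
        PlotRecord("P1", box(1, 1, 3, 5), row_id="R1"),
        PlotRecord("P2", box(3, 1, 5, 5), row_id="R1"),
    ]
    return FieldLayout(field=field, plots=plots)


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Zero-noise quarter-scale experiment (cached: fully deterministic)."""
    return generate_experiment(noiseless_config())


@pytest.fixture(scope="session")
def default_experiment():
    """Default (noisy) quarter-scale experiment, seed 42."""
    return generate_experiment(SyntheticConfig(random_seed=42))
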