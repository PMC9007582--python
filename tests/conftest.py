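import dataclasses

import numpy as np
import pytest

from ringblot import MembraneLayout, SimulationConfig, SpotModel, build_ring_mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def symmetric_model():
    """Spot model with no shape jitter: circularly symmetric spots."""
    return dataclasses.replace(SpotModel(), shape_jitter=0.0)


@pytest.fixture
def clean_layout():
    """Layout with no placement jitter, flat illumination and no pixel noise."""
    return MembraneLayout(
        placement_jitter=0.0, illumination_amplitude=0.0, noise_sd=0.0
    )


@pytest.fixture
def clean_sim_config(clean_layout, symmetric_model):
    return SimulationConfig(layout=clean_layout, spot_model=symmetric_model)


@pytest.fixture(scope="session")
def default_mask():
    return build_ring_mask(n_rings=6, thickness=6, metric="chebyshev")


def brute_force_ring_means(gray, center, mask):
    """Independent per-pixel accumulation of ring means, row-major order."""
    cy, cx = center
    h = mask.half_width
    buckets = [[] for _ in range(mask.n_rings)]
    for wy in range(mask.span):
        for wx in range(mask.span):
            k = mask.ring_index[wy, wx]
            if k >= 0:
                buckets[k].append(gray[cy - h + wy, cx - h + wx])
    return np.array([np.mean(np.array(b)) for b in buckets])
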