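"""Shared fixtures: phantoms and pipeline runs reused across test modules.

The expensive objects (96-cube noise-free phantom and its full pipeline
result) are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from atriaflow.config import PipelineConfig
from atriaflow.phantom import default_phantom_spec, generate_phantom
from atriaflow.pipeline import run_pipeline


@pytest.fixture(scope="session")
def nf_phantom():
    """Default 96-cube, 2 mm, noise-free phantom (series, truth)."""
    spec = default_phantom_spec(noise_scale=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def nf_result(nf_phantom):
    """Full pipeline result on the noise-free default phantom."""
    series, _ = nf_phantom
    return run_pipeline(series, PipelineConfig())


@pytest.fixture(scope="session")
def small_phantom():
    """64-cube, 3 mm noise-free phantom for cheaper end-to-end checks."""
    spec = default_phantom_spec(grid_n=64, voxel_mm=3.0, noise_scale=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_result(small_phantom):
    series, _ = small_phantom
    return run_pipeline(series, PipelineConfig())


@pytest.fixture(scope="session")
def small_inputs(small_phantom):
    """First-pass maps + clustered input functions on the small phantom."""
    from atriaflow.firstpass import compute_parametric_maps
    from atriaflow.input_functions import cluster_input_functions

    series, truth = small_phantom
    maps = compute_parametric_maps(series)
    inputs = cluster_input_functions(series, maps, seed=0)
    return series, truth, maps, inputs


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / float(denom) if denom else 0.0
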