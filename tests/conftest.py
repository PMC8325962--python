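import numpy as np
import pytest

import pinoquant as pq


@pytest.fixture
def config():
    """Default analysis configuration with an absolute threshold suited to
    the synthetic scenes (between cytoplasm level 20 and membrane 200)."""
    return pq.AnalysisConfig(threshold_method="absolute", absolute_threshold=60.0)


@pytest.fixture
def noise_free_scene():
    """Small deterministic scene without noise, with its ground truth."""
    params = pq.SceneParams(
        seed=42,
        n_vesicles_per_cell=2,
        n_tubules_per_vesicle=(1, 1),
        n_organelles=6,
        noise=pq.NoiseParams(poisson_scale=0.0, read_sigma=0.0),
    )
    return pq.render_scene(params)


@pytest.fixture
def noisy_scene():
    params = pq.SceneParams(seed=7, n_vesicles_per_cell=2,
                            n_tubules_per_vesicle=(1, 2), n_organelles=6)
    return pq.render_scene(params)


def constant_stack(level, shape=(1, 1, 32, 32), **kwargs):
    kwargs.setdefault("frame_interval_s", 3.0)
    return pq.ImageStack(pixels=np.full(shape, float(level)), **kwargs)
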