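import numpy as np
import pytest

import caspaseflow as cf


@pytest.fixture(scope="session")
def default_mix():
    return cf.default_mixing_model()


@pytest.fixture(scope="session")
def small_population():
    """20 deterministic cells with ground truth, plus their config."""
    config = cf.PopulationConfig(n_cells=20, rng_seed=7)
    kinetics, records = cf.simulate_population(config)
    return config, kinetics, records


def normalized_traces(kinetics, config, noise_sd=0.0, seed=None):
    """Render ratio traces and normalize them the way the pipeline does."""
    rendered = cf.render_ratio_traces(
        kinetics,
        frame_interval=config.frame_interval,
        n_frames=config.n_frames,
        noise_sd=noise_sd,
        seed=seed,
        shape=config.shape,
        steepness=config.steepness,
    )
    return {
        sensor: np.stack([trace / trace[:10].mean() for trace in block])
        for sensor, block in rendered.items()
    }
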