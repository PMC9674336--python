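import numpy as np
import pytest

from junctionmap.synthetic import SceneParams, simulate_junction_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_scene():
    """A deterministic 256x256 scene with clusters offset 200 nm from the
    junction line."""
    params = SceneParams(
        seed=7,
        n_clusters=10,
        offset_perp_mean=200.0,
        offset_perp_sd=30.0,
    )
    pair, trace, truth = simulate_junction_scene(params)
    return params, pair, trace, truth


def make_band_pair(f, seed, n_clusters=8, shape=(128, 1024), sd=40.0,
                   min_separation_factor=3.0):
    """Simulated two-protein channel pair with a given shared-center
    fraction, plus its 400-nm band (trace-centered)."""
    from junctionmap.proximity import extract_band
    from junctionmap.synthetic import simulate_pair_with_overlap

    params = SceneParams(
        seed=seed,
        n_clusters=n_clusters,
        offset_perp_mean=0.0,
        offset_perp_sd=sd,
        background=5.0,
        image_shape=shape,
    )
    pair, trace, truth = simulate_pair_with_overlap(
        params, f, min_separation_factor=min_separation_factor
    )
    band = extract_band(pair, trace, 400.0, center_on_reference=False)
    return pair, trace, truth, band
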