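import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_design():
    from spherosynergy.study_design import desk_design

    return desk_design(n_cell_lines=1, n_pairs=2, n_replicates=2)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_design, tmp_path_factory):
    """One small simulated study on disk, shared across read-only tests."""
    from spherosynergy import simulate

    out = tmp_path_factory.mktemp("dataset")
    paths = simulate.generate_dataset(
        tiny_design,
        out,
        render_params=simulate.RenderParams(image_size=64),
        n_empty_wells=4,
        seed=11,
    )
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
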