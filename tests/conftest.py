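import numpy as np
import pytest

from enfacevf.mapping import assign_clusters, build_grid_10_2
from enfacevf.synthetic import SyntheticSpec, render_eye


@pytest.fixture(scope="session")
def grid():
    return build_grid_10_2()


@pytest.fixture(scope="session")
def clustered_grid():
    return assign_clusters(build_grid_10_2())


@pytest.fixture(scope="session")
def clean_case():
    """One noise-free, fully concordant synthetic eye."""
    spec = SyntheticSpec(discordance_prob=0.0, noise_sd=0.0)
    return render_eye(spec, eye_seed=424242)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
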