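import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazescan import CohortSpec, simulate_cohort, tracks_from_dataframes

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_tracks(effect_size=1.0, n_children=15, videos_per_child=2,
                frames=1000, seed=0, **spec_kwargs):
    """Simulated two-cohort track set (equal cohort sizes)."""
    spec = CohortSpec(
        n_children_asd=n_children, n_children_nt=n_children,
        videos_per_child_mean=videos_per_child, videos_per_child_sd=0,
        frames_per_video=frames, effect_size=effect_size, seed=seed,
        **spec_kwargs)
    ann, meta = simulate_cohort(spec)
    return tracks_from_dataframes(ann, meta)


@pytest.fixture(scope="session")
def planted_tracks():
    """30+30 videos with the full planted cohort contrast."""
    return make_tracks(effect_size=1.0, seed=7)


@pytest.fixture(scope="session")
def null_tracks():
    """30+30 videos with identical generative kernels (no contrast)."""
    return make_tracks(effect_size=0.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
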