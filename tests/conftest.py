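import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bitecount import RatioSeries, TraceConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def make_ratio(values, fps=30.0, smoothed=True, video_id="v", participant_id="p"):
    """A ratio series from raw values; smoothed=True marks it as already
    smoothed (window 1) so the detector uses the values verbatim."""
    return RatioSeries(
        video_id=video_id,
        participant_id=participant_id,
        fps=fps,
        ratio=np.asarray(values, dtype=float),
        smoothed=smoothed,
        window=1 if smoothed else None,
    )


@pytest.fixture
def ratio_factory():
    return make_ratio


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Small noise-free annotated cohort: 3 participants x 4 meals, exact
    planted ground truth, so a perfect threshold exists for everyone."""
    return simulate_cohort(
        n_participants=3,
        videos_per_participant=4,
        template=TraceConfig(noise_sd=0.0),
        seed=7,
        mean_bites=14.0,
        sd_bites=3.0,
    )
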