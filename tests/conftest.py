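import numpy as np
import pytest

from socmetrics.synthetic import CohortDesign, SceneConfig


@pytest.fixture
def clean_scene_config():
    """Factory for noise-free, blur-free scene configs."""

    def make(**kwargs):
        defaults = dict(noise_sd=0.0, blur_sigma_px=0.0, seed=0)
        defaults.update(kwargs)
        return SceneConfig(**defaults)

    return make


@pytest.fixture
def small_cohort_design():
    """Factory for quick-to-fit cohort designs (4 days, modest chip counts)."""

    def make(seed=0, n_control=8, n_cocult=12, days=(2, 3, 5, 6), **kwargs):
        d = len(days)
        sd = np.linspace(10.0, 30.0, d)
        idx = np.arange(d)
        cov = 0.5 ** np.abs(idx[:, None] - idx[None, :]) * sd[:, None] * sd[None, :]
        defaults = dict(
            days=tuple(days),
            groups=("control", "co-culture"),
            mean_trajectories={
                "control": tuple(1300.0 + 0.5 * idx),
                "co-culture": tuple(1300.0 - 15.0 * idx),
            },
            covariance=cov,
            n_chips={"control": n_control, "co-culture": n_cocult},
            dropout_schedule=None,
            seed=seed,
        )
        defaults.update(kwargs)
        return CohortDesign(**defaults)

    return make
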