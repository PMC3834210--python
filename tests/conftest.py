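"""Shared fixtures: small synthetic instances that keep the unit tests fast."""

import numpy as np
import pytest

from anechoid import (
    ScenarioConfig,
    SourceSpec,
    TrajectorySet,
    gait_reach_config,
    make_gait_marker_fixture,
    make_mixture_dataset,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_ts(rng):
    """A tiny generic trajectory set (3 channels x 40 samples)."""
    t = np.linspace(0, 1, 40)
    data = np.vstack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t) + 1.0, rng.normal(size=40)])
    return TrajectorySet(data=data, sample_rate=40.0, channel_labels=["a", "b", "c"])


def small_mixture(seed=0, noise=0.0, n_trials=4, n_samples=128):
    """Noise-controllable 2-source gait-reach mixture, small enough for fast fits."""
    cfg = gait_reach_config(n_trials=n_trials, noise_level=noise, seed=seed, n_samples=n_samples)
    return make_mixture_dataset(cfg)


@pytest.fixture()
def noiseless_mixture():
    return small_mixture(seed=0, noise=0.0)


@pytest.fixture()
def single_source_ts():
    """One discrete source, two channels: weight 2.5 and a 17-sample delay."""
    cfg = ScenarioConfig(
        source_specs=[SourceSpec("discrete", {"center": 0.5, "width": 0.08})],
        weight_pattern=np.array([[1.0], [2.5]]),
        delay_mean=np.array([[0.0], [17.0 / 120.0]]),
        delay_sd=np.zeros((2, 1)),
        n_trials=1,
        n_samples=128,
        sample_rate=120.0,
        noise_sigma=0.0,
        seed=0,
    )
    return make_mixture_dataset(cfg)


@pytest.fixture()
def gait_fixture():
    return make_gait_marker_fixture(n_strides=4, cadence=1.25, noise_sigma=0.0, seed=0)
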