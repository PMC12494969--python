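"""Shared fixtures: small seeded synthetic sessions and tensor builders."""

import numpy as np
import pandas as pd
import pytest

from mecmap.synthio import SynthConfig, generate_session


@pytest.fixture(scope="session")
def sm_config() -> SynthConfig:
    """Compact split-maze session: full task structure at reduced scale."""
    return SynthConfig(
        seed=7,
        n_dark=6,
        n_blockA=10,
        n_blockB=10,
        n_alternation=12,
        n_gain=4,
        cell_counts={
            "grid": 3,
            "ngs": 2,
            "speed_pos": 2,
            "speed_neg": 1,
            "fs_in": 1,
            "untuned": 2,
        },
        grid_scales=(60.0, 80.0),
    )


@pytest.fixture(scope="session")
def sm_bundle(sm_config):
    return generate_session(sm_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_frames(
    speed: np.ndarray,
    frame_rate: float = 50.0,
    track_length: float = 400.0,
    start_position: float = 0.0,
) -> pd.DataFrame:
    """Minimal frame table driven by a given speed trace (cm/s)."""
    speed = np.asarray(speed, dtype=float)
    dt = 1.0 / frame_rate
    cum = start_position + np.concatenate([[0.0], np.cumsum(speed[:-1] * dt)])
    lap = np.floor(cum / track_length).astype(int)
    return pd.DataFrame(
        {
            "t": np.arange(speed.shape[0]) * dt,
            "position": cum - lap * track_length,
            "trial": lap - lap.min(),
            "context": "A",
            "trial_type": "vr",
            "speed": speed,
            "lick": 0,
            "reward": 0,
            "reward_start": np.nan,
            "reward_end": np.nan,
        }
    )


def make_two_map_tensor(
    n_trials: int = 40,
    n_bins: int = 40,
    n_cells: int = 10,
    n_maps: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
    labels: np.ndarray | None = None,
):
    """Discrete multi-map tensor: per-trial centroid + Gaussian noise.

    Returns (X, labels, centroids) with well-separated smooth centroids.
    """
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter1d

    centroids = gaussian_filter1d(
        rng.uniform(0.0, 1.0, size=(n_maps, n_bins, n_cells)), 3.0, axis=1
    )
    # push centroids apart so maps are unambiguous
    for r in range(n_maps):
        centroids[r] = np.roll(centroids[r], r * (n_bins // n_maps), axis=0)
    if labels is None:
        labels = rng.integers(0, n_maps, size=n_trials)
        for r in range(n_maps):  # guarantee every map occurs
            labels[r] = r
    X = centroids[labels] + rng.normal(0.0, noise_sd, size=(n_trials, n_bins, n_cells))
    return X, labels, centroids
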