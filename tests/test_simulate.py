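"""Synthetic trajectory generator: closed forms, determinism, bookkeeping."""

from dataclasses import replace

import numpy as np
import pytest

from trajseg import Trajectory, separable_preset, simulate_dataset, write_trajectories
from trajseg.exceptions import ConfigurationError, ValidationError
from trajseg.simulate import (
    MotionParams,
    SimulationConfig,
    dataset_summary,
    hard_preset,
    simulate_trajectory,
)


def _single_state(state, motion, **kwargs):
    return replace(separable_preset(**kwargs), states=(state,), motion=motion)


def test_stalled_track_is_constant():
    cfg = _single_state("stalled", MotionParams(sigma_loc=0.0))
    t = simulate_trajectory(cfg, np.random.default_rng(0), length=9)
    np.testing.assert_array_equal(t.coords, np.tile(t.coords[0], (9, 1)))
    assert (t.labels == 0).all()


def test_directed_noiseless_track_matches_closed_form():
    cfg = _single_state(
        "directed", MotionParams(v=1.0, sigma_phi=0.0, sigma_loc=0.0, heading=0.0)
    )
    t = simulate_trajectory(cfg, np.random.default_rng(0), length=5)
    np.testing.assert_allclose(t.coords[:, 0], [0, 1, 2, 3, 4], atol=1e-12)
    np.testing.assert_allclose(t.coords[:, 1], 0.0, atol=1e-12)
    assert (t.labels == 1).all()


def test_brownian_msd_matches_diffusion_law():
    """2D random walk with per-axis step std σ has MSD(τ) = 2 σ² τ."""
    sigma = 0.25
    cfg = _single_state("brownian", MotionParams(sigma_b=sigma, sigma_loc=0.0))
    t = simulate_trajectory(cfg, np.random.default_rng(7), length=10_000)
    for tau in (1, 2, 5, 10):
        d = t.coords[tau:] - t.coords[:-tau]
        msd = float((d**2).sum(axis=1).mean())
        assert msd == pytest.approx(2 * sigma**2 * tau, rel=0.15)
    assert (t.labels == 0).all()


def test_directed_mean_step_length_approaches_speed():
    cfg = _single_state("directed", MotionParams(v=0.8, sigma_phi=0.3, sigma_loc=0.0))
    t = simulate_trajectory(cfg, np.random.default_rng(1), length=5_000)
    steps = np.linalg.norm(np.diff(t.coords, axis=0), axis=1)
    assert steps.mean() == pytest.approx(0.8, rel=0.02)


def test_confined_track_stays_near_anchor():
    cfg = _single_state(
        "confined", MotionParams(kappa=0.5, sigma_c=0.25, sigma_loc=0.0)
    )
    t = simulate_trajectory(cfg, np.random.default_rng(2), length=5_000)
    # OU stationary std per axis = sigma_c / sqrt(1 - (1-kappa)^2)
    expected_std = 0.25 / np.sqrt(1 - 0.25)
    spread = t.coords[100:].std(axis=0)
    np.testing.assert_allclose(spread, expected_std, rtol=0.15)


def test_labels_follow_true_state(rng):
    from trajseg.simulate import STATE_LABEL, STATES

    assert STATE_LABEL["directed"] == 1
    assert all(STATE_LABEL[s] == 0 for s in STATES if s != "directed")
    cfg = separable_preset(n_tracks=30, seed=3)
    trajs, _ = simulate_dataset(cfg)
    labs = np.concatenate([t.labels for t in trajs])
    assert set(np.unique(labs)) <= {0, 1}


def test_seeded_dataset_is_byte_reproducible(tmp_path):
    cfg = separable_preset(n_tracks=15, seed=9)
    for name in ("a.csv", "b.csv"):
        trajs, _ = simulate_dataset(cfg)
        write_trajectories(trajs, tmp_path / name)
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_length_bounds_honoured():
    cfg = separable_preset(n_tracks=300, seed=4)
    trajs, _ = simulate_dataset(cfg)
    lengths = np.array([len(t) for t in trajs])
    assert lengths.min() >= 5
    assert lengths.max() <= 135
    # skew toward short tracks
    assert np.median(lengths) < lengths.mean() + 5
    assert (lengths <= 20).mean() > 0.3


def test_class_balance_near_stationary_expectation():
    """The default symmetric switching process has a uniform stationary
    distribution over 4 states, so about 25% of points are 'moving'."""
    cfg = separable_preset(n_tracks=400, seed=5)
    trajs, _ = simulate_dataset(cfg)
    summary = dataset_summary(trajs)
    assert summary["moving_fraction"] == pytest.approx(0.25, abs=0.05)


def test_split_is_disjoint_by_trajectory():
    cfg = separable_preset(n_tracks=20, seed=6)
    train, test = simulate_dataset(cfg, n_test=5)
    assert len(train) == 15 and len(test) == 5
    assert not ({t.track_id for t in train} & {t.track_id for t in test})


def test_invalid_split_rejected():
    with pytest.raises(ValidationError):
        simulate_dataset(separable_preset(n_tracks=3), n_test=3)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(min_length=0),
        dict(max_length=3, min_length=5),
        dict(mean_dwell=0.5),
        dict(states=("warp",)),
        dict(transition_matrix=((0.5, 0.6), (0.5, 0.4)), states=("directed", "brownian")),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        replace(SimulationConfig(), **kwargs)


def test_hard_preset_overlaps_step_statistics():
    cfg = hard_preset()
    assert cfg.motion.v == pytest.approx(0.4)
    assert cfg.motion.sigma_b == pytest.approx(0.3)
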