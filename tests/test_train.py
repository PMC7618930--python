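"""Training-set assembly, the cross-entropy loss, and the Adam loop."""

import numpy as np
import pytest

from trajseg import TrainConfig, Trajectory, WindowSpec
from trajseg.exceptions import ConfigurationError, ValidationError
from trajseg.train import bce_loss, build_training_set, train

from conftest import make_trajectory


# -- dataset assembly --------------------------------------------------------


def _labelled(rng, L, track_id="t"):
    return make_trajectory(rng, L, track_id=track_id)


@pytest.mark.parametrize("L,expected", [(8, 1), (12, 3)])
def test_single_track_window_count(rng, L, expected):
    feats, labels, masks = build_training_set([_labelled(rng, L)], WindowSpec())
    assert feats.shape == (expected, 2, 8)
    assert labels.shape == masks.shape == (expected, 8)


def test_ten_short_tracks_give_ten_samples(rng):
    trajs = [_labelled(rng, 5, f"t{i}") for i in range(10)]
    feats, _, masks = build_training_set(trajs, WindowSpec())
    assert feats.shape[0] == 10
    np.testing.assert_array_equal(masks[:, 5:], False)


def test_total_window_count_matches_per_track_oracle(rng):
    """Σ over tracks of the enumeration count equals the dataset size (the
    trajectories -> samples bookkeeping)."""
    from trajseg.windows import enumerate_windows

    lengths = [5, 6, 8, 9, 17, 40, 133]
    trajs = [_labelled(rng, L, f"t{L}") for L in lengths]
    feats, _, _ = build_training_set(trajs, WindowSpec())
    expected = sum(
        len(enumerate_windows(max(L, 8), WindowSpec())) for L in lengths
    )
    assert feats.shape[0] == expected


def test_unlabelled_track_rejected(rng):
    t = make_trajectory(rng, 10, track_id="naked", labelled=False)
    with pytest.raises(ValidationError, match="naked"):
        build_training_set([t], WindowSpec())


# -- loss --------------------------------------------------------------------


def test_loss_zero_for_perfect_prediction():
    y = np.array([[0.0, 1.0, 1.0, 0.0]])
    p = np.where(y == 1, 1 - 1e-9, 1e-9)
    loss, _ = bce_loss(p, y)
    assert loss == pytest.approx(0.0, abs=1e-7)


def test_loss_half_probability_is_ln2():
    p = np.full((3, 8), 0.5)
    y = np.zeros((3, 8))
    loss, _ = bce_loss(p, y)
    assert loss == pytest.approx(np.log(2), rel=1e-12)


def test_loss_matches_hand_computed_example():
    # two points: y=1 with p=0.8 and y=0 with p=0.3
    # -(ln 0.8 + ln 0.7) / 2 computed independently by hand:
    #   ln 0.8 = -0.2231435513, ln 0.7 = -0.3566749439
    #   loss = (0.2231435513 + 0.3566749439) / 2 = 0.2899092476
    p = np.array([[0.8, 0.3]])
    y = np.array([[1.0, 0.0]])
    loss, _ = bce_loss(p, y)
    assert loss == pytest.approx(0.2899092476, abs=1e-9)


def test_loss_mask_excludes_points():
    p = np.array([[0.5, 0.99]])
    y = np.array([[0.0, 0.0]])
    loss, grad = bce_loss(p, y, mask=np.array([[True, False]]))
    assert loss == pytest.approx(np.log(2), rel=1e-12)
    assert grad[0, 1] == 0.0


def test_loss_finite_at_saturated_predictions():
    loss, grad = bce_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))
    assert np.isfinite(loss) and np.all(np.isfinite(grad))


def test_loss_gradient_matches_finite_difference():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.05, 0.95, size=(2, 4))
    y = rng.integers(0, 2, size=(2, 4)).astype(float)
    _, grad = bce_loss(p, y)
    eps = 1e-7
    for i in range(2):
        for j in range(4):
            pp = p.copy()
            pp[i, j] += eps
            lp, _ = bce_loss(pp, y)
            pp[i, j] -= 2 * eps
            lm, _ = bce_loss(pp, y)
            assert (lp - lm) / (2 * eps) == pytest.approx(grad[i, j], rel=1e-5)


# -- config guards and determinism -------------------------------------------


@pytest.mark.parametrize(
    "kwargs", [dict(epochs=0), dict(learning_rate=0.0), dict(batch_size=0)]
)
def test_train_config_guards(kwargs):
    with pytest.raises(ConfigurationError):
        TrainConfig(**kwargs)


def test_same_seed_same_loss_history(rng):
    trajs = [_labelled(rng, L, f"t{L}") for L in (10, 15, 22)]
    feats, labels, masks = build_training_set(trajs, WindowSpec())
    cfg = TrainConfig(epochs=3, seed=4)
    _, h1 = train(feats, labels, masks, cfg)
    _, h2 = train(feats, labels, masks, cfg)
    assert h1 == h2
    _, h3 = train(feats, labels, masks, TrainConfig(epochs=3, seed=5))
    assert h1 != h3


def test_artifact_embeds_preprocessing_metadata(rng):
    trajs = [_labelled(rng, 12)]
    spec = WindowSpec()
    feats, labels, masks = build_training_set(trajs, spec, "cartesian")
    cfg = TrainConfig(epochs=1, coord_system="cartesian")
    artifact, history = train(feats, labels, masks, cfg, window_spec=spec)
    assert artifact.training_meta["coord_system"] == "cartesian"
    assert artifact.training_meta["window_spec"] == spec.to_dict()
    assert len(history) == 1
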