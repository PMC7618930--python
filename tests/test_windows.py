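"""Sliding-window preprocessing: padding, placement, normalisation, polar."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trajseg import Trajectory, WindowSpec
from trajseg.exceptions import ConfigurationError, ValidationError
from trajseg.windows import (
    build_features,
    enumerate_windows,
    normalize_window,
    pad_trajectory,
    to_polar,
)

finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


def brute_force_contributors(L, spec):
    """Independent oracle: for each point of a padded trajectory, the set of
    windows contributing to it, derived point-by-point from the stitching
    rule (centre block of every window; extended to the edge for the first
    and last windows)."""
    starts = []
    s = 0
    while s <= L - spec.W:
        starts.append(s)
        s += spec.step
    if starts[-1] != L - spec.W:
        starts.append(L - spec.W)
    c0 = (spec.W - spec.center_len) // 2
    c1 = c0 + spec.center_len
    contributors = {p: set() for p in range(L)}
    for wi, start in enumerate(starts):
        for offset in range(spec.W):
            in_center = c0 <= offset < c1
            in_first = wi == 0 and offset < c0
            in_last = wi == len(starts) - 1 and offset >= c1
            if in_center or in_first or in_last:
                contributors[start + offset].add(wi)
    return starts, contributors


# -- padding ----------------------------------------------------------------


def test_pad_short_track_repeats_last_point():
    coords = np.arange(10, dtype=float).reshape(5, 2)
    labels = np.array([1, 1, 0, 0, 1])
    padded, mask, plab = pad_trajectory(coords, 8, labels)
    assert padded.shape == (8, 2)
    np.testing.assert_array_equal(padded[5:], np.tile(coords[-1], (3, 1)))
    np.testing.assert_array_equal(mask, [True] * 5 + [False] * 3)
    np.testing.assert_array_equal(plab, [1, 1, 0, 0, 1, 0, 0, 0])


def test_pad_noop_when_long_enough():
    coords = np.zeros((8, 2))
    padded, mask, _ = pad_trajectory(coords, 8)
    assert padded is coords
    assert mask.all()


def test_pad_single_point():
    coords = np.array([[3.0, 4.0]])
    padded, mask, _ = pad_trajectory(coords, 8)
    np.testing.assert_array_equal(padded, np.tile([3.0, 4.0], (8, 1)))
    np.testing.assert_array_equal(mask, [True] + [False] * 7)


def test_pad_idempotent():
    coords = np.random.default_rng(0).normal(size=(5, 2))
    once, _, _ = pad_trajectory(coords, 8)
    twice, mask, _ = pad_trajectory(once, 8)
    np.testing.assert_array_equal(once, twice)
    assert mask.all()  # already length W, nothing flagged


def test_pad_rejects_bad_window():
    with pytest.raises(ConfigurationError):
        pad_trajectory(np.zeros((3, 2)), 0)


# -- window spec and enumeration --------------------------------------------


def test_default_spec_matches_quarter_stride_half_center():
    spec = WindowSpec()
    assert (spec.W, spec.step, spec.center_len, spec.center_start) == (8, 2, 4, 2)


@pytest.mark.parametrize(
    "kwargs",
    [dict(W=3), dict(W=8, step=0), dict(W=8, step=9),
     dict(W=8, center_fraction=0.0), dict(W=8, step=4, center_fraction=0.25)],
)
def test_invalid_specs_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        WindowSpec(**kwargs)


def test_single_window_weights_all_positions():
    (start, mask), = enumerate_windows(8, WindowSpec())
    assert start == 0
    assert mask.all()


@pytest.mark.parametrize("L,expected", [(12, [0, 2, 4]), (11, [0, 2, 3])])
def test_start_snapping(L, expected):
    starts = [s for s, _ in enumerate_windows(L, WindowSpec())]
    assert starts == expected


def test_enumerate_requires_padded_input():
    with pytest.raises(ValidationError):
        enumerate_windows(5, WindowSpec())


@pytest.mark.parametrize("L", range(8, 201))
def test_weight_masks_match_brute_force_oracle(L):
    """Window placement + stitching weights agree with the point-by-point
    oracle, and every point has at least one contributor."""
    spec = WindowSpec()
    windows = enumerate_windows(L, spec)
    oracle_starts, oracle = brute_force_contributors(L, spec)
    assert [s for s, _ in windows] == oracle_starts
    got = {p: set() for p in range(L)}
    for wi, (start, mask) in enumerate(windows):
        for offset in np.flatnonzero(mask):
            got[start + offset].add(wi)
    assert got == oracle
    assert all(got[p] for p in range(L))


# -- normalisation and polar conversion --------------------------------------


def test_normalize_hand_case():
    out = normalize_window(np.array([[3.0, 4.0], [4.0, 4.0]]))
    np.testing.assert_array_equal(out, [[0.0, 0.0], [1.0, 0.0]])


def test_normalize_constant_track_is_zero():
    out = normalize_window(np.tile([7.0, -2.0], (6, 1)))
    np.testing.assert_array_equal(out, np.zeros((6, 2)))


@given(
    coords=st.lists(st.tuples(finite, finite), min_size=2, max_size=16),
    offset=st.tuples(finite, finite),
)
def test_normalize_translation_invariant(coords, offset):
    coords = np.asarray(coords)
    shifted = coords + np.asarray(offset)
    np.testing.assert_allclose(
        normalize_window(shifted), normalize_window(coords), atol=1e-6
    )


def test_polar_unit_axes_and_origin():
    out = to_polar(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
    np.testing.assert_allclose(
        out, [[0.0, 0.0], [1.0, 0.0], [1.0, np.pi / 2]], atol=1e-15
    )


@given(coords=st.lists(st.tuples(finite, finite), min_size=1, max_size=16))
def test_polar_round_trip(coords):
    d = np.asarray(coords)
    rt = to_polar(d)
    back = np.column_stack([rt[:, 0] * np.cos(rt[:, 1]), rt[:, 0] * np.sin(rt[:, 1])])
    assert np.max(np.abs(back - d)) < 1e-9 * max(1.0, np.max(np.abs(d)))
    assert (rt[:, 0] >= 0).all()
    assert ((rt[:, 1] > -np.pi) & (rt[:, 1] <= np.pi)).all()


# -- feature assembly --------------------------------------------------------


def _track(rng, L):
    return Trajectory("t", np.arange(L), rng.normal(size=(L, 2)))


@pytest.mark.parametrize("L,n_windows", [(5, 1), (8, 1), (12, 3), (20, 7)])
def test_window_counts(rng, L, n_windows):
    assert len(build_features(_track(rng, L), WindowSpec())) == n_windows


@pytest.mark.parametrize("coord_system", ["cartesian", "polar"])
def test_first_feature_row_is_origin(rng, coord_system):
    for w in build_features(_track(rng, 30), WindowSpec(), coord_system):
        np.testing.assert_array_equal(w.features[:, 0], [0.0, 0.0])


def test_features_translation_invariant(rng):
    t = _track(rng, 25)
    shifted = t.translated((123.4, -56.7))
    for a, b in zip(
        build_features(t, WindowSpec(), "polar"),
        build_features(shifted, WindowSpec(), "polar"),
    ):
        np.testing.assert_allclose(a.features, b.features, atol=1e-9)


def test_cartesian_x_equals_polar_r_for_axis_aligned_motion():
    coords = np.column_stack([np.arange(8.0), np.zeros(8)])
    t = Trajectory("ax", np.arange(8), coords)
    (cart,) = build_features(t, WindowSpec(), "cartesian")
    (pol,) = build_features(t, WindowSpec(), "polar")
    np.testing.assert_allclose(pol.features[0], cart.features[0], atol=1e-12)


def test_padded_window_labels_not_moving(rng):
    t = Trajectory("p", np.arange(5), rng.normal(size=(5, 2)),
                   labels=np.ones(5, dtype=int))
    (w,) = build_features(t, WindowSpec())
    np.testing.assert_array_equal(w.labels, [1] * 5 + [0] * 3)
    np.testing.assert_array_equal(w.valid_mask, [True] * 5 + [False] * 3)


def test_unknown_coord_system_rejected(rng):
    with pytest.raises(ConfigurationError):
        build_features(_track(rng, 10), WindowSpec(), "spherical")
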