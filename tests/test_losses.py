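"""Losses: class weights, GenDice, the depth-gradient mask, and GWDice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from marginseg.losses import (
    class_weights,
    gen_dice_loss,
    gradient_weight_mask,
    gw_dice_loss,
    to_two_channel,
)

from conftest import blob_mask, random_mask


# -- independent scalar-loop oracles ----------------------------------------


def _weights_oracle(g, eps):
    return [1.0 / (sum(g[k].ravel()) ** 2 + eps) for k in (0, 1)]


def gen_dice_oracle(mask, probs, eps=1e-8):
    g = to_two_channel(mask)
    p = [1.0 - probs, probs]
    w = _weights_oracle(g, eps)
    num = den = 0.0
    for k in (0, 1):
        for i in range(mask.shape[0]):
            for j in range(mask.shape[1]):
                num += w[k] * g[k][i, j] * p[k][i, j]
                den += w[k] * (g[k][i, j] + p[k][i, j])
    return 1.0 - 2.0 * num / (den + eps)


def algo1_oracle(mask):
    """Literal double-loop transcription of the weight-mask pseudocode."""
    g = to_two_channel(mask)
    t = np.zeros_like(g)
    fg_rows = [x for x in range(mask.shape[0]) if any(g[1][x, y] == 1 for y in range(mask.shape[1]))]
    min_m, max_m = min(fg_rows), max(fg_rows)
    for x in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            t[0][x, y] = g[0][x, y]
            if g[1][x, y] == 1:
                if max_m == min_m:
                    t[1][x, y] = 1.0
                else:
                    t[1][x, y] = ((x - max_m) / (max_m - min_m)) ** 2
            else:
                t[1][x, y] = 0.0
    return t


def gw_dice_oracle(mask, t, probs, eps=1e-8):
    g = to_two_channel(mask)
    p = [1.0 - probs, probs]
    w = _weights_oracle(g, eps)
    num = den = 0.0
    for k in (0, 1):
        for i in range(mask.shape[0]):
            for j in range(mask.shape[1]):
                num += w[k] * g[k][i, j] * t[k][i, j] * p[k][i, j]
                den += w[k] * (t[k][i, j] + p[k][i, j])
    return 1.0 - 2.0 * num / (den + eps)


# -- class weights -----------------------------------------------------------


def test_class_weights_inverse_squared_areas():
    mask = np.zeros((4, 4))
    mask[1:3, 1:3] = 1  # 4 tumor px, 12 background px
    w = class_weights(mask, epsilon=0.0)
    assert w.foreground == pytest.approx(1 / 16)
    assert w.background == pytest.approx(1 / 144)


def test_class_weights_empty_class_is_finite_and_warns():
    with pytest.warns(UserWarning, match="empty"):
        w = class_weights(np.zeros((4, 4)), epsilon=1e-8)
    assert w.foreground == pytest.approx(1e8)
    assert np.isfinite(w.foreground)


def test_class_weights_equal_areas_equal_weights():
    mask = np.zeros((4, 4))
    mask[:2] = 1  # 8 px each class
    w = class_weights(mask)
    assert w.foreground == pytest.approx(w.background)


# -- generalized Dice loss ----------------------------------------------------


def test_gen_dice_perfect_and_complement(rng):
    mask = random_mask(rng)
    mask[0, 0] = 0  # both classes present
    assert gen_dice_loss(mask, mask.astype(float)) == pytest.approx(0.0, abs=1e-6)
    assert gen_dice_loss(mask, 1.0 - mask.astype(float)) == pytest.approx(1.0, abs=1e-6)


def test_gen_dice_matches_scalar_oracle(rng):
    for _ in range(20):
        mask = random_mask(rng)
        probs = rng.random((8, 8))
        assert gen_dice_loss(mask, probs) == pytest.approx(gen_dice_oracle(mask, probs), abs=1e-6)


def test_gen_dice_shape_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        gen_dice_loss(np.ones((4, 4)), np.ones((4, 5)) * 0.5)


def test_gen_dice_bounded(rng):
    for _ in range(20):
        mask = random_mask(rng)
        loss = gen_dice_loss(mask, rng.random((8, 8)))
        assert -1e-9 <= loss <= 1 + 1e-9


# -- gradient weight mask ------------------------------------------------------


def test_gradient_weights_quadratic_profile():
    # tumor spanning rows 2..6: top weight 1, mid 0.25, bottom 0
    mask = blob_mask((8, 8), 2, 7, 1, 6)
    gwm = gradient_weight_mask(mask)
    assert gwm.tumor_row_extent == (2, 6)
    assert gwm.foreground[2, 3] == pytest.approx(1.0)
    assert gwm.foreground[4, 3] == pytest.approx(0.25)
    assert gwm.foreground[6, 3] == pytest.approx(0.0)


def test_gradient_weights_single_row_tumor():
    mask = blob_mask((8, 8), 3, 4, 1, 6)
    gwm = gradient_weight_mask(mask)
    assert np.all(gwm.foreground[mask > 0] == 1.0)


def test_gradient_weights_match_double_loop_oracle(rng):
    for _ in range(20):
        mask = random_mask(rng)
        expected = algo1_oracle(mask)
        got = gradient_weight_mask(mask).channels
        np.testing.assert_array_equal(got, expected)


def test_gradient_weights_background_copied_and_zero_outside(rng):
    mask = random_mask(rng)
    gwm = gradient_weight_mask(mask)
    np.testing.assert_array_equal(gwm.channels[0], to_two_channel(mask)[0])
    assert np.all(gwm.foreground[mask == 0] == 0.0)


def test_gradient_weights_non_increasing_with_depth(rng):
    mask = random_mask(rng, shape=(12, 12))
    fg = gradient_weight_mask(mask).foreground
    for col in range(12):
        vals = fg[mask[:, col] > 0, col]
        assert np.all(np.diff(vals) <= 1e-12)


def test_gradient_weights_empty_foreground_raises():
    with pytest.raises(ValueError, match="no tumor"):
        gradient_weight_mask(np.zeros((4, 4)))


def test_gradient_weights_baseline_and_scale():
    mask = blob_mask((8, 8), 2, 7, 1, 6)
    uniform = gradient_weight_mask(mask, baseline=1.0)
    np.testing.assert_array_equal(uniform.channels, to_two_channel(mask))
    prose = gradient_weight_mask(mask, baseline=0.5, scale=2.0)
    assert prose.foreground[2, 3] == pytest.approx(2.0)  # top doubled
    assert prose.foreground[6, 3] == pytest.approx(1.0)  # bottom keeps Dice weight


# -- gradient-weighted Dice loss ----------------------------------------------


def test_gw_dice_reduces_to_gen_dice_with_uniform_weights(rng):
    for _ in range(5):
        mask = random_mask(rng)
        probs = rng.random((8, 8))
        uniform = gradient_weight_mask(mask, baseline=1.0)
        assert gw_dice_loss(mask, uniform, probs) == pytest.approx(
            gen_dice_loss(mask, probs), abs=1e-9
        )


def test_gw_dice_matches_scalar_oracle(rng):
    for _ in range(20):
        mask = random_mask(rng)
        probs = rng.random((8, 8))
        gwm = gradient_weight_mask(mask)
        assert gw_dice_loss(mask, gwm, probs) == pytest.approx(
            gw_dice_oracle(mask, gwm.channels, probs), abs=1e-6
        )


def test_gw_dice_penalizes_top_miss_more_than_bottom_miss():
    # equal-Dice predictions: one missing the top 3 tumor rows, one the bottom 3
    mask = blob_mask((16, 16), 4, 13, 3, 13)
    gwm = gradient_weight_mask(mask)
    top_miss = mask.astype(float).copy()
    top_miss[4:7] = 0
    bottom_miss = mask.astype(float).copy()
    bottom_miss[10:13] = 0
    assert gw_dice_loss(mask, gwm, top_miss) > gw_dice_loss(mask, gwm, bottom_miss)
    assert gen_dice_loss(mask, top_miss) == pytest.approx(
        gen_dice_loss(mask, bottom_miss), abs=1e-9
    )


@pytest.mark.filterwarnings("ignore:.*class is empty")
@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    mask=hnp.arrays(np.uint8, (6, 6), elements=st.integers(0, 1)),
    probs=hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)),
)
def test_loss_invariants_hold_for_arbitrary_inputs(mask, probs):
    """GenDice stays in [0,1]; GWDice with uniform weights equals GenDice;
    the weight field is bounded by [0,1] and zero off the tumor."""
    loss = gen_dice_loss(mask, probs)
    assert -1e-9 <= loss <= 1 + 1e-9
    if mask.any():
        gwm = gradient_weight_mask(mask)
        assert gwm.foreground.max() <= 1.0 and gwm.foreground.min() >= 0.0
        assert np.all(gwm.foreground[mask == 0] == 0.0)
        uniform = gradient_weight_mask(mask, baseline=1.0)
        assert gw_dice_loss(mask, uniform, probs) == pytest.approx(loss, abs=1e-9)


def test_loss_gradients_match_finite_differences(rng):
    mask = random_mask(rng)
    probs = np.clip(rng.random((8, 8)), 0.05, 0.95)
    gwm = gradient_weight_mask(mask)
    cases = [
        lambda p, g=False: gen_dice_loss(mask, p, return_grad=g),
        lambda p, g=False: gw_dice_loss(mask, gwm, p, return_grad=g),
    ]
    for fn in cases:
        _, grad = fn(probs, True)
        step = 1e-4
        for i, j in [(0, 0), (3, 4), (7, 7), (2, 6)]:
            up = probs.copy()
            up[i, j] += step
            dn = probs.copy()
            dn[i, j] -= step
            fd = (fn(up) - fn(dn)) / (2 * step)
            assert grad[i, j] == pytest.approx(fd, abs=1e-3)
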