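"""Loss terms: analytic examples, zero cases, invariances, differentiability."""

import itertools

import numpy as np
import pytest

from microsr.imaging import average_pool_downsample, nearest_upsample
from microsr.losses import (
    LossWeights,
    SSIMConstants,
    adversarial_loss_d,
    adversarial_loss_g,
    adversarial_losses,
    cycle_loss,
    downsample_loss,
    mmsr_loss,
    ssim_global,
    ssim_loss,
    total_loss,
    upsample_loss,
)
from microsr.nn import Tensor


def _moment_ssim(a, b, c1, c2):
    """Independent oracle: SSIM from raw moments, coded separately."""
    mu_a, mu_b = a.mean(), b.mean()
    va, vb = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
    )


# --------------------------------------------------------------------- SSIM


def test_ssim_self_comparison_is_one(rng):
    for x in [rng.uniform(-1, 1, (8, 8)), np.full((4, 4), 0.3)]:
        assert ssim_global(x, x) == pytest.approx(1.0, abs=1e-12)


def test_ssim_symmetry_and_upper_bound(rng):
    for _ in range(5):
        a, b = rng.uniform(-1, 1, (6, 6)), rng.uniform(-1, 1, (6, 6))
        assert ssim_global(a, b) == pytest.approx(ssim_global(b, a), abs=1e-12)
        assert ssim_global(a, b) <= 1.0


def test_ssim_hand_computed_example():
    """mu = 0.5 both, var = 0.25 both, cov = 0 at L=1:
    value = C2 / (0.5 + C2) = 0.0009 / 0.5009."""
    a = np.array([[0.0, 0.0], [1.0, 1.0]])
    b = np.array([[0.0, 1.0], [0.0, 1.0]])
    c = SSIMConstants(data_range=1.0)
    expect = 0.0009 / 0.5009
    assert ssim_global(a, b, c) == pytest.approx(expect, rel=1e-9)
    assert expect == pytest.approx(0.001797, abs=1e-6)


def test_ssim_matches_moment_oracle(rng):
    c = SSIMConstants()
    for _ in range(5):
        a, b = rng.uniform(-1, 1, (8, 8)), rng.uniform(-1, 1, (8, 8))
        assert ssim_global(a, b, c) == pytest.approx(
            _moment_ssim(a, b, c.c1, c.c2), abs=1e-12
        )


def test_ssim_shape_mismatch_raises(rng):
    with pytest.raises(ValueError, match="mismatch"):
        ssim_global(np.zeros((4, 4)), np.zeros((5, 5)))


# ---------------------------------------------------------------- SSIM loss


def test_ssim_loss_zero_when_sr_is_nearest_upsample(rng):
    x = rng.uniform(-1, 1, (4, 4))
    assert ssim_loss(x, nearest_upsample(x, 2)) == pytest.approx(0.0, abs=1e-12)


def test_ssim_loss_second_form_zero_on_constant(rng):
    y = np.full((8, 8), 0.4)
    y_lr = average_pool_downsample(y, 2)
    assert ssim_loss(y, y_lr) == pytest.approx(0.0, abs=1e-12)


def test_ssim_loss_matches_moment_oracle_on_random_pairs(rng):
    c = SSIMConstants()
    x = rng.uniform(-1, 1, (4, 4))
    x_sr = rng.uniform(-1, 1, (8, 8))
    expect = 1.0 - _moment_ssim(x, average_pool_downsample(x_sr, 2), c.c1, c.c2)
    assert ssim_loss(x, x_sr, c) == pytest.approx(expect, abs=1e-12)
    assert 0.0 <= ssim_loss(x, x_sr) <= 2.0


def test_ssim_loss_incompatible_sizes_raise(rng):
    with pytest.raises(ValueError, match="incompatible"):
        ssim_loss(np.zeros((4, 4)), np.zeros((6, 6)))


# ------------------------------------------------- downsample/upsample loss


def test_downsample_loss_examples(rng):
    assert downsample_loss(np.array([[0.5]]), np.full((2, 2), 0.5)) == 0.0
    assert downsample_loss(np.array([[0.0]]), np.full((2, 2), 1.0)) == pytest.approx(1.0)
    x, x_sr = rng.uniform(-1, 1, (3, 3)), rng.uniform(-1, 1, (6, 6))
    base = downsample_loss(x, x_sr)
    assert downsample_loss(0.5 * x, 0.5 * x_sr) == pytest.approx(0.25 * base, rel=1e-9)
    assert base >= 0.0


def test_upsample_loss_examples(rng):
    assert upsample_loss(np.full((4, 4), 0.2), np.array([[0.2]])) == pytest.approx(0.0)
    y = np.array([[0.0, 1.0], [0.0, 1.0]])
    assert upsample_loss(y, np.array([[0.5]])) == pytest.approx(0.25)
    # agrees with a direct formula oracle on random pairs
    y = rng.uniform(-1, 1, (6, 6))
    y_lr = rng.uniform(-1, 1, (3, 3))
    expect = ((y - nearest_upsample(y_lr, 2)) ** 2).mean()
    assert upsample_loss(y, y_lr) == pytest.approx(expect, abs=1e-12)


def test_pixelwise_losses_see_only_pooled_sr(rng):
    """Permuting sub-pixels within each 2x2 block of x_sr leaves L_S and L_D
    unchanged — both observe only f-down(x_sr).  Exhaustive for s=2."""
    x = rng.uniform(-1, 1, (2, 2))
    x_sr = rng.uniform(-1, 1, (4, 4))
    base = (ssim_loss(x, x_sr), downsample_loss(x, x_sr))
    for perm in itertools.permutations(range(4)):
        shuffled = x_sr.copy()
        for by in range(2):
            for bx in range(2):
                block = x_sr[2 * by : 2 * by + 2, 2 * bx : 2 * bx + 2].ravel()
                shuffled[2 * by : 2 * by + 2, 2 * bx : 2 * bx + 2] = (
                    block[list(perm)].reshape(2, 2)
                )
        assert ssim_loss(x, shuffled) == pytest.approx(base[0], abs=1e-12)
        assert downsample_loss(x, shuffled) == pytest.approx(base[1], abs=1e-12)


# ------------------------------------------------------------- adversarial


def test_lsgan_generator_and_discriminator_values():
    ones = np.ones((3, 3))
    assert adversarial_loss_g(ones) == pytest.approx(0.0)
    half = np.full((3, 3), 0.5)
    assert adversarial_loss_d(half, half) == pytest.approx(0.25)
    # generator loss decreases monotonically as D(fake) -> 1
    losses = [adversarial_loss_g(np.full((2, 2), v)) for v in (0.0, 0.5, 0.9, 1.0)]
    assert all(a > b for a, b in zip(losses, losses[1:]))


def test_adversarial_role_dispatch_and_validation(rng):
    r, f = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
    assert adversarial_losses(r, f, "generator") == adversarial_loss_g(f)
    assert adversarial_losses(r, f, "discriminator") == adversarial_loss_d(r, f)
    with pytest.raises(ValueError, match="role"):
        adversarial_losses(r, f, "critic")
    with pytest.raises(ValueError, match="non-finite"):
        adversarial_loss_g(np.array([[np.inf]]))


def test_bce_mode_available(rng):
    f = rng.normal(size=(3, 3))
    assert adversarial_loss_g(f, mode="bce") >= 0.0
    assert adversarial_loss_d(f, f, mode="bce") >= 0.0


# -------------------------------------------------------------------- cycle


def test_cycle_loss_examples(rng):
    x = rng.uniform(-1, 1, (3, 3))
    y = rng.uniform(-1, 1, (6, 6))
    assert cycle_loss(x, x, y, y) == pytest.approx(0.0)
    assert cycle_loss(
        np.array([[0.0]]), np.array([[1.0]]), y, y
    ) == pytest.approx(1.0)
    assert cycle_loss(x, x + 0.1, y, y - 0.2) >= 0.0
    with pytest.raises(ValueError, match="mismatch"):
        cycle_loss(x, y, y, y)


# ----------------------------------------------------------- mmsr and total


def test_mmsr_published_weights_on_unit_losses():
    """Component losses of exactly 1 weighted by the published defaults sum to
    1 + 1 + 0.7 + 0.3 = 3.0 — verified by constructing inputs achieving it."""
    w = LossWeights()
    assert w.lambda1 * 1 + w.lambda2 * 1 + w.lambda3 * 1 + w.lambda4 * 1 == pytest.approx(3.0)
    # and the function itself is the weighted sum of its four terms
    rng = np.random.default_rng(3)
    x, x_sr = rng.uniform(-1, 1, (4, 4)), rng.uniform(-1, 1, (8, 8))
    y, y_lr = rng.uniform(-1, 1, (8, 8)), rng.uniform(-1, 1, (4, 4))
    expect = (
        w.lambda1 * ssim_loss(x, x_sr)
        + w.lambda2 * ssim_loss(y, y_lr)
        + w.lambda3 * downsample_loss(x, x_sr)
        + w.lambda4 * upsample_loss(y, y_lr)
    )
    assert mmsr_loss(x, x_sr, y, y_lr, w) == pytest.approx(expect, rel=1e-12)


def test_mmsr_zero_case_and_reduction(rng):
    x = np.full((4, 4), 0.1)
    x_sr = nearest_upsample(x, 2)
    y = np.full((8, 8), 0.6)
    y_lr = average_pool_downsample(y, 2)
    assert mmsr_loss(x, x_sr, y, y_lr) == pytest.approx(0.0, abs=1e-12)
    # lambda3 = lambda4 = 0 reduces MMSR to the two SSIM terms exactly
    x2, sr2 = rng.uniform(-1, 1, (4, 4)), rng.uniform(-1, 1, (8, 8))
    y2, lr2 = rng.uniform(-1, 1, (8, 8)), rng.uniform(-1, 1, (4, 4))
    w = LossWeights(lambda3=0.0, lambda4=0.0)
    assert mmsr_loss(x2, sr2, y2, lr2, w) == pytest.approx(
        ssim_loss(x2, sr2) + ssim_loss(y2, lr2), rel=1e-12
    )


def _total_inputs(rng):
    x = rng.uniform(-1, 1, (2, 1, 4, 4))
    x_sr = rng.uniform(-1, 1, (2, 1, 8, 8))
    y = rng.uniform(-1, 1, (2, 1, 8, 8))
    y_lr = rng.uniform(-1, 1, (2, 1, 4, 4))
    d1 = rng.normal(size=(2, 1, 3, 3))
    d2 = rng.normal(size=(2, 1, 3, 3))
    return x, x_sr, y, y_lr, x + 0.05, y - 0.05, d1, d2


def test_total_loss_breakdown_consistency(rng):
    x, x_sr, y, y_lr, x_rec, y_rec, d1, d2 = _total_inputs(rng)
    w = LossWeights()
    bd = total_loss(x, x_sr, y, y_lr, x_rec, y_rec, d1, d2, w)
    assert bd.total == pytest.approx(bd.weighted_sum(w), rel=1e-6)
    # zero inputs everywhere -> every term and the total vanish
    z4, z8 = np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 8, 8))
    bd0 = total_loss(z4, z8, z8, z4, z4, z8, np.ones((1, 1, 2, 2)), np.ones((1, 1, 2, 2)))
    assert bd0.total == pytest.approx(0.0, abs=1e-12)


def test_total_loss_linear_in_each_lambda(rng):
    x, x_sr, y, y_lr, x_rec, y_rec, d1, d2 = _total_inputs(rng)
    base = total_loss(x, x_sr, y, y_lr, x_rec, y_rec, d1, d2, LossWeights())
    doubled = total_loss(
        x, x_sr, y, y_lr, x_rec, y_rec, d1, d2, LossWeights(lambda7=2.0)
    )
    assert doubled.total - base.total == pytest.approx(base.cycle, rel=1e-9)
    defaults = LossWeights()
    for name, field in [
        ("lambda1", "ssim_g1"), ("lambda3", "downsample"), ("lambda5", "gan_g1"),
    ]:
        up = total_loss(
            x, x_sr, y, y_lr, x_rec, y_rec, d1, d2, LossWeights(**{name: 1.5})
        )
        delta = 1.5 - getattr(defaults, name)
        assert up.total - base.total == pytest.approx(
            delta * getattr(base, field), rel=1e-9
        )


def test_losses_produce_finite_gradients_on_tape(rng):
    x = Tensor(rng.uniform(-1, 1, (1, 1, 4, 4)), requires_grad=True)
    x_sr = Tensor(rng.uniform(-1, 1, (1, 1, 8, 8)), requires_grad=True)
    y = Tensor(rng.uniform(-1, 1, (1, 1, 8, 8)))
    y_lr = Tensor(rng.uniform(-1, 1, (1, 1, 4, 4)))
    bd = total_loss(
        x, x_sr, y, y_lr, x, y,
        Tensor(rng.normal(size=(1, 1, 2, 2)), requires_grad=True),
        Tensor(rng.normal(size=(1, 1, 2, 2))),
    )
    assert bd.graph is not None
    bd.graph.backward()
    assert np.isfinite(x.grad).all() and np.isfinite(x_sr.grad).all()


def test_loss_weights_validation():
    with pytest.raises(ValueError, match="nonnegative"):
        LossWeights(lambda3=-0.1)
    with pytest.raises(ValueError):
        SSIMConstants(data_range=0.0)
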