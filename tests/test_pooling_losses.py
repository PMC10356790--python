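"""Pooling identities, loss formulas, beta, and metrics."""

import math

import numpy as np
import pytest

import patchbag as pb
from patchbag import nn
from patchbag._forward import forward_sample
from patchbag.pooling_losses import t_gate_entropy


def test_gap_pool_examples():
    assert pb.gap_pool(np.full((3, 3, 3), 2.5)) == pytest.approx(2.5)
    sym = np.array([1.0, -1.0] * 4).reshape(2, 2, 2)
    assert pb.gap_pool(sym) == pytest.approx(0.0)
    assert pb.gap_pool(np.arange(1.0, 9.0).reshape(2, 2, 2)) == pytest.approx(4.5)
    with pytest.raises(ValueError):
        pb.gap_pool(np.zeros((0, 2, 2)))


def test_gated_pool_selector_and_degenerate_gate(rng):
    r = rng.standard_normal((3, 3, 3))
    g = np.zeros((3, 3, 3))
    g[1, 2, 0] = 1.0
    z, e = pb.gated_pool(r, g)
    assert z == pytest.approx(r[1, 2, 0])
    np.testing.assert_allclose(e.values, g * r, atol=1e-6)
    with pytest.raises(ValueError, match="degenerate"):
        pb.gated_pool(r, np.zeros((3, 3, 3)))
    with pytest.raises(ValueError, match="extents"):
        pb.gated_pool(r, np.ones((2, 2, 2)))


def test_gated_pool_constant_gate_reduces_to_gap(rng):
    for _ in range(50):
        r = rng.standard_normal((4, 4, 4))
        c = rng.uniform(0.05, 1.0)
        z, _ = pb.gated_pool(r, np.full((4, 4, 4), c))
        assert abs(z - pb.gap_pool(r)) < 1e-10


def test_gated_pool_invariant_to_positive_rescaling(rng):
    r = rng.standard_normal((5, 5, 5))
    g = rng.uniform(0.0, 1.0, (5, 5, 5))
    z0, _ = pb.gated_pool(r, g)
    for k in (1e-3, 0.5, 7.0):
        zk, _ = pb.gated_pool(r, k * g)
        assert abs(zk - z0) < 1e-10


def _loss_oracle(y_hat, y_ls, beta):
    """Direct scalar transcription of the balanced label-smoothed BCE."""
    return -beta * y_ls * math.log(y_hat) - (1 - beta) * (1 - y_ls) * math.log(1 - y_hat)


@pytest.mark.parametrize("beta", [0.3, 0.5, 433 / 792])
@pytest.mark.parametrize("y", [0, 1])
@pytest.mark.parametrize("y_hat", [0.05, 0.5, 0.9, 0.99])
def test_classification_loss_matches_scalar_oracle(beta, y, y_hat):
    cfg = pb.LossConfig(beta=beta)
    y_ls = 0.9 if y == 1 else 0.1
    assert pb.classification_loss(y_hat, y, cfg) == pytest.approx(
        _loss_oracle(y_hat, y_ls, beta), rel=1e-12
    )


def test_classification_loss_diverges_for_confident_mistake():
    cfg = pb.LossConfig(beta=0.5)
    losses = [pb.classification_loss(p, 0, cfg) for p in (0.9, 0.99, 0.999, 1 - 1e-9)]
    assert all(b > a for a, b in zip(losses, losses[1:]))


def test_unsmoothed_balanced_loss_is_half_standard_bce():
    cfg = pb.LossConfig(beta=0.5, smooth_targets=(0.0, 1.0))
    for y, p in [(1, 0.7), (0, 0.2)]:
        bce = -(y * math.log(p) + (1 - y) * math.log(1 - p))
        assert pb.classification_loss(p, y, cfg) == pytest.approx(0.5 * bce, rel=1e-10)


def test_batch_loss_is_mean_over_samples():
    cfg = pb.LossConfig(beta=0.4)
    singles = [pb.classification_loss(p, y, cfg) for p, y in [(0.8, 1), (0.3, 0)]]
    batch = pb.classification_loss([0.8, 0.3], [1, 0], cfg)
    assert batch == pytest.approx(np.mean(singles))


def test_gate_entropy_bounds_and_extremes(rng):
    assert pb.gate_entropy(np.full((4, 4, 4), 0.5)) == pytest.approx(math.log(2))
    assert pb.gate_entropy(np.zeros((4, 4, 4))) < 1e-10
    assert pb.gate_entropy(np.ones((4, 4, 4))) < 1e-10
    for _ in range(1000):
        h = pb.gate_entropy(rng.uniform(0, 1, (3, 3, 3)))
        assert 0.0 <= h <= math.log(2) + 1e-12


def test_total_loss_composition():
    cfg0 = pb.LossConfig(beta=0.5, lam=0.0)
    cfg = pb.LossConfig(beta=0.5, lam=0.01)
    g = np.full((3, 3, 3), 0.5)
    assert pb.total_loss(0.8, 1, g, cfg0) == pytest.approx(
        pb.classification_loss(0.8, 1, cfg0)
    )
    assert pb.total_loss(0.8, 1, g, cfg) == pytest.approx(
        pb.classification_loss(0.8, 1, cfg) - 0.01 * math.log(2)
    )


def test_entropy_gradient_touches_only_gating_branch(rng):
    """The gate map is a function of coordinates alone, so the entropy term
    cannot move the encoder or classifier: their gradients are exactly zero."""
    state = pb.build_model(pb.EncoderSpec(9), "position_gate", seed=5)
    grid = pb.make_coordinate_grid((32, 32, 32))
    ind = pb.extract_position_indicator(grid, state.spec.layer_geoms())
    x = rng.standard_normal((32, 32, 32)).astype(np.float32)
    out = forward_sample(state, x, ind)
    (-t_gate_entropy(out["g"])).backward()
    for p in list(state.phi.values()) + list(state.psi.values()):
        assert p.grad is None or not p.grad.any()
    assert any(p.grad is not None and p.grad.any() for p in state.pi.values())
    assert any(p.grad is not None and p.grad.any() for p in state.rho.values())


def test_compute_beta_counts():
    assert pb.compute_beta([0, 0, 1, 1]) == pytest.approx(0.5)
    assert pb.compute_beta([0, 0, 0, 1]) == pytest.approx(0.75)
    # a 433-negative / 359-positive cohort
    labels = [0] * 433 + [1] * 359
    assert pb.compute_beta(labels) == pytest.approx(433 / 792)
    with pytest.raises(ValueError):
        pb.compute_beta([1, 1, 1])


def test_evaluate_metrics(rng):
    acc, auroc = pb.evaluate([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0])
    assert acc == 1.0 and auroc == 1.0
    scores = rng.uniform(0, 1, 4000)
    labels = rng.integers(0, 2, 4000)
    _, a = pb.evaluate(scores, labels)
    assert 0.45 < a < 0.55
    with pytest.raises(ValueError, match="one class"):
        pb.evaluate([0.2, 0.8], [1, 1])
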