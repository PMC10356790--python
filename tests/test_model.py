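"""Encoder family, branch contracts, and checkpointing."""

import numpy as np
import pytest

import patchbag as pb
from patchbag import nn
from patchbag.model import _N3


def test_exactly_five_encoder_variants():
    assert pb.PATCH_SIZES == (9, 17, 25, 41, 57)
    assert min(pb.PATCH_SIZES) == 9
    with pytest.raises(ValueError, match="unsupported"):
        pb.EncoderSpec(patch_size=13)


@pytest.mark.parametrize("ps", pb.PATCH_SIZES)
def test_block_kernel_allocation_reaches_target_rf(ps):
    spec = pb.EncoderSpec(patch_size=ps)
    kernels = [k for pair in spec.block_kernels() for k in pair]
    assert kernels.count(3) == _N3[ps]
    # front-loaded: all 3^3 convs precede all 1^3 convs
    assert kernels == sorted(kernels, reverse=True)
    geom = pb.compose_geometry(spec.layer_geoms())
    assert geom.rf == ps and geom.jump == 4


def test_build_is_bit_reproducible_from_seed():
    a = pb.build_model(pb.EncoderSpec(9), "position_gate", seed=3)
    b = pb.build_model(pb.EncoderSpec(9), "position_gate", seed=3)
    c = pb.build_model(pb.EncoderSpec(9), "position_gate", seed=4)
    for (ka, ta), (kb, tb) in zip(_flat(a), _flat(b)):
        assert ka == kb
        np.testing.assert_array_equal(ta.data, tb.data)
    assert any(not np.array_equal(ta.data, tc.data) for (_, ta), (_, tc) in zip(_flat(a), _flat(c)))


def _flat(state):
    return [
        (f"{bn}/{k}", t)
        for bn, params in state.branches().items()
        for k, t in sorted(params.items())
    ]


def test_parameter_partition_is_exact(small_state):
    names = [n for n, _ in _flat(small_state)]
    assert len(names) == len(set(names))
    gap = pb.build_model(pb.EncoderSpec(9), "gap", seed=0)
    assert not gap.pi and not gap.rho
    fg = pb.build_model(pb.EncoderSpec(9), "feature_gate", seed=0)
    assert not fg.pi and fg.rho


def test_constant_input_gives_constant_responses(small_state):
    r = pb.patch_responses(small_state, np.zeros((32, 32, 32), np.float32))
    assert r.values.shape == (6, 6, 6)
    assert np.ptp(r.values) < 1e-5


def test_response_extent_follows_output_arithmetic(small_state, rng):
    x = rng.standard_normal((48, 48, 48)).astype(np.float32)
    assert pb.patch_responses(small_state, x).values.shape == (10, 10, 10)
    with pytest.raises(ValueError):
        pb.patch_responses(small_state, np.zeros((7, 7, 7), np.float32))


def test_interior_responses_shift_with_input(small_state, rng):
    """Shifting the content by one jump (4 voxels) shifts the response grid
    by one cell; the voxel multiset is unchanged so instance-norm statistics
    are identical and the match is tight."""
    x = np.zeros((48, 48, 48), np.float32)
    x[8:36, 8:36, 8:36] = rng.standard_normal((28, 28, 28))
    r1 = pb.patch_responses(small_state, x).values
    r2 = pb.patch_responses(small_state, np.roll(x, 4, axis=0)).values
    assert np.abs(r2[1:] - r1[:-1]).max() < 1e-4


def test_gate_depends_only_on_coordinates(small_state, rng):
    grid = pb.make_coordinate_grid((48, 48, 48))
    ind = pb.extract_position_indicator(grid, small_state.spec.layer_geoms())
    g = pb.gate_forward(small_state, ind)
    assert g.values.shape == (10, 10, 10)
    assert np.all((g.values >= 0) & (g.values <= 1))
    # same crop, any two subjects: identical map (no image input at all)
    g2 = pb.gate_forward(small_state, ind)
    np.testing.assert_array_equal(g.values, g2.values)


def test_zero_gate_weights_give_half(small_state):
    import copy

    state = pb.build_model(pb.EncoderSpec(9), "position_gate", seed=0)
    for k in ("gate.conv1.w", "gate.conv1.b"):
        state.rho[k].data = np.zeros_like(state.rho[k].data)
    grid = pb.make_coordinate_grid((32, 32, 32))
    ind = pb.extract_position_indicator(grid, state.spec.layer_geoms())
    g = pb.gate_forward(state, ind)
    np.testing.assert_allclose(g.values, 0.5, atol=1e-7)


def test_gate_is_pointwise_permutation_equivariant(small_state, rng):
    """Permuting indicator positions permutes the gate map identically."""
    grid = pb.make_coordinate_grid((32, 32, 32))
    ind = pb.extract_position_indicator(grid, small_state.spec.layer_geoms())
    g = pb.gate_forward(small_state, ind).values
    perm = rng.permutation(ind.coords.shape[0])
    shuffled = pb.PositionIndicator(coords=ind.coords[perm])
    g_shuffled = pb.gate_forward(small_state, shuffled).values
    np.testing.assert_allclose(g_shuffled, g[perm], atol=1e-6)


def test_gate_valid_for_out_of_range_coordinates(small_state):
    coords = np.full((3, 3, 3, 3), 7.5, np.float32)
    g = pb.gate_forward(small_state, pb.PositionIndicator(coords=coords))
    assert np.all((g.values >= 0) & (g.values <= 1))


def test_feature_gate_contract(rng):
    state = pb.build_model(pb.EncoderSpec(9), "feature_gate", seed=1)
    feats = rng.standard_normal((256, 4, 4, 4)).astype(np.float32)
    g = pb.feature_gate_forward(state, feats)
    assert g.values.shape == (4, 4, 4)
    # unlike the position gate, different features give different maps
    g2 = pb.feature_gate_forward(state, feats + 1.0)
    assert np.abs(g.values - g2.values).max() > 0
    with pytest.raises(ValueError, match="channels"):
        pb.feature_gate_forward(state, feats[:64])


def test_checkpoint_roundtrip(tmp_path, small_state, rng):
    x = rng.standard_normal((32, 32, 32)).astype(np.float32)
    before = pb.patch_responses(small_state, x).values
    pb.save_checkpoint(small_state, tmp_path / "ckpt")
    loaded = pb.load_checkpoint(tmp_path / "ckpt")
    assert loaded.gating_mode == small_state.gating_mode
    assert loaded.spec == small_state.spec
    np.testing.assert_array_equal(pb.patch_responses(loaded, x).values, before)
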