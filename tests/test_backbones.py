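"""Lead (Xception-style) and assisting (CoAtNet-style) backbone contracts."""

import numpy as np
import pytest

from leafseg.backbones import (
    AssistPlan,
    MBConvBlock,
    PlanError,
    RelAttention,
    StagePlan,
    build_assist,
    build_lead,
    default_lead_plan,
    tiny_assist_plan,
    tiny_lead_plan,
)
from leafseg.backbones.assist import FFN
from leafseg.nn import Tensor, no_grad

RNG = np.random.default_rng(0)


def _image(n=1, size=64):
    return Tensor(RNG.random((n, 3, size, size)))


# -- lead backbone ---------------------------------------------------------

def test_lead_taps_shrink_and_reach_stride_16():
    lead = build_lead(tiny_lead_plan(), seed=1)
    with no_grad():
        pyramid = lead(_image(size=64))
    sizes = [level.tensor.shape[2] for level in pyramid.levels]
    assert sizes == sorted(sizes, reverse=True)
    assert pyramid["L4"].tensor.shape[2:] == (4, 4)  # 64 / 16
    assert pyramid["L4"].stride == 16


def test_lead_channels_follow_the_plan():
    plan = tiny_lead_plan()
    lead = build_lead(plan, seed=1)
    with no_grad():
        pyramid = lead(_image(size=32))
    for sp in plan:
        assert pyramid[sp.stage_id].tensor.shape[1] == sp.out_channels


def test_default_plan_has_sixteen_l3_repeats_and_stride_16():
    plan = default_lead_plan()
    assert plan[3].repeats == 16
    assert int(np.prod([sp.stride for sp in plan])) == 16


def test_bad_plans_are_rejected():
    plan = default_lead_plan()
    with pytest.raises(PlanError):
        build_lead(plan[:4])
    wrong_stride = plan[:4] + [
        StagePlan("L4", 1, 32, 1, "separable_conv")  # cumulative stride 8
    ]
    with pytest.raises(PlanError, match="16"):
        build_lead(wrong_stride)
    with pytest.raises(PlanError):
        StagePlan("L0", 1, 32, 3, "conv")


def test_zero_injections_match_no_injections():
    lead = build_lead(tiny_lead_plan(), seed=2)
    x = _image(size=32)
    with no_grad():
        plain = lead(x)
        zeros = {
            "L1": Tensor(np.zeros((1, 8, 16, 16))),
            "L3": Tensor(np.zeros((1, 16, 4, 4))),
        }
        injected = lead(x, zeros)
    for sid in ("L0", "L1", "L2", "L3", "L4"):
        np.testing.assert_array_equal(
            plain[sid].tensor.data, injected[sid].tensor.data
        )


def test_nonzero_injection_changes_the_output():
    lead = build_lead(tiny_lead_plan(), seed=2)
    x = _image(size=32)
    with no_grad():
        plain = lead(x)
        bumped = lead(x, {"L2": Tensor(RNG.random((1, 16, 8, 8)))})
    assert np.abs(plain["L4"].tensor.data - bumped["L4"].tensor.data).max() > 0


def test_shape_mismatched_injection_names_the_stage():
    lead = build_lead(tiny_lead_plan(), seed=2)
    with pytest.raises(PlanError, match="L1"):
        with no_grad():
            lead(_image(size=32), {"L1": Tensor(np.zeros((1, 8, 5, 5)))})


def test_lead_inference_is_deterministic():
    lead = build_lead(tiny_lead_plan(), seed=3).eval()
    x = _image(size=32)
    with no_grad():
        a = lead(x)["L4"].tensor.data
        b = lead(x)["L4"].tensor.data
    np.testing.assert_array_equal(a, b)


def test_stage_parameter_count_matches_shape_oracle():
    lead = build_lead(tiny_lead_plan(), seed=0)
    stage = lead.stages[1]  # L1: one XceptionBlock, 8 -> 16 channels, stride 2
    in_ch, out_ch = 8, 16
    sep1 = in_ch * 9 + (in_ch * out_ch + out_ch)  # depthwise + pointwise
    sep2 = out_ch * 9 + (out_ch * out_ch + out_ch)
    bns = 2 * (2 * out_ch)
    shortcut = in_ch * out_ch + 2 * out_ch  # 1x1 conv (no bias) + BN
    assert stage.param_count() == sep1 + sep2 + bns + shortcut


# -- MBConv ----------------------------------------------------------------

def test_mbconv_zero_body_is_identity_at_stride_1():
    block = MBConvBlock(8, 8, stride=1, rng=np.random.default_rng(0))
    block.project.weight.data[:] = 0.0
    block.project.bias.data[:] = 0.0
    x = Tensor(RNG.random((2, 8, 8, 8)))
    with no_grad():
        np.testing.assert_array_equal(block(x).data, x.data)


def test_mbconv_stride_2_halves_the_grid():
    block = MBConvBlock(4, 8, stride=2, rng=np.random.default_rng(0))
    with no_grad():
        out = block(Tensor(RNG.random((1, 4, 16, 16))))
    assert out.shape == (1, 8, 8, 8)
    with pytest.raises(PlanError):
        MBConvBlock(4, 8, stride=3)


def test_mbconv_parameter_count_matches_shape_oracle():
    in_ch, out_ch, e = 4, 4, 4
    block = MBConvBlock(in_ch, out_ch, stride=1, expansion=e,
                        rng=np.random.default_rng(0))
    hidden = in_ch * e
    expected = (
        2 * in_ch  # pre-BN
        + (in_ch * hidden + hidden) + 2 * hidden  # expand + BN
        + hidden * 9 + hidden + 2 * hidden  # depthwise + bias + BN
        + (hidden * out_ch + out_ch)  # project
    )
    assert block.param_count() == expected


# -- relative attention ----------------------------------------------------

def test_attention_rows_sum_to_one():
    attn = RelAttention(8, 8, heads=2, head_dim=4, grid_hw=(3, 3),
                        rng=np.random.default_rng(1))
    attn.rel_bias.data[:] = RNG.random(attn.rel_bias.shape)
    x = Tensor(RNG.random((2, 8, 3, 3)))
    with no_grad():
        scores = attn.attention_matrix(x)
    np.testing.assert_allclose(scores.sum(axis=-1), 1.0, atol=1e-6)


def test_singleton_attention_is_the_value_projection():
    attn = RelAttention(4, 4, heads=1, head_dim=4, grid_hw=(1, 1),
                        rng=np.random.default_rng(2))
    x = Tensor(RNG.random((1, 4, 1, 1)))
    with no_grad():
        out = attn(x).data
        v = attn.wv(x.reshape(1, 4).transpose(0, 1)).data  # the single token
        expected = attn.wo(Tensor(v)).data
    np.testing.assert_allclose(out.ravel(), expected.ravel(), atol=1e-12)


def test_identical_tokens_give_identical_outputs():
    attn = RelAttention(4, 4, heads=1, head_dim=4, grid_hw=(2, 2),
                        rng=np.random.default_rng(3))
    token = RNG.random(4)
    x = Tensor(np.tile(token[None, :, None, None], (1, 1, 2, 2)))
    with no_grad():
        out = attn(x).data[0].reshape(4, -1)
    for col in range(1, out.shape[1]):
        np.testing.assert_allclose(out[:, col], out[:, 0], atol=1e-12)


def test_zero_bias_attention_is_permutation_equivariant():
    """Brute-force equivariance on 2x2 grids: permuting tokens permutes outputs."""
    attn = RelAttention(4, 4, heads=2, head_dim=2, grid_hw=(2, 2),
                        rng=np.random.default_rng(4))
    attn.rel_bias.data[:] = 0.0
    x = RNG.random((1, 4, 2, 2))
    tokens = x.reshape(1, 4, 4)  # N, C, L
    for perm in ([1, 0, 3, 2], [3, 2, 1, 0], [2, 0, 3, 1]):
        permuted = tokens[:, :, perm].reshape(1, 4, 2, 2)
        with no_grad():
            out = attn(Tensor(x)).data.reshape(1, 4, 4)
            out_perm = attn(Tensor(permuted)).data.reshape(1, 4, 4)
        np.testing.assert_allclose(out[:, :, perm], out_perm, atol=1e-12)


def test_nonzero_bias_breaks_permutation_equivariance():
    attn = RelAttention(4, 4, heads=1, head_dim=4, grid_hw=(2, 2),
                        rng=np.random.default_rng(5))
    attn.rel_bias.data[:] = RNG.random(attn.rel_bias.shape) * 3
    x = RNG.random((1, 4, 2, 2))
    tokens = x.reshape(1, 4, 4)
    perm = [3, 2, 1, 0]
    permuted = tokens[:, :, perm].reshape(1, 4, 2, 2)
    with no_grad():
        out = attn(Tensor(x)).data.reshape(1, 4, 4)
        out_perm = attn(Tensor(permuted)).data.reshape(1, 4, 4)
    assert np.abs(out[:, :, perm] - out_perm).max() > 1e-8


def test_off_design_grid_resamples_bias():
    attn = RelAttention(4, 4, heads=1, head_dim=4, grid_hw=(4, 4),
                        rng=np.random.default_rng(6))
    attn.rel_bias.data[:] = RNG.random(attn.rel_bias.shape)
    with no_grad():
        out = attn(Tensor(RNG.random((1, 4, 2, 2))))
    assert out.shape == (1, 4, 2, 2)


# -- FFN -------------------------------------------------------------------

def test_ffn_zero_init_is_identity():
    f = FFN(4, expansion=4, rng=np.random.default_rng(0))
    for p in f.parameters():
        p.data[:] = 0.0
    x = Tensor(RNG.random((1, 4, 3, 3)))
    with no_grad():
        np.testing.assert_array_equal(f(x).data, x.data)


def test_ffn_hidden_width_is_expansion_times_channels():
    f = FFN(6, expansion=4)
    assert f.fc1.weight.shape == (6, 24)
    assert f.fc2.weight.shape == (24, 6)


def test_ffn_commutes_with_position_permutation():
    f = FFN(4, expansion=2, rng=np.random.default_rng(1))
    x = RNG.random((1, 4, 2, 2))
    tokens = x.reshape(1, 4, 4)
    perm = [2, 3, 0, 1]
    with no_grad():
        out = f(Tensor(x)).data.reshape(1, 4, 4)
        out_perm = f(Tensor(tokens[:, :, perm].reshape(1, 4, 2, 2))).data
    np.testing.assert_allclose(out[:, :, perm], out_perm.reshape(1, 4, 4),
                               atol=1e-12)


# -- assisting backbone ----------------------------------------------------

def test_assist_strides_and_channels():
    assist = build_assist(tiny_assist_plan(input_size=64), seed=1)
    with no_grad():
        pyramid = assist(_image(size=64))
    assert [lvl.stride for lvl in pyramid.levels] == [2, 4, 8, 16, 32]
    assert pyramid["A4"].tensor.shape[2:] == (2, 2)
    widths = tiny_assist_plan().widths
    for sid, w in zip(("A0", "A1", "A2", "A3", "A4"), widths):
        assert pyramid[sid].tensor.shape[1] == w


def test_default_repeats_are_2_4_8_2():
    plan = AssistPlan()
    assert plan.repeats == (2, 4, 8, 2)
    assist = build_assist(AssistPlan(widths=(8, 16, 16, 24, 32), head_dim=8,
                                     input_size=64))
    assert [len(s) for s in (assist.stage1, assist.stage2, assist.stage3,
                             assist.stage4)] == [2, 4, 8, 2]


def test_assist_plan_validation():
    with pytest.raises(PlanError):
        AssistPlan(widths=(8, 16, 16, 25, 32), head_dim=8)  # 25 % 8 != 0
    with pytest.raises(PlanError):
        AssistPlan(ffn_expansion=0)


def test_assist_rejects_indivisible_input():
    assist = build_assist(tiny_assist_plan(input_size=64))
    with pytest.raises(PlanError, match="divisible"):
        with no_grad():
            assist(Tensor(RNG.random((1, 3, 48, 48))))


def test_assist_inference_is_deterministic():
    assist = build_assist(tiny_assist_plan(input_size=32), seed=5).eval()
    x = _image(size=32)
    with no_grad():
        a = assist(x)["A4"].tensor.data
        b = assist(x)["A4"].tensor.data
    np.testing.assert_array_equal(a, b)
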