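"""Novel blocks: space-to-depth, SPD-Conv, ADown, deformable attention,
OmniKernel/CSP-OmniKernel and the small-object pyramid."""

import math

import numpy as np
import pytest

from headseg.graph import DimensionError, GraphValidationError
from headseg.nn_blocks import build_c2f, build_cbs
from headseg.novel_blocks import (
    DeformableAttentionSpec,
    OmniKernelSpec,
    build_adown,
    build_c2f_dattention,
    build_csp_omnikernel,
    build_deformable_attention,
    build_omnikernel,
    build_soep_neck,
    build_spdconv,
)


class TestSPDConv:
    def test_shape_halves_resolution(self):
        g = build_spdconv(64, 128)
        ch, hw = g.trace(160)
        assert ch[g.outputs[0]] == 128 and hw[g.outputs[0]] == (80, 80)

    def test_param_closed_form(self):
        g = build_spdconv(64, 128)
        assert g.param_count() == 9 * (4 * 64) * 128 + 2 * 128
        assert g.param_count() == g.enumerate_weight_sizes()

    def test_odd_resolution_rejected_at_apply_time(self, rng):
        g = build_spdconv(4, 8)
        g.materialize(0)
        with pytest.raises(DimensionError):
            g.forward(rng.normal(0, 1, (4, 7, 8)).astype(np.float32))

    def test_constant_input_gives_constant_interior(self, rng):
        g = build_spdconv(4, 8)
        g.materialize(2)
        y = g.forward_one(np.full((4, 16, 16), 2.0, dtype=np.float32))
        interior = y[:, 1:-1, 1:-1].reshape(8, -1)
        spread = interior.max(axis=1) - interior.min(axis=1)
        np.testing.assert_allclose(spread, 0.0, atol=1e-5)


class TestADown:
    def test_param_closed_form_example(self):
        g = build_adown(256, 256)
        assert g.param_count() == 9 * 128 * 128 + 2 * 128 + 128 * 128 + 2 * 128
        assert g.param_count() == 164_352

    def test_cheaper_than_plain_strided_conv_everywhere(self):
        for cin in (2, 16, 64, 128, 256):
            for cout in (2, 16, 64, 128, 256):
                adown = build_adown(cin, cout).param_count()
                plain = build_cbs(cin, cout, 3, 2).param_count()
                assert adown < plain, (cin, cout)

    def test_param_ratio_below_028_for_wide_case(self):
        ratio = build_adown(256, 256).param_count() / build_cbs(
            256, 256, 3, 2).param_count()
        assert ratio < 0.28

    def test_output_spatial_size_halves_even_input(self, rng):
        g = build_adown(8, 8)
        g.materialize(0)
        y = g.forward_one(rng.normal(0, 1, (8, 32, 32)).astype(np.float32))
        assert y.shape == (8, 16, 16)
        assert np.isfinite(y).all()

    def test_odd_channels_rejected(self):
        with pytest.raises(GraphValidationError):
            build_adown(7, 8)


def _grid_attention_oracle(x, w, spec):
    """Independent loop implementation of attention over the uniform
    stride-``sr`` reference grid (zero offsets, zero position bias)."""
    c, h, wd = x.shape
    sr = spec.grid_stride
    q = np.einsum("oc,chw->ohw", w["wq"][:, :, 0, 0], x)
    # reference points at the centres of sr x sr cells; bilinear at +0.5 is
    # the mean of the 2x2 neighbourhood for sr=2
    ys = [(i + 0.5) * sr - 0.5 for i in range((h - 1) // sr + 1)]
    xs = [(j + 0.5) * sr - 0.5 for j in range((wd - 1) // sr + 1)]
    samples = []
    for yy in ys:
        for xx in xs:
            y0, x0 = int(math.floor(yy)), int(math.floor(xx))
            y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, wd - 1)
            fy, fx = yy - y0, xx - x0
            v = (x[:, y0, x0] * (1 - fy) * (1 - fx) + x[:, y0, x1] * (1 - fy) * fx
                 + x[:, y1, x0] * fy * (1 - fx) + x[:, y1, x1] * fy * fx)
            samples.append(v)
    xs_mat = np.stack(samples, axis=1)  # (C, Ng)
    k = w["wk"][:, :, 0, 0] @ xs_mat
    v = w["wv"][:, :, 0, 0] @ xs_mat
    nh = spec.n_heads
    dh = c // nh
    out = np.zeros((c, h * wd))
    qf = q.reshape(c, h * wd)
    for head in range(nh):
        sl = slice(head * dh, (head + 1) * dh)
        logits = qf[sl].T @ k[sl] / math.sqrt(dh)
        logits -= logits.max(axis=1, keepdims=True)
        a = np.exp(logits)
        a /= a.sum(axis=1, keepdims=True)
        out[sl] = v[sl] @ a.T
    return out.reshape(c, h, wd)


class TestDeformableAttention:
    SPEC = DeformableAttentionSpec(dim=32, n_heads=4, n_groups=1,
                                   nominal_grid=(8, 8))

    def _graph(self, seed=5):
        g = build_deformable_attention(self.SPEC)
        g.materialize(seed)
        return g

    def test_zero_offsets_equal_uniform_grid_oracle(self, rng):
        g = self._graph()
        w = g.weights["dattn"]
        w["off_dw"][...] = 0.0
        w["off_pw"][...] = 0.0
        w["rpe"][...] = 0.0
        x = rng.normal(0, 1, (32, 16, 16)).astype(np.float32)
        got = g.forward_one(x)
        want = _grid_attention_oracle(x.astype(np.float64), w, self.SPEC)
        np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-5)

    def test_zero_range_factor_collapses_learned_offsets(self, rng):
        x = rng.normal(0, 1, (32, 16, 16)).astype(np.float32)
        frozen = build_deformable_attention(
            DeformableAttentionSpec(dim=32, n_heads=4, nominal_grid=(8, 8),
                                    offset_range_factor=0.0))
        frozen.materialize(5)
        zeroed = self._graph(seed=5)
        zw = zeroed.weights["dattn"]
        zw["off_dw"][...] = 0.0
        zw["off_pw"][...] = 0.0
        zw["off_ln_b"][...] = 0.0
        np.testing.assert_allclose(frozen.forward_one(x), zeroed.forward_one(x),
                                   rtol=1e-5, atol=1e-6)

    def test_output_spec_equals_input_spec(self, rng):
        g = self._graph()
        x = rng.normal(0, 1, (32, 12, 20)).astype(np.float32)
        y = g.forward_one(x)
        assert y.shape == x.shape
        assert np.isfinite(y).all()

    def test_indivisible_dim_rejected(self):
        with pytest.raises(GraphValidationError):
            DeformableAttentionSpec(dim=30, n_heads=4)
        with pytest.raises(GraphValidationError):
            DeformableAttentionSpec(dim=32, n_heads=4, n_groups=8)


class TestC2fDAttention:
    def test_param_overhead_is_attention_closed_form(self):
        plain = build_c2f(256, 256, 1, True).param_count()
        datt = build_c2f_dattention(256, 256, 1).param_count()
        h = 128
        spec = DeformableAttentionSpec(dim=h)
        ngc = h // spec.n_groups
        gh, gw = spec.nominal_grid
        expected = (3 * h * h                      # q, k, v projections
                    + spec.offset_kernel**2 * ngc  # offset depthwise conv
                    + 2 * ngc + 2 * ngc            # offset LN + pointwise
                    + spec.n_heads * (2 * gh - 1) * (2 * gw - 1))
        assert datt - plain == expected == 58_948

    def test_shape_contract_identical_to_plain_c2f(self, rng):
        x = rng.normal(0, 1, (32, 16, 16)).astype(np.float32)
        a = build_c2f(32, 32, 1, True)
        b = build_c2f_dattention(32, 32, 1,
                                 DeformableAttentionSpec(dim=16, n_heads=4))
        a.materialize(0)
        b.materialize(0)
        assert a.forward_one(x).shape == b.forward_one(x).shape


class TestOmniKernel:
    SPEC = OmniKernelSpec(dim=16, large_kernel=7, strip_kernel=5)

    def test_constant_input_finite_output(self):
        g = build_omnikernel(self.SPEC)
        g.materialize(3)
        y = g.forward_one(np.full((16, 12, 12), 4.0, dtype=np.float32))
        assert np.isfinite(y).all()

    def test_shape_preserved_and_params_enumerate(self, rng):
        g = build_omnikernel(self.SPEC)
        g.materialize(1)
        x = rng.normal(0, 1, (16, 10, 14)).astype(np.float32)
        assert g.forward_one(x).shape == x.shape
        assert g.param_count() == g.enumerate_weight_sizes()

    def test_even_large_kernel_rejected(self):
        with pytest.raises(GraphValidationError):
            OmniKernelSpec(dim=16, large_kernel=8)


class TestCSPOmniKernel:
    def test_zeroed_mixer_branch_isolates_bypass_half(self, rng):
        g = build_csp_omnikernel(16, 16)
        g.materialize(4)
        g.zero_("csp_ok.ok")
        x1 = rng.normal(0, 1, (16, 8, 8)).astype(np.float32)
        x2 = x1.copy()
        x2[8:] = rng.normal(0, 1, (8, 8, 8))  # change only the mixed half
        np.testing.assert_allclose(g.forward_one(x1), g.forward_one(x2),
                                   atol=1e-6)

    def test_spatial_size_preserved(self, rng):
        g = build_csp_omnikernel(16, 8)
        g.materialize(0)
        y = g.forward_one(rng.normal(0, 1, (16, 9, 9)).astype(np.float32))
        assert y.shape == (8, 9, 9)

    def test_odd_channels_rejected(self):
        with pytest.raises(GraphValidationError):
            build_csp_omnikernel(15, 8)


class TestSOEP:
    def test_p2_information_reaches_output(self, rng):
        g = build_soep_neck(8, 16, 32, 64, spd_width=8)
        g.materialize(6)
        inputs = {
            "p2": rng.normal(0, 1, (8, 16, 16)).astype(np.float32),
            "p3": rng.normal(0, 1, (16, 8, 8)).astype(np.float32),
            "topdown": rng.normal(0, 1, (32, 8, 8)).astype(np.float32),
        }
        base = g.forward(inputs)[g.outputs[0]]
        inputs2 = {k: v.copy() for k, v in inputs.items()}
        inputs2["p2"][0, 3, 3] += 1.0
        perturbed = g.forward(inputs2)[g.outputs[0]]
        assert not np.allclose(base, perturbed)

    def test_resolution_mismatch_rejected(self, rng):
        g = build_soep_neck(8, 16, 32, 64, spd_width=8)
        g.materialize(0)
        with pytest.raises(GraphValidationError):
            g.forward({
                "p2": rng.normal(0, 1, (8, 8, 8)).astype(np.float32),
                "p3": rng.normal(0, 1, (16, 8, 8)).astype(np.float32),
                "topdown": rng.normal(0, 1, (32, 8, 8)).astype(np.float32),
            })

    def test_head_strides_remain_8_16_32(self):
        from headseg.model_assembly import VARIANTS, build_variant

        g = build_variant(VARIANTS["full"])
        _, hw = g.trace(640)
        assert hw["head.p3.box.out"] == (80, 80)
        assert hw["head.p4.box.out"] == (40, 40)
        assert hw["head.p5.box.out"] == (20, 20)


class TestDropInCompatibility:
    """Every novel block is shape-compatible with the block it replaces."""

    def test_adown_matches_strided_cbs_shape(self, rng):
        x = rng.normal(0, 1, (16, 24, 24)).astype(np.float32)
        a = build_adown(16, 32)
        b = build_cbs(16, 32, 3, 2)
        a.materialize(0)
        b.materialize(0)
        assert a.forward_one(x).shape == b.forward_one(x).shape

    def test_spdconv_matches_strided_cbs_shape(self, rng):
        x = rng.normal(0, 1, (16, 24, 24)).astype(np.float32)
        a = build_spdconv(16, 32)
        b = build_cbs(16, 32, 3, 2)
        a.materialize(0)
        b.materialize(0)
        assert a.forward_one(x).shape == b.forward_one(x).shape

    def test_csp_omnikernel_matches_c2f_shape(self, rng):
        x = rng.normal(0, 1, (24, 12, 12)).astype(np.float32)
        a = build_csp_omnikernel(24, 16)
        b = build_c2f(24, 16, 1, False)
        a.materialize(0)
        b.materialize(0)
        assert a.forward_one(x).shape == b.forward_one(x).shape
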