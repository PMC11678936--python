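"""The three architecture contributions: deformable-attention C2f, ADown
downsampling, and the Small Object Enhance Pyramid (SPD-Conv + CSP-OmniKernel).

Internal hyper-parameters that the published model never spells out (attention
heads/offset groups, strip-kernel sizes, SPD output width, channel-attention
reduction) are reconstructions, calibrated so that swapping each block into
the assembled baseline reproduces the printed parameter/GFLOP ablation ladder;
docs/methods.md records every such choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import (
    Act,
    Add,
    BlockGraph,
    Concat,
    Conv,
    DimensionError,
    GraphValidationError,
    Node,
    Pool,
    Split,
    bilinear_sample,
    conv2d,
    depth_to_space,
    gelu,
    sigmoid,
    space_to_depth,
)
from .nn_blocks import add_c2f, add_cbs

__all__ = [
    "DeformableAttentionSpec",
    "OmniKernelSpec",
    "space_to_depth",
    "depth_to_space",
    "build_spdconv",
    "build_adown",
    "build_deformable_attention",
    "build_c2f_dattention",
    "build_omnikernel",
    "build_csp_omnikernel",
    "build_soep_neck",
    "add_adown",
    "add_spdconv",
    "add_csp_omnikernel",
    "dattention_hook",
    "soep_fusion_builder",
    "SPD_WIDTH_BASE",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeformableAttentionSpec:
    """Configuration of the deformable-attention operator.

    ``n_heads``/``n_groups`` are never stated by the published model and are a
    reconstruction (4 heads, 1 offset group).  The offset field carries two
    channels (x, y displacement) per group; ``offset_range_factor`` scales the
    tanh-bounded offsets in units of the reference-grid spacing.
    """

    dim: int
    n_heads: int = 4
    n_groups: int = 1
    offset_range_factor: float = 1.0
    offset_kernel: int = 5
    grid_stride: int = 2
    nominal_grid: tuple = (20, 20)

    def __post_init__(self):
        if self.dim % self.n_heads or self.dim % self.n_groups:
            raise GraphValidationError(
                f"dim {self.dim} must divide n_heads {self.n_heads} and "
                f"n_groups {self.n_groups}")
        if self.n_heads % self.n_groups:
            raise GraphValidationError("n_heads must be a multiple of n_groups")


@dataclass(frozen=True)
class OmniKernelSpec:
    """Shape-preserving multi-branch mixer: local 1x1, large-kernel + strip
    depthwise convs, and a global frequency-attention branch."""

    dim: int
    large_kernel: int = 31
    strip_kernel: int = 11
    ca_reduction: int = 4

    def __post_init__(self):
        if self.large_kernel % 2 == 0 or self.strip_kernel % 2 == 0:
            raise GraphValidationError("kernel sizes must be odd (center alignment)")
        if self.dim < 1:
            raise DimensionError("dim must be positive")


# width of the SPD-Conv output before fusion, in base (unscaled) channels;
# 352 * nano width (1/4) = 88, calibrated against the published model profile
SPD_WIDTH_BASE = 352

_FFT_MACS_PER_ELT = 2.5  # counts one real FFT as 5*N*log2(N) flops per channel


def _fft_macs(c, h, w):
    return int(_FFT_MACS_PER_ELT * h * w * math.log2(max(h * w, 2)) * c)


# ---------------------------------------------------------------------------
# Deformable attention
# ---------------------------------------------------------------------------


class DeformAttn(Node):
    """Multi-head attention over dynamically sampled key/value points.

    Queries come from a 1x1 projection at every position.  A depthwise-conv
    offset network predicts per-group 2-D displacements from the queries,
    bounded by ``tanh`` and scaled by ``offset_range_factor`` grid spacings;
    keys/values are bilinearly sampled at reference-grid + offset locations
    and projected by 1x1 convs.  A relative-position bias table (per head,
    sized for the nominal grid and interpolated at other resolutions) is added
    to the attention logits.  The fuse convolution that always follows in the
    surrounding block acts as the output projection, so none is included here.
    With all offsets zero the operator reduces to attention over the uniform
    downsampled reference grid.
    """

    def __init__(self, name, inp, spec: DeformableAttentionSpec):
        super().__init__(name, [inp])
        self.spec = spec

    def out_channels(self, in_ch):
        if in_ch[0] != self.spec.dim:
            raise GraphValidationError(
                f"{self.name}: expected dim {self.spec.dim}, got {in_ch[0]}")
        return self.spec.dim

    def param_shapes(self, in_ch):
        s = self.spec
        ngc = s.dim // s.n_groups
        gh, gw = s.nominal_grid
        return {
            "wq": (s.dim, s.dim, 1, 1),
            "wk": (s.dim, s.dim, 1, 1),
            "wv": (s.dim, s.dim, 1, 1),
            "off_dw": (ngc, 1, s.offset_kernel, s.offset_kernel),
            "off_ln_g": (ngc,),
            "off_ln_b": (ngc,),
            "off_pw": (2, ngc, 1, 1),
            "rpe": (s.n_heads, 2 * gh - 1, 2 * gw - 1),
        }

    def init_weights(self, in_ch, rng):
        shapes = self.param_shapes(in_ch)
        w = {}
        for k, shp in shapes.items():
            if k == "off_ln_g":
                w[k] = np.ones(shp, dtype=np.float32)
            elif k in ("off_ln_b", "off_pw", "rpe"):
                w[k] = np.zeros(shp, dtype=np.float32) if k != "rpe" else (
                    rng.normal(0, 0.02, shp).astype(np.float32))
            else:
                fan = np.prod(shp[1:])
                w[k] = rng.normal(0, math.sqrt(2.0 / fan), shp).astype(np.float32)
        return w

    def _grid(self, h, w):
        sr = self.spec.grid_stride
        gh = (h - 1) // sr + 1
        gw = (w - 1) // sr + 1
        ys = (np.arange(gh, dtype=np.float32) + 0.5) * sr - 0.5
        xs = (np.arange(gw, dtype=np.float32) + 0.5) * sr - 0.5
        return ys, xs

    def macs(self, in_ch, in_hw):
        s = self.spec
        h, w = in_hw[0]
        hw = h * w
        gy, gx = self._grid(h, w)
        ng = len(gy) * len(gx)
        ngc = s.dim // s.n_groups
        m = hw * s.dim * s.dim                     # q projection
        m += 2 * ng * s.dim * s.dim                # k, v projections
        m += ng * s.dim * s.offset_kernel**2       # offset depthwise conv
        m += ng * ngc * 2 * s.n_groups             # offset pointwise conv
        m += 2 * hw * ng * s.dim                   # qk logits + attn*v
        m += hw * ng * s.n_heads                   # position-bias interpolation
        m += ng * s.dim * 4                        # bilinear sampling
        return m

    def forward(self, xs, w):
        s = self.spec
        x = xs[0].astype(np.float32)
        c, h, wd = x.shape
        sr, kk = s.grid_stride, s.offset_kernel
        g, ngc = s.n_groups, c // s.n_groups
        q = conv2d(x, w["wq"])
        ref_y, ref_x = self._grid(h, wd)
        gh, gw = len(ref_y), len(ref_x)
        ryy, rxx = np.meshgrid(ref_y, ref_x, indexing="ij")

        pos, sampled = [], []
        for gi in range(g):
            qg = q[gi * ngc:(gi + 1) * ngc]
            o = conv2d(qg, w["off_dw"], stride=sr, padding=kk // 2, groups=ngc)
            mu, var = o.mean(axis=0), o.var(axis=0)
            o = (o - mu) / np.sqrt(var + 1e-5)
            o = o * w["off_ln_g"][:, None, None] + w["off_ln_b"][:, None, None]
            o = conv2d(gelu(o), w["off_pw"])  # (2, gh, gw): (dy, dx)
            o = np.tanh(o) * (s.offset_range_factor * sr)
            py = np.clip(ryy + o[0], 0.0, h - 1.0).ravel()
            px = np.clip(rxx + o[1], 0.0, wd - 1.0).ravel()
            pos.append((py, px))
            sampled.append(bilinear_sample(x[gi * ngc:(gi + 1) * ngc], py, px))
        x_s = np.concatenate(sampled, axis=0)  # (C, Ng)

        k = w["wk"][:, :, 0, 0] @ x_s
        v = w["wv"][:, :, 0, 0] @ x_s
        nh, dh = s.n_heads, c // s.n_heads
        qf = q.reshape(nh, dh, h * wd)
        kf = k.reshape(nh, dh, -1)
        vf = v.reshape(nh, dh, -1)
        logits = np.einsum("hdq,hdk->hqk", qf, kf) / math.sqrt(dh)
        logits += self._position_bias(w["rpe"], pos, h, wd)
        logits -= logits.max(axis=2, keepdims=True)
        attn = np.exp(logits)
        attn /= attn.sum(axis=2, keepdims=True)
        out = np.einsum("hqk,hdk->hdq", attn, vf).reshape(c, h, wd)
        return out

    def _position_bias(self, rpe, pos, h, wd):
        s = self.spec
        gh_n, gw_n = s.nominal_grid
        qy, qx = np.mgrid[0:h, 0:wd].astype(np.float32)
        qy, qx = qy.ravel(), qx.ravel()
        heads_per_group = s.n_heads // s.n_groups
        bias = np.empty((s.n_heads, qy.size, pos[0][0].size), dtype=np.float32)
        for head in range(s.n_heads):
            py, px = pos[head // heads_per_group]
            dy = (qy[:, None] - py[None, :]) / max(h - 1, 1)   # [-1, 1]
            dx = (qx[:, None] - px[None, :]) / max(wd - 1, 1)
            ty = (dy + 1.0) * 0.5 * (2 * gh_n - 2)
            tx = (dx + 1.0) * 0.5 * (2 * gw_n - 2)
            bias[head] = bilinear_sample(rpe[head][None], ty, tx)[0]
        return bias


# ---------------------------------------------------------------------------
# Frequency-domain attention nodes (OmniKernel global branch)
# ---------------------------------------------------------------------------


class DualDomainChannelAttn(Node):
    """DCAM: channel gate from spatial-pooled and spectral-magnitude descriptors.

    A reconstruction: the published figure names the module without defining
    it.  Two squeeze-excite MLPs (reduction ``r``) read a global-average
    descriptor and a mean Fourier-magnitude descriptor; their sum passes a
    sigmoid and rescales the channels.
    """

    def __init__(self, name, inp, dim, reduction=4):
        super().__init__(name, [inp])
        self.dim, self.r = dim, reduction

    def out_channels(self, in_ch):
        if in_ch[0] != self.dim:
            raise GraphValidationError(f"{self.name}: channel mismatch")
        return self.dim

    def param_shapes(self, in_ch):
        dr = max(self.dim // self.r, 1)
        return {"w1": (dr, self.dim), "w2": (self.dim, dr),
                "w3": (dr, self.dim), "w4": (self.dim, dr)}

    def macs(self, in_ch, in_hw):
        h, w = in_hw[0]
        dr = max(self.dim // self.r, 1)
        return 4 * self.dim * dr + _fft_macs(self.dim, h, w) + h * w * self.dim

    def init_weights(self, in_ch, rng):
        return {k: rng.normal(0, math.sqrt(2.0 / s[1]), s).astype(np.float32)
                for k, s in self.param_shapes(in_ch).items()}

    def forward(self, xs, w):
        x = xs[0]
        d_sp = x.mean(axis=(1, 2))
        spec = np.abs(np.fft.rfft2(x, axes=(1, 2)))
        d_fr = spec.mean(axis=(1, 2))
        gate = sigmoid(w["w2"] @ gelu(w["w1"] @ d_sp) + w["w4"] @ gelu(w["w3"] @ d_fr))
        return x * gate[:, None, None]


class FreqSpatialGate(Node):
    """FSAM: spatial gate from high-pass frequency-filtered features.

    A reconstruction (named but undefined in the published figure): the
    feature map is high-pass filtered in the Fourier domain (low-frequency
    square of relative half-width 1/8 removed), collapsed to one channel by a
    1x1 conv, and the sigmoid of that map gates the input spatially.
    """

    def __init__(self, name, inp, dim, cutoff=0.125):
        super().__init__(name, [inp])
        self.dim, self.cutoff = dim, cutoff

    def out_channels(self, in_ch):
        if in_ch[0] != self.dim:
            raise GraphValidationError(f"{self.name}: channel mismatch")
        return self.dim

    def param_shapes(self, in_ch):
        return {"w": (1, self.dim), "b": (1,)}

    def macs(self, in_ch, in_hw):
        h, w = in_hw[0]
        return 2 * _fft_macs(self.dim, h, w) + 2 * h * w * self.dim

    def init_weights(self, in_ch, rng):
        return {"w": rng.normal(0, math.sqrt(2.0 / self.dim), (1, self.dim)
                                ).astype(np.float32),
                "b": np.zeros(1, dtype=np.float32)}

    def forward(self, xs, w):
        x = xs[0]
        c, h, wd = x.shape
        f = np.fft.rfft2(x, axes=(1, 2))
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.rfftfreq(wd)[None, :]
        lowpass = (np.abs(fy) < self.cutoff) & (fx < self.cutoff)
        f[:, lowpass] = 0.0
        band = np.fft.irfft2(f, s=(h, wd), axes=(1, 2)).astype(np.float32)
        m = sigmoid(np.einsum("oc,chw->ohw", w["w"], band) + w["b"][:, None, None])
        return x * m


# ---------------------------------------------------------------------------
# In-graph builders
# ---------------------------------------------------------------------------


def add_spdconv(g: BlockGraph, prefix: str, inp: str, cin: int, cout: int) -> str:
    """Space-to-depth (factor 2) + stride-1 CBS: halves resolution losslessly."""
    from .graph import SpaceToDepth

    s2d = g.add(SpaceToDepth(f"{prefix}.s2d", inp, 2))
    return add_cbs(g, f"{prefix}.cv", s2d, 4 * cin, cout, 3, 1)


def add_adown(g: BlockGraph, prefix: str, inp: str, cin: int, cout: int) -> str:
    """Average-pool, channel split, strided-conv / max-pool dual branch."""
    if cin % 2 or cout % 2:
        raise GraphValidationError(f"{prefix}: adown channels must be even")
    avg = g.add(Pool(f"{prefix}.avg", inp, "avg", 2, 1, 0))
    sp = g.add(Split(f"{prefix}.split", avg))
    a = add_cbs(g, f"{prefix}.cv1", f"{sp}:0", cin // 2, cout // 2, 3, 2)
    mp = g.add(Pool(f"{prefix}.max", f"{sp}:1", "max", 3, 2, 1))
    b = add_cbs(g, f"{prefix}.cv2", mp, cin // 2, cout // 2, 1, 1)
    return g.add(Concat(f"{prefix}.cat", [a, b]))


def add_omnikernel(g: BlockGraph, prefix: str, inp: str,
                   spec: OmniKernelSpec) -> str:
    d, lk, sk = spec.dim, spec.large_kernel, spec.strip_kernel
    cin = g.add(Conv(f"{prefix}.in", inp, d, d, 1, bias=True))
    x0 = g.add(Act(f"{prefix}.in_act", cin, "gelu"))
    big = g.add(Conv(f"{prefix}.dw_big", x0, d, d, lk, groups=d, bias=True))
    s1 = _strip(g, f"{prefix}.dw_h", x0, d, 1, sk)
    s2 = _strip(g, f"{prefix}.dw_v", x0, d, sk, 1)
    large = g.add(Add(f"{prefix}.large", [big, s1, s2]))
    local = g.add(Conv(f"{prefix}.dw_local", x0, d, d, 1, groups=d, bias=True))
    gc = g.add(Conv(f"{prefix}.g_proj", x0, d, d, 1, bias=True))
    gca = g.add(DualDomainChannelAttn(f"{prefix}.dcam", gc, d, spec.ca_reduction))
    gout = g.add(FreqSpatialGate(f"{prefix}.fsam", gca, d))
    merged = g.add(Add(f"{prefix}.sum", [x0, large, local, gout]))
    return g.add(Conv(f"{prefix}.out", merged, d, d, 1, bias=True))


class _StripConv(Conv):
    """Depthwise 1xK / Kx1 conv (anisotropic kernel)."""

    def __init__(self, name, inp, channels, kh, kw):
        Node.__init__(self, name, [inp])
        from .graph import LayerSpec

        self.spec = LayerSpec(kind="conv", kernel_h=kh, kernel_w=kw,
                              in_channels=channels, out_channels=channels,
                              stride=1, padding=0, groups=channels, has_bias=True)

    def out_hw(self, in_hw):
        return in_hw[0]

    def forward(self, xs, w):
        s = self.spec
        x = np.pad(xs[0], ((0, 0), (s.kernel_h // 2,) * 2, (s.kernel_w // 2,) * 2))
        win = np.lib.stride_tricks.sliding_window_view(
            x, (s.kernel_h, s.kernel_w), axis=(1, 2))
        y = np.einsum("chwkl,ckl->chw", win.astype(np.float32),
                      w["weight"][:, 0].astype(np.float32))
        return y + w["bias"][:, None, None]

    def macs(self, in_ch, in_hw):
        s = self.spec
        h, w = in_hw[0]
        return h * w * s.out_channels * (s.kernel_h * s.kernel_w + 1)


def _strip(g, name, inp, channels, kh, kw):
    return g.add(_StripConv(name, inp, channels, kh, kw))


def add_csp_omnikernel(g: BlockGraph, prefix: str, inp: str, cin: int, cout: int,
                       ok_spec: OmniKernelSpec | None = None) -> str:
    """Cross-stage partial wrap: half the channels bypass, half pass the
    OmniKernel mixer; concat, then a 1x1 CBS fuses down to ``cout``."""
    if cin % 2 or cout % 2:
        raise GraphValidationError(f"{prefix}: csp channels must be even")
    spec = ok_spec or OmniKernelSpec(dim=cin // 2)
    if spec.dim != cin // 2:
        raise GraphValidationError(f"{prefix}: omnikernel dim must equal cin/2")
    sp = g.add(Split(f"{prefix}.split", inp))
    ok = add_omnikernel(g, f"{prefix}.ok", f"{sp}:1", spec)
    cat = g.add(Concat(f"{prefix}.cat", [f"{sp}:0", ok]))
    return add_cbs(g, f"{prefix}.fuse", cat, cin, cout, 1)


def dattention_hook(spec: DeformableAttentionSpec | None = None):
    """branch_post hook for ``add_c2f``: deformable attention with a residual
    connection on the hidden bottleneck branch."""

    def hook(g: BlockGraph, prefix: str, node: str, h: int) -> str:
        s = spec or DeformableAttentionSpec(dim=h)
        attn = g.add(DeformAttn(f"{prefix}.dattn", node, s))
        return g.add(Add(f"{prefix}.dattn_add", [node, attn]))

    return hook


def soep_fusion_builder(spd_width: int | None = None):
    """p3_fusion_builder for :func:`assemble_baseline`.

    SPD-Conv folds the high-resolution P2 map to P3 scale without discarding
    pixels; its output is concatenated with the top-down feature and the
    backbone P3 map, and a CSP-OmniKernel block aggregates the result.  The
    downstream PAFPN paths and the three heads are untouched.
    """

    def build(g: BlockGraph, prefix: str, inputs: dict, cin: int, cout: int) -> str:
        ch = g._static_in_channels()
        p2_ch = ch[inputs["p2"].partition(":")[0]]
        c_spd = spd_width if spd_width is not None else max(
            8, int(round(SPD_WIDTH_BASE * cout / 256 / 8) * 8))
        spd = add_spdconv(g, f"{prefix}.spd", inputs["p2"], p2_ch, c_spd)
        cat = g.add(Concat(f"{prefix}.cat", [inputs["topdown"], inputs["p3"], spd]))
        return add_csp_omnikernel(g, f"{prefix}.csp_ok", cat, cin + c_spd, cout)

    return build


# ---------------------------------------------------------------------------
# Spec-surface builders
# ---------------------------------------------------------------------------


def build_spdconv(in_channels, out_channels) -> BlockGraph:
    if min(in_channels, out_channels) < 1:
        raise DimensionError("channels must be >= 1")
    g = BlockGraph(tag="SPDConv")
    x = g.add_input("x", in_channels)
    g.outputs = [add_spdconv(g, "spd", x, in_channels, out_channels)]
    return g


def build_adown(in_channels, out_channels) -> BlockGraph:
    g = BlockGraph(tag="ADown")
    x = g.add_input("x", in_channels)
    g.outputs = [add_adown(g, "adown", x, in_channels, out_channels)]
    return g


def build_deformable_attention(spec: DeformableAttentionSpec) -> BlockGraph:
    g = BlockGraph(tag="DAttention")
    x = g.add_input("x", spec.dim)
    g.outputs = [g.add(DeformAttn("dattn", x, spec))]
    return g


def build_c2f_dattention(in_channels, out_channels, n=1,
                         spec: DeformableAttentionSpec | None = None) -> BlockGraph:
    g = BlockGraph(tag="C2f-DAttention")
    x = g.add_input("x", in_channels)
    g.outputs = [add_c2f(g, "c2f", x, in_channels, out_channels, n, True,
                         branch_post=dattention_hook(spec))]
    return g


def build_omnikernel(spec: OmniKernelSpec) -> BlockGraph:
    g = BlockGraph(tag="OmniKernel")
    x = g.add_input("x", spec.dim)
    g.outputs = [add_omnikernel(g, "ok", x, spec)]
    return g


def build_csp_omnikernel(in_channels, out_channels) -> BlockGraph:
    g = BlockGraph(tag="CSP-OmniKernel")
    x = g.add_input("x", in_channels)
    g.outputs = [add_csp_omnikernel(g, "csp_ok", x, in_channels, out_channels)]
    return g


def build_soep_neck(p2_ch, p3_ch, p4_ch, p5_ch, spd_width=None) -> BlockGraph:
    """Standalone P3-fusion subgraph of the small-object pyramid.

    Inputs: ``p2`` at twice the P3 resolution, ``p3``, and the upsampled
    top-down feature ``topdown`` (``p4_ch`` channels) at P3 resolution.
    """
    g = BlockGraph(tag="SOEP")
    g.add_input("p2", p2_ch)
    g.add_input("p3", p3_ch)
    g.add_input("topdown", p4_ch)
    build = soep_fusion_builder(spd_width)
    g.outputs = [build(g, "soep", {"p2": "p2", "p3": "p3", "topdown": "topdown"},
                       p4_ch + p3_ch, p3_ch)]
    return g
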