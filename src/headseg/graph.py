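"""Computation-graph primitives for the segmentation network.

Everything in this package is expressed as a :class:`BlockGraph`: a small DAG of
typed nodes (convolutions, norms, activations, pools, concats, attention
operators, ...).  Each node knows three things in closed form:

* its learnable-parameter shapes (so totals can be cross-checked against an
  independent enumeration of the materialized weight tensors),
* its multiply-accumulate cost given the input spatial size (profiling uses the
  MAC x 2 floating-point convention), and
* how to execute itself on NumPy arrays (single image, channel-first ``CHW``).

Parameter accounting follows the usual closed forms: a convolution holds
``Kh*Kw*Cin/groups*Cout`` weights (plus ``Cout`` if biased), a norm layer holds
the ``2*C`` affine parameters (running statistics are not learnable), and
pooling/activation/reshape nodes hold none.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal


class GraphValidationError(ValueError):
    """Raised when channel bookkeeping or shape preconditions fail."""


class DimensionError(GraphValidationError):
    """Raised for non-positive or indivisible tensor dimensions."""


@dataclass(frozen=True)
class TensorSpec:
    """Shape of a feature map: channels x height x width (batch of one)."""

    channels: int
    height: int
    width: int

    def __post_init__(self):
        if min(self.channels, self.height, self.width) < 1:
            raise DimensionError(f"tensor dimensions must be positive: {self}")

    @property
    def hw(self):
        return (self.height, self.width)


@dataclass(frozen=True)
class LayerSpec:
    """A parameterized layer with closed-form parameter and output-size rules."""

    kind: str  # conv | depthwise_conv | linear | norm | pool | activation
    kernel_h: int = 1
    kernel_w: int = 1
    in_channels: int = 0
    out_channels: int = 0
    stride: int = 1
    padding: int = 0
    groups: int = 1
    has_bias: bool = False

    def param_count(self) -> int:
        if self.kind in ("conv", "depthwise_conv"):
            g = self.in_channels if self.kind == "depthwise_conv" else self.groups
            n = self.kernel_h * self.kernel_w * (self.in_channels // g) * self.out_channels
            return n + (self.out_channels if self.has_bias else 0)
        if self.kind == "linear":
            return self.in_channels * self.out_channels + (
                self.out_channels if self.has_bias else 0
            )
        if self.kind == "norm":
            return 2 * self.out_channels
        if self.kind in ("pool", "activation"):
            return 0
        raise ValueError(f"unknown layer kind {self.kind!r}")

    def out_size(self, in_size: int) -> int:
        """floor((in + 2*pad - K) / stride) + 1 along one spatial axis."""
        k = max(self.kernel_h, self.kernel_w)
        out = (in_size + 2 * self.padding - k) // self.stride + 1
        if out < 1:
            raise DimensionError(
                f"kernel {k} with stride {self.stride} does not fit input size {in_size}"
            )
        return out


def _node_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _pad2d(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (ph, ph), (pw, pw)))


def _windows(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(C, Ho, Wo, kh, kw) view of sliding windows."""
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    return v[:, ::stride, ::stride]


def conv2d(x, w, b=None, stride=1, padding=0, groups=1):
    """Grouped 2-D cross-correlation on a CHW array. Weight: (Cout, Cin/g, kh, kw)."""
    cout, cpg, kh, kw = w.shape
    cin = x.shape[0]
    if cin != cpg * groups:
        raise GraphValidationError(
            f"conv expected {cpg * groups} input channels, got {cin}"
        )
    xp = _pad2d(np.ascontiguousarray(x, dtype=np.float32), padding, padding)
    if groups == cin and cpg == 1 and kh * kw > 81:
        # Large depthwise kernels: frequency-domain convolution, channel-batched.
        kernel = w[:, 0, ::-1, ::-1].astype(np.float32)
        full = _signal.fftconvolve(xp, kernel, mode="valid", axes=(1, 2))
        y = full[:, ::stride, ::stride].astype(np.float32)
    else:
        win = _windows(xp, kh, kw, stride)  # (Cin, Ho, Wo, kh, kw)
        ho, wo = win.shape[1], win.shape[2]
        win = win.transpose(0, 3, 4, 1, 2).reshape(groups, cpg * kh * kw, ho * wo)
        wm = w.reshape(groups, cout // groups, cpg * kh * kw)
        y = np.einsum("gok,gkl->gol", wm.astype(np.float32), win.astype(np.float32))
        y = y.reshape(cout, ho, wo)
    if b is not None:
        y = y + b[:, None, None].astype(np.float32)
    return y


def silu(x):
    return x / (1.0 + np.exp(-x))


def gelu(x):
    return 0.5 * x * (1.0 + np.tanh(0.7978845608028654 * (x + 0.044715 * x**3)))


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def bilinear_sample(x: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Sample a CHW map at fractional (y, x) locations. Returns (C, N)."""
    c, h, w = x.shape
    ys = np.clip(ys, 0.0, h - 1.0)
    xs = np.clip(xs, 0.0, w - 1.0)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = (ys - y0).astype(np.float32)
    fx = (xs - x0).astype(np.float32)
    v00 = x[:, y0, x0]
    v01 = x[:, y0, x1]
    v10 = x[:, y1, x0]
    v11 = x[:, y1, x1]
    return (
        v00 * (1 - fy) * (1 - fx)
        + v01 * (1 - fy) * fx
        + v10 * fy * (1 - fx)
        + v11 * fy * fx
    )


# ---------------------------------------------------------------------------
# Nodes
# ---------------------------------------------------------------------------


class Node:
    """One operation in a BlockGraph."""

    n_outputs = 1

    def __init__(self, name: str, inputs: list[str]):
        self.name = name
        self.inputs = list(inputs)

    # -- static accounting -------------------------------------------------
    def out_channels(self, in_ch: list[int]) -> int:
        raise NotImplementedError

    def out_hw(self, in_hw: list[tuple[int, int]]) -> tuple[int, int]:
        return in_hw[0]

    def param_shapes(self, in_ch: list[int]) -> dict[str, tuple]:
        return {}

    def param_count(self, in_ch: list[int]) -> int:
        return int(sum(np.prod(s) for s in self.param_shapes(in_ch).values()))

    def macs(self, in_ch, in_hw) -> int:
        return 0

    # -- execution ---------------------------------------------------------
    def init_weights(self, in_ch: list[int], rng: np.random.Generator) -> dict:
        return {
            k: np.zeros(s, dtype=np.float32)
            for k, s in self.param_shapes(in_ch).items()
        }

    def forward(self, xs: list[np.ndarray], w: dict) -> np.ndarray:
        raise NotImplementedError


class Input(Node):
    def __init__(self, name, channels):
        super().__init__(name, [])
        self.channels = channels

    def out_channels(self, in_ch):
        return self.channels


class Conv(Node):
    """2-D convolution; ``bias`` is off when a norm layer follows (it absorbs it)."""

    def __init__(self, name, inp, in_channels, out_channels, kernel=1, stride=1,
                 padding=None, groups=1, bias=False):
        super().__init__(name, [inp])
        if min(in_channels, out_channels, kernel, stride) < 1:
            raise DimensionError("conv dimensions must be >= 1")
        if in_channels % groups or out_channels % groups:
            raise GraphValidationError("channels must divide groups")
        self.spec = LayerSpec(
            kind="conv", kernel_h=kernel, kernel_w=kernel,
            in_channels=in_channels, out_channels=out_channels, stride=stride,
            padding=kernel // 2 if padding is None else padding,
            groups=groups, has_bias=bias,
        )

    def out_channels(self, in_ch):
        if in_ch[0] != self.spec.in_channels:
            raise GraphValidationError(
                f"{self.name}: expected {self.spec.in_channels} input channels, "
                f"got {in_ch[0]}"
            )
        return self.spec.out_channels

    def out_hw(self, in_hw):
        return (self.spec.out_size(in_hw[0][0]), self.spec.out_size(in_hw[0][1]))

    def param_shapes(self, in_ch):
        s = self.spec
        shapes = {
            "weight": (s.out_channels, s.in_channels // s.groups, s.kernel_h, s.kernel_w)
        }
        if s.has_bias:
            shapes["bias"] = (s.out_channels,)
        return shapes

    def macs(self, in_ch, in_hw):
        s = self.spec
        ho, wo = self.out_hw(in_hw)
        per_out = s.kernel_h * s.kernel_w * (s.in_channels // s.groups)
        # the +1 mirrors the fused conv+norm bias term of standard profilers
        return ho * wo * s.out_channels * (per_out + (1 if s.has_bias else 0))

    def init_weights(self, in_ch, rng):
        s = self.spec
        fan_in = s.kernel_h * s.kernel_w * s.in_channels // s.groups
        w = {
            "weight": rng.normal(
                0.0, math.sqrt(2.0 / fan_in), self.param_shapes(in_ch)["weight"]
            ).astype(np.float32)
        }
        if s.has_bias:
            w["bias"] = np.zeros(s.out_channels, dtype=np.float32)
        return w

    def forward(self, xs, w):
        s = self.spec
        return conv2d(xs[0], w["weight"], w.get("bias"), s.stride, s.padding, s.groups)


class ConvTranspose(Node):
    """Stride-2, kernel-2 transposed conv (the prototype-mask upsampler)."""

    def __init__(self, name, inp, in_channels, out_channels):
        super().__init__(name, [inp])
        self.cin, self.cout = in_channels, out_channels

    def out_channels(self, in_ch):
        if in_ch[0] != self.cin:
            raise GraphValidationError(f"{self.name}: channel mismatch")
        return self.cout

    def out_hw(self, in_hw):
        return (in_hw[0][0] * 2, in_hw[0][1] * 2)

    def param_shapes(self, in_ch):
        return {"weight": (self.cin, self.cout, 2, 2), "bias": (self.cout,)}

    def macs(self, in_ch, in_hw):
        # standard-profiler convention: kernel taps counted per *output* element
        h, w = in_hw[0]
        return (2 * h) * (2 * w) * self.cout * (4 * self.cin + 1)

    def init_weights(self, in_ch, rng):
        return {
            "weight": rng.normal(0, math.sqrt(2.0 / self.cin), (self.cin, self.cout, 2, 2)
                                 ).astype(np.float32),
            "bias": np.zeros(self.cout, dtype=np.float32),
        }

    def forward(self, xs, w):
        x = xs[0]
        c, h, wd = x.shape
        y = np.einsum("chw,cokl->okhlw", x.astype(np.float32), w["weight"])
        y = y.reshape(self.cout, 2, h, 2, wd).transpose(0, 2, 1, 4, 3)
        y = y.reshape(self.cout, 2 * h, 2 * wd)
        return y + w["bias"][:, None, None]


class Norm(Node):
    """Channel norm with learnable affine (2C params); inference-time affine map."""

    def __init__(self, name, inp, channels):
        super().__init__(name, [inp])
        self.channels = channels

    def out_channels(self, in_ch):
        if in_ch[0] != self.channels:
            raise GraphValidationError(f"{self.name}: channel mismatch")
        return self.channels

    def param_shapes(self, in_ch):
        return {"gamma": (self.channels,), "beta": (self.channels,)}

    def init_weights(self, in_ch, rng):
        return {
            "gamma": np.ones(self.channels, dtype=np.float32),
            "beta": np.zeros(self.channels, dtype=np.float32),
        }

    def forward(self, xs, w):
        return xs[0] * w["gamma"][:, None, None] + w["beta"][:, None, None]


class Act(Node):
    FUNCS = {"silu": silu, "gelu": gelu, "relu": lambda x: np.maximum(x, 0.0),
             "sigmoid": sigmoid, "tanh": np.tanh}

    def __init__(self, name, inp, fn="silu"):
        super().__init__(name, [inp])
        self.fn = fn

    def out_channels(self, in_ch):
        return in_ch[0]

    def forward(self, xs, w):
        return self.FUNCS[self.fn](xs[0])


class Pool(Node):
    def __init__(self, name, inp, mode, kernel, stride, padding=0):
        super().__init__(name, [inp])
        self.mode, self.kernel, self.stride, self.padding = mode, kernel, stride, padding

    def out_channels(self, in_ch):
        return in_ch[0]

    def out_hw(self, in_hw):
        h, w = in_hw[0]
        f = lambda n: (n + 2 * self.padding - self.kernel) // self.stride + 1
        if f(h) < 1 or f(w) < 1:
            raise DimensionError(f"{self.name}: pool does not fit input {h}x{w}")
        return (f(h), f(w))

    def forward(self, xs, w):
        x = xs[0]
        if self.mode == "max" and self.padding:
            xp = np.pad(x, ((0, 0), (self.padding,) * 2, (self.padding,) * 2),
                        constant_values=-np.inf)
        else:
            xp = _pad2d(x, self.padding, self.padding)
        win = _windows(xp, self.kernel, self.kernel, self.stride)
        return win.max(axis=(3, 4)) if self.mode == "max" else win.mean(axis=(3, 4))


class Upsample(Node):
    """Nearest-neighbour x2."""

    def __init__(self, name, inp):
        super().__init__(name, [inp])

    def out_channels(self, in_ch):
        return in_ch[0]

    def out_hw(self, in_hw):
        return (in_hw[0][0] * 2, in_hw[0][1] * 2)

    def forward(self, xs, w):
        return np.repeat(np.repeat(xs[0], 2, axis=1), 2, axis=2)


class Concat(Node):
    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def out_channels(self, in_ch):
        return sum(in_ch)

    def out_hw(self, in_hw):
        if len(set(in_hw)) != 1:
            raise GraphValidationError(f"{self.name}: concat spatial mismatch {in_hw}")
        return in_hw[0]

    def forward(self, xs, w):
        return np.concatenate(xs, axis=0)


class Split(Node):
    """Channel chunk into equal halves; outputs referenced as name:0, name:1."""

    n_outputs = 2

    def __init__(self, name, inp):
        super().__init__(name, [inp])

    def out_channels(self, in_ch):
        if in_ch[0] % 2:
            raise GraphValidationError(f"{self.name}: cannot split odd channels")
        return (in_ch[0] // 2, in_ch[0] // 2)

    def forward(self, xs, w):
        c = xs[0].shape[0] // 2
        return (xs[0][:c], xs[0][c:])


class Add(Node):
    def __init__(self, name, inputs):
        super().__init__(name, inputs)

    def out_channels(self, in_ch):
        if len(set(in_ch)) != 1:
            raise GraphValidationError(f"{self.name}: add channel mismatch {in_ch}")
        return in_ch[0]

    def forward(self, xs, w):
        out = xs[0]
        for x in xs[1:]:
            out = out + x
        return out


class SpaceToDepth(Node):
    """Lossless (H, W, C) -> (H/f, W/f, C*f^2) fold.

    Sub-lattice ordering: output channel block ``(dy, dx)`` (row-major over the
    f x f phase grid) holds ``x[:, dy::f, dx::f]``.  Bijective by construction.
    """

    def __init__(self, name, inp, factor=2):
        super().__init__(name, [inp])
        if factor < 1:
            raise DimensionError("factor must be >= 1")
        self.factor = factor

    def out_channels(self, in_ch):
        return in_ch[0] * self.factor**2

    def out_hw(self, in_hw):
        h, w = in_hw[0]
        f = self.factor
        if h % f or w % f:
            raise DimensionError(
                f"{self.name}: spatial size {h}x{w} not divisible by factor {f}"
            )
        return (h // f, w // f)

    def forward(self, xs, w):
        return space_to_depth(xs[0], self.factor)


def space_to_depth(x: np.ndarray, factor: int) -> np.ndarray:
    """Functional space-to-depth on a CHW array (see :class:`SpaceToDepth`)."""
    c, h, wd = x.shape
    f = factor
    if f == 1:
        return x.copy()
    if h % f or wd % f:
        raise DimensionError(f"spatial size {h}x{wd} not divisible by factor {f}")
    y = x.reshape(c, h // f, f, wd // f, f).transpose(2, 4, 0, 1, 3)
    return y.reshape(c * f * f, h // f, wd // f)


def depth_to_space(x: np.ndarray, factor: int) -> np.ndarray:
    """Exact inverse of :func:`space_to_depth`."""
    c, h, wd = x.shape
    f = factor
    if f == 1:
        return x.copy()
    if c % (f * f):
        raise DimensionError(f"channels {c} not divisible by factor^2 {f * f}")
    y = x.reshape(f, f, c // (f * f), h, wd).transpose(2, 3, 0, 4, 1)
    return y.reshape(c // (f * f), h * f, wd * f)


# ---------------------------------------------------------------------------
# BlockGraph
# ---------------------------------------------------------------------------


@dataclass
class BlockGraph:
    """An ordered DAG of nodes with named external inputs and outputs."""

    tag: str = ""
    nodes: dict = field(default_factory=dict)
    input_channels: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    _weights: dict | None = field(default=None, repr=False)

    # -- construction ------------------------------------------------------
    def add_input(self, name: str, channels: int) -> str:
        if channels < 1:
            raise DimensionError("input channels must be positive")
        self.input_channels[name] = channels
        return name

    def add(self, node: Node) -> str:
        if node.name in self.nodes or node.name in self.input_channels:
            raise GraphValidationError(f"duplicate node name {node.name!r}")
        for ref in node.inputs:
            base = ref.split(":")[0]
            if base not in self.nodes and base not in self.input_channels:
                raise GraphValidationError(f"{node.name}: unknown input {ref!r}")
        self.nodes[node.name] = node
        self._weights = None
        return node.name

    def merge(self, other: "BlockGraph", prefix: str, input_map: dict) -> dict:
        """Graft ``other`` into this graph under ``prefix``; returns output renames."""
        for ext in other.input_channels:
            if ext not in input_map:
                raise GraphValidationError(f"merge: unmapped input {ext!r}")
        rename = dict(input_map)
        for name, node in other.nodes.items():
            import copy

            new = copy.deepcopy(node)
            new.name = f"{prefix}.{name}"
            new.inputs = [
                (rename[r.split(":")[0]] + (":" + r.split(":")[1] if ":" in r else ""))
                if r.split(":")[0] in rename
                else f"{prefix}.{r}"
                for r in node.inputs
            ]
            self.add(new)
            rename[name] = new.name
        return {
            out: (
                rename[out.split(":")[0]]
                + (":" + out.split(":")[1] if ":" in out else "")
            )
            for out in other.outputs
        }

    # -- analysis ----------------------------------------------------------
    def _ref_channels(self, ref: str, ch: dict) -> int:
        base, _, idx = ref.partition(":")
        c = ch[base]
        return c[int(idx)] if isinstance(c, tuple) else c

    def _ref_hw(self, ref: str, hw: dict):
        return hw[ref.partition(":")[0]]

    def trace(self, input_hw: dict | int):
        """Propagate (channels, h, w) through the graph; validates bookkeeping."""
        if isinstance(input_hw, int):
            input_hw = {k: (input_hw, input_hw) for k in self.input_channels}
        ch = dict(self.input_channels)
        hw = dict(input_hw)
        for name, node in self.nodes.items():
            in_ch = [self._ref_channels(r, ch) for r in node.inputs]
            in_hw = [self._ref_hw(r, hw) for r in node.inputs]
            ch[name] = node.out_channels(in_ch)
            hw[name] = node.out_hw(in_hw)
        return ch, hw

    def validate(self, input_hw: dict | int = 64) -> None:
        self.trace(input_hw)

    def _static_in_channels(self):
        """Channel map derived without spatial sizes (for param counting)."""
        ch = dict(self.input_channels)
        for name, node in self.nodes.items():
            ch[name] = node.out_channels(
                [self._ref_channels(r, ch) for r in node.inputs]
            )
        return ch

    def param_count(self) -> int:
        ch = dict(self.input_channels)
        total = 0
        for name, node in self.nodes.items():
            in_ch = [self._ref_channels(r, ch) for r in node.inputs]
            total += node.param_count(in_ch)
            ch[name] = node.out_channels(in_ch)
        return total

    def per_node_params(self) -> dict:
        ch = dict(self.input_channels)
        out = {}
        for name, node in self.nodes.items():
            in_ch = [self._ref_channels(r, ch) for r in node.inputs]
            out[name] = node.param_count(in_ch)
            ch[name] = node.out_channels(in_ch)
        return out

    def macs(self, input_hw: dict | int) -> int:
        if isinstance(input_hw, int):
            input_hw = {k: (input_hw, input_hw) for k in self.input_channels}
        ch = dict(self.input_channels)
        hw = dict(input_hw)
        total = 0
        for name, node in self.nodes.items():
            in_ch = [self._ref_channels(r, ch) for r in node.inputs]
            in_hw = [self._ref_hw(r, hw) for r in node.inputs]
            total += node.macs(in_ch, in_hw)
            ch[name] = node.out_channels(in_ch)
            hw[name] = node.out_hw(in_hw)
        return total

    def per_node_macs(self, input_hw: dict | int) -> dict:
        if isinstance(input_hw, int):
            input_hw = {k: (input_hw, input_hw) for k in self.input_channels}
        ch = dict(self.input_channels)
        hw = dict(input_hw)
        out = {}
        for name, node in self.nodes.items():
            in_ch = [self._ref_channels(r, ch) for r in node.inputs]
            in_hw = [self._ref_hw(r, hw) for r in node.inputs]
            out[name] = node.macs(in_ch, in_hw)
            ch[name] = node.out_channels(in_ch)
            hw[name] = node.out_hw(in_hw)
        return out

    # -- execution ---------------------------------------------------------
    def materialize(self, seed: int = 0) -> dict:
        """Create (deterministically seeded) weights for every node."""
        ch = dict(self.input_channels)
        weights = {}
        for name, node in self.nodes.items():
            in_ch = [self._ref_channels(r, ch) for r in node.inputs]
            weights[name] = node.init_weights(in_ch, _node_rng(seed, name))
            ch[name] = node.out_channels(in_ch)
        self._weights = weights
        return weights

    @property
    def weights(self) -> dict:
        if self._weights is None:
            self.materialize(0)
        return self._weights

    def zero_(self, prefix: str = "") -> None:
        """Zero all weights (optionally only nodes under ``prefix``)."""
        for name, w in self.weights.items():
            if name.startswith(prefix):
                for arr in w.values():
                    arr[...] = 0.0

    def forward(self, inputs: dict | np.ndarray) -> dict:
        """Run the graph; returns {output name: array}."""
        if isinstance(inputs, np.ndarray):
            if len(self.input_channels) != 1:
                raise GraphValidationError("graph has multiple inputs; pass a dict")
            inputs = {next(iter(self.input_channels)): inputs}
        self.validate({k: v.shape[1:] for k, v in inputs.items()})
        weights = self.weights
        vals: dict = {}
        for k, v in inputs.items():
            if v.shape[0] != self.input_channels[k]:
                raise GraphValidationError(
                    f"input {k!r}: expected {self.input_channels[k]} channels, "
                    f"got {v.shape[0]}"
                )
            vals[k] = np.asarray(v, dtype=np.float32)

        def fetch(ref):
            base, _, idx = ref.partition(":")
            v = vals[base]
            return v[int(idx)] if isinstance(v, tuple) else v

        for name, node in self.nodes.items():
            vals[name] = node.forward([fetch(r) for r in node.inputs], weights[name])
        return {out: fetch(out) for out in self.outputs}

    def forward_one(self, x: np.ndarray) -> np.ndarray:
        """Convenience: single input, single output."""
        out = self.forward(x)
        if len(out) != 1:
            raise GraphValidationError("graph has multiple outputs")
        return next(iter(out.values()))

    def enumerate_weight_sizes(self) -> int:
        """Independent parameter total from the materialized tensors themselves."""
        return int(sum(a.size for w in self.weights.values() for a in w.values()))
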