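"""Assembly of the ablation-ladder model variants and analytic profiling.

The four published configurations are the baseline and the cumulative
additions of the deformable-attention C2f, ADown downsampling, and the small
object enhance pyramid.  Profiling is hardware-independent: parameters are the
closed-form sum over learnable tensors, and FLOPs are the per-layer analytic
multiply-accumulate count x 2 at a given input size (attention and
frequency-domain branches counted from their constituent operations;
transposed convolutions counted kernel-per-output-element, matching the
convention of the standard profilers that produced the published tables).
Frames per second is a wall-clock measurement and deliberately separate.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .graph import BlockGraph, DimensionError, GraphValidationError
from .nn_blocks import assemble_baseline, named_head_outputs
from .novel_blocks import add_adown, dattention_hook, soep_fusion_builder

#: backbone stage transitions (after the first post-stem conv) and neck
#: downsampling convs replaced when the adown flag is set; calibrated against
#: the published parameter/GFLOP ladder (see docs/methods.md)
ADOWN_PREFIXES = ("b.down2", "b.down3", "b.down4", "n.down1", "n.down2")


@dataclass(frozen=True)
class ModelVariant:
    """Flags selecting one ablation configuration.

    The published ladder is (F,F,F) -> (T,F,F) -> (T,T,F) -> (T,T,T); any
    other combination builds fine but is off the ladder.
    """

    c2f_dattention: bool = False
    adown: bool = False
    soep: bool = False
    n_classes: int = 1
    width_multiple: float = 0.25
    depth_multiple: float = 1 / 3

    @property
    def name(self) -> str:
        if not any((self.c2f_dattention, self.adown, self.soep)):
            return "baseline"
        parts = [p for p, on in (("dattention", self.c2f_dattention),
                                 ("adown", self.adown), ("soep", self.soep)) if on]
        return "+".join(parts) if parts != ["dattention", "adown", "soep"] else "full"

    def on_ladder(self) -> bool:
        flags = (self.c2f_dattention, self.adown, self.soep)
        return flags in {(False, False, False), (True, False, False),
                         (True, True, False), (True, True, True)}


VARIANTS = {
    "baseline": ModelVariant(),
    "dattention": ModelVariant(c2f_dattention=True),
    "dattention+adown": ModelVariant(c2f_dattention=True, adown=True),
    "full": ModelVariant(c2f_dattention=True, adown=True, soep=True),
}


@dataclass
class ProfileReport:
    """Parameter/FLOP/latency profile of one model variant."""

    variant: str
    total_params: int
    params_millions: float
    flops: int | None = None
    flops_g: float | None = None
    input_size: int | None = None
    fps: float | None = None
    per_block_breakdown: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def table(self) -> str:
        lines = [f"variant: {self.variant}",
                 f"params: {self.total_params} ({self.params_millions:.2f} M)"]
        if self.flops_g is not None:
            lines.append(f"flops @ {self.input_size}: {self.flops_g:.1f} G")
        if self.fps is not None:
            lines.append(f"fps: {self.fps:.1f}")
        if self.per_block_breakdown:
            lines.append("")
            lines.append(f"{'block':<12}{'params':>12}{'flops':>16}")
            for blk, row in self.per_block_breakdown.items():
                fl = f"{row['flops']:,}" if "flops" in row else "-"
                lines.append(f"{blk:<12}{row['params']:>12,}{fl:>16}")
        return "\n".join(lines)


def round_half_up(x: float, digits: int) -> float:
    """Round half away from zero at the printed precision."""
    f = 10.0**digits
    return np.sign(x) * np.floor(abs(x) * f + 0.5) / f


def build_variant(variant: ModelVariant, *, logger=None) -> BlockGraph:
    """Build a validated, runnable graph for one variant."""
    if variant.soep and not variant.adown and logger is not None:
        logger.warning("soep without adown: off-ladder configuration")
    hooks = {}
    if variant.c2f_dattention:
        # the deepest backbone C2f carries the attention branch
        hooks["b.s4"] = dattention_hook()

    def adown_builder(g, prefix, inp, cin, cout):
        if prefix in ADOWN_PREFIXES:
            return add_adown(g, prefix, inp, cin, cout)
        from .nn_blocks import add_cbs

        return add_cbs(g, prefix, inp, cin, cout, 3, 2)

    graph = assemble_baseline(
        width_multiple=variant.width_multiple,
        depth_multiple=variant.depth_multiple,
        n_classes=variant.n_classes,
        c2f_hooks=hooks,
        downsample_builder=adown_builder if variant.adown else None,
        p3_fusion_builder=soep_fusion_builder() if variant.soep else None,
    )
    graph.tag = variant.name
    return graph


def _block_of(node_name: str) -> str:
    parts = node_name.split(".")
    return ".".join(parts[:2]) if len(parts) > 1 else parts[0]


def count_params(graph: BlockGraph) -> ProfileReport:
    """Closed-form learnable-parameter total (independent of input size)."""
    per_node = graph.per_node_params()
    breakdown: dict = {}
    for name, p in per_node.items():
        blk = breakdown.setdefault(_block_of(name), {"params": 0})
        blk["params"] += p
    total = sum(per_node.values())
    return ProfileReport(
        variant=graph.tag, total_params=total,
        params_millions=round_half_up(total / 1e6, 2),
        per_block_breakdown=breakdown,
    )


def count_flops(graph: BlockGraph, input_size: int = 640) -> ProfileReport:
    """Analytic FLOPs (MAC x 2) for a square input; size must divide by 32."""
    if input_size % 32:
        raise DimensionError(f"input size {input_size} not divisible by 32")
    report = count_params(graph)
    per_node = graph.per_node_macs(input_size)
    for name, m in per_node.items():
        blk = report.per_block_breakdown.setdefault(
            _block_of(name), {"params": 0})
        blk["flops"] = blk.get("flops", 0) + 2 * m
    report.flops = 2 * sum(per_node.values())
    report.flops_g = round_half_up(report.flops / 1e9, 1)
    report.input_size = input_size
    return report


def measure_fps(graph: BlockGraph, n_frames: int = 10, warmup: int = 2,
                input_size: int = 640, seed: int = 0) -> float:
    """Frames per second of the NumPy forward pass (hardware-dependent)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    graph.weights  # materialize once
    x = rng.normal(0, 1, (3, input_size, input_size)).astype(np.float32)
    for _ in range(warmup):
        graph.forward(x)
    t0 = time.perf_counter()
    for _ in range(n_frames):
        graph.forward(x)
    elapsed = time.perf_counter() - t0
    if elapsed <= 0:
        raise ValueError("zero elapsed time; increase n_frames")
    return n_frames / elapsed


def profile_variant(variant: ModelVariant, input_size: int = 640,
                    with_fps: bool = False) -> ProfileReport:
    graph = build_variant(variant)
    report = count_flops(graph, input_size)
    if with_fps:
        report.fps = measure_fps(graph, n_frames=3, warmup=1, input_size=input_size)
    return report


def predict(graph: BlockGraph, image: np.ndarray, conf_threshold: float = 0.25,
            iou_threshold: float = 0.7, input_size: int = 640):
    """Run the model on an HWC RGB image end to end; returns instance masks."""
    from .data_io import letterbox_image
    from .nn_blocks import postprocess

    lb = letterbox_image(image, input_size)
    x = lb.astype(np.float32).transpose(2, 0, 1) / 255.0
    raw = named_head_outputs(graph, graph.forward(x))
    return postprocess(raw, conf_threshold, iou_threshold,
                       image.shape[:2], input_size)
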