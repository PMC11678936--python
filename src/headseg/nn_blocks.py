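"""Baseline single-stage segmentation blocks (YOLOv8n-seg-style).

The baseline is an anchor-free one-stage instance segmenter: a CSP backbone
(stem + four stages of strided conv and C2f blocks, closed by fast spatial
pyramid pooling), a PAFPN neck (two top-down and two bottom-up fusion paths),
and a decoupled head per pyramid level (P3/P4/P5, strides 8/16/32) emitting a
16-bin box-side distribution, class logits, and mask coefficients, plus a
prototype branch that produces shared mask bases at stride 4.  An instance
mask is the sigmoid of the coefficient-weighted prototype combination, cropped
to its box.

The nano scaling used throughout is depth 1/3, width 1/4 (channel plan
16/32/64/128/256); convolutions feeding a norm carry no bias.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _resize

from .graph import (
    Add,
    BlockGraph,
    Concat,
    Conv,
    ConvTranspose,
    DimensionError,
    GraphValidationError,
    Norm,
    Act,
    Pool,
    Split,
    Upsample,
)

REG_MAX = 16  # box-side distribution bins
N_MASK_COEFFS = 32


def _make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(round(x / divisor) * divisor))


def scaled_channels(base: int, width_multiple: float) -> int:
    """Width-scaled channel count, rounded to a multiple of 8."""
    return _make_divisible(base * width_multiple)


def scaled_depth(base: int, depth_multiple: float) -> int:
    return max(1, round(base * depth_multiple))


# ---------------------------------------------------------------------------
# In-graph builders (append nodes, return the output node name)
# ---------------------------------------------------------------------------


def add_cbs(g: BlockGraph, prefix: str, inp: str, cin: int, cout: int,
            kernel: int = 1, stride: int = 1) -> str:
    """Conv (no bias) + norm + SiLU."""
    c = g.add(Conv(f"{prefix}.conv", inp, cin, cout, kernel, stride))
    n = g.add(Norm(f"{prefix}.norm", c, cout))
    return g.add(Act(f"{prefix}.silu", n, "silu"))


def add_bottleneck(g: BlockGraph, prefix: str, inp: str, channels: int,
                   shortcut: bool = True) -> str:
    y = add_cbs(g, f"{prefix}.cv1", inp, channels, channels, 3)
    y = add_cbs(g, f"{prefix}.cv2", y, channels, channels, 3)
    if shortcut:
        y = g.add(Add(f"{prefix}.add", [inp, y]))
    return y


def add_c2f(g: BlockGraph, prefix: str, inp: str, cin: int, cout: int,
            n: int = 1, shortcut: bool = True, branch_post=None) -> str:
    """Split / chain bottlenecks / concat-all / fuse.

    ``branch_post(g, prefix, name, h)`` may wrap the final bottleneck branch
    (used by the deformable-attention variant).
    """
    if cout % 2:
        raise GraphValidationError(f"{prefix}: c2f out_channels must be even, got {cout}")
    if n < 1:
        raise GraphValidationError(f"{prefix}: need at least one bottleneck")
    h = cout // 2
    y = add_cbs(g, f"{prefix}.cv1", inp, cin, 2 * h, 1)
    sp = g.add(Split(f"{prefix}.split", y))
    branches = [f"{sp}:0", f"{sp}:1"]
    cur = f"{sp}:1"
    for i in range(n):
        cur = add_bottleneck(g, f"{prefix}.m{i}", cur, h, shortcut)
        branches.append(cur)
    if branch_post is not None:
        branches[-1] = branch_post(g, prefix, cur, h)
    cat = g.add(Concat(f"{prefix}.cat", branches))
    return add_cbs(g, f"{prefix}.cv2", cat, (2 + n) * h, cout, 1)


def add_sppf(g: BlockGraph, prefix: str, inp: str, channels: int,
             pool_kernel: int = 5) -> str:
    if channels % 2:
        raise GraphValidationError(f"{prefix}: sppf channels must be even")
    half = channels // 2
    y = add_cbs(g, f"{prefix}.cv1", inp, channels, half, 1)
    p1 = g.add(Pool(f"{prefix}.p1", y, "max", pool_kernel, 1, pool_kernel // 2))
    p2 = g.add(Pool(f"{prefix}.p2", p1, "max", pool_kernel, 1, pool_kernel // 2))
    p3 = g.add(Pool(f"{prefix}.p3", p2, "max", pool_kernel, 1, pool_kernel // 2))
    cat = g.add(Concat(f"{prefix}.cat", [y, p1, p2, p3]))
    return add_cbs(g, f"{prefix}.cv2", cat, 4 * half, channels, 1)


def _add_head_branch(g, prefix, inp, cin, mid, cout):
    y = add_cbs(g, f"{prefix}.b0", inp, cin, mid, 3)
    y = add_cbs(g, f"{prefix}.b1", y, mid, mid, 3)
    return g.add(Conv(f"{prefix}.out", y, mid, cout, 1, bias=True))


def add_seg_heads(g: BlockGraph, prefix: str, levels: list[tuple[str, int]],
                  n_classes: int, n_mask_coeffs: int = N_MASK_COEFFS,
                  proto_ch: int | None = None) -> dict:
    """Decoupled detect + segment heads over (node, channels) pyramid levels."""
    if len(levels) != 3:
        raise GraphValidationError("seg heads need exactly three feature levels")
    if n_mask_coeffs < 1:
        raise GraphValidationError("n_mask_coeffs must be >= 1")
    ch0 = levels[0][1]
    c_box = max(16, ch0 // 4, 4 * REG_MAX)
    c_cls = max(ch0, min(n_classes, 100))
    c_mcf = max(ch0 // 4, n_mask_coeffs)
    proto_ch = ch0 if proto_ch is None else proto_ch
    outputs = {}
    for i, (node, cin) in enumerate(levels):
        lvl = f"p{i + 3}"
        outputs[f"{lvl}_box"] = _add_head_branch(
            g, f"{prefix}.{lvl}.box", node, cin, c_box, 4 * REG_MAX)
        outputs[f"{lvl}_cls"] = _add_head_branch(
            g, f"{prefix}.{lvl}.cls", node, cin, c_cls, n_classes)
        outputs[f"{lvl}_mcf"] = _add_head_branch(
            g, f"{prefix}.{lvl}.mcf", node, cin, c_mcf, n_mask_coeffs)
    # prototype branch off P3, upsampled x2 (stride 4 mask bases)
    p3_node, p3_ch = levels[0]
    y = add_cbs(g, f"{prefix}.proto.cv1", p3_node, p3_ch, proto_ch, 3)
    y = g.add(ConvTranspose(f"{prefix}.proto.up", y, proto_ch, proto_ch))
    y = g.add(Act(f"{prefix}.proto.up_act", y, "silu"))
    y = add_cbs(g, f"{prefix}.proto.cv2", y, proto_ch, proto_ch, 3)
    outputs["protos"] = add_cbs(
        g, f"{prefix}.proto.cv3", y, proto_ch, n_mask_coeffs, 1)
    return outputs


# ---------------------------------------------------------------------------
# Spec-surface builders returning standalone BlockGraphs
# ---------------------------------------------------------------------------


def build_cbs(in_channels, out_channels, kernel=3, stride=1) -> BlockGraph:
    if min(in_channels, out_channels, kernel, stride) < 1:
        raise DimensionError("cbs dimensions must be >= 1")
    g = BlockGraph(tag="CBS")
    x = g.add_input("x", in_channels)
    out = add_cbs(g, "cbs", x, in_channels, out_channels, kernel, stride)
    g.outputs = [out]
    return g


def build_c2f(in_channels, out_channels, n_bottlenecks=1, shortcut=True) -> BlockGraph:
    g = BlockGraph(tag="C2f")
    x = g.add_input("x", in_channels)
    out = add_c2f(g, "c2f", x, in_channels, out_channels, n_bottlenecks, shortcut)
    g.outputs = [out]
    return g


def build_sppf(channels, pool_kernel=5) -> BlockGraph:
    g = BlockGraph(tag="SPPF")
    x = g.add_input("x", channels)
    out = add_sppf(g, "sppf", x, channels, pool_kernel)
    g.outputs = [out]
    return g


def build_seg_heads(p3_ch, p4_ch, p5_ch, n_classes=1,
                    n_mask_coeffs=N_MASK_COEFFS, proto_ch=None) -> BlockGraph:
    g = BlockGraph(tag="SegHead")
    p3 = g.add_input("p3", p3_ch)
    p4 = g.add_input("p4", p4_ch)
    p5 = g.add_input("p5", p5_ch)
    outs = add_seg_heads(g, "head", [(p3, p3_ch), (p4, p4_ch), (p5, p5_ch)],
                         n_classes, n_mask_coeffs, proto_ch)
    g.outputs = list(outs.values())
    return g


def assemble_baseline(width_multiple: float = 0.25, depth_multiple: float = 1 / 3,
                      n_classes: int = 1, *, c2f_hooks: dict | None = None,
                      downsample_builder=None, p3_fusion_builder=None) -> BlockGraph:
    """Full backbone + PAFPN neck + segmentation heads.

    The three ``*_hooks``/``*_builder`` extension points let the ablation
    variants swap blocks in place while keeping one channel plan:

    * ``c2f_hooks``: {stage name: branch_post callable} (deformable attention),
    * ``downsample_builder(g, prefix, inp, cin, cout) -> node``: replaces the
      listed stride-2 transition convs,
    * ``p3_fusion_builder(g, prefix, inputs, cin, cout) -> node``: replaces the
      P3 top-down fusion block (small-object pyramid).
    """
    if not (0 < width_multiple <= 1 and 0 < depth_multiple <= 1):
        raise GraphValidationError("scale multiples must lie in (0, 1]")
    c2f_hooks = c2f_hooks or {}
    w = lambda c: scaled_channels(c, width_multiple)
    d = lambda n: scaled_depth(n, depth_multiple)
    c1, c2, c3, c4, c5 = w(64), w(128), w(256), w(512), w(1024)

    def down(g, prefix, inp, cin, cout, use_builder):
        if use_builder and downsample_builder is not None:
            return downsample_builder(g, prefix, inp, cin, cout)
        return add_cbs(g, prefix, inp, cin, cout, 3, 2)

    g = BlockGraph(tag="model")
    img = g.add_input("image", 3)
    # backbone; the first post-stem transition stays a plain strided conv
    x = add_cbs(g, "b.stem", img, 3, c1, 3, 2)                      # P1 /2
    x = down(g, "b.down1", x, c1, c2, use_builder=False)            # P2 /4
    p2 = add_c2f(g, "b.s1", x, c2, c2, d(3), True,
                 branch_post=c2f_hooks.get("b.s1"))
    x = down(g, "b.down2", p2, c2, c3, use_builder=True)            # P3 /8
    p3 = add_c2f(g, "b.s2", x, c3, c3, d(6), True,
                 branch_post=c2f_hooks.get("b.s2"))
    x = down(g, "b.down3", p3, c3, c4, use_builder=True)            # P4 /16
    p4 = add_c2f(g, "b.s3", x, c4, c4, d(6), True,
                 branch_post=c2f_hooks.get("b.s3"))
    x = down(g, "b.down4", p4, c4, c5, use_builder=True)            # P5 /32
    x = add_c2f(g, "b.s4", x, c5, c5, d(3), True,
                branch_post=c2f_hooks.get("b.s4"))
    p5 = add_sppf(g, "b.sppf", x, c5)

    # neck: top-down
    u1 = g.add(Upsample("n.up1", p5))
    cat1 = g.add(Concat("n.cat1", [u1, p4]))
    t4 = add_c2f(g, "n.td4", cat1, c5 + c4, c4, d(3), False)
    u2 = g.add(Upsample("n.up2", t4))
    if p3_fusion_builder is not None:
        t3 = p3_fusion_builder(g, "n.td3", {"topdown": u2, "p3": p3, "p2": p2},
                               c4 + c3, c3)
    else:
        cat2 = g.add(Concat("n.cat2", [u2, p3]))
        t3 = add_c2f(g, "n.td3", cat2, c4 + c3, c3, d(3), False)
    # neck: bottom-up
    dn1 = down(g, "n.down1", t3, c3, c3, use_builder=True)
    cat3 = g.add(Concat("n.cat3", [dn1, t4]))
    o4 = add_c2f(g, "n.bu4", cat3, c3 + c4, c4, d(3), False)
    dn2 = down(g, "n.down2", o4, c4, c4, use_builder=True)
    cat4 = g.add(Concat("n.cat4", [dn2, p5]))
    o5 = add_c2f(g, "n.bu5", cat4, c4 + c5, c5, d(3), False)

    outs = add_seg_heads(g, "head", [(t3, c3), (o4, c4), (o5, c5)], n_classes)
    g.outputs = [outs[k] for k in
                 ("p3_box", "p3_cls", "p3_mcf", "p4_box", "p4_cls", "p4_mcf",
                  "p5_box", "p5_cls", "p5_mcf", "protos")]
    g.output_names = list(
        ("p3_box", "p3_cls", "p3_mcf", "p4_box", "p4_cls", "p4_mcf",
         "p5_box", "p5_cls", "p5_mcf", "protos"))
    g.validate(64)
    return g


def named_head_outputs(graph: BlockGraph, outputs: dict) -> dict:
    """Map graph.forward() results onto the canonical head-output names."""
    return {name: outputs[node] for name, node in
            zip(graph.output_names, graph.outputs)}


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------


def letterbox_params(original_hw: tuple[int, int], target: int) -> tuple[float, int, int]:
    """(scale, pad_top, pad_left) of the aspect-preserving symmetric letterbox."""
    h, w = original_hw
    scale = min(target / h, target / w)
    nh, nw = round(h * scale), round(w * scale)
    return scale, (target - nh) // 2, (target - nw) // 2


def _decode_boxes(box_map: np.ndarray, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """DFL decode: (4*REG_MAX, H, W) -> boxes (N, 4) xyxy in input pixels."""
    _, h, w = box_map.shape
    dist = box_map.reshape(4, REG_MAX, h * w)
    dist = np.exp(dist - dist.max(axis=1, keepdims=True))
    dist /= dist.sum(axis=1, keepdims=True)
    ltrb = np.einsum("kbn,b->kn", dist, np.arange(REG_MAX, dtype=np.float32))
    gy, gx = np.mgrid[0:h, 0:w]
    cx = (gx.ravel() + 0.5) * stride
    cy = (gy.ravel() + 0.5) * stride
    l, t, r, b = ltrb * stride
    return np.stack([cx - l, cy - t, cx + r, cy + b], axis=1), np.stack([cx, cy], 1)


def _box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.prod(np.clip(br - tl, 0, None), axis=2)
    area_a = np.prod(a[:, 2:] - a[:, :2], axis=1)
    area_b = np.prod(b[:, 2:] - b[:, :2], axis=1)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list[int]:
    """Class-agnostic NMS; score ties broken by original index (deterministic)."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    keep: list[int] = []
    if len(boxes) == 0:
        return keep
    iou = _box_iou(boxes, boxes)
    for i in order:
        if all(iou[i, j] <= iou_threshold for j in keep):
            keep.append(i)
    return keep


def postprocess(raw: dict, conf_threshold: float, iou_threshold: float,
                original_size: tuple[int, int], input_size: int = 640,
                mask_threshold: float = 0.5, max_det: int = 300) -> list:
    """Raw head maps -> instance list in original-image pixel coordinates.

    ``raw`` holds ``p{3,4,5}_{box,cls,mcf}`` maps plus ``protos``.  Instances
    are confidence-filtered, NMS-deduplicated, their masks assembled from the
    prototype bases (bilinear upsample, 0.5 threshold, crop to box) and mapped
    back through the inverse letterbox transform.  Returns instances sorted by
    descending confidence.
    """
    from .metrics import InstanceMask

    if not (0 <= conf_threshold <= 1 and 0 <= iou_threshold <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    boxes, scores, classes, coeffs = [], [], [], []
    for lvl, stride in (("p3", 8), ("p4", 16), ("p5", 32)):
        if f"{lvl}_box" not in raw:
            continue
        b, _ = _decode_boxes(np.asarray(raw[f"{lvl}_box"], np.float32), stride)
        cls = 1.0 / (1.0 + np.exp(-np.asarray(raw[f"{lvl}_cls"], np.float32)))
        nc = cls.shape[0]
        cls = cls.reshape(nc, -1)
        mcf = np.asarray(raw[f"{lvl}_mcf"], np.float32).reshape(
            raw[f"{lvl}_mcf"].shape[0], -1)
        best = cls.argmax(axis=0)
        score = cls[best, np.arange(cls.shape[1])]
        keep = score >= conf_threshold
        boxes.append(b[keep])
        scores.append(score[keep])
        classes.append(best[keep])
        coeffs.append(mcf[:, keep].T)
    if not boxes or sum(len(b) for b in boxes) == 0:
        return []
    boxes = np.concatenate(boxes)
    scores = np.concatenate(scores)
    classes = np.concatenate(classes)
    coeffs = np.concatenate(coeffs)

    keep = nms(boxes, scores, iou_threshold)[:max_det]
    protos = np.asarray(raw["protos"], np.float32)
    scale, pad_top, pad_left = letterbox_params(original_size, input_size)
    oh, ow = original_size
    nh, nw = round(oh * scale), round(ow * scale)

    instances = []
    for i in keep:
        mask_lo = 1.0 / (1.0 + np.exp(-np.einsum("m,mhw->hw", coeffs[i], protos)))
        mask_in = _resize(mask_lo, (input_size, input_size), order=1,
                          preserve_range=True, anti_aliasing=False)
        crop = mask_in[pad_top:pad_top + nh, pad_left:pad_left + nw]
        mask_orig = _resize(crop, (oh, ow), order=1, preserve_range=True,
                            anti_aliasing=False)
        mask = mask_orig >= mask_threshold
        x1, y1, x2, y2 = boxes[i]
        bx = (np.array([x1, y1, x2, y2]) - [pad_left, pad_top, pad_left, pad_top])
        bx = bx / scale
        bx = np.clip(bx, 0, [ow, oh, ow, oh]).astype(np.float32)
        box_mask = np.zeros_like(mask)
        yy1, yy2 = int(np.floor(bx[1])), int(np.ceil(bx[3]))
        xx1, xx2 = int(np.floor(bx[0])), int(np.ceil(bx[2]))
        box_mask[max(yy1, 0):yy2, max(xx1, 0):xx2] = True
        mask &= box_mask
        instances.append(InstanceMask(
            mask=mask, polygon=_mask_polygon(mask), class_id=int(classes[i]),
            confidence=float(scores[i]), bbox=tuple(float(v) for v in bx)))
    instances.sort(key=lambda m: -m.confidence)
    return instances


def _mask_polygon(mask: np.ndarray) -> list[np.ndarray]:
    """Contours of a binary mask as (x, y) vertex arrays."""
    if not mask.any():
        return []
    from .data_io import mask_to_polygons

    return mask_to_polygons(mask, tolerance=0.5)
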