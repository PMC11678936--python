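"""Dataset pipeline: annotation parsing, format conversion, letterbox resizing
and reproducible splitting.

Coordinate conventions (used everywhere in the package): 0-based pixels,
x right / y down; polygons are continuous (x, y) vertex arrays with
``0 <= x <= width`` and ``0 <= y <= height``; COCO boxes are ``[x, y, w, h]``.
Instances occluded into several visible parts are stored as multiple polygon
segments of one annotation, COCO style.

Three dialects are read and written:

* ``polygon-json`` — one JSON per image in the annotation-tool style
  (``shapes`` with ``label``/``points``; a documented superset is accepted and
  unknown keys are logged, never fatal),
* ``yolo-seg`` — one txt per image, ``class x1 y1 x2 y2 ...`` normalized to
  [0, 1], plus a dataset YAML stub,
* ``coco`` — a single JSON with images/annotations/categories and computed
  bbox/area.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import polygon2mask

from .metrics import InstanceMask

log = logging.getLogger("headseg.data_io")

DIALECTS = ("polygon-json", "coco", "yolo-seg")
CLASS_NAMES = ["cabbage head"]

_KNOWN_SHAPE_KEYS = {"label", "points", "shape_type", "group_id", "flags",
                     "description", "attributes", "mask", "score",
                     "difficult", "kie_linking"}


@dataclass
class SceneSample:
    """One image with its instance annotations."""

    image_id: str
    source_size: tuple  # (h, w)
    instances: list = field(default_factory=list)
    image: np.ndarray | None = None  # HWC uint8, optional
    transform: dict | None = None  # letterbox record, if resized

    def validate(self) -> None:
        h, w = self.source_size
        for inst in self.instances:
            for seg in inst.polygon:
                if seg.shape[0] < 3:
                    raise ValueError(f"{self.image_id}: degenerate polygon")
                if (seg[:, 0].min() < 0 or seg[:, 1].min() < 0
                        or seg[:, 0].max() > w or seg[:, 1].max() > h):
                    raise ValueError(f"{self.image_id}: vertex out of bounds")


@dataclass
class SplitManifest:
    train: list
    val: list
    test: list
    ratios: tuple
    seed: int

    def to_dict(self):
        return {"train": self.train, "val": self.val, "test": self.test,
                "ratios": list(self.ratios), "seed": self.seed}

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(d["train"], d["val"], d["test"], tuple(d["ratios"]), d["seed"])


# ---------------------------------------------------------------------------
# Polygon helpers
# ---------------------------------------------------------------------------


def rasterize_polygons(segments: list, shape: tuple) -> np.ndarray:
    """(x, y) polygon segments as a binary (h, w) mask, even-odd fill.

    For disjoint segments this is the plain union; a segment nested inside
    another cuts a hole, so occlusion rings survive rasterization exactly.
    """
    mask = np.zeros(shape, dtype=bool)
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        mask ^= polygon2mask(shape, seg[:, ::-1])  # (x, y) -> (row, col)
    return mask


def mask_to_polygons(mask: np.ndarray, tolerance: float = 0.01) -> list:
    """Trace a binary mask into (x, y) polygon segments (even-odd semantics:
    hole contours are emitted as nested segments).  With the default tolerance
    only collinear vertex runs are collapsed, so
    ``rasterize_polygons(mask_to_polygons(m), m.shape)`` reproduces ``m``."""
    from skimage import measure

    polys = []
    padded = np.pad(np.asarray(mask, dtype=np.float32), 1)
    for contour in measure.find_contours(padded, 0.5):
        contour = measure.approximate_polygon(contour, tolerance) - 1.0
        if contour.shape[0] < 4:
            continue
        xy = contour[:-1, ::-1]
        xy = np.clip(xy, 0, (mask.shape[1], mask.shape[0]))
        if xy.shape[0] >= 3:
            polys.append(xy)
    return polys


def merge_segments(segments: list) -> np.ndarray:
    """Stitch polygon segments into one keyhole polygon.

    Segments (disjoint visible parts or hole contours) are connected through
    zero-width bridges at their closest vertex pairs, the standard trick for
    single-polygon formats; even-odd rasterization of the result reproduces
    the multi-segment mask up to the bridge lines.
    """
    from scipy.spatial.distance import cdist

    merged = np.asarray(segments[0], dtype=float)
    for seg in segments[1:]:
        seg = np.asarray(seg, dtype=float)
        d = cdist(merged, seg)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        merged = np.concatenate([
            merged[:i + 1],
            np.roll(seg, -j, axis=0),
            seg[j:j + 1],
            merged[i:],
        ])
    return merged


def make_instance(segments: list, shape: tuple, class_id: int = 0,
                  confidence: float | None = None) -> InstanceMask:
    segs = [np.asarray(s, dtype=float) for s in segments]
    return InstanceMask(mask=rasterize_polygons(segs, shape), polygon=segs,
                        class_id=class_id, confidence=confidence,
                        bbox=_segments_bbox(segs))


def _segments_bbox(segs):
    pts = np.concatenate(segs)
    return (float(pts[:, 0].min()), float(pts[:, 1].min()),
            float(pts[:, 0].max()), float(pts[:, 1].max()))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def load_annotations(path, dialect: str, image_sizes: dict | None = None,
                     class_names: list | None = None) -> list[SceneSample]:
    """Read annotations into SceneSamples with absolute-pixel polygons.

    Malformed records (degenerate polygons, out-of-bounds after clipping
    tolerance, unparsable lines) are skipped per record with a logged reason,
    never silently.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {DIALECTS}")
    path = Path(path)
    if dialect == "polygon-json":
        files = sorted(path.glob("*.json")) if path.is_dir() else [path]
        return [s for f in files if (s := _load_polygon_json(f)) is not None]
    if dialect == "coco":
        return _load_coco(path)
    return _load_yolo(path, image_sizes or {}, class_names or CLASS_NAMES)


def _load_polygon_json(f: Path) -> SceneSample | None:
    try:
        d = json.loads(f.read_text())
        h, w = int(d["imageHeight"]), int(d["imageWidth"])
    except (json.JSONDecodeError, KeyError, ValueError) as e:
        log.warning("skipping %s: unreadable annotation (%s)", f.name, e)
        return None
    sample = SceneSample(image_id=f.stem, source_size=(h, w))
    groups: dict = {}
    for k, shape in enumerate(d.get("shapes", [])):
        unknown = set(shape) - _KNOWN_SHAPE_KEYS
        if unknown:
            log.info("%s: ignoring unknown shape keys %s", f.name, sorted(unknown))
        if shape.get("shape_type", "polygon") != "polygon":
            log.warning("%s: skipping non-polygon shape %d", f.name, k)
            continue
        pts = np.asarray(shape.get("points", []), dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3:
            log.warning("%s: skipping degenerate polygon %d (<3 vertices)",
                        f.name, k)
            continue
        pts[:, 0] = np.clip(pts[:, 0], 0, w)
        pts[:, 1] = np.clip(pts[:, 1], 0, h)
        gid = shape.get("group_id")
        key = ("g", gid) if gid is not None else ("s", k)
        groups.setdefault(key, {"label": shape.get("label", CLASS_NAMES[0]),
                                "segments": []})["segments"].append(pts)
    names = list(CLASS_NAMES)
    for rec in groups.values():
        if rec["label"] not in names:
            names.append(rec["label"])
        sample.instances.append(
            make_instance(rec["segments"], (h, w), names.index(rec["label"])))
    return sample


def _load_coco(path: Path) -> list[SceneSample]:
    d = json.loads(Path(path).read_text())
    images = {im["id"]: im for im in d["images"]}
    samples = {
        im["id"]: SceneSample(image_id=str(Path(im["file_name"]).stem),
                              source_size=(im["height"], im["width"]))
        for im in d["images"]
    }
    cat_index = {c["id"]: i for i, c in
                 enumerate(sorted(d.get("categories", []), key=lambda c: c["id"]))}
    for ann in d.get("annotations", []):
        im = images.get(ann["image_id"])
        if im is None:
            log.warning("coco: skipping annotation %s (unknown image)", ann.get("id"))
            continue
        segs = []
        for flat in ann.get("segmentation", []):
            pts = np.asarray(flat, dtype=float).reshape(-1, 2)
            if pts.shape[0] < 3:
                log.warning("coco: skipping degenerate segment in ann %s",
                            ann.get("id"))
                continue
            segs.append(pts)
        if not segs:
            log.warning("coco: skipping annotation %s (no valid segments)",
                        ann.get("id"))
            continue
        samples[ann["image_id"]].instances.append(make_instance(
            segs, (im["height"], im["width"]),
            cat_index.get(ann["category_id"], 0), ann.get("score")))
    return [samples[k] for k in sorted(samples)]


def _load_yolo(path: Path, image_sizes: dict, class_names: list):
    labels = sorted((path / "labels").glob("*.txt")) if path.is_dir() else [path]
    samples = []
    for f in labels:
        size = image_sizes.get(f.stem)
        if size is None:
            log.warning("yolo: skipping %s (image size unknown)", f.name)
            continue
        h, w = size
        sample = SceneSample(image_id=f.stem, source_size=(h, w))
        for ln, line in enumerate(f.read_text().splitlines()):
            parts = line.split()
            if not parts:
                continue
            try:
                cls = int(parts[0])
                vals = np.asarray([float(v) for v in parts[1:]], dtype=float)
                pts = vals.reshape(-1, 2)
            except ValueError:
                log.warning("%s:%d: skipping unparsable line", f.name, ln + 1)
                continue
            if pts.shape[0] < 3:
                log.warning("%s:%d: skipping degenerate polygon", f.name, ln + 1)
                continue
            pts = pts * [w, h]
            sample.instances.append(make_instance([pts], (h, w), cls))
        samples.append(sample)
    return samples


# ---------------------------------------------------------------------------
# Saving / conversion
# ---------------------------------------------------------------------------


def save_polygon_json(sample: SceneSample, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h, w = sample.source_size
    shapes = []
    for k, inst in enumerate(sample.instances):
        gid = k if len(inst.polygon) > 1 else None
        for seg in inst.polygon:
            shapes.append({
                "label": CLASS_NAMES[inst.class_id]
                if inst.class_id < len(CLASS_NAMES) else str(inst.class_id),
                "points": [[float(x), float(y)] for x, y in seg],
                "shape_type": "polygon",
                "group_id": gid,
            })
    doc = {"version": "headseg-0.1", "imagePath": f"{sample.image_id}.png",
           "imageHeight": h, "imageWidth": w, "shapes": shapes}
    out = out_dir / f"{sample.image_id}.json"
    out.write_text(json.dumps(doc, indent=1))
    return out


def convert(samples: list, target_format: str, out_dir,
            class_names: list | None = None) -> list[Path]:
    """Write samples in ``yolo-seg`` or ``coco`` format; returns written paths."""
    if target_format not in ("yolo-seg", "coco"):
        raise ValueError(f"unknown target format {target_format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = class_names or CLASS_NAMES
    if target_format == "yolo-seg":
        label_dir = out_dir / "labels"
        label_dir.mkdir(exist_ok=True)
        written = []
        for s in samples:
            h, w = s.source_size
            lines = []
            for inst in s.instances:
                # one line per instance: multi-segment annotations are stitched
                # into a keyhole polygon; shortest-round-trip float repr keeps
                # the reloaded rasterization bit-exact away from bridge lines
                seg = (merge_segments(inst.polygon) if len(inst.polygon) > 1
                       else inst.polygon[0])
                norm = np.asarray(seg, dtype=float) / [w, h]
                coords = " ".join(repr(float(v)) for v in norm.ravel())
                lines.append(f"{inst.class_id} {coords}")
            p = label_dir / f"{s.image_id}.txt"
            p.write_text("\n".join(lines) + ("\n" if lines else ""))
            written.append(p)
        yaml_stub = out_dir / "dataset.yaml"
        yaml_stub.write_text(
            "path: .\ntrain: images/train\nval: images/val\ntest: images/test\n"
            f"nc: {len(names)}\nnames: {names}\n")
        return written + [yaml_stub]

    images, annotations = [], []
    ann_id = 1
    for img_id, s in enumerate(samples, start=1):
        h, w = s.source_size
        images.append({"id": img_id, "file_name": f"{s.image_id}.png",
                       "height": h, "width": w})
        for inst in s.instances:
            x1, y1, x2, y2 = inst.bbox if inst.bbox else _segments_bbox(inst.polygon)
            annotations.append({
                "id": ann_id, "image_id": img_id,
                "category_id": inst.class_id + 1,
                "segmentation": [[float(v) for v in
                                  np.asarray(seg, dtype=float).ravel()]
                                 for seg in inst.polygon],
                "bbox": [float(x1), float(y1), float(x2 - x1), float(y2 - y1)],
                "area": float(inst.mask.sum()),
                "iscrowd": 0,
            })
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i + 1, "name": n} for i, n in enumerate(names)],
    }
    out = out_dir / "annotations.json"
    out.write_text(json.dumps(doc))
    return [out]


# ---------------------------------------------------------------------------
# Letterboxing
# ---------------------------------------------------------------------------


def letterbox_image(image: np.ndarray, target: int = 640,
                    fill: int = 114) -> np.ndarray:
    """Aspect-preserving resize + symmetric pad of an HWC image."""
    from skimage.transform import resize as _resize

    h, w = image.shape[:2]
    scale = min(target / h, target / w)
    nh, nw = round(h * scale), round(w * scale)
    if (nh, nw) != (h, w):
        resized = _resize(image, (nh, nw), order=1, preserve_range=True,
                          anti_aliasing=scale < 1).astype(image.dtype)
    else:
        resized = image
    out = np.full((target, target) + image.shape[2:], fill, dtype=image.dtype)
    top, left = (target - nh) // 2, (target - nw) // 2
    out[top:top + nh, left:left + nw] = resized
    return out


def letterbox_resize(sample: SceneSample, target: int = 640) -> SceneSample:
    """Letterbox a sample; polygons follow the same affine map and the inverse
    transform is recorded on the result."""
    h, w = sample.source_size
    if h < 1 or w < 1:
        raise ValueError("source size must be positive")
    scale = min(target / h, target / w)
    nh, nw = round(h * scale), round(w * scale)
    top, left = (target - nh) // 2, (target - nw) // 2
    instances = []
    for inst in sample.instances:
        segs = [np.asarray(seg, dtype=float) * scale + [left, top]
                for seg in inst.polygon]
        instances.append(make_instance(segs, (target, target), inst.class_id,
                                       inst.confidence))
    return SceneSample(
        image_id=sample.image_id, source_size=(target, target),
        instances=instances,
        image=None if sample.image is None else letterbox_image(sample.image,
                                                                target),
        transform={"scale": scale, "pad_top": top, "pad_left": left,
                   "source_size": (h, w)},
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_dataset(image_ids: list, ratios=(6, 2, 2), seed: int = 0) -> SplitManifest:
    """Deterministic 3-way split.

    Ids are sorted before shuffling (permutation-invariant to input order),
    val/test sizes are floor allocations and the remainder goes to train.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or min(ratios) < 0 or sum(ratios) <= 0:
        raise ValueError("need three non-negative ratios with positive sum")
    ids = sorted(str(i) for i in image_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids")
    n_splits = sum(1 for r in ratios if r > 0)
    if len(ids) < n_splits:
        raise ValueError(f"{len(ids)} ids cannot fill {n_splits} splits")
    total = sum(ratios)
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    n_val = int(n * ratios[1] / total)
    n_test = int(n * ratios[2] / total)
    n_train = n - n_val - n_test
    return SplitManifest(
        train=perm[:n_train],
        val=perm[n_train:n_train + n_val],
        test=perm[n_train + n_val:],
        ratios=ratios, seed=seed,
    )
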