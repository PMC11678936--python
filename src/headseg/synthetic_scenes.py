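"""Synthetic field scenes for exercising the full pipeline without data.

Scenes emulate the statistical structure of harvest-period crop-head imagery:
quasi-elliptical (superellipse) head instances of widely varying size with an
explicit small-object mass (< 32 px diameter), depth-ordered occlusion with
visible-region annotation, leaf-like background clutter, and illumination
jitter.  Rendering is deliberately schematic — the point is to exercise
occlusion, small-object and format-conversion code paths deterministically,
not photo-realism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .data_io import SceneSample, make_instance, save_polygon_json, split_dataset

log = logging.getLogger("headseg.synthetic")

MIN_VISIBLE_AREA = 16  # px; occluded instances below this are dropped


@dataclass(frozen=True)
class SceneRecipe:
    """Statistical description of one synthetic scene family.

    ``size_distribution`` is a two-component mixture over instance diameters:
    a small-object component (uniform on ``small_diameter`` px, mass
    ``small_object_mass``) and a log-normal bulk (median ``large_median`` px,
    log-sd ``large_sigma``, clipped to ``large_clip``).
    """

    n_instances: tuple = (3, 8)
    small_object_mass: float = 0.3
    small_diameter: tuple = (8.0, 30.0)
    large_median: float = 90.0
    large_sigma: float = 0.4
    large_clip: tuple = (48.0, 240.0)
    occlusion_prob: float = 0.35
    clutter_density: float = 0.5
    illumination_jitter: float = 0.15
    seed: int = 0

    def sample_diameters(self, rng: np.random.Generator, n: int) -> np.ndarray:
        small = rng.random(n) < self.small_object_mass
        d = np.exp(rng.normal(math.log(self.large_median), self.large_sigma, n))
        d = np.clip(d, *self.large_clip)
        d[small] = rng.uniform(*self.small_diameter, small.sum())
        return d


def _superellipse_mask(shape, cx, cy, a, b, power, theta):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float32)
    dx, dy = xx - cx, yy - cy
    u = (dx * math.cos(theta) + dy * math.sin(theta)) / a
    v = (-dx * math.sin(theta) + dy * math.cos(theta)) / b
    r = np.abs(u) ** power + np.abs(v) ** power
    return r <= 1.0, u, v


def _background(rng, size, clutter_density, illumination_jitter):
    base = np.empty((size, size, 3), dtype=np.float32)
    base[..., 0] = 0.22
    base[..., 1] = 0.34
    base[..., 2] = 0.16
    soil = gaussian_filter(rng.normal(0, 1, (size, size)).astype(np.float32), 9)
    base += 0.05 * soil[..., None]
    n_leaves = int(clutter_density * size * size / 4000)
    for _ in range(n_leaves):
        cx, cy = rng.uniform(0, size, 2)
        a = rng.uniform(10, 45)
        b = a * rng.uniform(0.25, 0.6)
        theta = rng.uniform(0, math.pi)
        x1, x2 = int(max(cx - a - 2, 0)), int(min(cx + a + 3, size))
        y1, y2 = int(max(cy - a - 2, 0)), int(min(cy + a + 3, size))
        if x2 <= x1 or y2 <= y1:
            continue
        m, _, _ = _superellipse_mask((y2 - y1, x2 - x1), cx - x1, cy - y1,
                                     a, b, 2.0, theta)
        tone = rng.uniform(-0.08, 0.12)
        base[y1:y2, x1:x2][m] += np.float32([0.3 * tone, tone, 0.2 * tone])
    gy = np.linspace(-1, 1, size, dtype=np.float32)
    gain = 1.0 + illumination_jitter * (
        rng.uniform(-1, 1) * gy[:, None] + rng.uniform(-1, 1) * gy[None, :])
    return base * gain[..., None]


def _paint_head(img, mask_full, u, v, box, rng):
    """Radial vein-like texture inside the visible mask."""
    y1, y2, x1, x2 = box
    r = np.sqrt(u**2 + v**2)
    phi = np.arctan2(v, u)
    k = rng.integers(7, 14)
    shade = (0.55 + 0.30 * np.clip(1 - r, 0, 1)
             + 0.06 * np.cos(k * phi) * np.clip(r, 0, 1))
    sub = img[y1:y2, x1:x2]
    m = mask_full
    sub[m, 0] = 0.62 * shade[m]
    sub[m, 1] = 0.80 * shade[m]
    sub[m, 2] = 0.45 * shade[m]


def _visible_polygons(mask: np.ndarray) -> list:
    """Visible-region boundary, including hole contours of occlusion rings."""
    from .data_io import mask_to_polygons

    return mask_to_polygons(mask)


def generate_scene(recipe: SceneRecipe, image_size: int = 640,
                   image_id: str | None = None, max_retries: int = 5) -> SceneSample:
    """Render one deterministic scene with visible-region annotations.

    Later instances occlude earlier ones; each annotation traces its visible
    boundary (amodal completion is never annotated).  If every instance is
    clipped/occluded away the scene regenerates with a logged retry.
    """
    if recipe.n_instances[0] < 1 or recipe.n_instances[0] > recipe.n_instances[1]:
        raise ValueError("invalid n_instances range")
    rng = np.random.default_rng(recipe.seed)
    for attempt in range(max_retries):
        sample = _generate_once(recipe, rng, image_size, image_id)
        if sample is not None:
            return sample
        log.warning("scene %s: no drawable instances, retry %d",
                    image_id, attempt + 1)
    raise RuntimeError(f"scene generation failed after {max_retries} retries")


def _generate_once(recipe, rng, size, image_id):
    img = _background(rng, size, recipe.clutter_density,
                      recipe.illumination_jitter)
    n = int(rng.integers(recipe.n_instances[0], recipe.n_instances[1] + 1))
    diameters = np.minimum(recipe.sample_diameters(rng, n), size - 6)
    placed = []  # (full mask, u, v, box)
    occupancy = np.zeros((size, size), dtype=bool)
    for d in diameters:
        a = d / 2.0
        b = a * rng.uniform(0.75, 1.0)
        power = rng.uniform(1.6, 3.0)
        theta = rng.uniform(0, math.pi)
        margin = a + 2
        may_occlude = rng.random() < recipe.occlusion_prob
        for _ in range(20):
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            x1, x2 = int(cx - a - 2), int(math.ceil(cx + a + 2))
            y1, y2 = int(cy - a - 2), int(math.ceil(cy + a + 2))
            m, u, v = _superellipse_mask((y2 - y1, x2 - x1), cx - x1, cy - y1,
                                         a, b, power, theta)
            if not m.any():
                continue
            if may_occlude or not occupancy[y1:y2, x1:x2][m].any():
                break
        else:
            continue  # could not place without overlap; skip this instance
        occupancy[y1:y2, x1:x2] |= m
        placed.append((m, u, v, (y1, y2, x1, x2)))

    # depth order = placement order: later instances occlude earlier ones
    cover = np.zeros((size, size), dtype=bool)
    visible = []
    for m, u, v, box in reversed(placed):
        y1, y2, x1, x2 = box
        vis = m & ~cover[y1:y2, x1:x2]
        cover[y1:y2, x1:x2] |= m
        visible.append((vis, m, u, v, box))
    visible.reverse()

    instances = []
    for vis, m, u, v, box in visible:
        if vis.sum() < MIN_VISIBLE_AREA:
            continue
        y1, y2, x1, x2 = box
        _paint_head(img, vis, u, v, box, rng)
        full = np.zeros((size, size), dtype=bool)
        full[y1:y2, x1:x2] = vis
        polys = _visible_polygons(full)
        if not polys:
            continue
        inst = make_instance(polys, (size, size), class_id=0)
        if inst.mask.sum() < MIN_VISIBLE_AREA:
            continue
        instances.append(inst)
    if not instances:
        return None
    img8 = (np.clip(img, 0, 1) * 255).astype(np.uint8)
    return SceneSample(image_id=image_id or f"scene_{recipe.seed:08d}",
                       source_size=(size, size), instances=instances,
                       image=img8)


def generate_dataset(recipe: SceneRecipe, n_images: int, out_dir,
                     image_size: int = 640, ratios=(6, 2, 2),
                     write_images: bool = True) -> list[SceneSample]:
    """Emit ``n_images`` scenes as PNGs + polygon-JSON plus a split manifest."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    samples = []
    for i in range(n_images):
        per_seed = (recipe.seed * 100003 + i) % (2**31 - 1)
        sub = SceneRecipe(**{**recipe.__dict__, "seed": per_seed})
        sample = generate_scene(sub, image_size, image_id=f"img_{i:05d}")
        if write_images:
            import imageio.v3 as iio

            iio.imwrite(out_dir / "images" / f"{sample.image_id}.png",
                        sample.image)
        save_polygon_json(sample, out_dir / "annotations")
        samples.append(sample)
    ids = [s.image_id for s in samples]
    n_splits = sum(1 for r in ratios if r > 0)
    if len(ids) < n_splits:
        log.warning("only %d image(s): split manifest keeps everything in train",
                    len(ids))
        manifest = split_dataset(ids, (1, 0, 0), recipe.seed)
    else:
        manifest = split_dataset(ids, ratios, recipe.seed)
    manifest.save(out_dir / "split.json")
    return samples
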