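"""Seeded generator of annotated larva-like scenes.

Real field imagery of visually similar lepidopteran larvae is hard to come
by, so this module fabricates it: each scene is a cluttered vegetation-like
background on which curved, striped, elongated capsules ("larvae") are
rendered.  The generator exposes exactly the difficulty drivers of the field
problem as knobs — inter-class appearance similarity, instance scale mixture
(medium vs large in the COCO sense), background clutter, illumination
variation and occlusion — and is fully deterministic given a seed.

Annotation boxes are the analytic bounding boxes of the capsule geometry
(spine ± local width); rasterisation is constrained to stay inside them, so
the scale statistics of a dataset can be computed from layouts alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .annotation import (DatasetManifest, ImageMeta, ManifestEntry,
                         write_voc_xml)
from .boxes import BoxSet, scale_of_box

__all__ = ["SceneSpec", "ClassAppearance", "class_appearances",
           "sample_layout", "render_scene", "make_dataset", "scale_of_box",
           "TINY_IMAGE_SIZE", "tiny_scene_spec"]

TINY_IMAGE_SIZE = (128, 128)


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters for one synthetic scene."""

    image_size: tuple[int, int] = (800, 600)       # (width, height) px
    n_classes: int = 5
    similarity: float = 0.8        # 1 = classes nearly identical in appearance
    scale_mix: float = 0.396       # probability an instance is medium-scale
    n_instances: tuple[int, int] = (1, 2)          # inclusive range per image
    clutter_level: float = 0.6
    illumination_jitter: float = 0.4
    occlusion_prob: float = 0.3
    seed: int = 0
    fixed_class: int | None = None  # force all instances to one class

    def validate(self):
        w, h = self.image_size
        if not (0.0 <= self.similarity <= 1.0):
            raise ValueError("similarity must lie in [0, 1]")
        if not (0.0 <= self.scale_mix <= 1.0):
            raise ValueError("scale_mix must lie in [0, 1]")
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if self.scale_mix < 1.0 and 0.5 * w * h < _LARGE_AREA[0]:
            raise ValueError(
                f"canvas {w}x{h} is too small to hold large-scale instances; "
                "set scale_mix=1.0 for tiny canvases")
        lo, hi = self.n_instances
        if lo < 0 or hi < lo:
            raise ValueError("invalid n_instances range")


@dataclass(frozen=True)
class ClassAppearance:
    """Procedural appearance of one larva class."""

    base_hue: float           # HSV hue in [0, 1)
    stripe_frequency: float   # cycles per body length
    stripe_contrast: float
    head_marker_size: float   # fraction of body length
    body_aspect: float        # length / width

    def vector(self) -> np.ndarray:
        return np.array([self.base_hue, self.stripe_frequency,
                         self.stripe_contrast, self.head_marker_size,
                         self.body_aspect])


# archetype around which classes vary; olive-brown striped larva
_ARCHETYPE = ClassAppearance(base_hue=0.16, stripe_frequency=7.0,
                             stripe_contrast=0.35, head_marker_size=0.10,
                             body_aspect=5.0)
# per-parameter spread when classes are fully dissimilar (similarity = 0)
_SPREAD = np.array([0.10, 4.0, 0.25, 0.06, 1.8])

# sampled bounding-box areas per scale bin, with margin to the COCO
# boundaries (1024 / 9216 px²) so integer rounding cannot cross a bin edge
_MEDIUM_AREA = (1700.0, 8100.0)
_LARGE_AREA = (11800.0, 40000.0)


def class_appearances(n_classes: int, similarity: float) -> list[ClassAppearance]:
    """Appearance vectors whose pairwise distance scales with (1 − similarity)."""
    apps = []
    base = _ARCHETYPE.vector()
    for k in range(n_classes):
        # deterministic per-class unit direction; hue is spread evenly so
        # classes remain visually ordered, the rest comes from a fixed draw
        c = 0.0 if n_classes == 1 else (k / (n_classes - 1) - 0.5) * 2.0
        d = np.random.default_rng(7919 + k).normal(size=5)
        d /= np.linalg.norm(d)
        offset = _SPREAD * (0.6 * d + 0.4 * np.array([c, -c, c, c, -c]))
        offset[0] = _SPREAD[0] * c  # hue strictly ordered across classes
        v = base + (1.0 - similarity) * offset
        apps.append(ClassAppearance(
            base_hue=float(v[0] % 1.0),
            stripe_frequency=float(max(1.0, v[1])),
            stripe_contrast=float(np.clip(v[2], 0.05, 0.9)),
            head_marker_size=float(np.clip(v[3], 0.04, 0.25)),
            body_aspect=float(np.clip(v[4], 2.5, 8.0))))
    return apps


# ---------------------------------------------------------------------------
# layout sampling (geometry only, no rasterisation)
# ---------------------------------------------------------------------------

@dataclass
class InstanceLayout:
    class_id: int
    spine: np.ndarray         # (m, 2) absolute (x, y)
    widths: np.ndarray        # (m,) half-widths in px
    box: np.ndarray           # (4,) x1 y1 x2 y2, integer-valued
    scale_class: str
    phase: float              # stripe phase
    hue_jitter: float


@dataclass
class SceneLayout:
    spec: SceneSpec
    instances: list[InstanceLayout]
    warnings: list[str]

    def boxset(self) -> BoxSet:
        if not self.instances:
            return BoxSet.empty()
        return BoxSet(np.stack([i.box for i in self.instances]),
                      np.array([i.class_id for i in self.instances]))


def _capsule_geometry(rng: np.random.Generator, aspect: float, m: int = 24):
    """Unit-length curved capsule: spine points and half-width profile."""
    t = np.linspace(0.0, 1.0, m)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    total_curve = rng.normal(0.0, 0.9)
    wiggle = rng.normal(0.0, 0.15, size=3)
    theta = (theta0 + total_curve * (t - 0.5)
             + wiggle[0] * np.sin(2 * math.pi * t)
             + wiggle[1] * np.sin(4 * math.pi * t) * 0.5
             + wiggle[2] * np.cos(3 * math.pi * t) * 0.3)
    step = 1.0 / (m - 1)
    spine = np.zeros((m, 2))
    spine[1:, 0] = np.cumsum(np.cos(theta[:-1]) * step)
    spine[1:, 1] = np.cumsum(np.sin(theta[:-1]) * step)
    halfw = 0.5 / aspect * np.sqrt(np.clip(1.0 - (2.0 * t - 1.0) ** 2, 0.08, 1.0)) ** 0.6
    return spine, halfw


def sample_layout(spec: SceneSpec) -> SceneLayout:
    """Sample instance classes, scales, geometry and placement for one scene."""
    spec.validate()
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0])
    W, H = spec.image_size
    apps = class_appearances(spec.n_classes, spec.similarity)
    lo, hi = spec.n_instances
    n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    placed: list[InstanceLayout] = []
    warns: list[str] = []
    for _ in range(n):
        if spec.fixed_class is not None:
            k = int(spec.fixed_class)
        else:
            k = int(rng.integers(1, spec.n_classes + 1))
        app = apps[k - 1]
        medium = rng.random() < spec.scale_mix
        area_cap = min(_LARGE_AREA[1], 0.5 * W * H)
        lo_a, hi_a = _MEDIUM_AREA if medium else (_LARGE_AREA[0], area_cap)
        target_area = rng.uniform(lo_a, hi_a)
        aspect = app.body_aspect * (1.0 + 0.15 * (2.0 * rng.random() - 1.0))

        ok = False
        for _attempt in range(40):
            spine, halfw = _capsule_geometry(rng, aspect)
            x_lo = (spine[:, 0] - halfw).min()
            x_hi = (spine[:, 0] + halfw).max()
            y_lo = (spine[:, 1] - halfw).min()
            y_hi = (spine[:, 1] + halfw).max()
            area_norm = (x_hi - x_lo) * (y_hi - y_lo)
            s = math.sqrt(target_area / area_norm)
            bw, bh = s * (x_hi - x_lo), s * (y_hi - y_lo)
            if bw > W - 6 or bh > H - 6:
                continue  # unusually stretched draw; try new geometry
            x1 = rng.uniform(2.0, W - 2.0 - bw)
            y1 = rng.uniform(2.0, H - 2.0 - bh)
            box = np.array([math.floor(x1), math.floor(y1),
                            math.ceil(x1 + bw), math.ceil(y1 + bh)],
                           dtype=np.float64)
            overlap = False
            for other in placed:
                from .boxes import iou
                if iou(box, other.box) > 0.25:
                    overlap = True
                    break
            if overlap:
                continue
            abs_spine = (spine - [x_lo, y_lo]) * s + [x1, y1]
            placed.append(InstanceLayout(
                class_id=k, spine=abs_spine, widths=halfw * s, box=box,
                scale_class=scale_of_box(box),
                phase=float(rng.uniform(0.0, 2.0 * math.pi)),
                hue_jitter=float(rng.normal(0.0, 0.01))))
            ok = True
            break
        if not ok:
            warns.append(f"could not place instance of class {k}; scene has "
                         f"{len(placed)} of {n} requested instances")
    return SceneLayout(spec, placed, warns)


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def _hsv_to_rgb(h, s, v):
    h = (np.asarray(h) % 1.0) * 6.0
    i = np.floor(h)
    f = h - i
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    i = i.astype(int) % 6
    lut = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)]
    r = np.choose(i, [c[0] for c in lut])
    g = np.choose(i, [c[1] for c in lut])
    b = np.choose(i, [c[2] for c in lut])
    return np.stack([r, g, b], axis=-1)


def _background(rng: np.random.Generator, W: int, H: int, clutter: float):
    coarse = gaussian_filter(rng.normal(size=(H, W)), sigma=max(4, W // 30))
    fine = gaussian_filter(rng.normal(size=(H, W)), sigma=2.5)

    def norm(a):
        return (a - a.min()) / (a.max() - a.min() + 1e-9)

    mix = norm(coarse)
    green = np.array([0.26, 0.42, 0.18])
    brown = np.array([0.42, 0.36, 0.24])
    img = mix[..., None] * green + (1 - mix[..., None]) * brown
    img += (norm(fine)[..., None] - 0.5) * (0.12 + 0.25 * clutter)
    # leaf/stem clutter shapes
    n_shapes = int(round(clutter * 24))
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(n_shapes):
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        ang = rng.uniform(0, math.pi)
        ca, sa = math.cos(ang), math.sin(ang)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        if rng.random() < 0.55:                       # leaf-like ellipse
            a = rng.uniform(0.02, 0.10) * W
            b = a * rng.uniform(0.25, 0.6)
            mask = (u / a) ** 2 + (v / b) ** 2 < 1.0
        else:                                         # thin stem
            length = rng.uniform(0.1, 0.5) * W
            width = rng.uniform(1.5, 4.0)
            mask = (np.abs(u) < length / 2) & (np.abs(v) < width)
        hue = 0.22 + rng.normal(0, 0.05)
        val = rng.uniform(0.25, 0.55)
        color = _hsv_to_rgb(hue, rng.uniform(0.3, 0.7), val)
        alpha = 0.75
        img[mask] = (1 - alpha) * img[mask] + alpha * color
    return np.clip(img, 0.0, 1.0)


def _paint_instance(img: np.ndarray, inst: InstanceLayout,
                    app: ClassAppearance) -> None:
    x1, y1, x2, y2 = inst.box.astype(int)
    H, W = img.shape[:2]
    x2, y2 = min(x2, W), min(y2, H)
    ys, xs = np.mgrid[y1:y2, x1:x2]
    px = xs.astype(np.float64).ravel()
    py = ys.astype(np.float64).ravel()

    # densified spine; track nearest point and its arclength parameter
    m_dense = 80
    t_dense = np.linspace(0.0, 1.0, m_dense)
    t_src = np.linspace(0.0, 1.0, len(inst.spine))
    sx = np.interp(t_dense, t_src, inst.spine[:, 0])
    sy = np.interp(t_dense, t_src, inst.spine[:, 1])
    wd = np.interp(t_dense, t_src, inst.widths)

    d2min = np.full(px.shape, np.inf)
    tmin = np.zeros(px.shape)
    wmin = np.zeros(px.shape)
    for j in range(m_dense):
        d2 = (px - sx[j]) ** 2 + (py - sy[j]) ** 2
        closer = d2 < d2min
        d2min[closer] = d2[closer]
        tmin[closer] = t_dense[j]
        wmin[closer] = wd[j]
    dist = np.sqrt(d2min)
    alpha = np.clip(wmin - dist, 0.0, 1.0)          # 1 px soft edge, inside box
    body = alpha > 0
    if not np.any(body):
        return

    t = tmin[body]
    d_rel = np.clip(dist[body] / np.maximum(wmin[body], 1e-6), 0.0, 1.0)
    stripe = 1.0 + app.stripe_contrast * np.sin(
        2.0 * math.pi * app.stripe_frequency * t + inst.phase)
    shade = 0.45 + 0.55 * np.sqrt(np.clip(1.0 - d_rel ** 2, 0.0, 1.0))
    hue = app.base_hue + inst.hue_jitter
    val = np.clip(0.55 * stripe * shade, 0.0, 1.0)
    color = _hsv_to_rgb(np.full(t.shape, hue), 0.55, val)
    head = t < app.head_marker_size
    color[head] *= 0.45                               # dark head capsule

    patch = img[y1:y2, x1:x2].reshape(-1, 3)
    a = alpha[body][:, None]
    sel = np.flatnonzero(body)
    patch[sel] = (1 - a) * patch[sel] + a * color
    img[y1:y2, x1:x2] = patch.reshape(y2 - y1, x2 - x1, 3)


def _paint_occluder(img: np.ndarray, rng: np.random.Generator,
                    inst: InstanceLayout) -> None:
    x1, y1, x2, y2 = inst.box
    t = rng.uniform(0.25, 0.75)
    idx = int(t * (len(inst.spine) - 1))
    cx, cy = inst.spine[idx]
    diag = math.hypot(x2 - x1, y2 - y1)
    a = rng.uniform(0.15, 0.30) * diag
    b = a * rng.uniform(0.3, 0.7)
    ang = rng.uniform(0, math.pi)
    ca, sa = math.cos(ang), math.sin(ang)
    H, W = img.shape[:2]
    ry1, ry2 = max(0, int(cy - a - 2)), min(H, int(cy + a + 3))
    rx1, rx2 = max(0, int(cx - a - 2)), min(W, int(cx + a + 3))
    if ry2 <= ry1 or rx2 <= rx1:
        return
    yy, xx = np.mgrid[ry1:ry2, rx1:rx2]
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    mask = (u / a) ** 2 + (v / max(b, 1.0)) ** 2 < 1.0
    color = _hsv_to_rgb(0.27 + rng.normal(0, 0.03), 0.6, rng.uniform(0.3, 0.5))
    region = img[ry1:ry2, rx1:rx2]
    region[mask] = 0.15 * region[mask] + 0.85 * color
    img[ry1:ry2, rx1:rx2] = region


def render_scene(spec: SceneSpec) -> tuple[Image.Image, BoxSet]:
    """Render one annotated scene; identical spec (incl. seed) gives
    byte-identical output."""
    layout = sample_layout(spec)
    for w in layout.warnings:
        warnings.warn(w, stacklevel=2)
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 1])
    W, H = spec.image_size
    img = _background(rng, W, H, spec.clutter_level)
    apps = class_appearances(spec.n_classes, spec.similarity)
    for inst in layout.instances:
        _paint_instance(img, inst, apps[inst.class_id - 1])
    for inst in layout.instances:
        if rng.random() < spec.occlusion_prob:
            _paint_occluder(img, rng, inst)
    # illumination: global gain plus a linear gradient across the canvas
    jit = spec.illumination_jitter
    gain = 1.0 + jit * rng.uniform(-0.4, 0.4)
    gx, gy = rng.uniform(-1, 1), rng.uniform(-1, 1)
    xg = (np.arange(W) / W - 0.5) * gx
    yg = (np.arange(H) / H - 0.5) * gy
    grad = 1.0 + 0.3 * jit * (xg[None, :] + yg[:, None])
    img = np.clip(img * gain * grad[..., None], 0.0, 1.0)
    pil = Image.fromarray((img * 255.0 + 0.5).astype(np.uint8), mode="RGB")
    return pil, layout.boxset()


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def default_class_names(n: int) -> list[str]:
    return [f"larva{k}" for k in range(1, n + 1)]


def train_count(n: int, split_ratio: float) -> int:
    """Images assigned to the training split: floor(ratio·n + 0.5)."""
    return int(math.floor(split_ratio * n + 0.5))


def make_dataset(spec_template: SceneSpec, n_per_class: int,
                 split_ratio: float, seed: int, out_dir,
                 class_names: list[str] | None = None) -> DatasetManifest:
    """Render a stratified dataset: ``n_per_class`` single-species images per
    class, split per class into train/test by ``split_ratio``."""
    if not (0.0 < split_ratio < 1.0):
        raise ValueError("split_ratio must lie strictly between 0 and 1")
    if n_per_class < 2:
        raise ValueError("need at least 2 images per class to split")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    K = spec_template.n_classes
    names = class_names or default_class_names(K)
    n_train = train_count(n_per_class, split_ratio)
    entries = []
    for k in range(1, K + 1):
        for i in range(n_per_class):
            sseed = int((seed * 1000003 + k * 1009 + i) % (2 ** 31 - 1))
            spec = replace(spec_template, seed=sseed, fixed_class=k)
            img, boxes = render_scene(spec)
            stem = f"{names[k - 1]}_{i:05d}"
            img_path = out_dir / "images" / f"{stem}.png"
            xml_path = out_dir / "annotations" / f"{stem}.xml"
            img.save(img_path)
            meta = ImageMeta(img_path.name, img.width, img.height)
            write_voc_xml(meta, boxes, names, xml_path)
            entries.append(ManifestEntry(
                str(img_path), str(xml_path),
                "train" if i < n_train else "test", k))
    manifest = DatasetManifest(names, entries, seed, spec_template.image_size)
    manifest.save(out_dir / "manifest.json")
    return manifest


def tiny_scene_spec(seed: int = 0, n_classes: int = 2) -> SceneSpec:
    """CPU-scale preset: small canvas, medium-only instances, mild clutter."""
    return SceneSpec(image_size=TINY_IMAGE_SIZE, n_classes=n_classes,
                     similarity=0.5, scale_mix=1.0, n_instances=(1, 2),
                     clutter_level=0.3, illumination_jitter=0.2,
                     occlusion_prob=0.0, seed=seed)
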