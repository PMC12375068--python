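"""Procedural generation of labeled leaf-like images.

The generator emulates the visual structure of leaf-disease photographs —
a green leaf silhouette on a darker background, with class-conditional
lesions rendered as smooth-edged disks and blotches in brown/yellow hues —
without copying any real dataset.  A clutter level in [0, 1] adds background
texture emulating in-field photographs with complex backgrounds; at clutter
0 the background is a flat soil tone, which guarantees by construction that
the healthy class has the highest mean green intensity.

The same spec and seed always produce byte-identical PNG files, so datasets
are reproducible fixtures.  Output layout: ``root/class_name/img_#####.png``
plus a tab-separated manifest (path, label) — the layout the dataset reader
of the training pipeline consumes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from PIL import Image

__all__ = ["LesionClass", "SyntheticDatasetSpec", "generate_dataset",
           "train_val_split", "load_manifest", "load_images",
           "default_classes"]


@dataclass(frozen=True)
class LesionClass:
    """Lesion morphology of one disease class.

    spot_density: expected lesion count per image; spot_radius: radius range
    as a fraction of the leaf half-width; spot_color: lesion RGB; color_shift:
    additive shift of the base leaf color (mosaic-like discoloration);
    blotch: render each lesion as an irregular blotch (a short random walk of
    overlapping disks) instead of a round spot.
    """
    name: str
    spot_density: float = 0.0
    spot_radius: Tuple[float, float] = (0.05, 0.12)
    spot_color: Tuple[int, int, int] = (110, 70, 30)
    color_shift: Tuple[int, int, int] = (0, 0, 0)
    blotch: bool = False


_ARCHETYPES = [
    LesionClass("healthy"),
    LesionClass("brown_spot", spot_density=12, spot_radius=(0.05, 0.11),
                spot_color=(105, 62, 28)),
    LesionClass("rust", spot_density=40, spot_radius=(0.02, 0.045),
                spot_color=(175, 110, 30)),
    LesionClass("blight", spot_density=2.5, spot_radius=(0.12, 0.2),
                spot_color=(92, 74, 40), blotch=True),
    LesionClass("mosaic", spot_density=8, spot_radius=(0.08, 0.16),
                spot_color=(150, 160, 60), color_shift=(25, 10, -10)),
]


def default_classes(n: int) -> List[LesionClass]:
    """The first n lesion archetypes (healthy first), cycling beyond five."""
    out = []
    for i in range(n):
        a = _ARCHETYPES[i % len(_ARCHETYPES)]
        if i >= len(_ARCHETYPES):
            a = LesionClass(f"{a.name}_{i // len(_ARCHETYPES)}",
                            a.spot_density * 1.5, a.spot_radius, a.spot_color,
                            a.color_shift, a.blotch)
        out.append(a)
    return out


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Dataset recipe: classes, counts, size, clutter level and seed.

    ``images_per_class`` may be a single count or one count per class (the
    imbalance switch emulating skewed real datasets).
    """
    num_classes: int = 3
    images_per_class: Union[int, Tuple[int, ...]] = 100
    image_size: int = 64
    clutter: float = 0.0
    seed: int = 0
    classes: Optional[Tuple[LesionClass, ...]] = None

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("need at least one class")
        if not 0.0 <= self.clutter <= 1.0:
            raise ValueError("clutter must lie in [0, 1]")
        counts = self.counts()
        if min(counts) < 1:
            raise ValueError("need at least one image per class")
        cls = self.classes or tuple(default_classes(self.num_classes))
        if len(cls) != self.num_classes:
            raise ValueError("one LesionClass per class required")
        object.__setattr__(self, "classes", tuple(cls))

    def counts(self) -> List[int]:
        if isinstance(self.images_per_class, int):
            return [self.images_per_class] * self.num_classes
        if len(self.images_per_class) != self.num_classes:
            raise ValueError("images_per_class length must equal num_classes")
        return list(self.images_per_class)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _smooth_field(rng, size, scale=4):
    """Smooth random field in [0, 1] from low-resolution bilinear noise."""
    coarse = rng.random((scale, scale))
    img = Image.fromarray((coarse * 255).astype(np.uint8))
    fine = np.asarray(img.resize((size, size), Image.BILINEAR),
                      dtype=np.float32) / 255.0
    return fine


def _leaf_mask(rng, size):
    """Soft elliptical leaf silhouette with a pointed tip and a random pose."""
    s = size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    cx = s * (0.5 + 0.08 * (rng.random() - 0.5))
    cy = s * (0.5 + 0.08 * (rng.random() - 0.5))
    theta = rng.random() * np.pi
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    a = s * (0.34 + 0.06 * rng.random())   # half-length
    b = s * (0.18 + 0.05 * rng.random())   # half-width
    taper = 1.0 - 0.35 * np.clip(u / a, 0, 1) ** 2   # pointed tip
    r = np.sqrt((u / a) ** 2 + (v / (b * taper + 1e-6)) ** 2)
    mask = np.clip((1.05 - r) / 0.1, 0.0, 1.0)       # smooth edge
    return mask, (u, v, a, b)


def _render_image(rng, cls: LesionClass, size: int, clutter: float) -> np.ndarray:
    s = size
    img = np.empty((s, s, 3), dtype=np.float32)
    soil = np.array([46, 36, 26], dtype=np.float32)
    img[:] = soil
    if clutter > 0:
        tex = np.stack([_smooth_field(rng, s, 5) for _ in range(3)], axis=-1)
        tint = np.array([90, 75, 50], np.float32) * tex \
            + np.array([30, 50, 25], np.float32) * _smooth_field(rng, s, 3)[..., None]
        img = (1 - clutter) * img + clutter * tint
        # scattered background debris
        n_blobs = rng.poisson(6 * clutter)
        yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
        for _ in range(n_blobs):
            bx, by = rng.random(2) * s
            br = s * (0.03 + 0.07 * rng.random())
            alpha = np.clip(1 - np.hypot(xx - bx, yy - by) / br, 0, 1)
            color = np.array([60, 55, 35], np.float32) + 40 * rng.random(3)
            img = img * (1 - alpha[..., None] * 0.7) \
                + color * alpha[..., None] * 0.7

    mask, (u, v, a, b) = _leaf_mask(rng, s)
    base = np.array([52, 120, 44], dtype=np.float32) \
        + np.asarray(cls.color_shift, dtype=np.float32) \
        + rng.normal(0, 4, 3).astype(np.float32)
    shading = 1.0 - 0.25 * np.abs(v) / (b + 1e-6)
    leaf = base * shading[..., None]
    # central vein and side veins, slightly darker
    vein = np.clip(1 - np.abs(v) / (0.015 * s), 0, 1)
    for k in range(-3, 4):
        side = np.clip(1 - np.abs(v - (u - k * a / 4) * 0.55) / (0.008 * s), 0, 1)
        side = side * (np.abs(u - k * a / 4) < a / 4)
        vein = np.maximum(vein, 0.6 * side)
    leaf = leaf * (1 - 0.18 * vein[..., None])

    # class-conditional lesions, drawn only on the leaf
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    n_lesions = rng.poisson(cls.spot_density) if cls.spot_density > 0 else 0
    lesion_alpha = np.zeros((s, s), dtype=np.float32)
    lesion_col = np.zeros((s, s, 3), dtype=np.float32)
    for _ in range(n_lesions):
        # rejection-sample a center inside the silhouette
        for _attempt in range(20):
            lx, ly = rng.random(2) * s
            if mask[int(ly), int(lx)] > 0.5:
                break
        lo, hi = cls.spot_radius
        radius = b * (lo + (hi - lo) * rng.random()) * 2.0
        color = np.asarray(cls.spot_color, np.float32) \
            + rng.normal(0, 10, 3).astype(np.float32)
        steps = rng.integers(3, 7) if cls.blotch else 1
        px, py = lx, ly
        for _step in range(steps):
            dist = np.hypot(xx - px, yy - py)
            alpha = np.clip((radius - dist) / (0.5 * radius + 1e-6), 0, 1)
            new = alpha > lesion_alpha
            lesion_col[new] = color
            lesion_alpha = np.maximum(lesion_alpha, alpha)
            px += rng.normal(0, radius * 0.8)
            py += rng.normal(0, radius * 0.8)
    lesion_alpha = lesion_alpha * mask

    leaf = leaf * (1 - lesion_alpha[..., None]) \
        + lesion_col * lesion_alpha[..., None]
    img = img * (1 - mask[..., None]) + leaf * mask[..., None]
    img += rng.normal(0, 2.0, img.shape).astype(np.float32)   # sensor noise
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def generate_dataset(spec: SyntheticDatasetSpec, root) -> Path:
    """Write one directory of PNGs per class plus ``manifest.tsv``.

    Returns the manifest path.  Identical spec + seed produce byte-identical
    files.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, (cls, count) in enumerate(zip(spec.classes, spec.counts())):
        cdir = root / cls.name
        cdir.mkdir(exist_ok=True)
        for i in range(count):
            img = _render_image(rng, cls, spec.image_size, spec.clutter)
            rel = Path(cls.name) / f"img_{i:05d}.png"
            Image.fromarray(img).save(root / rel)
            rows.append((str(rel), label))
    manifest = root / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["path", "label"])
        w.writerows(rows)
    return manifest


def load_manifest(manifest) -> List[Tuple[str, int]]:
    manifest = Path(manifest)
    with open(manifest, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header[:2] != ["path", "label"]:
            raise ValueError("manifest must have 'path' and 'label' columns")
        return [(p, int(l)) for p, l in r]


def train_val_split(rows: Sequence[Tuple[str, int]], fraction: float,
                    seed: int):
    """Stratified split into (train, val); class proportions kept within one.

    ``fraction`` is the training share in (0, 1).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    labels = sorted({l for _, l in rows})
    train, val = [], []
    for label in labels:
        members = [r for r in rows if r[1] == label]
        if len(members) < 2:
            raise ValueError(
                f"class {label} has fewer than 2 images; cannot split")
        idx = rng.permutation(len(members))
        k = int(round(fraction * len(members)))
        k = min(max(k, 1), len(members) - 1)
        train.extend(members[i] for i in idx[:k])
        val.extend(members[i] for i in idx[k:])
    return train, val


def load_images(rows: Sequence[Tuple[str, int]], root, size: int):
    """Load manifest rows into (images in [0,1] as (N,H,W,3) float32, labels)."""
    root = Path(root)
    imgs = np.empty((len(rows), size, size, 3), dtype=np.float32)
    labels = np.empty(len(rows), dtype=np.int64)
    for i, (rel, label) in enumerate(rows):
        with Image.open(root / rel) as im:
            im = im.convert("RGB")
            if im.size != (size, size):
                im = im.resize((size, size), Image.BILINEAR)
            imgs[i] = np.asarray(im, dtype=np.float32) / 255.0
        labels[i] = label
    return imgs, labels
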