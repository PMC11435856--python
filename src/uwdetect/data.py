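"""Synthetic benthic scene generator with YOLO-format annotations.

Scenes emulate the structure of shallow-water benthic imagery: four
class-distinct invertebrate shapes (spiny disc ~ sea urchin, five-armed
star ~ starfish, spiral ~ conch, ridged fan ~ scallop) rendered at sizes
drawn from the area bins used to characterise the reference datasets
(object sides < 18 px up to > 90 px), on a textured seabed, then degraded
by wavelength-dependent attenuation (red suppressed most), Gaussian blur
and sensor noise.  Ground-truth boxes are the pre-degradation geometry:
photometric degradation never moves an annotation.

Everything is a pure function of (spec, seed): the same spec yields
bit-identical images and labels.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

CLASS_NAMES = ("urchin", "starfish", "conch", "scallop")

#: object-side bin edges in pixels; the last bin is open-ended
SCALE_BIN_EDGES = (0, 18, 36, 54, 72, 90, 141)


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed within the occlusion budget."""


@dataclass
class SceneSpec:
    width: int = 640
    height: int = 640
    n_objects: int = 8
    class_mixture: tuple = (0.25, 0.25, 0.25, 0.25)
    scale_mixture: tuple = (0.25, 0.25, 0.20, 0.15, 0.10, 0.05)
    tint_strength: float = 0.6    # 0 = no attenuation, 1 = strong blue-green cast
    blur_sigma: float = 1.0       # px, forward-scattering blur
    noise_level: float = 0.02     # sd of additive Gaussian noise (0..1 scale)
    occlusion_prob: float = 0.2   # chance a new object may overlap an old one
    seed: int = 0

    def __post_init__(self):
        for name, mix in (("class_mixture", self.class_mixture),
                          ("scale_mixture", self.scale_mixture)):
            if abs(sum(mix) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
        if self.n_objects < 0:
            raise ValueError("n_objects must be non-negative")


def _sample_side(rng, mixture):
    b = rng.choice(len(mixture), p=np.asarray(mixture, dtype=float))
    lo = max(SCALE_BIN_EDGES[b], 8)   # below ~8 px nothing is drawable
    hi = SCALE_BIN_EDGES[b + 1]
    return float(rng.uniform(lo, hi))


def _shape_mask(cls, side, rng):
    """Binary mask of one rendered organism, normalised so its tight
    bounding box is exactly ceil(side) x ceil(side)."""
    n = int(np.ceil(side))
    mask = _raw_shape_mask(cls, side, rng)
    ys, xs = np.nonzero(mask)
    tight = mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    ri = np.linspace(0, tight.shape[0] - 1, n).round().astype(int)
    ci = np.linspace(0, tight.shape[1] - 1, n).round().astype(int)
    return tight[np.ix_(ri, ci)]


def _raw_shape_mask(cls, side, rng):
    n = max(int(np.ceil(side)), 4)
    yy, xx = np.mgrid[0:n, 0:n]
    cx = cy = (n - 1) / 2.0
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    R = side / 2.0
    if cls == 0:      # urchin: disc with radial spines
        spines = 0.30 * R * np.abs(np.sin(theta * rng.integers(8, 13)))
        mask = r <= (0.68 * R + spines)
    elif cls == 1:    # starfish: five-armed star
        phase = rng.uniform(0, 2 * np.pi)
        mask = r <= R * (0.45 + 0.55 * np.abs(np.cos(2.5 * (theta - phase))) ** 1.5)
    elif cls == 2:    # conch: logarithmic spiral band
        phase = rng.uniform(0, 2 * np.pi)
        spiral = np.exp(((theta - phase) % (2 * np.pi)) / (2 * np.pi) - 1.0)
        mask = np.abs(r - R * 0.75 * spiral) <= 0.22 * R
        mask |= r <= 0.25 * R
    else:             # scallop: ridged half-fan
        phase = rng.uniform(0, 2 * np.pi)
        ang = (theta - phase + np.pi) % (2 * np.pi) - np.pi
        ridges = 0.12 * R * np.cos(8 * ang)
        mask = (np.abs(ang) <= np.pi / 2.2) & (r <= 0.95 * R + ridges)
    return mask


def _tight_box(mask, x0, y0):
    ys, xs = np.nonzero(mask)
    return (x0 + xs.min(), y0 + ys.min(), x0 + xs.max() + 1, y0 + ys.max() + 1)


def _boxes_overlap(a, b):
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


def generate_scene(spec: SceneSpec):
    """Render one scene.

    Returns ``(image, boxes, classes)``: a (H, W, 3) uint8 image, an
    (N, 4) float array of xyxy pixel boxes (all inside the image) and an
    (N,) int array of class ids.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width, spec.height
    # seabed: vertical light gradient plus low-frequency texture
    grad = np.linspace(0.55, 0.30, h)[:, None]
    texture = gaussian_filter(rng.standard_normal((h, w)), 8) * 0.35
    base = np.clip(grad + texture, 0.05, 0.9)
    img = np.stack([base * 0.9, base * 0.95, base], axis=-1)

    palette = np.array([[0.45, 0.25, 0.35],   # urchin: dark purple
                        [0.85, 0.55, 0.30],   # starfish: orange
                        [0.80, 0.70, 0.55],   # conch: sandy
                        [0.75, 0.65, 0.70]])  # scallop: pale pink
    boxes, classes, masks = [], [], []
    for _ in range(spec.n_objects):
        cls = int(rng.choice(4, p=np.asarray(spec.class_mixture, dtype=float)))
        placed = False
        for _attempt in range(60):
            side = _sample_side(rng, spec.scale_mixture)
            n = int(np.ceil(side))
            if n >= min(w, h):
                continue
            x0 = int(rng.integers(0, w - n))
            y0 = int(rng.integers(0, h - n))
            mask = _shape_mask(cls, side, rng)
            box = _tight_box(mask, x0, y0)
            overlap = any(_boxes_overlap(box, b) for b in boxes)
            if overlap and rng.random() >= spec.occlusion_prob:
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place {spec.n_objects} objects of the requested "
                f"scales in a {w}x{h} scene within the occlusion budget")
        color = palette[cls] * rng.uniform(0.8, 1.2)
        shade = 1.0 - 0.3 * rng.random()
        region = img[y0:y0 + mask.shape[0], x0:x0 + mask.shape[1]]
        region[mask] = np.clip(color * shade, 0, 1)
        boxes.append(box)
        classes.append(cls)
        masks.append((mask, x0, y0))

    # photometric degradation (annotations above are already final)
    retention = np.array([0.35, 0.75, 0.92])  # red lost fastest under water
    factors = retention ** spec.tint_strength
    img = img * factors
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, (spec.blur_sigma, spec.blur_sigma, 0))
    if spec.noise_level > 0:
        img = img + rng.normal(0, spec.noise_level, img.shape)
    img = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    return img, boxes, np.asarray(classes, dtype=np.int64)


# --------------------------------------------------------------- datasets
@dataclass
class DatasetManifest:
    root: Path
    class_names: tuple = CLASS_NAMES
    splits: dict = field(default_factory=lambda: {"train": [], "val": [], "test": []})

    def label_path(self, image_path: Path) -> Path:
        p = Path(image_path)
        return p.parent.parent.parent / "labels" / p.parent.name / (p.stem + ".txt")


def split_counts(n: int) -> tuple:
    """7:2:1 split by count; floor rule, remainder goes to train."""
    val, test = n * 2 // 10, n * 1 // 10
    return n - val - test, val, test


def boxes_to_yolo(boxes, classes, w, h):
    lines = []
    for (x1, y1, x2, y2), c in zip(boxes, classes):
        cx, cy = (x1 + x2) / 2 / w, (y1 + y2) / 2 / h
        bw, bh = (x2 - x1) / w, (y2 - y1) / h
        lines.append(f"{int(c)} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    return "\n".join(lines)


def yolo_to_boxes(text, w, h):
    boxes, classes = [], []
    for line in text.strip().splitlines():
        if not line.strip():
            continue
        c, cx, cy, bw, bh = line.split()
        cx, cy, bw, bh = float(cx) * w, float(cy) * h, float(bw) * w, float(bh) * h
        boxes.append((cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2))
        classes.append(int(c))
    return (np.asarray(boxes, dtype=np.float64).reshape(-1, 4),
            np.asarray(classes, dtype=np.int64))


def write_dataset(out_dir, specs, single_split: str | None = None) -> DatasetManifest:
    """Generate scenes for ``specs``, write PNG images, YOLO label files and
    a YAML manifest; returns the manifest.

    By default scenes are assigned 7:2:1 to train/val/test; pass
    ``single_split`` to place every scene in one split instead.
    """
    import yaml

    root = Path(out_dir)
    manifest = DatasetManifest(root=root)
    if single_split is not None:
        split_of = [single_split] * len(specs)
    else:
        n_train, n_val, n_test = split_counts(len(specs))
        split_of = (["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
    for split in ("train", "val", "test"):
        (root / "images" / split).mkdir(parents=True, exist_ok=True)
        (root / "labels" / split).mkdir(parents=True, exist_ok=True)
    for i, spec in enumerate(specs):
        img, boxes, classes = generate_scene(spec)
        split = split_of[i]
        ip = root / "images" / split / f"scene_{i:05d}.png"
        lp = root / "labels" / split / f"scene_{i:05d}.txt"
        Image.fromarray(img).save(ip)
        lp.write_text(boxes_to_yolo(boxes, classes, spec.width, spec.height) + "\n")
        manifest.splits[split].append(str(ip))
    doc = {"path": str(root), "names": list(CLASS_NAMES),
           "train": manifest.splits["train"], "val": manifest.splits["val"],
           "test": manifest.splits["test"]}
    (root / "dataset.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))
    return manifest


def load_manifest(path) -> DatasetManifest:
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    m = DatasetManifest(root=Path(doc["path"]), class_names=tuple(doc["names"]))
    for split in ("train", "val", "test"):
        m.splits[split] = list(doc.get(split, []))
    return m


def load_sample(manifest: DatasetManifest, image_path):
    """Read one image and its YOLO labels back as arrays."""
    img = np.asarray(Image.open(image_path), dtype=np.uint8)
    h, w = img.shape[:2]
    boxes, classes = yolo_to_boxes(manifest.label_path(image_path).read_text(), w, h)
    return img, boxes, classes


def default_specs(n: int, size: int = 640, seed: int = 0, **overrides):
    """Per-scene specs with per-index derived seeds (deterministic)."""
    return [SceneSpec(width=size, height=size, seed=seed * 100_003 + i, **overrides)
            for i in range(n)]
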