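"""Synthetic laryngoscopy-like scenes with color-coded polygon masks.

Real training data for this task is a laryngoscopy photograph paired with a
ground-truth mask in which each lesion or structure is a filled polygon
painted in one of the seven canonical colors, plus "dummy" lesion-free
frames.  This module generates that format from scratch so the whole
pipeline — training, evaluation, file I/O — runs with no clinical data:

* the mask is black except for exact table-color polygons;
* the image is an endoscopy-like background (dark vignette around a shaded
  circular lumen, smooth gradient, speckle) with each lesion region tinted
  toward its class color, so the mapping from image to mask is learnable;
* a configurable fraction of samples is lesion-free (dummy);
* the two corruptions used by adversarial training — random affine
  distortion and Gaussian-noise mixing — live here too.

Pixel conventions: origin top-left, x rightward, y downward; polygon
membership is decided at pixel centers with even-odd (crossing-number)
filling, giving the half-open behavior where an axis-aligned rectangle
(x0,y0)-(x1,y1) covers exactly (x1−x0)×(y1−y0) pixels.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import AffineTransform, warp

from .color_codec import COLOR_TABLE, HueBandRule, classify_image

__all__ = [
    "SceneConfig",
    "SegSample",
    "DatasetManifest",
    "rasterize_polygon",
    "generate_sample",
    "generate_dataset",
    "apply_random_affine",
    "mix_gaussian_noise",
    "load_manifest",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene distribution.

    ``image_size`` must have both dimensions divisible by 32 (the network
    downsamples five times).  384×256 mirrors the per-image pixel count of
    the clinical evaluation tables; 256×256 (default) and smaller sizes are
    for fast experiments.
    """

    image_size: tuple[int, int] = (256, 256)  # (H, W)
    classes_per_image: tuple[int, int] = (2, 3)  # inclusive range
    polygon_vertices: tuple[int, int] = (5, 9)  # inclusive range
    area_fraction: tuple[float, float] = (0.04, 0.12)  # per-lesion area / image area
    # per-class sampling weights, proportional to the average per-image pixel
    # mass (TP+FN) each class carries in the published clinical evaluation
    # tables: cancer and L-FVC dominate laryngoscopy frames, benign tumors
    # are rare and small
    class_weights: tuple[float, ...] = (418, 708, 718, 1179, 1120, 3740, 3389)
    speckle_amplitude: float = 8.0  # 8-bit units of background texture noise
    lesion_tint: float = 0.55  # blend weight of class color inside a lesion
    dummy_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h % 32 or w % 32:
            raise ValueError(f"image dimensions must be divisible by 32, got {h}×{w}")
        if not (0.0 <= self.dummy_fraction <= 1.0):
            raise ValueError("dummy_fraction must be in [0, 1]")
        if not (0.0 <= self.lesion_tint <= 1.0):
            raise ValueError("lesion_tint must be in [0, 1]")


@dataclass
class SegSample:
    """A paired photograph-like image and color-coded polygon mask."""

    image: np.ndarray  # H×W×3 uint8
    mask: np.ndarray  # H×W×3 uint8, black background + exact table colors
    is_dummy: bool
    present_classes: frozenset[int]
    index: int
    image_path: str = ""
    mask_path: str = ""


@dataclass
class DatasetManifest:
    """On-disk dataset listing: one row per sample, split into train/test."""

    root: Path
    frame: pd.DataFrame  # columns: split, image_path, mask_path, is_dummy, classes

    def rows(self, split: str | None = None) -> pd.DataFrame:
        if split is None:
            return self.frame
        return self.frame[self.frame["split"] == split].reset_index(drop=True)


def rasterize_polygon(
    vertices: np.ndarray | list[tuple[float, float]],
    size: tuple[int, int],
    color: tuple[int, int, int],
) -> np.ndarray:
    """Fill a polygon on a black RGB canvas using even-odd pixel-center tests.

    ``vertices`` are (x, y) points; ``size`` is (H, W).  A degenerate
    (zero-area) polygon paints nothing and raises a warning.
    """
    verts = np.asarray(vertices, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    h, w = size
    x1 = verts[:, 0]
    y1 = verts[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    # shoelace area; exactly zero for collinear vertices
    if np.abs(np.sum(x1 * y2 - x2 * y1)) == 0.0:
        warnings.warn("degenerate (zero-area) polygon; nothing painted", stacklevel=2)
        return np.zeros((h, w, 3), dtype=np.uint8)

    py, px = np.mgrid[0:h, 0:w]
    px = px + 0.5
    py = py + 0.5
    inside = np.zeros((h, w), dtype=bool)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue
        crosses = (ey1 > py) != (ey2 > py)
        with np.errstate(invalid="ignore"):
            xint = ex1 + (py - ey1) * (ex2 - ex1) / (ey2 - ey1)
        inside ^= crosses & (px < xint)

    canvas = np.zeros((h, w, 3), dtype=np.uint8)
    canvas[inside] = np.asarray(color, dtype=np.uint8)
    return canvas


def _sample_rng(cfg: SceneConfig, index: int) -> np.random.Generator:
    # one stream per (master seed, sample index): order-independent generation
    return np.random.default_rng([cfg.seed, index])


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Endoscopy-like background: dark vignette, bright shaded lumen, speckle."""
    h, w = cfg.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy = h * rng.uniform(0.4, 0.6)
    cx = w * rng.uniform(0.4, 0.6)
    r = np.hypot(yy - cy, xx - cx) / (0.5 * min(h, w))
    lumen = np.clip(1.0 - r, 0.0, 1.0) ** 1.5
    # warm mucosa tones: strongest in red, weakest in blue
    base = np.stack(
        [40 + 150 * lumen, 25 + 90 * lumen, 25 + 70 * lumen],
        axis=-1,
    )
    gx, gy = rng.uniform(-20, 20, size=2)
    base += gx * (xx[..., None] / w - 0.5) + gy * (yy[..., None] / h - 0.5)
    base += rng.normal(0.0, cfg.speckle_amplitude, size=base.shape)
    return np.clip(base, 0, 255)


def _random_polygon(
    cfg: SceneConfig, rng: np.random.Generator, region_center: tuple[float, float]
) -> np.ndarray:
    h, w = cfg.image_size
    n = int(rng.integers(cfg.polygon_vertices[0], cfg.polygon_vertices[1] + 1))
    frac = rng.uniform(*cfg.area_fraction)
    radius = np.sqrt(frac * h * w / np.pi)
    angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=n))
    radii = radius * rng.uniform(0.6, 1.3, size=n)
    cx, cy = region_center
    x = np.clip(cx + radii * np.cos(angles), 1.0, w - 1.0)
    y = np.clip(cy + radii * np.sin(angles), 1.0, h - 1.0)
    return np.stack([x, y], axis=1)


def generate_sample(cfg: SceneConfig, index: int = 0) -> SegSample:
    """Deterministically generate the sample at ``index`` for this config.

    The first ``round(dummy_fraction * 1/step)`` pattern is not used;
    instead each sample independently draws its dummy flag, so a dataset of
    n samples is the first n entries of one infinite exchangeable stream.
    """
    rng = _sample_rng(cfg, index)
    h, w = cfg.image_size
    image = _background(cfg, rng)
    mask = np.zeros((h, w, 3), dtype=np.uint8)

    is_dummy = bool(rng.random() < cfg.dummy_fraction)
    if not is_dummy:
        k = int(rng.integers(cfg.classes_per_image[0], cfg.classes_per_image[1] + 1))
        weights = np.asarray(cfg.class_weights, dtype=np.float64)
        class_ids = rng.choice(
            len(COLOR_TABLE), size=k, replace=False, p=weights / weights.sum()
        )
        # spread lesion centers on a ring around the lumen so polygons rarely
        # overlap; later classes overwrite earlier ones where they do
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for j, class_id in enumerate(class_ids):
            theta = phase + 2.0 * np.pi * j / max(k, 1)
            cx = w / 2 + 0.28 * w * np.cos(theta) + rng.uniform(-0.04, 0.04) * w
            cy = h / 2 + 0.28 * h * np.sin(theta) + rng.uniform(-0.04, 0.04) * h
            verts = _random_polygon(cfg, rng, (cx, cy))
            spec = COLOR_TABLE[int(class_id)]
            poly = rasterize_polygon(verts, (h, w), spec.rgb)
            painted = poly.any(axis=-1)
            mask[painted] = spec.rgb
            tint = np.asarray(spec.rgb, dtype=np.float64)
            image[painted] = (1.0 - cfg.lesion_tint) * image[painted] + cfg.lesion_tint * tint

    image = np.clip(image, 0, 255).astype(np.uint8)
    present = frozenset(int(c) for c in np.unique(classify_image(mask, HueBandRule())) if c >= 0)
    return SegSample(image=image, mask=mask, is_dummy=len(present) == 0, present_classes=present, index=index)


def generate_dataset(
    cfg: SceneConfig,
    n: int,
    split: tuple[int, int],
    out_dir: str | Path,
) -> DatasetManifest:
    """Write ``n`` paired PNGs plus a manifest CSV under ``out_dir``.

    ``split = (n_train, n_test)`` must sum to ``n``; the first ``n_train``
    sample indices are train, the rest test (the stream is exchangeable, so
    this is a random split).
    """
    n_train, n_test = split
    if n_train + n_test != n:
        raise ValueError(f"split {split} does not sum to n={n}")
    root = Path(out_dir)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)

    records = []
    for i in range(n):
        sample = generate_sample(cfg, i)
        image_path = f"images/{i:05d}.png"
        mask_path = f"masks/{i:05d}.png"
        Image.fromarray(sample.image).save(root / image_path)
        Image.fromarray(sample.mask).save(root / mask_path)
        records.append(
            {
                "split": "train" if i < n_train else "test",
                "image_path": image_path,
                "mask_path": mask_path,
                "is_dummy": sample.is_dummy,
                "classes": " ".join(str(c) for c in sorted(sample.present_classes)),
            }
        )
    frame = pd.DataFrame.from_records(records)
    frame.to_csv(root / "manifest.csv", index=False)
    return DatasetManifest(root=root, frame=frame)


def load_manifest(root: str | Path) -> DatasetManifest:
    root = Path(root)
    frame = pd.read_csv(root / "manifest.csv", keep_default_na=False)
    frame["classes"] = frame["classes"].astype(str)
    return DatasetManifest(root=root, frame=frame)


def manifest_digest(manifest: DatasetManifest) -> str:
    """SHA-256 of the manifest CSV contents (reproducibility checks)."""
    payload = manifest.frame.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


def apply_random_affine(
    image: np.ndarray,
    max_rotation: float | tuple[float, float] = 15.0,
    max_translate: float | tuple[float, float] = 0.10,
    max_shear: float | tuple[float, float] = 5.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Random affine distortion (rotation°, translation fraction, shear°).

    Scalars mean symmetric ±bound; a (lo, hi) pair fixes the range exactly
    (so (180, 180) forces a half-turn).  The rotation/shear pivot is the
    image center; out-of-frame pixels are filled by edge replication.
    """
    rng = rng or np.random.default_rng()

    def draw(bound: float | tuple[float, float]) -> float:
        lo, hi = (-bound, bound) if np.isscalar(bound) else bound
        return float(rng.uniform(lo, hi))

    theta = np.deg2rad(draw(max_rotation))
    shear = np.deg2rad(draw(max_shear))
    h, w = image.shape[:2]
    tx = draw(max_translate) * w
    ty = draw(max_translate) * h

    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t_fwd = AffineTransform(translation=center)
    t_mid = AffineTransform(rotation=theta, shear=shear, translation=(tx, ty))
    t_back = AffineTransform(translation=-center)
    tform = t_back + t_mid + t_fwd  # maps output coords back through the pivot

    out = warp(
        image.astype(np.float64),
        tform.inverse,
        mode="edge",
        order=1,
        preserve_range=True,
    )
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out.astype(image.dtype)


def mix_gaussian_noise(
    image: np.ndarray, sigma: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Mix the image with a Gaussian noise field of standard deviation ``sigma``.

    The blend weight grows with sigma (``min(sigma/255, 1)``): sigma 0 is the
    identity, sigma ≥ 255 replaces the content entirely with noise, which is
    the information-free input the adversarial validity target needs.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return image.copy()
    rng = rng or np.random.default_rng()
    noise = rng.normal(128.0, sigma, size=image.shape)
    beta = min(sigma / 255.0, 1.0)
    out = (1.0 - beta) * image.astype(np.float64) + beta * noise
    out = np.clip(out, 0, 255)
    if np.issubdtype(image.dtype, np.integer):
        return np.rint(out).astype(image.dtype)
    return out.astype(image.dtype)
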