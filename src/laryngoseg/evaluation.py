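"""Pixel-level evaluation of color-coded segmentations.

Predictions and ground truth are both RGB images whose lesion regions are
painted in the seven canonical colors, so every metric starts from hue-band
pixel classification: per class, the pixel confusion cells TP/TN/FP/FN are
counted, then

* accuracy = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP) and
  recall = TP/(TP+FN) are computed from the *dataset-averaged* cells (this
  is the convention that reproduces the published per-class tables), while
* F1 = 2TP/(2TP+FP+FN), pixel IoU, bounding-box IoU and the mAUC
  approximation are averaged per image over the images where the class
  occurs.

bbIoU compares axis-aligned bounding boxes of the largest connected
component of each mask.  mAUC is a documented stand-in for an unspecified
per-image AUC approximation: the hue-band half-width applied to the
prediction is swept over a fixed grid, each width yields an (FPR, TPR)
point against the fixed ground truth, and the trapezoidal area under the
(0,0)-anchored, (1,1)-completed curve is reported.

``evaluate_dataset`` runs a trained model over a manifest and writes the
per-class metrics table, a 13-column per-image prediction CSV, a JPG
directory of input/output overlays, and a PNG directory of the largest
detected polygon per image.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import measure

from .color_codec import BACKGROUND, COLOR_TABLE, HueBandRule, _EDGE_EPS, rgb_to_hsv_units
from .model import SegModel, load_checkpoint
from .synthetic_data import DatasetManifest, apply_random_affine

__all__ = [
    "ConfusionCells",
    "PolygonRecord",
    "confusion_cells",
    "accuracy",
    "precision_recall",
    "f1_per_image",
    "iou_pixels",
    "iou_boxes",
    "mauc",
    "MAUC_HALF_WIDTHS",
    "gram_difference",
    "extract_max_polygon",
    "evaluate_pairs",
    "evaluate_dataset",
    "evaluate_ground_truth",
]

_NUM_CLASSES = len(COLOR_TABLE)

#: Fixed half-width grid (0–179 hue units) swept by the mAUC approximation.
MAUC_HALF_WIDTHS: tuple[float, ...] = (1, 2, 3, 5, 7, 10, 14, 20, 28, 40, 60, 90)


@dataclass(frozen=True)
class ConfusionCells:
    """Per-class pixel counts (floats: they average across images)."""

    tp: float
    tn: float
    fp: float
    fn: float

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class PolygonRecord:
    """Largest detected polygon of one class in one prediction image."""

    vertices: np.ndarray  # (k, 2) float (x, y), empty when nothing detected
    area: float
    centroid: tuple[float, float]  # (x, y)
    area_ratio: float
    n_colors: int


# ---------------------------------------------------------------------------
# hue decomposition (shared by the classifier sweep)


def _hue_decomposition(image: np.ndarray, rule: HueBandRule):
    """Per-pixel nearest class, circular hue distance, and floor mask."""
    hsv = rgb_to_hsv_units(image)
    hues = np.array([spec.hue_units for spec in COLOR_TABLE])
    d = np.abs(hsv[..., 0][..., None] - hues)
    d = np.minimum(d, 180.0 - d)
    nearest = np.argmin(d, axis=-1)
    dist = np.min(d, axis=-1)
    floored = (hsv[..., 1] < rule.min_saturation) | (hsv[..., 2] < rule.min_value)
    return nearest, dist, floored


def _labels_at(nearest, dist, floored, half_width: float) -> np.ndarray:
    labels = np.where((dist <= half_width + _EDGE_EPS) & ~floored, nearest, BACKGROUND)
    return labels


def _labels(image: np.ndarray, rule: HueBandRule) -> np.ndarray:
    nearest, dist, floored = _hue_decomposition(image, rule)
    return _labels_at(nearest, dist, floored, rule.half_width_units)


# ---------------------------------------------------------------------------
# confusion cells and scalar metrics


def confusion_cells(
    pred_img: np.ndarray, gt_img: np.ndarray, class_id: int, rule: HueBandRule | None = None
) -> ConfusionCells:
    """Pixel confusion cells of one class between two color-coded images."""
    if pred_img.shape != gt_img.shape:
        raise ValueError(f"shape mismatch: {pred_img.shape} vs {gt_img.shape}")
    rule = rule or HueBandRule()
    pred = _labels(pred_img, rule) == class_id
    gt = _labels(gt_img, rule) == class_id
    return _cells_from_masks(pred, gt)


def _cells_from_masks(pred: np.ndarray, gt: np.ndarray) -> ConfusionCells:
    tp = float(np.sum(pred & gt))
    fp = float(np.sum(pred & ~gt))
    fn = float(np.sum(~pred & gt))
    tn = float(pred.size - tp - fp - fn)
    return ConfusionCells(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(cells: ConfusionCells | tuple) -> float:
    """(TP+TN)/(TP+TN+FP+FN)."""
    cells = _coerce_cells(cells)
    if cells.total == 0:
        raise ValueError("accuracy undefined for all-zero cells")
    return (cells.tp + cells.tn) / cells.total


def precision_recall(cells: ConfusionCells | tuple) -> tuple[float, float]:
    """(TP/(TP+FP), TP/(TP+FN)); a degenerate denominator gives 0.0."""
    cells = _coerce_cells(cells)
    precision = cells.tp / (cells.tp + cells.fp) if cells.tp + cells.fp > 0 else 0.0
    recall = cells.tp / (cells.tp + cells.fn) if cells.tp + cells.fn > 0 else 0.0
    return precision, recall


def f1_per_image(cells: ConfusionCells | tuple) -> float:
    """2·TP/(2·TP+FP+FN); 0.0 when the class is absent on both sides."""
    cells = _coerce_cells(cells)
    denom = 2.0 * cells.tp + cells.fp + cells.fn
    return 2.0 * cells.tp / denom if denom > 0 else 0.0


def _coerce_cells(cells) -> ConfusionCells:
    if isinstance(cells, ConfusionCells):
        return cells
    return ConfusionCells(*map(float, cells))


# ---------------------------------------------------------------------------
# IoU on pixels and on bounding boxes


def iou_pixels(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """|∩|/|∪| of two binary masks; both-empty is defined as 0."""
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("mask shape mismatch")
    union = np.sum(pred_mask | gt_mask)
    if union == 0:
        return 0.0
    return float(np.sum(pred_mask & gt_mask)) / float(union)


_CONN8 = np.ones((3, 3), dtype=int)


def _largest_component(mask: np.ndarray) -> np.ndarray | None:
    labeled, n = ndimage.label(mask, structure=_CONN8)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    return labeled == (int(np.argmax(sizes)) + 1)


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return xs.min(), ys.min(), xs.max() + 1, ys.max() + 1  # half-open


def iou_boxes(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """IoU of the axis-aligned bounding boxes of the largest components."""
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("mask shape mismatch")
    comp_p = _largest_component(pred_mask)
    comp_g = _largest_component(gt_mask)
    if comp_p is None or comp_g is None:
        return 0.0
    x0p, y0p, x1p, y1p = _bbox(comp_p)
    x0g, y0g, x1g, y1g = _bbox(comp_g)
    iw = max(0, min(x1p, x1g) - max(x0p, x0g))
    ih = max(0, min(y1p, y1g) - max(y0p, y0g))
    inter = iw * ih
    union = (x1p - x0p) * (y1p - y0p) + (x1g - x0g) * (y1g - y0g) - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# mAUC approximation


def mauc(
    pred_img: np.ndarray, gt_img: np.ndarray, class_id: int, rule: HueBandRule | None = None
) -> float:
    """Trapezoidal area under (FPR, TPR) points from a hue-band width sweep.

    The ground-truth mask is fixed at ``rule``; the prediction's band
    half-width runs over ``MAUC_HALF_WIDTHS``.  The curve is anchored at
    (0,0) and completed at (1,1).  Returns NaN when the class is absent
    from the ground truth (flagged; excluded from dataset averages).
    """
    if pred_img.shape != gt_img.shape:
        raise ValueError(f"shape mismatch: {pred_img.shape} vs {gt_img.shape}")
    rule = rule or HueBandRule()
    gt = _labels(gt_img, rule) == class_id
    n_pos = int(gt.sum())
    n_neg = gt.size - n_pos
    if n_pos == 0:
        return float("nan")
    nearest, dist, floored = _hue_decomposition(pred_img, rule)
    points = [(0.0, 0.0), (1.0, 1.0)]
    for width in MAUC_HALF_WIDTHS:
        pred = _labels_at(nearest, dist, floored, width) == class_id
        tp = float(np.sum(pred & gt))
        fp = float(np.sum(pred & ~gt))
        tpr = tp / n_pos
        fpr = fp / n_neg if n_neg > 0 else 0.0
        points.append((fpr, tpr))
    points.sort()
    fprs, tprs = zip(*points)
    return float(np.trapezoid(tprs, fprs))


# ---------------------------------------------------------------------------
# encoder-side scores


def gram_difference(features_a: np.ndarray, features_b: np.ndarray) -> float:
    """Frobenius norm of the difference of channel Gram matrices.

    Feature maps are (C, ...) arrays; G = A·Aᵀ over flattened spatial axes,
    normalized by the feature-map element count.
    """
    fa = np.asarray(features_a, dtype=np.float64)
    fb = np.asarray(features_b, dtype=np.float64)
    if fa.shape != fb.shape:
        raise ValueError(f"feature shape mismatch: {fa.shape} vs {fb.shape}")
    a = fa.reshape(fa.shape[0], -1)
    b = fb.reshape(fb.shape[0], -1)
    ga = (a @ a.T) / a.size
    gb = (b @ b.T) / b.size
    return float(np.linalg.norm(ga - gb))


def extract_max_polygon(
    pred_img: np.ndarray, class_id: int, rule: HueBandRule | None = None
) -> PolygonRecord:
    """Largest connected component of one class, as a polygon record.

    ``area_ratio`` relates this class's largest polygon to the sum of the
    largest polygons over all detected classes; ``n_colors`` counts the
    distinct classes detected anywhere in the image.
    """
    rule = rule or HueBandRule()
    labels = _labels(pred_img, rule)
    areas: dict[int, float] = {}
    components: dict[int, np.ndarray] = {}
    for cid in range(_NUM_CLASSES):
        comp = _largest_component(labels == cid)
        if comp is not None:
            components[cid] = comp
            areas[cid] = float(comp.sum())
    if class_id not in components:
        return PolygonRecord(np.empty((0, 2)), 0.0, (0.0, 0.0), 0.0, len(areas))
    comp = components[class_id]
    area = areas[class_id]
    cy, cx = ndimage.center_of_mass(comp)
    contours = measure.find_contours(comp.astype(float), 0.5)
    longest = max(contours, key=len) if contours else np.empty((0, 2))
    vertices = longest[:, ::-1]  # (row, col) -> (x, y)
    ratio = area / sum(areas.values())
    return PolygonRecord(vertices, area, (float(cx), float(cy)), ratio, len(areas))


# ---------------------------------------------------------------------------
# dataset-level evaluation


_TABLE_COLUMNS = ["Cls", "Count", "F1", "TP", "TN", "FP", "FN", "ACC", "IoU",
                  "bbIoU", "mAUC", "Precision", "Recall"]


def evaluate_pairs(
    preds: list[np.ndarray], gts: list[np.ndarray], rule: HueBandRule | None = None
) -> pd.DataFrame:
    """Per-class metrics table from paired prediction/ground-truth images.

    Cells are averaged over all images; F1/IoU/bbIoU/mAUC are per-image
    means over images where the class occurs (in ground truth or
    prediction).  Rows are ordered class 6 → 0 like the published tables.
    """
    rule = rule or HueBandRule()
    if len(preds) != len(gts):
        raise ValueError("prediction and ground-truth counts differ")
    n = len(preds)
    cells_sum = np.zeros((_NUM_CLASSES, 4))
    per_image: dict[int, dict[str, list[float]]] = {
        c: {"f1": [], "iou": [], "bbiou": [], "mauc": []} for c in range(_NUM_CLASSES)
    }
    for pred_img, gt_img in zip(preds, gts):
        if pred_img.shape != gt_img.shape:
            raise ValueError("image shape mismatch")
        pred_labels = _labels(pred_img, rule)
        gt_labels = _labels(gt_img, rule)
        for cid in range(_NUM_CLASSES):
            pred = pred_labels == cid
            gt = gt_labels == cid
            c = _cells_from_masks(pred, gt)
            cells_sum[cid] += (c.tp, c.tn, c.fp, c.fn)
            if not (pred.any() or gt.any()):
                continue
            per_image[cid]["f1"].append(f1_per_image(c))
            per_image[cid]["iou"].append(iou_pixels(pred, gt))
            per_image[cid]["bbiou"].append(iou_boxes(pred, gt))
            if gt.any():
                per_image[cid]["mauc"].append(mauc(pred_img, gt_img, cid, rule))
    rows = []
    for cid in range(_NUM_CLASSES - 1, -1, -1):
        tp, tn, fp, fn = cells_sum[cid] / n
        mean_cells = ConfusionCells(tp, tn, fp, fn)
        precision, recall = precision_recall(mean_cells)
        stats = per_image[cid]
        rows.append(
            {
                "Cls": cid,
                "Count": n,
                "F1": _mean_or_zero(stats["f1"]),
                "TP": tp, "TN": tn, "FP": fp, "FN": fn,
                "ACC": accuracy(mean_cells),
                "IoU": _mean_or_zero(stats["iou"]),
                "bbIoU": _mean_or_zero(stats["bbiou"]),
                "mAUC": _mean_or_zero(stats["mauc"]),
                "Precision": precision,
                "Recall": recall,
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def _mean_or_zero(values: list[float]) -> float:
    finite = [v for v in values if np.isfinite(v)]
    return float(np.mean(finite)) if finite else 0.0


def _run_root(out_dir: Path, manifest: DatasetManifest) -> Path:
    run_date = os.environ.get("DATE", date.today().strftime("%Y%m%d"))
    dataset = os.environ.get("DATASET", manifest.root.name or "dataset")
    root = out_dir / f"{run_date}-{dataset}"
    (root / "JPG").mkdir(parents=True, exist_ok=True)
    (root / "PNG").mkdir(parents=True, exist_ok=True)
    return root


def _prediction_record(
    model: SegModel | None,
    image: np.ndarray,
    pred_img: np.ndarray,
    image_path: str,
    rule: HueBandRule,
    rng: np.random.Generator,
) -> tuple[dict, PolygonRecord]:
    labels = _labels(pred_img, rule)
    present = [c for c in range(_NUM_CLASSES) if np.any(labels == c)]
    best = {c: extract_max_polygon(pred_img, c, rule) for c in present}
    if best:
        predicted_class = max(best, key=lambda c: best[c].area)
        poly = best[predicted_class]
    else:
        predicted_class = BACKGROUND
        poly = PolygonRecord(np.empty((0, 2)), 0.0, (0.0, 0.0), 0.0, 0)

    top3 = (0, 0, 0)
    latent_diff = 0.0
    validity = 0.0
    encoder_error = 0.0
    if model is not None:
        from .nn import Tensor, no_grad

        distorted = apply_random_affine(image, rng=rng)
        x = np.stack([image, distorted]).transpose(0, 3, 1, 2).astype(np.float32) / 255.0
        with no_grad():
            latent, _, validity_logit, _, _ = model.encode(Tensor(x))
            feats = model.encoder_feature_map(Tensor(x)).data
        z, z_dist = latent.data
        order = np.argsort(z)[::-1]
        top3 = tuple(int(i) for i in order[:3])
        latent_diff = float(np.linalg.norm(z - z_dist))
        validity = float(1.0 / (1.0 + np.exp(-validity_logit.data[0, 0])))
        encoder_error = gram_difference(feats[0], feats[1])

    record = {
        "C1": int(predicted_class),
        "C2": top3[0], "C3": top3[1], "C4": top3[2],
        "C5": latent_diff,
        "C6": validity,
        "C7": encoder_error,
        "C8": poly.n_colors,
        "C9": poly.area,
        "C10": poly.area_ratio,
        "C11": poly.centroid[0],
        "C12": poly.centroid[1],
        "C13": image_path,
    }
    return record, poly


def _evaluate(
    model: SegModel | None,
    manifest: DatasetManifest,
    out_dir: str | Path,
    rule: HueBandRule,
    split: str,
    seed: int = 0,
    self_test: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    rows = manifest.rows(split)
    if len(rows) == 0:
        raise ValueError(f"manifest has no rows for split {split!r}")
    root = _run_root(Path(out_dir), manifest)
    rng = np.random.default_rng(seed)

    preds, gts, records = [], [], []
    missing: list[str] = []
    for _, row in rows.iterrows():
        image_file = manifest.root / row["image_path"]
        mask_file = manifest.root / row["mask_path"]
        if not image_file.exists() or not mask_file.exists():
            missing.append(str(image_file))
            continue
        image = np.asarray(Image.open(image_file).convert("RGB"))
        gt = np.asarray(Image.open(mask_file).convert("RGB"))
        if self_test:
            pred = gt
        else:
            seg = model.predict(image[None])["seg_image"][0]
            pred = np.clip(seg * 255.0, 0, 255).astype(np.uint8)
        preds.append(pred)
        gts.append(gt)
        record, poly = _prediction_record(model, image, pred, row["image_path"], rule, rng)
        records.append(record)

        stem = Path(row["image_path"]).stem
        overlay = np.clip(0.5 * image + 0.5 * pred, 0, 255).astype(np.uint8)
        Image.fromarray(overlay).save(root / "JPG" / f"{stem}.jpg")
        poly_img = np.zeros_like(pred)
        if poly.area > 0 and record["C1"] >= 0:
            comp = _largest_component(_labels(pred, rule) == record["C1"])
            poly_img[comp] = COLOR_TABLE[record["C1"]].rgb
        Image.fromarray(poly_img).save(root / "PNG" / f"{stem}.png")

    table = evaluate_pairs(preds, gts, rule)
    pred_frame = pd.DataFrame(records, columns=[f"C{i}" for i in range(1, 14)])
    table.to_csv(root / "metrics.csv", index=False)
    pred_frame.to_csv(root / "predictions.csv", index=False)

    validity = pred_frame["C6"].to_numpy(dtype=float)
    top_counts = pred_frame["C2"].value_counts().to_dict() if model is not None else {}
    summary = {
        "n_images": len(preds),
        "missing_files": missing,
        "validity_mean": float(validity.mean()) if len(validity) else 0.0,
        "validity_std": float(validity.std()) if len(validity) else 0.0,
        "latent_top1_counts": {int(k): int(v) for k, v in top_counts.items()},
        "out_dir": str(root),
    }
    return table, pred_frame, summary


def evaluate_dataset(
    checkpoint: str | Path | SegModel,
    manifest: DatasetManifest,
    out_dir: str | Path,
    rule: HueBandRule | None = None,
    split: str = "test",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run a trained model over a manifest split and write all outputs.

    Returns (per-class metrics table, per-image prediction records, summary
    dict with validity statistics and latent top-index counts).
    """
    model = checkpoint if isinstance(checkpoint, SegModel) else load_checkpoint(checkpoint)[0]
    return _evaluate(model, manifest, out_dir, rule or HueBandRule(), split, seed=seed)


def evaluate_ground_truth(
    manifest: DatasetManifest,
    out_dir: str | Path,
    rule: HueBandRule | None = None,
    split: str = "test",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Oracle ceiling: evaluate the ground truth against itself."""
    return _evaluate(None, manifest, out_dir, rule or HueBandRule(), split, self_test=True)
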