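"""Published per-class confusion-matrix tables used as worked-example inputs.

Two evaluation campaigns on clinical laryngoscopy data are distributed as
printed per-class tables: dataset-averaged pixel confusion cells (TP, TN,
FP, FN) together with the derived ACC/IoU/bbIoU/mAUC/precision/recall
columns, one for a 300-image test split and one for a 1035-image test
split.  The cells are inputs here: the evaluation module's accuracy /
precision / recall formulas applied to the printed cells must reproduce the
printed derived columns at their printed precision, which pins down the
arithmetic conventions of the evaluation stack.

Cell sums are ~98,304 = 384×256 pixels per image, which is why 384×256 is
offered as a scene preset.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceRow", "TEST_300", "TEST_1035", "WORKED_EXAMPLE_CELLS"]


@dataclass(frozen=True)
class ReferenceRow:
    """One printed row: averaged confusion cells plus derived metrics."""

    class_id: int
    count: int
    f1: float
    tp: float
    tn: float
    fp: float
    fn: float
    acc: float
    iou: float
    bb_iou: float
    mauc: float
    precision: float
    recall: float


# 300-image evaluation split (2700:300 train:test campaign).
TEST_300: tuple[ReferenceRow, ...] = (
    ReferenceRow(6, 300, 0.77, 2417.41, 94777.63, 432.32, 676.65, 0.99, 0.65, 0.38, 0.39, 0.85, 0.78),
    ReferenceRow(5, 300, 0.74, 2670.96, 94389.35, 479.80, 763.89, 0.99, 0.62, 0.46, 0.37, 0.85, 0.78),
    ReferenceRow(4, 300, 0.72, 871.88, 97029.50, 166.04, 236.59, 1.00, 0.55, 0.42, 0.35, 0.84, 0.79),
    ReferenceRow(3, 300, 0.74, 977.20, 96889.34, 215.41, 222.06, 1.00, 0.59, 0.39, 0.39, 0.82, 0.81),
    ReferenceRow(2, 300, 0.64, 409.78, 97535.78, 140.10, 218.34, 1.00, 0.33, 0.28, 0.33, 0.75, 0.65),
    ReferenceRow(1, 300, 0.65, 396.02, 97564.11, 123.58, 220.30, 1.00, 0.35, 0.29, 0.32, 0.76, 0.64),
    ReferenceRow(0, 300, 0.54, 125.57, 97775.43, 68.55, 334.45, 1.00, 0.14, 0.19, 0.20, 0.65, 0.27),
)

# 1035-image evaluation split (4136:1035 train:test campaign).
TEST_1035: tuple[ReferenceRow, ...] = (
    ReferenceRow(6, 1035, 0.75, 2814.15, 93923.13, 697.20, 869.52, 0.98, 0.61, 0.49, 0.38, 0.80, 0.76),
    ReferenceRow(5, 1035, 0.72, 3140.11, 93426.73, 831.94, 905.22, 0.98, 0.59, 0.56, 0.37, 0.79, 0.78),
    ReferenceRow(4, 1035, 0.68, 861.58, 96943.25, 228.44, 270.73, 0.99, 0.51, 0.53, 0.33, 0.79, 0.76),
    ReferenceRow(3, 1035, 0.73, 935.46, 96909.83, 235.43, 223.27, 1.00, 0.56, 0.54, 0.36, 0.80, 0.81),
    ReferenceRow(2, 1035, 0.65, 586.78, 97251.42, 245.84, 219.95, 1.00, 0.42, 0.41, 0.33, 0.70, 0.73),
    ReferenceRow(1, 1035, 0.65, 578.17, 97275.17, 229.28, 221.37, 1.00, 0.44, 0.43, 0.32, 0.72, 0.72),
    ReferenceRow(0, 1035, 0.50, 128.96, 97857.93, 70.05, 247.06, 1.00, 0.15, 0.22, 0.17, 0.65, 0.34),
)

#: The worked-example confusion cells (class 6, 300-image split): their
#: accuracy (TP+TN)/(TP+TN+FP+FN) evaluates to ≈0.989.
WORKED_EXAMPLE_CELLS: tuple[float, float, float, float] = (2417.41, 94777.63, 432.32, 676.65)
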