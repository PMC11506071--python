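"""Seven-color lesion codec.

Ground-truth masks for laryngoscopy segmentation paint each anatomical
structure or lesion as a filled polygon in one of seven fully saturated
colors.  Every color sits at a distinct hue with S = V = 100%, so decoding a
mask (or a network prediction) reduces to hue-band classification in HSV
space.  This module owns the canonical color table, exact HSV→RGB→hex
conversion, and the vectorized hue-band classifier used by evaluation and by
the synthetic data generator.

Hue is handled on the 0–179 integer scale (1 unit = 2 degrees) as is
conventional for 8-bit HSV images; canonical class hues may fall on
half-units (e.g. 105° = 52.5 units), so all comparisons are done in float.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LesionClassSpec",
    "HueBandRule",
    "COLOR_TABLE",
    "BACKGROUND",
    "hsv_to_rgb",
    "rgb_to_hex",
    "rgb_to_hsv_units",
    "classify_pixel",
    "classify_image",
    "class_mask",
    "color_table_csv",
]

#: Sentinel class id for pixels that belong to no lesion class.
BACKGROUND: int = -1


@dataclass(frozen=True)
class LesionClassSpec:
    """One lesion/structure class with its canonical color.

    ``hue_deg`` is on the 0–359 degree circle; ``saturation`` and ``value``
    are fractions (always 1.0 for the canonical table).  ``rgb`` and ``hex``
    are the exact 8-bit rendering of that HSV triple.
    """

    class_id: int
    name: str
    hue_deg: float
    saturation: float
    value: float
    rgb: tuple[int, int, int]
    hex: str

    @property
    def hue_units(self) -> float:
        """Canonical hue on the 0–179 half-degree scale (may be fractional)."""
        return self.hue_deg / 2.0


@dataclass(frozen=True)
class HueBandRule:
    """Decision rule for assigning a pixel to the nearest class hue.

    A pixel is assigned to the class whose canonical hue is circularly
    nearest, provided the distance is at most ``half_width_units`` (default
    10 units = 20 degrees, i.e. a 40-degree total band) and the pixel clears
    the saturation/value floors.  Ties on distance break toward the lower
    class id.  Everything else is background.

    8-bit pixels produce rational hues that can land exactly on a band
    edge; the edge comparison therefore carries a 1e-9 guard so that
    float round-off cannot flip an exact-boundary pixel to background.
    """

    half_width_units: float = 10.0
    min_saturation: int = 64
    min_value: int = 64


_EDGE_EPS = 1e-9  # see HueBandRule: absorbs float error at exact band edges


def hsv_to_rgb(h: float, s: float, v: float) -> tuple[int, int, int]:
    """Exact hexcone HSV→RGB conversion, channels rounded to 0–255 ints.

    ``h`` in degrees [0, 360), ``s`` and ``v`` fractions in [0, 1].
    """
    if not (0.0 <= h < 360.0):
        raise ValueError(f"hue must be in [0, 360), got {h!r}")
    if not (0.0 <= s <= 1.0 and 0.0 <= v <= 1.0):
        raise ValueError(f"saturation and value must be in [0, 1], got s={s!r}, v={v!r}")
    c = v * s
    hp = h / 60.0
    x = c * (1.0 - abs(hp % 2.0 - 1.0))
    sector = int(hp)
    rgb1 = [(c, x, 0.0), (x, c, 0.0), (0.0, c, x), (0.0, x, c), (x, 0.0, c), (c, 0.0, x)][sector]
    m = v - c
    return tuple(int(round(255.0 * (ch + m))) for ch in rgb1)  # type: ignore[return-value]


def rgb_to_hex(rgb: Sequence[int]) -> str:
    """Uppercase ``#RRGGBB`` for an 8-bit RGB triple."""
    r, g, b = rgb
    for ch in (r, g, b):
        if not (isinstance(ch, (int, np.integer)) and 0 <= ch <= 255):
            raise ValueError(f"RGB channels must be integers in 0–255, got {rgb!r}")
    return f"#{r:02X}{g:02X}{b:02X}"


def _make_table() -> tuple[LesionClassSpec, ...]:
    rows = [
        (0, "Benign Tumor", 0.0),
        (1, "Subglottis", 60.0),
        (2, "R-TVC", 105.0),
        (3, "L-TVC", 180.0),
        (4, "R-FVC", 210.0),
        (5, "L-FVC", 255.0),
        (6, "Cancer", 300.0),
    ]
    table = []
    for class_id, name, hue in rows:
        rgb = hsv_to_rgb(hue, 1.0, 1.0)
        table.append(
            LesionClassSpec(
                class_id=class_id,
                name=name,
                hue_deg=hue,
                saturation=1.0,
                value=1.0,
                rgb=rgb,
                hex=rgb_to_hex(rgb),
            )
        )
    return tuple(table)


#: The canonical seven-class color table, ordered by class id.
COLOR_TABLE: tuple[LesionClassSpec, ...] = _make_table()

_CLASS_HUES = np.array([spec.hue_units for spec in COLOR_TABLE])  # 0–179 scale


def rgb_to_hsv_units(image: np.ndarray) -> np.ndarray:
    """Vectorized RGB→HSV on 8-bit integer scales (H 0–179 float, S/V 0–255).

    Matches the convention of 8-bit HSV images: hue is halved to fit a byte,
    but is returned as float so half-unit class hues compare exactly.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim < 1 or img.shape[-1] != 3:
        raise ValueError("expected an array with a trailing RGB axis of size 3")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    v = np.max(img, axis=-1)
    c = v - np.min(img, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v > 0, c / v * 255.0, 0.0)
        hp = np.where(
            c > 0,
            np.select(
                [v == r, v == g],
                [(g - b) / c % 6.0, (b - r) / c + 2.0],
                default=(r - g) / c + 4.0,
            ),
            0.0,
        )
    h = hp * 30.0  # 60 deg/sector on the halved 0–179 scale
    return np.stack([h, s, v], axis=-1)


def _circular_hue_distance(h: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d = np.abs(h[..., None] - centers)
    return np.minimum(d, 180.0 - d)


def classify_image(image: np.ndarray, rule: HueBandRule | None = None) -> np.ndarray:
    """Classify every pixel of an RGB image into a class id or ``BACKGROUND``.

    Nearest-hue assignment with a hard band radius: a pixel farther than
    ``rule.half_width_units`` from every canonical hue, or below the
    saturation/value floors, is background.  ``np.argmin`` breaks distance
    ties toward the lower class id.
    """
    rule = rule or HueBandRule()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {img.shape}")
    hsv = rgb_to_hsv_units(img)
    dist = _circular_hue_distance(hsv[..., 0], _CLASS_HUES)
    labels = np.argmin(dist, axis=-1).astype(np.int64)
    nearest = np.min(dist, axis=-1)
    background = (
        (nearest > rule.half_width_units + _EDGE_EPS)
        | (hsv[..., 1] < rule.min_saturation)
        | (hsv[..., 2] < rule.min_value)
    )
    labels[background] = BACKGROUND
    return labels


def classify_pixel(hsv: Sequence[float], rule: HueBandRule | None = None) -> int:
    """Classify one HSV pixel (H on 0–179, S/V on 0–255) — total function."""
    rule = rule or HueBandRule()
    h, s, v = float(hsv[0]), float(hsv[1]), float(hsv[2])
    if s < rule.min_saturation or v < rule.min_value:
        return BACKGROUND
    dist = _circular_hue_distance(np.array(h), _CLASS_HUES)
    nearest = int(np.argmin(dist))
    if dist[nearest] > rule.half_width_units + _EDGE_EPS:
        return BACKGROUND
    return nearest


def class_mask(image: np.ndarray, class_id: int, rule: HueBandRule | None = None) -> np.ndarray:
    """Boolean H×W mask of pixels classified as ``class_id``."""
    if class_id not in range(len(COLOR_TABLE)):
        raise ValueError(f"unknown class id {class_id!r}; expected 0–{len(COLOR_TABLE) - 1}")
    return classify_image(image, rule) == class_id


def color_table_csv() -> str:
    """The color table as CSV (columns: name, class_id, hue_deg, r, g, b, hex)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["name", "class_id", "hue_deg", "r", "g", "b", "hex"])
    for spec in COLOR_TABLE:
        writer.writerow([spec.name, spec.class_id, spec.hue_deg, *spec.rgb, spec.hex])
    return buf.getvalue()
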