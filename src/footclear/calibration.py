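"""Laser-dot detection and pixel-to-millimetre calibration.

Two parallel laser beams a known physical distance ``D`` apart (164 mm by
default) are projected onto the pedestrian's lower leg.  Their dots appear
in the image as two bright, nearly vertically aligned circular blobs whose
pixel separation ``x`` fixes the scale at the pedestrian's depth:

    k = D / x          (mm per pixel)
    clearance_mm = d * k

Detection thresholds at a high intensity quantile (lighting varies between
recording sites, so an adaptive threshold is used), labels connected
components, and filters candidates by area, circularity (4*pi*A/P**2),
vertical alignment and separation range.  When detection fails the manual
annotation path provides the same calibration from two clicked points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .frames import VideoFrame

logger = logging.getLogger(__name__)

DEFAULT_LASER_DISTANCE_MM = 164.0


@dataclass(frozen=True)
class LaserDetectionConfig:
    """Tunable thresholds for automatic laser-dot detection."""

    brightness_quantile: float = 0.999
    min_area: int = 3
    max_area: int = 400
    min_circularity: float = 0.6
    max_column_offset: float = 12.0
    expected_separation_range: tuple[float, float] = (30.0, 600.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.brightness_quantile < 1.0:
            raise ValueError("brightness_quantile must be in (0, 1)")
        if self.min_area > self.max_area:
            raise ValueError("min_area must not exceed max_area")
        if not 0.0 < self.min_circularity <= 1.0:
            raise ValueError("min_circularity must be in (0, 1]")


@dataclass(frozen=True)
class LaserCalibration:
    """A detected (or annotated) laser dot pair and the derived scale.

    ``upper_dot``/``lower_dot`` are sub-pixel ``(column, row)`` centers,
    ``x`` their pixel separation, ``D`` the physical inter-laser distance
    in mm and ``k = D / x`` the conversion factor in mm/pixel.
    """

    upper_dot: tuple[float, float]
    lower_dot: tuple[float, float]
    x: float
    D: float
    k: float = field(default=None)  # type: ignore[assignment]
    source: str = "automatic"

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("pixel separation x must be positive")
        if self.lower_dot[1] <= self.upper_dot[1]:
            raise ValueError("lower dot must lie below upper dot")
        if self.source not in ("automatic", "manual"):
            raise ValueError("source must be 'automatic' or 'manual'")
        expected = self.D / self.x
        if self.k is None:
            object.__setattr__(self, "k", expected)
        elif not math.isclose(self.k, expected, rel_tol=1e-9):
            raise ValueError("k must equal D / x")

    def to_dict(self) -> dict:
        return {
            "upper": list(self.upper_dot),
            "lower": list(self.lower_dot),
            "x_px": self.x,
            "D_mm": self.D,
            "k_mm_per_px": self.k,
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LaserCalibration":
        return cls(
            upper_dot=tuple(d["upper"]),
            lower_dot=tuple(d["lower"]),
            x=d["x_px"],
            D=d["D_mm"],
            k=d.get("k_mm_per_px"),
            source=d.get("source", "automatic"),
        )


def compute_conversion_factor(x: float, D: float = DEFAULT_LASER_DISTANCE_MM) -> float:
    """Return ``k = D / x`` in mm per pixel.

    ``x`` is the pixel separation of the two laser dot centers and ``D``
    the physical distance between the beams in mm.
    """
    if x <= 0:
        raise ValueError("pixel separation x must be positive")
    if D <= 0:
        raise ValueError("physical distance D must be positive")
    return D / x


def clearance_to_mm(d: float, k: float) -> float:
    """Convert a pixel clearance ``d`` to millimetres via ``d * k``.

    Negative ``d`` is rejected: clearance below the ground line must be
    clipped upstream where the geometry is known.
    """
    if d < 0:
        raise ValueError("pixel clearance d must be non-negative")
    if k <= 0:
        raise ValueError("conversion factor k must be positive")
    return d * k


def manual_laser_annotation(
    upper: tuple[float, float],
    lower: tuple[float, float],
    D: float = DEFAULT_LASER_DISTANCE_MM,
) -> LaserCalibration:
    """Build a calibration from two user-clicked dot centers.

    ``x`` is the Euclidean distance between the points; the lower point
    must lie strictly below the upper one.
    """
    x = math.hypot(lower[0] - upper[0], lower[1] - upper[1])
    if x == 0:
        raise ValueError("zero separation: laser points coincide")
    return LaserCalibration(
        upper_dot=tuple(map(float, upper)),
        lower_dot=tuple(map(float, lower)),
        x=x,
        D=float(D),
        source="manual",
    )


def _intensity_quantile(img: np.ndarray, q: float) -> float:
    """Quantile of the intensity distribution (histogram-based for uint8)."""
    if img.dtype == np.uint8:
        counts = np.bincount(img.ravel(), minlength=256)
        cum = np.cumsum(counts)
        target = q * (cum[-1] - 1)
        return float(np.searchsorted(cum, target, side="right"))
    return float(np.quantile(img, q))


def detect_laser_dots(
    frame: VideoFrame,
    config: LaserDetectionConfig | None = None,
    D: float = DEFAULT_LASER_DISTANCE_MM,
) -> LaserCalibration | None:
    """Locate the projected laser dot pair in one frame.

    Bright pixels (above the configured intensity quantile) are grouped
    into connected blobs; blobs must pass area and circularity filters,
    and a pair must be nearly vertically aligned with separation inside
    the expected range.  Returns ``None`` when no valid pair exists (the
    caller then falls back to manual annotation).
    """
    cfg = config or LaserDetectionConfig()
    img = frame.pixels
    if img.min() == img.max():
        return None
    thr = _intensity_quantile(img, cfg.brightness_quantile)
    binary = img > thr
    if not binary.any():
        return None
    labels, n = ndi.label(binary)
    if n == 0:
        return None
    sizes = np.bincount(labels.ravel())
    keep = (sizes >= cfg.min_area) & (sizes <= cfg.max_area)
    keep[0] = False
    if not keep.any():
        return None
    remap = np.cumsum(keep).astype(np.int32) * keep
    labels = remap[labels]

    candidates = []
    for prop in measure.regionprops(labels, intensity_image=img):
        area = prop.area
        perimeter = prop.perimeter
        circ = 1.0 if perimeter == 0 else 4.0 * math.pi * area / perimeter**2
        if circ < cfg.min_circularity:
            continue
        row, col = prop.centroid_weighted
        candidates.append((float(col), float(row), float(prop.intensity_max)))
    if len(candidates) < 2:
        return None

    lo_sep, hi_sep = cfg.expected_separation_range
    best = None
    for a, b in combinations(candidates, 2):
        upper, lower = (a, b) if a[1] < b[1] else (b, a)
        if lower[1] <= upper[1]:
            continue
        col_off = abs(upper[0] - lower[0])
        if col_off > cfg.max_column_offset:
            continue
        sep = math.hypot(lower[0] - upper[0], lower[1] - upper[1])
        if not lo_sep <= sep <= hi_sep:
            continue
        # Prefer the brightest pair; break ties by tighter vertical alignment.
        key = (-(upper[2] + lower[2]), col_off)
        if best is None or key < best[0]:
            best = (key, upper, lower, sep)
    if best is None:
        return None
    _, upper, lower, sep = best
    return LaserCalibration(
        upper_dot=(upper[0], upper[1]),
        lower_dot=(lower[0], lower[1]),
        x=sep,
        D=float(D),
        source="automatic",
    )
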