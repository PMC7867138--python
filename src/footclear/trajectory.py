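"""Stride segmentation, quintic trajectory fitting and MFC extraction.

The swing foot's per-frame clearance samples form a trajectory whose
shape, over one stride, is well described by a 5th-degree polynomial
(the foot trajectory has three inflection points: toe-off rise, the
mid-swing dip at minimum foot clearance, and the terminal-swing rise
before heel strike).  The minimum foot clearance (MFC) is the local
minimum of that curve inside the stride.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import medfilt

from .calibration import LaserCalibration, clearance_to_mm
from .footwear import FootwearMask, Provenance

logger = logging.getLogger(__name__)

#: Minimum points for a quintic fit: six unknowns plus slack.
MIN_STRIDE_POINTS = 8


class Direction(Enum):
    LEFT_TO_RIGHT = "left_to_right"
    RIGHT_TO_LEFT = "right_to_left"


@dataclass(frozen=True)
class StridePoint:
    """One swing-foot clearance sample."""

    frame_index: int
    clearance_px: float
    centroid_col: float
    provenance: Provenance = Provenance.BACKEND

    def __post_init__(self) -> None:
        if self.clearance_px < 0:
            raise ValueError("clearance must be non-negative")


@dataclass
class Stride:
    """An ordered run of swing samples with an optional quintic fit.

    ``coefficients`` are reported in the raw frame-index basis
    (a0 + a1*f + ... + a5*f**5); the fit itself is performed on abscissae
    affinely mapped to [-1, 1] for conditioning and kept in ``poly``.
    """

    points: list[StridePoint]
    direction: Direction
    poly: Polynomial | None = None
    coefficients: np.ndarray | None = None
    fit_residual_rms: float | None = None

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([p.frame_index for p in self.points])

    @property
    def clearances(self) -> np.ndarray:
        return np.array([p.clearance_px for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class MFCEstimate:
    """A per-stride minimum-foot-clearance estimate.

    ``d_px`` is the clearance at the MFC point in pixels; ``mfc_mm`` is
    ``d_px * k`` when a calibration is available.
    """

    pedestrian_id: str
    stride_index: int
    frame_index: int
    d_px: float
    method: str  # fitted_curve | raw_series
    k_used: float | None = None
    mfc_mm: float | None = None

    def __post_init__(self) -> None:
        if self.d_px < 0:
            raise ValueError("d_px must be non-negative")
        if (self.mfc_mm is None) != (self.k_used is None):
            raise ValueError("mfc_mm and k_used must be given together")
        if self.mfc_mm is not None and abs(self.mfc_mm - self.d_px * self.k_used) > 1e-9:
            raise ValueError("mfc_mm must equal d_px * k_used")


def infer_walking_direction(
    first_detection: FootwearMask, frame_width: int
) -> Direction:
    """Direction from which half of the image the shoe appeared in first."""
    col = first_detection.centroid[0]
    if col < frame_width / 2:
        return Direction.LEFT_TO_RIGHT
    if col == frame_width / 2:
        logger.info("first detection exactly at midline; assuming right_to_left")
    return Direction.RIGHT_TO_LEFT


@dataclass(frozen=True)
class StrideSegmentationConfig:
    """Stride-cutting thresholds, sized to ~60 fps HD footage."""

    stationary_velocity_px: float = 0.5
    median_window: int = 3
    min_bad_run: int = 3
    min_points: int = MIN_STRIDE_POINTS


def segment_strides(
    track: list[StridePoint],
    direction: Direction | None = None,
    config: StrideSegmentationConfig | None = None,
) -> list[Stride]:
    """Split a swing-foot track into strides at motion reversals.

    The per-frame centroid-column velocity is median-smoothed; a reversal
    against the walking direction or near-zero speed (below the
    stationarity threshold) sustained for at least ``min_bad_run`` frames
    ends a stride.  Runs shorter than ``min_points`` are discarded.  With
    no reversal the whole track is a single stride.
    """
    cfg = config or StrideSegmentationConfig()
    if len(track) < 2:
        return []
    cols = np.array([p.centroid_col for p in track])
    if direction is None:
        direction = (
            Direction.LEFT_TO_RIGHT if cols[-1] >= cols[0]
            else Direction.RIGHT_TO_LEFT
        )
    vel = np.diff(cols)
    if vel.size >= cfg.median_window:
        vel = medfilt(vel, cfg.median_window)
    sign = 1.0 if direction is Direction.LEFT_TO_RIGHT else -1.0
    bad = (vel * sign < 0) | (np.abs(vel) < cfg.stationary_velocity_px)

    # Cut at sustained bad runs; shorter glitches stay inside the stride.
    segments: list[tuple[int, int]] = []  # inclusive point ranges
    start = 0
    i = 0
    n = len(track)
    while i < len(bad):
        if bad[i]:
            j = i
            while j < len(bad) and bad[j]:
                j += 1
            if j - i >= cfg.min_bad_run:
                segments.append((start, i))
                start = j
            i = j
        else:
            i += 1
    segments.append((start, n - 1))

    strides = []
    for s, e in segments:
        pts = track[s:e + 1]
        if len(pts) < cfg.min_points:
            logger.info(
                "discarding %d-point segment (frames %s..%s): below the "
                "%d-point minimum for a quintic fit",
                len(pts),
                pts[0].frame_index if pts else "-",
                pts[-1].frame_index if pts else "-",
                cfg.min_points,
            )
            continue
        strides.append(Stride(points=pts, direction=direction))
    return strides


def fit_quintic_trajectory(stride: Stride) -> Stride:
    """Least-squares quintic fit of clearance vs frame index, in place.

    Abscissae are mapped to [-1, 1] for conditioning; coefficients are
    additionally reported in the raw frame-index basis.  The second
    derivative of a quintic is a cubic, so the fitted curve has at most
    three inflection points; this is asserted on every fit.
    """
    if len(stride) < MIN_STRIDE_POINTS:
        raise ValueError(
            f"quintic fit needs >= {MIN_STRIDE_POINTS} points, got {len(stride)}"
        )
    x = stride.frame_indices.astype(float)
    y = stride.clearances
    if np.unique(x).size < 6:
        raise ValueError("insufficient support: fewer than 6 distinct abscissae")
    poly = Polynomial.fit(x, y, 5)
    fitted = poly(x)
    stride.poly = poly
    stride.coefficients = poly.convert().coef
    stride.fit_residual_rms = float(np.sqrt(np.mean((fitted - y) ** 2)))
    assert poly.deriv(2).convert().coef.size <= 4, "inflection count exceeds 3"
    return stride


def count_inflections(stride: Stride) -> int:
    """Real roots of the fitted curve's second derivative inside the stride."""
    if stride.poly is None:
        raise ValueError("stride has no fit")
    x0, x1 = stride.frame_indices[0], stride.frame_indices[-1]
    roots = stride.poly.deriv(2).roots()
    real = roots[np.abs(roots.imag) < 1e-8].real
    return int(np.sum((real > x0) & (real < x1)))


def locate_mfc(
    stride: Stride, method: str = "fitted_curve", pedestrian_id: str = "p0",
    stride_index: int = 0,
) -> MFCEstimate | None:
    """Extract the MFC point of a fitted stride.

    ``fitted_curve`` (default): real roots of the quintic's derivative in
    the open stride interval with positive second derivative are local
    minima; the lowest (clipped at zero) wins and the nearest interior
    integer frame is reported.  ``raw_series``: the smallest interior
    sample not larger than either neighbour.  A stride whose clearance is
    monotone in view (no interior minimum) yields ``None``: its true MFC
    may lie outside the field of view.
    """
    x = stride.frame_indices.astype(float)
    y = stride.clearances
    x0, x1 = x[0], x[-1]

    if method == "fitted_curve":
        if stride.poly is None:
            fit_quintic_trajectory(stride)
        dp = stride.poly.deriv()
        d2p = stride.poly.deriv(2)
        roots = dp.roots()
        real = roots[np.abs(roots.imag) < 1e-8].real
        minima = [r for r in real if x0 < r < x1 and d2p(r) > 0]
        if not minima:
            logger.info(
                "stride %d: no interior local minimum on the fitted curve",
                stride_index,
            )
            return None
        vals = np.maximum(stride.poly(np.array(minima)), 0.0)
        i = int(np.argmin(vals))
        frame = int(np.clip(round(minima[i]), x0 + 1, x1 - 1))
        d = float(vals[i])
    elif method == "raw_series":
        interior = [
            i for i in range(1, len(y) - 1)
            if y[i] <= y[i - 1] and y[i] <= y[i + 1]
        ]
        if not interior:
            logger.info("stride %d: no interior raw-series minimum", stride_index)
            return None
        i = min(interior, key=lambda j: y[j])
        frame = int(x[i])
        d = float(max(y[i], 0.0))
    else:
        raise ValueError(f"unknown MFC method {method!r}")
    return MFCEstimate(
        pedestrian_id=pedestrian_id,
        stride_index=stride_index,
        frame_index=frame,
        d_px=d,
        method=method,
    )


def estimate_pedestrian_mfc(
    strides: list[Stride],
    calibration: LaserCalibration | None = None,
    pedestrian_id: str = "p0",
    method: str = "fitted_curve",
) -> list[MFCEstimate]:
    """Per-stride MFC estimates for one pedestrian, in mm when calibrated.

    Without a calibration the estimates carry pixel values only; the
    caller is expected to flag the output as incomplete.
    """
    estimates = []
    for i, stride in enumerate(strides):
        if stride.poly is None and method == "fitted_curve":
            fit_quintic_trajectory(stride)
        est = locate_mfc(stride, method=method, pedestrian_id=pedestrian_id,
                         stride_index=i)
        if est is None:
            continue
        if calibration is not None:
            est = MFCEstimate(
                pedestrian_id=est.pedestrian_id,
                stride_index=est.stride_index,
                frame_index=est.frame_index,
                d_px=est.d_px,
                method=est.method,
                k_used=calibration.k,
                mfc_mm=clearance_to_mm(est.d_px, calibration.k),
            )
        estimates.append(est)
    return estimates


def summarize_estimates(estimates: list[MFCEstimate]) -> dict:
    """Per-pedestrian summary: per-stride values plus minimum and mean."""
    if not estimates:
        return {"n_strides": 0}
    px = [e.d_px for e in estimates]
    out = {
        "n_strides": len(estimates),
        "mfc_px_per_stride": px,
        "mfc_px_min": float(min(px)),
        "mfc_px_mean": float(np.mean(px)),
    }
    mm = [e.mfc_mm for e in estimates if e.mfc_mm is not None]
    if mm:
        out.update(
            mfc_mm_per_stride=mm,
            mfc_mm_min=float(min(mm)),
            mfc_mm_mean=float(np.mean(mm)),
        )
    return out
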