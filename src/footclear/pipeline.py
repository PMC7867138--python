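"""End-to-end analysis: frames in, per-stride MFC estimates out.

Orchestrates segmentation, the frame-state machine, swing/stance
labeling, occlusion recovery, laser calibration, stride segmentation,
quintic fitting and MFC extraction.  The two manual steps of a field
deployment — cropping the clip to one pedestrian and clicking the ground
plane — are inputs here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    LaserCalibration,
    LaserDetectionConfig,
    detect_laser_dots,
)
from .footwear import (
    FootwearMask,
    FrameState,
    MaskRole,
    OcclusionSearchConfig,
    Provenance,
    SegmentationBackend,
    assign_swing_stance,
    classify_frame_state,
    lowest_point_clearance,
    recover_occluded_swing,
    segment_footwear,
)
from .frames import GroundPlane, VideoFrame
from .trajectory import (
    Direction,
    StridePoint,
    StrideSegmentationConfig,
    estimate_pedestrian_mfc,
    infer_walking_direction,
    segment_strides,
    summarize_estimates,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Aggregated knobs for one analysis run."""

    laser: LaserDetectionConfig = field(default_factory=LaserDetectionConfig)
    occlusion: OcclusionSearchConfig = field(default_factory=OcclusionSearchConfig)
    strides: StrideSegmentationConfig = field(default_factory=StrideSegmentationConfig)
    laser_distance_mm: float = 164.0
    mfc_method: str = "fitted_curve"
    # Stop scanning for laser dots once the contiguous dot window has
    # clearly passed: this many consecutive misses after this many hits.
    laser_min_hits: int = 3
    laser_miss_patience: int = 2


@dataclass
class AnalysisResult:
    """Everything one run produces."""

    pedestrian_id: str
    estimates: list
    strides: list
    calibration: LaserCalibration | None
    direction: Direction | None
    states: list[FrameState]
    track: list[StridePoint]
    flags: list[str]
    summary: dict

    @property
    def results_table(self) -> pd.DataFrame:
        rows = []
        for est in self.estimates:
            stride = self.strides[est.stride_index]
            rows.append(
                {
                    "pedestrian_id": est.pedestrian_id,
                    "stride_index": est.stride_index,
                    "mfc_frame": est.frame_index,
                    "d_px": est.d_px,
                    "k_mm_per_px": est.k_used,
                    "mfc_mm": est.mfc_mm,
                    "method": est.method,
                    "fit_residual_rms": stride.fit_residual_rms,
                    "n_points": len(stride),
                    "flags": ";".join(self.flags),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "pedestrian_id", "stride_index", "mfc_frame", "d_px",
                "k_mm_per_px", "mfc_mm", "method", "fit_residual_rms",
                "n_points", "flags",
            ],
        )

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.results_table.to_csv(out_dir / "results.csv", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=1, sort_keys=True)


def _consistent_members(
    run: list[LaserCalibration], min_hits: int, rel_tol: float = 0.05
) -> list[LaserCalibration] | None:
    """Members of a detection run whose separation agrees with its median.

    The laser geometry is fixed, so genuine detections in one window
    share the same pixel separation to well under a percent; sporadic
    false pairs (bright noise clusters) do not.
    """
    xs = sorted(c.x for c in run)
    med = xs[len(xs) // 2]
    members = [c for c in run if abs(c.x - med) / med <= rel_tol]
    return members if len(members) >= min_hits else None


def scan_for_calibration(
    frames: list[VideoFrame],
    config: PipelineConfig,
) -> tuple[LaserCalibration | None, int]:
    """Find the laser dot window across the sequence.

    The dots land on the leg for one contiguous run of frames.  The scan
    groups per-frame detections into runs (a run ends after
    ``laser_miss_patience`` consecutive misses) and accepts the first run
    with at least ``laser_min_hits`` mutually consistent detections,
    stopping early at that point.  The detection with the median pixel
    separation within the accepted run is returned (robust to
    edge-of-window partial dots).
    """
    runs: list[list[LaserCalibration]] = []
    current: list[LaserCalibration] = []
    misses = 0
    accepted: list[LaserCalibration] | None = None
    for frame in frames:
        cal = detect_laser_dots(frame, config.laser, D=config.laser_distance_mm)
        if cal is not None:
            current.append(cal)
            misses = 0
            continue
        if not current:
            continue
        misses += 1
        if misses >= config.laser_miss_patience:
            runs.append(current)
            accepted = _consistent_members(current, config.laser_min_hits)
            current = []
            misses = 0
            if accepted is not None:
                break
    if current:
        runs.append(current)
    if accepted is None:
        for run in runs:
            accepted = _consistent_members(run, config.laser_min_hits)
            if accepted is not None:
                break
    if accepted is None:
        # Fall back to whatever was seen (possibly a single frame).
        if not runs:
            return None, 0
        accepted = max(runs, key=len)
    xs = np.array([c.x for c in accepted])
    median_idx = int(np.argsort(xs)[len(xs) // 2])
    return accepted[median_idx], len(accepted)


def analyze_video(
    frames: list[VideoFrame],
    ground: GroundPlane,
    backend: SegmentationBackend,
    config: PipelineConfig | None = None,
    manual_calibration: LaserCalibration | None = None,
    pedestrian_id: str = "p0",
    out_dir: str | Path | None = None,
) -> AnalysisResult:
    """Run the full offline analysis on one pedestrian's clip.

    Returns per-stride MFC estimates in pixels, and in millimetres when a
    calibration was found automatically or supplied manually; without any
    calibration the run is flagged ``incomplete_calibration``.
    """
    cfg = config or PipelineConfig()
    if not frames:
        raise ValueError("no frames to analyze")
    flags: list[str] = []

    state = FrameState.NO_ONE
    states: list[FrameState] = []
    track: list[StridePoint] = []
    prev_swing: FootwearMask | None = None
    prev_stance: FootwearMask | None = None
    prev_centroids: list[tuple[float, float]] | None = None
    first_detection: FootwearMask | None = None
    had_two = False

    first_swing: FootwearMask | None = None
    for frame in frames:
        masks = segment_footwear(frame, backend)
        if masks and first_detection is None:
            first_detection = max(masks, key=lambda m: m.area)
        state = classify_frame_state(state, len(masks), had_two)
        states.append(state)
        if state is FrameState.FULLY_VISIBLE:
            had_two = True
            swing, stance = assign_swing_stance(masks, ground, prev_centroids)
            if swing.role is MaskRole.SWING and first_swing is None:
                first_swing = swing
            if swing.role is MaskRole.SWING:
                d, _ = lowest_point_clearance(swing, ground)
                track.append(
                    StridePoint(
                        frame_index=frame.index,
                        clearance_px=d,
                        centroid_col=swing.centroid[0],
                        provenance=swing.provenance,
                    )
                )
                prev_swing = swing
            if stance.role is MaskRole.STANCE:
                prev_stance = stance
            prev_centroids = [m.centroid for m in masks]
        elif state is FrameState.OVERLAP and prev_swing is not None:
            recovered = recover_occluded_swing(
                prev_swing, frame, cfg.occlusion, stance_exclusion=prev_stance
            )
            d, _ = lowest_point_clearance(recovered, ground)
            track.append(
                StridePoint(
                    frame_index=frame.index,
                    clearance_px=d,
                    centroid_col=recovered.centroid[0],
                    provenance=Provenance.OCCLUSION_RECOVERY,
                )
            )
            prev_swing = recovered
            prev_centroids = [recovered.centroid]
        else:
            prev_centroids = [m.centroid for m in masks] if masks else None

    if first_detection is None:
        flags.append("no_pedestrian")
        result = AnalysisResult(
            pedestrian_id=pedestrian_id, estimates=[], strides=[],
            calibration=None, direction=None, states=states, track=[],
            flags=flags, summary={"flags": flags, "n_strides": 0},
        )
        if out_dir is not None:
            result.write(out_dir)
        return result

    # Prefer the first swing-labeled mask: when both feet enter the view
    # in the same frame, the stationary stance foot says nothing about
    # travel direction.
    direction = infer_walking_direction(
        first_swing if first_swing is not None else first_detection,
        frames[0].width,
    )

    calibration = manual_calibration
    n_laser_frames = 0
    if calibration is None:
        calibration, n_laser_frames = scan_for_calibration(frames, cfg)
    if calibration is None:
        flags.append("incomplete_calibration")

    strides = segment_strides(track, direction, cfg.strides)
    estimates = estimate_pedestrian_mfc(
        strides, calibration, pedestrian_id=pedestrian_id, method=cfg.mfc_method
    )
    if not estimates:
        flags.append("no_mfc_estimate")

    summary = {
        "pedestrian_id": pedestrian_id,
        "direction": direction.value,
        "n_frames": len(frames),
        "n_track_points": len(track),
        "n_strides": len(strides),
        "n_laser_detections": n_laser_frames,
        "calibration": calibration.to_dict() if calibration else None,
        "flags": flags,
        **summarize_estimates(estimates),
    }
    result = AnalysisResult(
        pedestrian_id=pedestrian_id,
        estimates=estimates,
        strides=strides,
        calibration=calibration,
        direction=direction,
        states=states,
        track=track,
        flags=flags,
        summary=summary,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
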