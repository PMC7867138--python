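"""Footwear masks, frame-state tracking and occlusion recovery.

The segmentation backend (a pluggable component; a trained instance-
segmentation network in a production deployment, an oracle or a classical
background-subtraction detector here) yields 0-2 unlabeled masks per
frame.  A four-state machine tracks whether nobody is in view, a person
has just entered, both feet are visible, or the two feet overlap in the
sagittal plane.  During overlap the swing foot is re-localized by matching
the previous swing mask's bottom edge against the current frame's edge map
over a grid of rotations and translations (chamfer scoring on a distance
transform).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from enum import Enum
from functools import cached_property
from pathlib import Path
from typing import Protocol

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, filters

from .frames import GroundPlane, VideoFrame

logger = logging.getLogger(__name__)


class FrameState(Enum):
    NO_ONE = "no_one"
    BEGIN = "begin"
    FULLY_VISIBLE = "fully_visible"
    OVERLAP = "overlap"


class MaskRole(Enum):
    SWING = "swing"
    STANCE = "stance"
    UNKNOWN = "unknown"


class Provenance(Enum):
    BACKEND = "backend"
    OCCLUSION_RECOVERY = "occlusion_recovery"
    ORACLE = "oracle"


@dataclass
class FootwearMask:
    """A binary instance mask for one shoe in one frame.

    ``bottom_edge`` holds, for every occupied column, the maximal (lowest)
    occupied row in that column as ``(column, row)`` pairs; it is the
    profile all clearance measurements are taken from.
    """

    frame_index: int
    mask: np.ndarray
    role: MaskRole = MaskRole.UNKNOWN
    provenance: Provenance = Provenance.BACKEND
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("mask must be a non-empty 2-D binary grid")

    @cached_property
    def bottom_edge(self) -> np.ndarray:
        """(n, 2) array of (column, lowest occupied row) per column."""
        cols = np.flatnonzero(self.mask.any(axis=0))
        h = self.mask.shape[0]
        rows = h - 1 - np.argmax(self.mask[::-1, cols], axis=0)
        return np.stack([cols, rows], axis=1)

    @cached_property
    def bbox(self) -> tuple[int, int, int, int]:
        """Tight bounding box (min_col, min_row, max_col, max_row)."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return (int(cols[0]), int(rows[0]), int(cols[-1]), int(rows[-1]))

    @cached_property
    def centroid(self) -> tuple[float, float]:
        """(column, row) centroid of the mask pixels."""
        rows, cols = np.nonzero(self.mask)
        return float(cols.mean()), float(rows.mean())

    @property
    def area(self) -> int:
        return int(self.mask.sum())


# Normative frame-state transition table: (previous state, mask count) ->
# next state.  FULLY_VISIBLE dropping to one mask raises the occlusion
# flag; two masks always resolve to FULLY_VISIBLE.
_TRANSITIONS: dict[tuple[FrameState, int], FrameState] = {
    (FrameState.NO_ONE, 0): FrameState.NO_ONE,
    (FrameState.NO_ONE, 1): FrameState.BEGIN,
    (FrameState.NO_ONE, 2): FrameState.FULLY_VISIBLE,
    (FrameState.BEGIN, 0): FrameState.NO_ONE,
    (FrameState.BEGIN, 1): FrameState.BEGIN,
    (FrameState.BEGIN, 2): FrameState.FULLY_VISIBLE,
    (FrameState.FULLY_VISIBLE, 0): FrameState.NO_ONE,
    (FrameState.FULLY_VISIBLE, 1): FrameState.OVERLAP,
    (FrameState.FULLY_VISIBLE, 2): FrameState.FULLY_VISIBLE,
    (FrameState.OVERLAP, 0): FrameState.NO_ONE,
    (FrameState.OVERLAP, 1): FrameState.OVERLAP,
    (FrameState.OVERLAP, 2): FrameState.FULLY_VISIBLE,
}


def classify_frame_state(
    previous: FrameState, n_masks: int, had_two_recently: bool = False
) -> FrameState:
    """Advance the frame-state machine given the detected mask count.

    The transition table is total and deterministic over the 12
    (state, count) pairs with count in {0, 1, 2}.  More than two masks
    would imply a second pedestrian, which is out of scope: the previous
    state is kept and a warning logged.
    """
    if n_masks > 2:
        logger.warning(
            "frame reported %d masks (had_two_recently=%s); keeping state %s",
            n_masks, had_two_recently, previous.value,
        )
        return previous
    if n_masks < 0:
        raise ValueError("mask count cannot be negative")
    return _TRANSITIONS[(previous, n_masks)]


def lowest_point_clearance(
    mask: FootwearMask, ground: GroundPlane
) -> tuple[float, tuple[int, int]]:
    """Vertical pixel distance from the mask's lowest point to the ground.

    For every bottom-edge point the distance is ``ground_row(column) -
    row``; the minimum and its achieving point are returned.  Negative
    distances (mask rendered below the ground line) are clipped to zero
    with a warning.
    """
    edge = mask.bottom_edge
    dist = ground.row_at(edge[:, 0]) - edge[:, 1]
    i = int(np.argmin(dist))
    d = float(dist[i])
    if d < 0:
        logger.warning(
            "frame %d: mask extends %.1f px below the ground line; clipping",
            mask.frame_index, -d,
        )
        d = 0.0
    return d, (int(edge[i, 0]), int(edge[i, 1]))


def assign_swing_stance(
    masks: list[FootwearMask],
    ground: GroundPlane,
    previous_centroids: list[tuple[float, float]] | None = None,
) -> tuple[FootwearMask, FootwearMask]:
    """Label two masks as (swing, stance) by distance from the walkway.

    The mask whose lowest point is further above the ground line is the
    swing foot.  Near-ties (< 0.5 px) are resolved by centroid
    displacement since the previous frame — the moving foot is swinging;
    with no history both remain UNKNOWN.
    """
    if len(masks) != 2:
        raise ValueError("swing/stance assignment requires exactly two masks")
    a, b = masks
    da, _ = lowest_point_clearance(a, ground)
    db, _ = lowest_point_clearance(b, ground)
    if abs(da - db) >= 0.5:
        swing, stance = (a, b) if da > db else (b, a)
    elif previous_centroids:
        def displacement(m: FootwearMask) -> float:
            c = m.centroid
            return min(
                math.hypot(c[0] - pc[0], c[1] - pc[1])
                for pc in previous_centroids
            )
        swing, stance = (a, b) if displacement(a) > displacement(b) else (b, a)
    else:
        a.role = MaskRole.UNKNOWN
        b.role = MaskRole.UNKNOWN
        return a, b
    swing.role = MaskRole.SWING
    stance.role = MaskRole.STANCE
    return swing, stance


@dataclass(frozen=True)
class OcclusionSearchConfig:
    """Search grid for re-localizing the swing foot during overlap.

    The previous swing mask's bottom edge is rotated through
    ``[-rotation_range_deg, +rotation_range_deg]`` in steps of
    ``rotation_step_deg`` about its centroid and translated over the
    window, and each placement is scored by the mean distance-transform
    value of the frame's edge map at the transformed points.
    """

    rotation_range_deg: float = 20.0
    rotation_step_deg: float = 5.0
    translation_window_px: tuple[int, int] = (40, 15)  # (columns, rows)
    edge_gradient_threshold: float | None = None  # None -> Otsu
    # Placements whose mean distance to the remembered stance foot's
    # bottom edge falls below this are rejected: both shoes look alike,
    # and the stationary foot is a perfect decoy for the template.
    stance_veto_px: float = 1.5

    def __post_init__(self) -> None:
        if self.rotation_step_deg <= 0 or self.rotation_range_deg < 0:
            raise ValueError("rotation grid must be positive")
        ratio = self.rotation_range_deg / self.rotation_step_deg
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("rotation_step_deg must divide rotation_range_deg")
        if min(self.translation_window_px) < 0:
            raise ValueError("translation window must be non-negative")

    @property
    def rotations_deg(self) -> np.ndarray:
        n = int(round(self.rotation_range_deg / self.rotation_step_deg))
        return np.arange(-n, n + 1) * self.rotation_step_deg


def edge_distance_map(
    frame: VideoFrame, config: OcclusionSearchConfig | None = None
) -> np.ndarray:
    """Distance transform of the frame's gradient-magnitude edge map.

    The gradient magnitude (Sobel) is binarized at the configured
    threshold (Otsu by default) and the Euclidean distance to the nearest
    edge pixel is returned for every pixel; chamfer scores are mean
    lookups into this map.
    """
    cfg = config or OcclusionSearchConfig()
    grad = filters.sobel(frame.pixels.astype(np.float32))
    thr = cfg.edge_gradient_threshold
    if thr is None:
        thr = filters.threshold_otsu(grad)
    edges = grad > thr
    if not edges.any():
        return np.full(frame.pixels.shape, np.inf)
    return ndi.distance_transform_edt(~edges)


N_ORIENTATION_BINS = 8  # bins of pi/8 over undirected edge orientation


def oriented_edge_distances(
    image: np.ndarray, threshold: float
) -> np.ndarray:
    """Per-orientation distance transforms of an image's edge map.

    Edge pixels are binned by their undirected tangent orientation
    (gradient direction + 90 degrees, modulo pi) into
    :data:`N_ORIENTATION_BINS` bins; the map for bin ``k`` measures the
    distance to the nearest edge pixel whose orientation falls in bins
    ``{k-1, k, k+1}`` (a ~34 degree tolerance).  Matching template points
    only against compatibly oriented edges stops the sliding-match bias
    where a shoe's toe profile latches onto the long horizontal sole
    edge.  Returns an ``(N_ORIENTATION_BINS + 1, H, W)`` stack whose last
    slice is the unoriented distance map, used for wildcard template
    points.
    """
    img = image.astype(np.float32)
    gy = filters.sobel_h(img)
    gx = filters.sobel_v(img)
    grad = np.hypot(gy, gx)
    edges = grad > threshold
    stack = np.empty((N_ORIENTATION_BINS + 1,) + img.shape)
    if not edges.any():
        stack[:] = np.inf
        return stack
    tangent = np.mod(np.arctan2(gy, gx) + np.pi / 2, np.pi)
    bins = np.floor(tangent / (np.pi / N_ORIENTATION_BINS)).astype(int)
    bins = np.clip(bins, 0, N_ORIENTATION_BINS - 1)
    fallback = ndi.distance_transform_edt(~edges)
    for k in range(N_ORIENTATION_BINS):
        allowed = (
            (bins == k)
            | (bins == (k - 1) % N_ORIENTATION_BINS)
            | (bins == (k + 1) % N_ORIENTATION_BINS)
        ) & edges
        if allowed.any():
            stack[k] = ndi.distance_transform_edt(~allowed)
        else:
            stack[k] = fallback
    stack[N_ORIENTATION_BINS] = fallback
    return stack


def template_orientation_bins(points: np.ndarray, rotation_deg: float = 0.0) -> np.ndarray:
    """Orientation bin of each bottom-edge point's local tangent.

    Tangents come from central differences along the (column-sorted)
    point sequence, rotated by ``rotation_deg``.  The two endpoints sit
    where the bottom edge meets the silhouette's side walls and their
    one-sided tangents are unreliable, so they get the wildcard bin
    (:data:`N_ORIENTATION_BINS`) and match edges of any orientation.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    prev_idx = np.maximum(np.arange(n) - 1, 0)
    next_idx = np.minimum(np.arange(n) + 1, n - 1)
    d = pts[next_idx] - pts[prev_idx]
    ang = np.arctan2(d[:, 1], d[:, 0]) + math.radians(rotation_deg)
    ang = np.mod(ang, np.pi)
    bins = np.floor(ang / (np.pi / N_ORIENTATION_BINS)).astype(int)
    bins = np.clip(bins, 0, N_ORIENTATION_BINS - 1)
    if n:
        bins[0] = N_ORIENTATION_BINS
        bins[-1] = N_ORIENTATION_BINS
    return bins


def rotate_points(
    points: np.ndarray, angle_deg: float, center: np.ndarray
) -> np.ndarray:
    """Rotate (column, row) points about ``center`` by ``angle_deg``."""
    theta = math.radians(angle_deg)
    ca, sa = math.cos(theta), math.sin(theta)
    rel = points - center
    return np.stack(
        [ca * rel[:, 0] - sa * rel[:, 1] + center[0],
         sa * rel[:, 0] + ca * rel[:, 1] + center[1]],
        axis=1,
    )


def search_occlusion_transform(
    prev_swing: FootwearMask,
    frame: VideoFrame,
    config: OcclusionSearchConfig | None = None,
    stance_exclusion: FootwearMask | None = None,
) -> tuple[float, int, int, float] | None:
    """Best rigid placement of the previous swing foot in an overlap frame.

    Every rotation of the previous swing mask's bottom-edge point set
    about its centroid, combined with every integer translation in the
    window, is scored by the mean edge-distance at the transformed points
    (lower is better; zero means the template lies exactly on edges).
    Ties prefer the smaller translation magnitude, then the smaller
    absolute rotation.  Returns ``(rotation_deg, dcol, drow, score)``, or
    ``None`` when the search window contains no edges to match.

    ``stance_exclusion``: the remembered stance mask.  Both shoes look
    alike, so the stationary stance foot's outline is a perfect decoy for
    the template; placements that would simply re-detect it (mean
    distance to its bottom edge below ``stance_veto_px``) are skipped.
    """
    cfg = config or OcclusionSearchConfig()
    pts = prev_swing.bottom_edge.astype(float)
    center = pts.mean(axis=0)

    # The search is local: compute the edge map on a padded crop around
    # the previous mask rather than the whole frame.
    win_c, win_r = cfg.translation_window_px
    min_c, min_r, max_c, max_r = prev_swing.bbox
    margin = 40
    fh, fw = frame.pixels.shape
    cr0 = max(0, min_r - win_r - margin)
    cc0 = max(0, min_c - win_c - margin)
    crop = frame.pixels[
        cr0: min(fh, max_r + win_r + margin + 1),
        cc0: min(fw, max_c + win_c + margin + 1),
    ]
    grad = filters.sobel(crop.astype(np.float32))
    thr = cfg.edge_gradient_threshold
    if thr is None:
        thr = filters.threshold_otsu(grad) if grad.max() > 0 else np.inf
    edges = grad > thr
    h, w = edges.shape
    region = edges[
        max(0, min_r - win_r - cr0): max_r + win_r + 1 - cr0,
        max(0, min_c - win_c - cc0): max_c + win_c + 1 - cc0,
    ]
    if region.size == 0 or not region.any():
        return None

    dt_stack = oriented_edge_distances(crop, thr)

    dt_veto = None
    if stance_exclusion is not None:
        stance_pts = stance_exclusion.bottom_edge
        sr = stance_pts[:, 1] - cr0
        sc = stance_pts[:, 0] - cc0
        inside = (sr >= 0) & (sr < h) & (sc >= 0) & (sc < w)
        if inside.any():
            stance_raster = np.ones((h, w), dtype=bool)
            stance_raster[sr[inside], sc[inside]] = False
            dt_veto = ndi.distance_transform_edt(stance_raster)

    dcs = np.arange(-win_c, win_c + 1)
    drs = np.arange(-win_r, win_r + 1)
    best = None       # (score, trans_mag2, abs_rot, rot, dc, dr)
    best_any = None   # fallback ignoring the stance veto
    for rot in cfg.rotations_deg:
        rp = rotate_points(pts, rot, center)
        base_c = np.rint(rp[:, 0]).astype(int) - cc0
        base_r = np.rint(rp[:, 1]).astype(int) - cr0
        bins = template_orientation_bins(pts, rot)
        cc = np.clip(base_c[None, :] + dcs[:, None], 0, w - 1)  # (Nc, P)
        scores_c = np.empty((drs.size, dcs.size))
        veto_c = (
            np.empty((drs.size, dcs.size)) if dt_veto is not None else None
        )
        for j, dr in enumerate(drs):
            rr = np.clip(base_r + dr, 0, h - 1)  # (P,)
            scores_c[j] = dt_stack[bins[None, :], rr[None, :], cc].mean(axis=1)
            if dt_veto is not None:
                veto_c[j] = dt_veto[rr[None, :], cc].mean(axis=1)

        def fold(scores, current):
            j, i = np.unravel_index(np.argmin(scores), scores.shape)
            min_score = scores[j, i]
            if not np.isfinite(min_score):
                return current
            tie_j, tie_i = np.nonzero(scores == min_score)
            for jj, ii in zip(tie_j, tie_i):
                dc, dr = int(dcs[ii]), int(drs[jj])
                cand = (float(min_score), dc * dc + dr * dr, abs(float(rot)),
                        float(rot), dc, dr)
                if current is None or cand[:3] < current[:3]:
                    current = cand
            return current

        best_any = fold(scores_c, best_any)
        if veto_c is not None:
            scores_c = np.where(veto_c < cfg.stance_veto_px, np.inf, scores_c)
        best = fold(scores_c, best)
    if best is None:  # every placement looked like the stance foot
        best = best_any
    return best[3], best[4], best[5], best[0]


def recover_occluded_swing(
    prev_swing: FootwearMask,
    frame: VideoFrame,
    config: OcclusionSearchConfig | None = None,
    stance_exclusion: FootwearMask | None = None,
) -> FootwearMask:
    """Re-localize the swing foot during overlap via the chamfer search.

    The returned mask is the previous swing mask under the winning rigid
    transform found by :func:`search_occlusion_transform`, with
    provenance ``occlusion_recovery``.  With no edges to match (or a
    transform that would leave the frame) the previous mask is kept and
    flagged low-confidence.
    """
    found = search_occlusion_transform(prev_swing, frame, config,
                                       stance_exclusion)
    if found is None:
        logger.warning(
            "frame %d: no edges in occlusion search window; keeping previous "
            "swing mask", frame.index,
        )
        return FootwearMask(
            frame_index=frame.index,
            mask=prev_swing.mask.copy(),
            role=MaskRole.SWING,
            provenance=Provenance.OCCLUSION_RECOVERY,
            low_confidence=True,
        )
    rot, dc, dr, _ = found
    center = prev_swing.bottom_edge.astype(float).mean(axis=0)
    new_mask = _transform_mask(prev_swing.mask, rot, center, dc, dr)
    if not new_mask.any():
        logger.warning("occlusion recovery pushed mask out of frame; keeping previous")
        new_mask = prev_swing.mask.copy()
        low_conf = True
    else:
        low_conf = False
    return FootwearMask(
        frame_index=frame.index,
        mask=new_mask,
        role=MaskRole.SWING,
        provenance=Provenance.OCCLUSION_RECOVERY,
        low_confidence=low_conf,
    )


def _transform_mask(
    mask: np.ndarray, angle_deg: float, center_cr: np.ndarray, dc: int, dr: int
) -> np.ndarray:
    """Apply the rigid transform (rotation about center, then translation)."""
    theta = math.radians(angle_deg)
    ca, sa = math.cos(theta), math.sin(theta)
    # Forward map on (row, col) is [[ca, sa], [-sa, ca]]; the inverse
    # (what affine_transform wants) is its transpose.
    m_inv = np.array([[ca, -sa], [sa, ca]])
    center_rc = np.array([center_cr[1], center_cr[0]])
    shift_rc = np.array([dr, dc], dtype=float)
    offset = center_rc - m_inv @ (center_rc + shift_rc)
    out = ndi.affine_transform(
        mask.astype(np.uint8), m_inv, offset=offset, order=0, mode="constant"
    )
    return out.astype(bool)


class SegmentationBackend(Protocol):
    """Contract for mask producers: one frame in, 0-2 candidate masks out.

    Adapters for trained instance-segmentation detectors implement this
    same interface (a detection confidence cutoff around 0.7 is typical);
    the package ships an oracle backend (synthetic ground truth) and a
    classical background-subtraction backend for fixtures.
    """

    name: str

    def detect(self, frame: VideoFrame) -> list[FootwearMask]: ...


class OracleBackend:
    """Backend returning the synthetic scene's true masks verbatim."""

    name = "oracle"

    def __init__(self, truth) -> None:
        self._truth = truth

    def detect(self, frame: VideoFrame) -> list[FootwearMask]:
        masks = []
        for m in self._truth.masks_for(frame.index):
            masks.append(
                FootwearMask(
                    frame_index=frame.index,
                    mask=m.copy(),
                    provenance=Provenance.ORACLE,
                )
            )
        return masks


class ClassicalBackend:
    """Background-subtraction detector for synthetic fixtures.

    Subtracts a cached empty-scene reference frame, thresholds the
    absolute difference, labels connected components and keeps the (at
    most two) largest above a minimum area.  Deterministic and
    dependency-light; adequate for rendered scenes, not real footage.
    """

    name = "classic"

    def __init__(
        self,
        background: np.ndarray | VideoFrame,
        diff_threshold: float = 30.0,
        min_area: int = 500,
    ) -> None:
        bg = background.pixels if isinstance(background, VideoFrame) else background
        self.background = np.asarray(bg, dtype=np.int16)
        self.diff_threshold = diff_threshold
        self.min_area = min_area

    def detect(self, frame: VideoFrame) -> list[FootwearMask]:
        diff = np.abs(frame.pixels.astype(np.int16) - self.background)
        binary = diff > self.diff_threshold
        # Label only the row slab containing changed pixels.
        row_any = binary.any(axis=1)
        rows = np.flatnonzero(row_any)
        if rows.size == 0:
            return []
        r0, r1 = rows[0], rows[-1] + 1
        labels, n = ndi.label(binary[r0:r1])
        if n == 0:
            return []
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        order = np.argsort(sizes)[::-1]
        masks = []
        for lab in order[:2]:
            if sizes[lab] < self.min_area:
                break
            full = np.zeros(binary.shape, dtype=bool)
            full[r0:r1] = labels == lab
            masks.append(FootwearMask(frame_index=frame.index, mask=full))
        return masks


class ExternalMaskBackend:
    """Backend reading pre-computed per-frame masks from disk.

    Accepts a directory of ``frame_{index}_mask_{i}.png`` binary images
    (0/255) or a COCO-style JSON with polygon annotations for category
    ``footwear``.
    """

    name = "masks"

    def __init__(self, source: str | Path, frame_shape: tuple[int, int] | None = None):
        self.source = Path(source)
        self.frame_shape = frame_shape
        self._index: dict[int, list] = {}
        if self.source.is_file() and self.source.suffix == ".json":
            self._load_coco(self.source)
        elif self.source.is_dir():
            for p in sorted(self.source.glob("frame_*_mask_*.png")):
                parts = p.stem.split("_")
                idx = int(parts[1])
                self._index.setdefault(idx, []).append(p)
        else:
            raise FileNotFoundError(self.source)

    def _load_coco(self, path: Path) -> None:
        with open(path) as fh:
            doc = json.load(fh)
        cat_ids = {
            c["id"] for c in doc.get("categories", [])
            if c.get("name") == "footwear"
        }
        images = {im["id"]: im for im in doc.get("images", [])}
        for ann in doc.get("annotations", []):
            if cat_ids and ann.get("category_id") not in cat_ids:
                continue
            im = images[ann["image_id"]]
            idx = im.get("frame_index", im["id"])
            self._index.setdefault(idx, []).append(
                (ann["segmentation"], (im["height"], im["width"]))
            )

    def detect(self, frame: VideoFrame) -> list[FootwearMask]:
        import imageio.v3 as iio

        out = []
        for item in self._index.get(frame.index, []):
            if isinstance(item, Path):
                arr = iio.imread(item)
                mask = np.asarray(arr) > 127
            else:
                polys, shape = item
                mask = np.zeros(shape, dtype=bool)
                for poly in polys:
                    xy = np.asarray(poly, dtype=float).reshape(-1, 2)
                    rr, cc = draw.polygon(xy[:, 1], xy[:, 0], shape=shape)
                    mask[rr, cc] = True
            if mask.any():
                out.append(FootwearMask(frame_index=frame.index, mask=mask))
        return out[:2]


def segment_footwear(
    frame: VideoFrame, backend: SegmentationBackend
) -> list[FootwearMask]:
    """Run the backend on one frame, tolerating backend failure.

    A failing backend is logged and treated as zero detections so the
    state machine can carry on.
    """
    try:
        return backend.detect(frame)
    except Exception:
        logger.warning(
            "segmentation backend %r failed on frame %d; treating as empty",
            getattr(backend, "name", backend), frame.index, exc_info=True,
        )
        return []
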