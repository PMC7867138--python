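"""Mask geometry, the frame-state machine, and occlusion recovery."""

import itertools

import numpy as np
import pytest

from footclear import (
    ClassicalBackend,
    FootwearMask,
    FrameState,
    GroundPlane,
    MaskRole,
    OcclusionSearchConfig,
    OracleBackend,
    Provenance,
    VideoFrame,
    assign_swing_stance,
    classify_frame_state,
    lowest_point_clearance,
    mask_iou,
    recover_occluded_swing,
    search_occlusion_transform,
    segment_footwear,
)
from footclear.footwear import _transform_mask, rotate_points

from conftest import small_spec

FLAT_GROUND = GroundPlane((0.0, 230.0), (479.0, 230.0))


def _blob(shape, r0, r1, c0, c1):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


class TestFootwearMask:
    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            FootwearMask(0, np.zeros((5, 5), dtype=bool))

    def test_bbox_is_tight(self):
        m = FootwearMask(0, _blob((20, 30), 5, 10, 8, 20))
        assert m.bbox == (8, 5, 19, 9)

    def test_bottom_edge_matches_bruteforce(self, rng):
        # Oracle: per-column scan for the maximal occupied row.
        for _ in range(20):
            mask = rng.random((15, 20)) < 0.3
            if not mask.any():
                mask[7, 9] = True
            fm = FootwearMask(0, mask)
            edge = {c: r for c, r in fm.bottom_edge}
            expected = {}
            for c in range(mask.shape[1]):
                rows = [r for r in range(mask.shape[0]) if mask[r, c]]
                if rows:
                    expected[c] = max(rows)
            assert edge == expected
            for c, r in fm.bottom_edge:
                assert mask[r, c]


class TestStateMachine:
    # Independent restatement of the normative transition table.
    TABLE = {
        ("no_one", 0): "no_one", ("no_one", 1): "begin",
        ("no_one", 2): "fully_visible",
        ("begin", 0): "no_one", ("begin", 1): "begin",
        ("begin", 2): "fully_visible",
        ("fully_visible", 0): "no_one", ("fully_visible", 1): "overlap",
        ("fully_visible", 2): "fully_visible",
        ("overlap", 0): "no_one", ("overlap", 1): "overlap",
        ("overlap", 2): "fully_visible",
    }

    @pytest.mark.parametrize(
        "state,n", list(itertools.product(FrameState, [0, 1, 2]))
    )
    def test_all_twelve_transitions(self, state, n):
        expected = self.TABLE[(state.value, n)]
        assert classify_frame_state(state, n).value == expected

    def test_transition_table_is_total_and_deterministic(self):
        for state, n in itertools.product(FrameState, [0, 1, 2]):
            first = classify_frame_state(state, n)
            assert classify_frame_state(state, n) is first

    def test_three_masks_keeps_state(self, caplog):
        assert classify_frame_state(FrameState.BEGIN, 3) is FrameState.BEGIN


class TestClearance:
    def test_horizontal_ground(self):
        mask = FootwearMask(0, _blob((600, 1000), 460, 481, 100, 200))
        d, point = lowest_point_clearance(
            mask, GroundPlane((0, 500), (999, 500))
        )
        assert d == pytest.approx(20.0)
        assert point[1] == 480

    def test_tilted_ground_interpolates(self):
        mask = FootwearMask(0, _blob((600, 1920), 480, 491, 955, 966))
        d, point = lowest_point_clearance(
            mask, GroundPlane((0, 500), (1920, 520))
        )
        # lowest pixel row 490 around column 960: ground row ~510 there
        assert d == pytest.approx(510 - 490, abs=0.1)

    def test_touching_ground_is_zero(self):
        mask = FootwearMask(0, _blob((600, 1000), 480, 501, 100, 200))
        d, _ = lowest_point_clearance(mask, GroundPlane((0, 500), (999, 500)))
        assert d == 0.0

    def test_below_ground_clipped_to_zero(self):
        mask = FootwearMask(0, _blob((600, 1000), 480, 521, 100, 200))
        d, _ = lowest_point_clearance(mask, GroundPlane((0, 500), (999, 500)))
        assert d == 0.0


class TestSwingStance:
    def test_clear_separation(self):
        shape = (270, 480)
        ga = FLAT_GROUND
        a = FootwearMask(0, _blob(shape, 180, 201, 100, 140))  # 30 px up
        b = FootwearMask(0, _blob(shape, 208, 229, 300, 340))  # 2 px up
        swing, stance = assign_swing_stance([a, b], ga)
        assert swing is a and swing.role is MaskRole.SWING
        assert stance is b and stance.role is MaskRole.STANCE

    def test_tie_resolved_by_displacement(self):
        shape = (270, 480)
        a = FootwearMask(1, _blob(shape, 209, 230, 112, 152))
        b = FootwearMask(1, _blob(shape, 209, 230, 300, 340))
        prev = [(120.0 + 5.7, 219.5 - 12 + 9), (320.05, 219.2)]
        # a moved ~12 px since last frame, b ~0.3 px
        prev = [(131.5 - 12.0, 219.5), (320.0, 219.6)]
        swing, stance = assign_swing_stance([a, b], FLAT_GROUND, prev)
        assert swing is a

    def test_tie_without_history_stays_unknown(self):
        shape = (270, 480)
        a = FootwearMask(0, _blob(shape, 209, 230, 100, 140))
        b = FootwearMask(0, _blob(shape, 209, 230, 300, 340))
        m1, m2 = assign_swing_stance([a, b], FLAT_GROUND, None)
        assert m1.role is MaskRole.UNKNOWN and m2.role is MaskRole.UNKNOWN

    def test_synthetic_scenes_label_all_nonoverlap_frames_correctly(self):
        # Across seeded scenes the swing/stance labels must match truth in
        # every frame where the feet are separate.
        from footclear import render_scene, sample_scene_specs

        base = small_spec(noise_sigma=0.0)
        total = correct = 0
        for spec, _ in sample_scene_specs(20, base, seed=505):
            spec = _shrink(spec)
            frames, truth = render_scene(spec)
            prev_centroids = None
            for i in range(spec.n_frames):
                if i in truth.overlap_frames:
                    continue
                sw, st = truth.swing_masks[i], truth.stance_masks[i]
                if sw is None or st is None or not st.any():
                    continue
                masks = [FootwearMask(i, st.copy()), FootwearMask(i, sw.copy())]
                swing, stance = assign_swing_stance(
                    masks, truth.ground, prev_centroids
                )
                prev_centroids = [m.centroid for m in masks]
                total += 1
                if swing.role is MaskRole.SWING:
                    correct += mask_iou(swing.mask, sw) == 1.0
        assert total > 100
        assert correct == total  # 100% on non-overlap frames


def _shrink(spec):
    """Scale a default-geometry sampled spec down to the small test frame."""
    import dataclasses

    return dataclasses.replace(
        spec,
        frame_height=270, frame_width=480, n_frames=48, n_lead=4,
        sole_length_px=spec.sole_length_px / 3,
        shoe_height_px=spec.shoe_height_px / 3,
        start_col=60.0, end_col=420.0,
        h_a=spec.h_a / 2.5, h_b=max(spec.h_b / 2.5, 2.0),
        ground=((0.0, 230.0), (479.0, 230.0)),
        laser_col=240.0, laser_upper_row=100.0,
        laser_sep_px=60.0, laser_radius=3.0, laser_n_frames=10,
    )


class TestBackends:
    def test_oracle_reproduces_truth_exactly(self, quiet_scene):
        frames, truth = quiet_scene
        backend = OracleBackend(truth)
        spec = truth.spec
        for i in range(spec.n_lead, spec.n_frames):
            masks = segment_footwear(frames[i], backend)
            truths = truth.masks_for(i)
            assert len(masks) == len(truths)
            for m, t in zip(masks, truths):
                assert mask_iou(m.mask, t) == 1.0

    def test_classical_backend_accuracy(self, noisy_scene):
        frames, truth = noisy_scene
        backend = ClassicalBackend(frames[0])
        checked = 0
        for i in range(truth.spec.n_lead, truth.spec.n_frames):
            if i in truth.overlap_frames:
                continue
            masks = segment_footwear(frames[i], backend)
            truths = truth.masks_for(i)
            if len(truths) < 2:
                continue
            assert len(masks) == 2
            for m in masks:
                best = max(mask_iou(m.mask, t) for t in truths)
                assert best >= 0.9
                checked += 1
        assert checked > 20

    def test_empty_scene_yields_no_masks(self, quiet_scene):
        frames, _ = quiet_scene
        backend = ClassicalBackend(frames[0])
        assert segment_footwear(frames[1], backend) == []

    def test_failing_backend_treated_as_empty(self):
        class Broken:
            name = "broken"

            def detect(self, frame):
                raise RuntimeError("boom")

        frame = VideoFrame(0, np.zeros((10, 10), dtype=np.uint8))
        assert segment_footwear(frame, Broken()) == []


def _paint_scene_frame(truth, swing_mask, index):
    """Background + stance + an arbitrary swing silhouette."""
    spec = truth.spec
    cols = np.arange(spec.frame_width, dtype=np.float32)
    img = np.broadcast_to(
        (spec.background_base
         + spec.illum_amplitude * (cols / spec.frame_width - 0.5)
         ).astype(np.float32),
        (spec.frame_height, spec.frame_width),
    ).copy()
    stance = truth.stance_masks[index]
    if stance is not None:
        img[stance & ~swing_mask] = spec.stance_intensity
    img[swing_mask] = spec.swing_intensity
    return VideoFrame(index, np.clip(np.rint(img), 0, 255).astype(np.uint8))


class TestOcclusionRecovery:
    def _prev_swing(self, truth, index):
        return FootwearMask(
            index, truth.swing_masks[index].copy(), role=MaskRole.SWING
        )

    def test_identity_on_unchanged_frame(self, quiet_scene):
        frames, truth = quiet_scene
        i = truth.spec.n_lead + 8
        prev = self._prev_swing(truth, i)
        found = search_occlusion_transform(prev, frames[i])
        rot, dc, dr, score = found
        assert (rot, dc, dr) == (0.0, 0, 0)
        assert score == 0.0

    def test_pure_translation_recovered_within_one_px(self, quiet_scene):
        frames, truth = quiet_scene
        i = truth.spec.n_lead + 8
        prev = self._prev_swing(truth, i)
        moved = np.zeros_like(prev.mask)
        rows, cols = np.nonzero(prev.mask)
        moved[rows - 3, cols + 8] = True  # +8 columns, -3 rows
        frame = _paint_scene_frame(truth, moved, i + 1)
        rot, dc, dr, _ = search_occlusion_transform(prev, frame)
        assert rot == 0.0
        assert abs(dc - 8) <= 1 and abs(dr + 3) <= 1

    def test_on_grid_rotation_recovered_exactly(self, quiet_scene):
        frames, truth = quiet_scene
        i = truth.spec.n_lead + 8
        prev = self._prev_swing(truth, i)
        center = prev.bottom_edge.astype(float).mean(axis=0)
        rotated = _transform_mask(prev.mask, 10.0, center, 0, 0)
        frame = _paint_scene_frame(truth, rotated, i + 1)
        rot, dc, dr, _ = search_occlusion_transform(prev, frame)
        assert rot == 10.0
        assert abs(dc) <= 1 and abs(dr) <= 1

    def test_search_matches_bruteforce_oracle(self, quiet_scene):
        # Exhaustive pure-Python scoring over the same grid must pick the
        # same transform.  The oriented-chamfer metric is restated here
        # from its definition: tangent bins of pi/8 with one-bin
        # tolerance, wildcard endpoints, per-bin distance transforms.
        import math

        from scipy import ndimage as ndi
        from skimage import filters

        frames, truth = quiet_scene
        cfg = OcclusionSearchConfig(
            translation_window_px=(12, 6), edge_gradient_threshold=20.0
        )
        i = truth.spec.n_lead + 8
        prev = self._prev_swing(truth, i)
        moved = np.zeros_like(prev.mask)
        rows, cols = np.nonzero(prev.mask)
        moved[rows - 2, cols + 5] = True
        frame = _paint_scene_frame(truth, moved, i + 1)

        got = search_occlusion_transform(prev, frame, cfg)[:3]

        n_bins = 8
        img = frame.pixels.astype(np.float32)
        gy, gx = filters.sobel_h(img), filters.sobel_v(img)
        edges = np.hypot(gy, gx) > 20.0
        edge_bins = np.floor(
            np.mod(np.arctan2(gy, gx) + np.pi / 2, np.pi) / (np.pi / n_bins)
        ).astype(int).clip(0, n_bins - 1)
        maps = []
        for k in range(n_bins):
            ok = edges & np.isin(edge_bins, [(k - 1) % n_bins, k,
                                             (k + 1) % n_bins])
            maps.append(ndi.distance_transform_edt(~ok) if ok.any()
                        else ndi.distance_transform_edt(~edges))
        maps.append(ndi.distance_transform_edt(~edges))  # wildcard

        pts = prev.bottom_edge.astype(float)
        center = pts.mean(axis=0)
        h, w = edges.shape
        best = None
        for rot in cfg.rotations_deg:
            rp = rotate_points(pts, rot, center)
            rc = np.rint(rp[:, 0]).astype(int)
            rr = np.rint(rp[:, 1]).astype(int)
            # template tangent bins under this rotation
            tbins = []
            for p in range(len(pts)):
                if p in (0, len(pts) - 1):
                    tbins.append(n_bins)
                    continue
                d = pts[p + 1] - pts[p - 1]
                ang = math.atan2(d[1], d[0]) + math.radians(rot)
                tbins.append(int(np.mod(ang, np.pi) // (np.pi / n_bins))
                             % n_bins)
            for dc in range(-12, 13):
                for dr in range(-6, 7):
                    total = 0.0
                    for c, r, b in zip(rc, rr, tbins):
                        cc = min(max(c + dc, 0), w - 1)
                        rrow = min(max(r + dr, 0), h - 1)
                        total += maps[b][rrow, cc]
                    cand = (total / len(rc), dc * dc + dr * dr, abs(rot),
                            (float(rot), dc, dr))
                    if best is None or cand[:3] < best[:3]:
                        best = cand
        assert got == best[3]

    def test_no_edges_falls_back_to_previous_mask(self):
        shape = (100, 200)
        prev = FootwearMask(0, _blob(shape, 50, 70, 40, 90))
        flat = VideoFrame(1, np.full(shape, 128, dtype=np.uint8))
        out = recover_occluded_swing(prev, flat)
        assert out.low_confidence
        assert np.array_equal(out.mask, prev.mask)
        assert out.provenance is Provenance.OCCLUSION_RECOVERY
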