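import numpy as np
import pandas as pd
import pytest

from bivos.align import (
    CATEGORIES,
    alignment_scores,
    dilate_masks,
    displacement,
    resolve_and_detect_swaps,
)
from bivos.consensus import ConsensusStream, assemble_consensus
from bivos.mask_io import KeypointSet, MaskStream
from bivos.synthetic import SceneSpec, generate_scene


def kp_set(rows, n_tracks=2, n_keypoints=9, scale=1):
    df = pd.DataFrame(rows, columns=["frame", "track", "keypoint", "x", "y"])
    return KeypointSet(df, n_tracks=n_tracks, n_keypoints=n_keypoints, scale=scale)


class TestDisplacement:
    def test_stationary_keypoints_give_zero(self):
        rows = [(t, 1, k, 10.0, 20.0) for t in range(4) for k in range(1, 4)]
        series = displacement(kp_set(rows, n_tracks=1, n_keypoints=3))
        assert np.allclose(series.d, 0.0)
        assert (series.k == 3).all()

    def test_three_four_five_move(self):
        rows = [(0, 1, 1, 0.0, 0.0), (1, 1, 1, 3.0, 4.0)]
        series = displacement(kp_set(rows, n_tracks=1, n_keypoints=1))
        assert series.d[0, 0] == pytest.approx(5.0)

    def test_all_invalid_next_frame_undefined(self):
        rows = [(0, 1, 1, 5.0, 5.0), (1, 1, 1, np.nan, 5.0)]
        series = displacement(kp_set(rows, n_tracks=1, n_keypoints=1))
        assert np.isnan(series.d[0, 0])
        assert series.k[0, 0] == 0

    def test_subset_restricts_keypoints(self):
        rows = [
            (0, 1, 1, 0.0, 0.0), (1, 1, 1, 10.0, 0.0),   # moving keypoint
            (0, 1, 2, 0.0, 0.0), (1, 1, 2, 0.0, 0.0),    # stationary keypoint
        ]
        kps = kp_set(rows, n_tracks=1, n_keypoints=2)
        assert displacement(kps, subset=[2]).d[0, 0] == pytest.approx(0.0)
        assert displacement(kps).d[0, 0] == pytest.approx(5.0)

    def test_unknown_subset_index_rejected(self):
        rows = [(0, 1, 1, 0.0, 0.0), (1, 1, 1, 1.0, 0.0)]
        with pytest.raises(ValueError, match="unknown keypoint"):
            displacement(kp_set(rows, n_tracks=1, n_keypoints=1), subset=[5])


class TestDilateMasks:
    def test_radius_zero_is_identity(self, disjoint_frame):
        out = dilate_masks(disjoint_frame, 0)
        for i in (1, 2):
            assert np.array_equal(out[i - 1], disjoint_frame == i)

    def test_masks_six_apart_share_boundary_pixels_at_radius_five(self):
        frame = np.zeros((5, 20), dtype=np.uint8)
        frame[2, 4] = 1
        frame[2, 10] = 2   # 6 px apart
        out = dilate_masks(frame, 5)
        both = out[0] & out[1]
        assert both.any()
        assert both[2, 7]  # midpoint belongs to both dilated masks

    def test_single_pixel_dilation_area_matches_disk_oracle(self):
        frame = np.zeros((21, 21), dtype=np.uint8)
        frame[10, 10] = 1
        out = dilate_masks(frame, 5)
        yy, xx = np.mgrid[-10:11, -10:11]
        oracle = ((yy**2 + xx**2) <= 25).sum()
        assert out[0].sum() == oracle

    def test_negative_radius_rejected(self, disjoint_frame):
        with pytest.raises(ValueError):
            dilate_masks(disjoint_frame, -1)


def _simple_masks(T=3, provenance=None):
    frame = np.zeros((40, 60), dtype=np.uint8)
    frame[10:20, 5:15] = 1
    frame[10:20, 40:50] = 2
    frames = np.tile(frame, (T, 1, 1))
    if provenance is None:
        return MaskStream(frames, n_animals=2)
    return ConsensusStream(
        frames=frames, n_animals=2,
        provenance=np.asarray(provenance, dtype=np.uint8),
    )


def _in_mask_rows(t, track, cx, cy, count=8):
    return [
        (t, track, k, float(cx + (k % 3)), float(cy + (k // 3)))
        for k in range(1, count + 1)
    ]


class TestAlignmentScores:
    def test_accuracy_times_hits_formula(self):
        masks = _simple_masks(T=1)
        rows = _in_mask_rows(0, 1, 7, 12) + _in_mask_rows(0, 2, 42, 12)
        series = alignment_scores(kp_set(rows, n_keypoints=8), masks, radius=0)
        assert series.scores[0, 0] == pytest.approx(16.0)  # 8^2/8 + 8^2/8
        assert series.scores[0, 1] == pytest.approx(0.0)
        assert series.category_names() == ["definitive"]
        assert series.perms[series.resolved[0]] == (1, 2)

    def test_evenly_split_keypoints_are_ambiguous(self):
        masks = _simple_masks(T=1)
        rows = (
            _in_mask_rows(0, 1, 7, 12, count=4)
            + [(0, 1, k, 42.0, 12.0) for k in (5, 6, 7, 8)]
            + _in_mask_rows(0, 2, 7, 14, count=4)
            + [(0, 2, k, 42.0, 14.0) for k in (5, 6, 7, 8)]
        )
        series = alignment_scores(kp_set(rows, n_keypoints=8), masks, radius=0)
        assert series.category_names() == ["ambiguous"]
        assert series.resolved[0] == -1

    def test_double_garbage_frame_has_no_valid_masks(self):
        masks = _simple_masks(T=3, provenance=[0, 2, 0])
        masks.frames[1] = 0
        rows = [r for t in range(3) for r in _in_mask_rows(t, 1, 7, 12)]
        rows += [r for t in range(3) for r in _in_mask_rows(t, 2, 42, 12)]
        series = alignment_scores(kp_set(rows, n_keypoints=8), masks, radius=0)
        assert series.category_names()[1] == "no_valid_masks"

    def test_frame_without_keypoints(self):
        masks = _simple_masks(T=2)
        rows = _in_mask_rows(0, 1, 7, 12) + _in_mask_rows(0, 2, 42, 12)
        series = alignment_scores(kp_set(rows, n_keypoints=8), masks, radius=0)
        assert series.category_names()[1] == "no_keypoints"

    def test_zero_overlap_category(self):
        masks = _simple_masks(T=1)
        rows = _in_mask_rows(0, 1, 25, 32) + _in_mask_rows(0, 2, 25, 2)
        series = alignment_scores(kp_set(rows, n_keypoints=8), masks, radius=0)
        assert series.category_names() == ["zero_overlap"]

    def test_disjoint_frame_ranges_rejected(self):
        masks = _simple_masks(T=2)
        rows = _in_mask_rows(10, 1, 7, 12)
        with pytest.raises(ValueError, match="overlap"):
            alignment_scores(kp_set(rows, n_keypoints=8), masks)

    def test_scale_reconciliation(self):
        """Full-resolution keypoints align to fourfold-downsampled masks."""
        from bivos.mask_io import downsample_mask

        masks_full = _simple_masks(T=1)
        small = np.stack([downsample_mask(masks_full.frames[0], 4)])
        masks4 = MaskStream(small, n_animals=2, scale=4)
        rows = _in_mask_rows(0, 1, 8, 12) + _in_mask_rows(0, 2, 42, 12)
        series = alignment_scores(
            kp_set(rows, n_keypoints=8, scale=1), masks4, radius=1
        )
        assert series.category_names() == ["definitive"]
        assert series.perms[series.resolved[0]] == (1, 2)

    def test_equivariant_under_consistent_relabeling(self):
        masks = _simple_masks(T=1)
        rows = _in_mask_rows(0, 1, 7, 12) + _in_mask_rows(0, 2, 42, 12)
        base = alignment_scores(kp_set(rows, n_keypoints=8), masks, radius=0)
        # exchange mask labels and track labels together
        flipped_frames = masks.frames.copy()
        m1, m2 = flipped_frames == 1, flipped_frames == 2
        flipped_frames[m1], flipped_frames[m2] = 2, 1
        masks_f = MaskStream(flipped_frames, n_animals=2)
        rows_f = _in_mask_rows(0, 2, 7, 12) + _in_mask_rows(0, 1, 42, 12)
        flipped = alignment_scores(kp_set(rows_f, n_keypoints=8), masks_f, radius=0)
        assert np.allclose(np.sort(base.scores[0]), np.sort(flipped.scores[0]))
        assert flipped.perms[flipped.resolved[0]] == (1, 2)


@pytest.fixture(scope="module")
def scene():
    spec = SceneSpec(n_frames=25, height=64, width=80, seed=17)
    truth, kps = generate_scene(spec)
    cons = assemble_consensus(truth, truth.copy(), [])
    return cons, kps


class TestGroundTruthRecovery:
    def test_clean_scene_fully_definitive_identity(self, scene):
        cons, kps = scene
        series = alignment_scores(kps, cons, radius=5)
        assert series.category_names() == ["definitive"] * len(series)
        assert all(series.perms[r] == (1, 2) for r in series.resolved)
        _, events = resolve_and_detect_swaps(series)
        assert events == []

    def test_injected_track_swap_localized_to_its_frame(self, scene):
        cons, kps = scene
        rec = kps.records.copy()
        late = rec["frame"] >= 12
        rec.loc[late, "track"] = rec.loc[late, "track"].map({1: 2, 2: 1})
        swapped = KeypointSet(rec, kps.n_tracks, kps.n_keypoints, kps.scale)
        series = alignment_scores(swapped, cons, radius=5)
        _, events = resolve_and_detect_swaps(series)
        assert len(events) == 1
        assert events[0].frame == 12
        assert events[0].type == "localized"
        assert events[0].previous == (1, 2) and events[0].new == (2, 1)

    def test_swap_across_unalignable_gap_is_unlocalized(self, scene):
        cons, kps = scene
        gapped = ConsensusStream(
            frames=cons.frames.copy(), n_animals=2,
            provenance=cons.provenance.copy(),
        )
        gapped.provenance[10:12] = 2  # double-garbage gap
        gapped.frames[10:12] = 0
        rec = kps.records.copy()
        late = rec["frame"] >= 11  # swap inside the gap
        rec.loc[late, "track"] = rec.loc[late, "track"].map({1: 2, 2: 1})
        swapped = KeypointSet(rec, kps.n_tracks, kps.n_keypoints, kps.scale)
        series = alignment_scores(swapped, gapped, radius=5)
        _, events = resolve_and_detect_swaps(series)
        assert len(events) == 1
        assert events[0].type == "unlocalized"
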