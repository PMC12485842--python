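import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bivos.iou import (
    IOUSeries,
    combined_iou,
    iou_series,
    permutations,
    quality_scores,
)
from bivos.mask_io import MaskStream


def brute_force_iou(fwd, rev, perm):
    """Per-pixel double-loop oracle for the combined IOU."""
    inter = union = 0
    h, w = fwd.shape
    for i, pi in enumerate(perm, start=1):
        for y in range(h):
            for x in range(w):
                in_f = fwd[y, x] == i
                in_r = rev[y, x] == pi
                inter += in_f and in_r
                union += in_f or in_r
    if union == 0:
        return 1.0
    return inter / union


class TestPermutations:
    def test_two_animals(self):
        assert permutations(2) == [(1, 2), (2, 1)]

    def test_three_animals_all_six_lexicographic(self):
        perms = permutations(3)
        assert len(perms) == 6
        assert perms == sorted(perms)
        assert perms[0] == (1, 2, 3)

    def test_single_animal(self):
        assert permutations(1) == [(1,)]

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            permutations(0)


class TestCombinedIOU:
    def test_identical_frames_identity_mapping(self, disjoint_frame):
        value, degenerate = combined_iou(disjoint_frame, disjoint_frame, (1, 2))
        assert value == 1.0 and not degenerate

    def test_identical_frames_flip_mapping(self, disjoint_frame):
        value, _ = combined_iou(disjoint_frame, disjoint_frame, (2, 1))
        assert value == 0.0

    def test_partial_overlap_matches_hand_computation(self):
        # forward animal 1: rows 0-4 (50 px); reverse animal 1: rows 1-5;
        # animal 2: identical 50 px block in both -> (40+50)/(60+50) = 90/110
        fwd = np.zeros((12, 10), dtype=np.uint8)
        rev = np.zeros((12, 10), dtype=np.uint8)
        fwd[0:5] = 1
        rev[1:6] = 1
        fwd[7:12] = 2
        rev[7:12] = 2
        value, _ = combined_iou(fwd, rev, (1, 2))
        assert value == pytest.approx(90 / 110)
        assert value == pytest.approx(brute_force_iou(fwd, rev, (1, 2)))

    def test_all_empty_frames_degenerate(self):
        empty = np.zeros((5, 5), dtype=np.uint8)
        value, degenerate = combined_iou(empty, empty, (1, 2))
        assert value == 1.0 and degenerate

    def test_shape_mismatch_rejected(self, disjoint_frame):
        with pytest.raises(ValueError, match="shape"):
            combined_iou(disjoint_frame, disjoint_frame[:-1], (1, 2))

    def test_matches_brute_force_on_random_three_animal_frames(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            fwd = rng.integers(0, 4, size=(20, 20), dtype=np.uint8)
            rev = rng.integers(0, 4, size=(20, 20), dtype=np.uint8)
            for perm in permutations(3):
                value, _ = combined_iou(fwd, rev, perm)
                assert value == pytest.approx(brute_force_iou(fwd, rev, perm))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_under_stream_exchange(self, seed):
        """IOU(fwd, rev, pi) == IOU(rev, fwd, pi^-1)."""
        rng = np.random.default_rng(seed)
        fwd = rng.integers(0, 3, size=(8, 8), dtype=np.uint8)
        rev = rng.integers(0, 3, size=(8, 8), dtype=np.uint8)
        for perm in permutations(2):
            inverse = tuple(np.argsort(perm) + 1)
            a, _ = combined_iou(fwd, rev, perm)
            b, _ = combined_iou(rev, fwd, inverse)
            assert a == pytest.approx(b)


def _streams_from(frames_f, frames_r, n):
    return (
        MaskStream(np.asarray(frames_f), n_animals=n),
        MaskStream(np.asarray(frames_r), n_animals=n, direction="reverse"),
    )


class TestIOUSeries:
    def test_clean_case_dominated_by_identity(self, small_scene):
        truth, _ = small_scene
        series = iou_series(truth, truth.copy())
        assert (series.dominant_index == 0).all()
        assert np.allclose(series.dominant_value, 1.0)
        assert not series.tie.any()

    def test_relabeling_equivariance(self, small_scene):
        """Relabeling one stream permutes the IOU map; dominant value unchanged."""
        truth, _ = small_scene
        flipped = truth.frames.copy()
        m1, m2 = flipped == 1, flipped == 2
        flipped[m1], flipped[m2] = 2, 1
        fwd, rev = _streams_from(truth.frames, flipped, 2)
        series = iou_series(fwd, rev)
        base = iou_series(truth, truth.copy())
        assert np.allclose(series.dominant_value, base.dominant_value)
        assert all(p == (2, 1) for p in series.dominant_perms)
        # columns swapped relative to the unrelabeled comparison
        assert np.allclose(series.values[:, 0], base.values[:, 1])
        assert np.allclose(series.values[:, 1], base.values[:, 0])

    def test_exact_tie_favors_identity_and_flags(self):
        # reverse animal 1 straddles both forward animals equally; reverse
        # animal 2 absent -> both mappings score 2/10 exactly
        fwd = np.zeros((1, 1, 8), dtype=np.uint8)
        rev = np.zeros((1, 1, 8), dtype=np.uint8)
        fwd[0, 0, 0:4] = 1
        fwd[0, 0, 4:8] = 2
        rev[0, 0, 2:6] = 1
        f, r = _streams_from(fwd, rev, 2)
        series = iou_series(f, r)
        assert series.values[0, 0] == pytest.approx(series.values[0, 1])
        assert series.dominant_perms[0] == (1, 2)
        assert series.tie[0]

    def test_length_mismatch_rejected(self, small_scene):
        truth, _ = small_scene
        short = MaskStream(truth.frames[:-1].copy(), n_animals=2)
        with pytest.raises(ValueError, match="length"):
            iou_series(truth, short)

    def test_bounds(self, small_scene):
        truth, _ = small_scene
        noisy = truth.frames.copy()
        noisy[:, ::3, ::2] = 0
        fwd, rev = _streams_from(truth.frames, noisy, 2)
        series = iou_series(fwd, rev)
        assert (series.values >= 0).all() and (series.values <= 1).all()


class TestQualityScores:
    @staticmethod
    def _series_from_values(ident, flip):
        values = np.column_stack([ident, flip]).astype(float)
        dominant = values.argmax(axis=1).astype(np.intp)
        T = len(ident)
        return IOUSeries(
            values=values,
            perms=[(1, 2), (2, 1)],
            dominant_index=dominant,
            tie=np.zeros(T, dtype=bool),
            degenerate=np.zeros(T, dtype=bool),
            n_animals=2,
        )

    def test_stable_ordering_keeps_full_score(self):
        q = quality_scores(self._series_from_values([1] * 5, [0] * 5))
        assert np.array_equal(q.q, np.ones(5))

    def test_single_crossing_zeroes_flanking_frames(self):
        q = quality_scores(
            self._series_from_values([1, 1, 1, 0, 0], [0, 0, 0, 1, 1])
        )
        assert np.array_equal(q.q, [1, 1, 0, 0, 1])
        assert np.array_equal(q.chi, [1, 1, 0, 0, 1])

    def test_interior_frame_direct_formula(self):
        q = quality_scores(
            self._series_from_values([0.8, 0.8, 0.8], [0.2, 0.2, 0.2])
        )
        assert q.q[1] == pytest.approx(0.6)

    def test_exact_tie_suppresses_tie_and_neighbors(self):
        q = quality_scores(
            self._series_from_values([1, 0.5, 1], [0, 0.5, 0])
        )
        assert np.array_equal(q.chi, [0, 0, 0])

    def test_boundaries_use_single_neighbor(self):
        # ordering stable at both ends; boundary frames keep their score
        q = quality_scores(self._series_from_values([0.9, 0.9], [0.1, 0.1]))
        assert np.allclose(q.q, 0.8)

    def test_rejected_for_three_animals(self, small_scene):
        truth, _ = small_scene
        frames3 = truth.frames.copy()
        series = iou_series(
            MaskStream(frames3, n_animals=3),
            MaskStream(frames3.copy(), n_animals=3, direction="reverse"),
        )
        with pytest.raises(ValueError, match="2 animals"):
            quality_scores(series)

    def test_bounded_by_curve_separation(self, small_scene):
        truth, _ = small_scene
        noisy = truth.frames.copy()
        noisy[:, ::4, :] = 0
        series = iou_series(truth, MaskStream(noisy, n_animals=2, direction="reverse"))
        q = quality_scores(series)
        gap = np.abs(series.values[:, 0] - series.values[:, 1])
        assert (q.q <= gap + 1e-12).all()
        assert ((q.q >= 0) & (q.q <= 1)).all()
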