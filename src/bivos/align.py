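"""Keypoint displacement, keypoint-to-mask alignment, and swap localization.

Pose-estimation tracks carry their own identity errors.  Aligning each
track's keypoints to the identity-validated consensus masks resolves them:
at every frame, for every permutation pi mapping keypoint tracks to mask
identities, the alignment score

    A_t(pi) = sum_x  SC_t(x -> pi(x))^2 / K_t(x)

combines the accuracy (SC/K, the fraction of track x's valid keypoints that
land inside the dilated mask of animal pi(x)) with the hit count SC itself,
so that both the proportion and the absolute number of supporting keypoints
contribute.  Masks are dilated independently per animal (a boundary keypoint
may belong to several adjoining dilated masks rather than risk a wrong
exclusive assignment).  Frames where the argmax is unique are *definitive*;
the rest fall into four categories: no keypoints, no valid masks (e.g. a
double-garbage ZOD), zero overlap, or ambiguous (tied scores).

A change of the resolved mapping relative to the most recent definitive
frame flags a keypoint-track identity swap; the event is *localized* to the
current frame only when the immediately preceding frame was itself
definitive, otherwise the swap happened somewhere inside the preceding
unalignable gap and is recorded as unlocalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.morphology import dilation, disk

from .consensus import ConsensusStream, PROVENANCE_CODES
from .iou import permutations
from .mask_io import KeypointSet, MaskStream

__all__ = [
    "DisplacementSeries",
    "AlignmentSeries",
    "SwapEvent",
    "CATEGORIES",
    "displacement",
    "dilate_masks",
    "alignment_scores",
    "resolve_and_detect_swaps",
]

CATEGORIES = ("definitive", "no_keypoints", "no_valid_masks",
              "zero_overlap", "ambiguous")
_CAT_CODE = {name: k for k, name in enumerate(CATEGORIES)}


def _keypoint_array(kps: KeypointSet, subset: Sequence[int] | None):
    """Dense (T, n_tracks, n_kp, 2) coordinate array (NaN = missing/invalid).

    Returns (coords, frame_index_of_slot_0).  Only keypoints in ``subset``
    (1-based indices; None = all) are materialised; invalid records are NaN.
    """
    rec = kps.records
    if subset is None:
        subset = sorted(rec["keypoint"].unique()) if len(rec) else []
    else:
        known = set(range(1, kps.n_keypoints + 1))
        bad = [k for k in subset if k not in known]
        if bad:
            raise ValueError(f"unknown keypoint indices in subset: {bad}")
    subset = list(subset)
    if not subset:
        raise ValueError("keypoint subset is empty")
    kp_slot = {k: i for i, k in enumerate(subset)}
    f_min = int(rec["frame"].min()) if len(rec) else 0
    f_max = int(rec["frame"].max()) if len(rec) else 0
    T = f_max - f_min + 1
    coords = np.full((T, kps.n_tracks, len(subset), 2), np.nan)
    sel = rec[rec["keypoint"].isin(subset) & rec["valid"]]
    t_idx = sel["frame"].to_numpy() - f_min
    a_idx = sel["track"].to_numpy() - 1
    k_idx = np.array([kp_slot[k] for k in sel["keypoint"]])
    coords[t_idx, a_idx, k_idx, 0] = sel["x"].to_numpy()
    coords[t_idx, a_idx, k_idx, 1] = sel["y"].to_numpy()
    return coords, f_min


@dataclass
class DisplacementSeries:
    """Mean per-keypoint displacement between adjacent frames, per track.

    ``d[t, a]`` is the average Euclidean motion (pixels) of track ``a + 1``'s
    keypoints between frames ``t`` and ``t + 1``, over the ``k[t, a]``
    keypoints valid in both; NaN exactly where no shared valid keypoints
    exist.
    """

    d: np.ndarray          # (T-1, n_tracks), NaN where undefined
    k: np.ndarray          # (T-1, n_tracks) shared valid keypoint counts
    frame_offset: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        T1, n = self.d.shape
        rows = []
        for a in range(n):
            rows.append(pd.DataFrame({
                "frame": np.arange(T1) + self.frame_offset,
                "track": a + 1,
                "displacement": self.d[:, a],
                "shared_keypoints": self.k[:, a],
            }))
        return pd.concat(rows, ignore_index=True)


def displacement(
    kps: KeypointSet, subset: Sequence[int] | None = None
) -> DisplacementSeries:
    """Average per-keypoint Euclidean displacement for each track and frame pair.

    Restricted to ``subset`` (1-based keypoint indices); a keypoint counts
    only when valid in both frames of the pair.
    """
    coords, f_min = _keypoint_array(kps, subset)
    delta = coords[1:] - coords[:-1]              # (T-1, n, k, 2)
    norms = np.linalg.norm(delta, axis=-1)        # NaN wherever either end invalid
    shared = ~np.isnan(norms)
    k = shared.sum(axis=-1)
    with np.errstate(invalid="ignore"):
        total = np.nansum(norms, axis=-1)
        d = np.where(k > 0, total / np.maximum(k, 1), np.nan)
    return DisplacementSeries(d=d, k=k, frame_offset=f_min)


def dilate_masks(frame: np.ndarray, radius: int) -> np.ndarray:
    """Per-animal binary masks after independent disk dilation.

    Returns a ``(n, H, W)`` boolean array where ``out[i]`` is animal
    ``i + 1``'s mask dilated by a Euclidean disk of the given radius; dilated
    masks may overlap.  Radius 0 returns the undilated per-animal masks.
    """
    if radius < 0:
        raise ValueError("dilation radius must be nonnegative")
    n = int(frame.max())
    out = np.zeros((n,) + frame.shape, dtype=bool)
    footprint = disk(radius) if radius > 0 else None
    for i in range(1, n + 1):
        mask = frame == i
        out[i - 1] = dilation(mask, footprint) if footprint is not None else mask
    return out


@dataclass
class AlignmentSeries:
    """Framewise alignment scores, categories, and resolved mappings.

    ``scores[t, p]`` is A_t of ``perms[p]`` (NaN on non-definitive-scoreable
    frames such as no-keypoint frames); ``hits[t, x, j]`` is SC_t(track x+1
    inside dilated mask j+1).  ``category`` uses the codes of
    :data:`CATEGORIES`; ``resolved[t]`` indexes ``perms`` on definitive
    frames and is -1 elsewhere.
    """

    scores: np.ndarray          # (T, n!)
    hits: np.ndarray            # (T, n, n)
    category: np.ndarray        # (T,) uint8 codes into CATEGORIES
    resolved: np.ndarray        # (T,) intp, -1 where not definitive
    perms: list[tuple[int, ...]]
    frame_offset: int = 0

    def __len__(self) -> int:
        return len(self.scores)

    def category_names(self) -> list[str]:
        return [CATEGORIES[c] for c in self.category]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"frame": np.arange(len(self)) + self.frame_offset}
        for p, perm in enumerate(self.perms):
            cols["A_" + "".join(map(str, perm))] = self.scores[:, p]
        cols["category"] = self.category_names()
        cols["resolved"] = [
            "".join(map(str, self.perms[r])) if r >= 0 else ""
            for r in self.resolved
        ]
        return pd.DataFrame(cols)


def alignment_scores(
    kps: KeypointSet,
    masks: ConsensusStream | MaskStream,
    radius: int = 5,
    subset: Sequence[int] | None = None,
) -> AlignmentSeries:
    """Score every track-to-identity permutation at every shared frame.

    Keypoint coordinates are rescaled to the mask resolution (divided by
    ``mask scale / keypoint scale``), rounded to the nearest pixel, and
    tested against per-animal masks dilated by ``radius`` pixels at mask
    scale; out-of-bounds keypoints count as misses.  Tracks with no valid
    keypoints contribute 0 to every score; a frame is ``no_keypoints`` only
    when every track is empty.
    """
    n = masks.n_animals
    coords, kp_f_min = _keypoint_array(kps, subset)
    kp_scale = getattr(kps, "scale", 1)
    factor = masks.scale / kp_scale
    coords = coords / factor

    m_start = masks.frame_offset
    m_end = m_start + len(masks.frames)
    k_start, k_end = kp_f_min, kp_f_min + coords.shape[0]
    if max(m_start, k_start) >= min(m_end, k_end):
        raise ValueError(
            f"keypoint frames [{k_start}, {k_end}) and mask frames "
            f"[{m_start}, {m_end}) do not overlap"
        )
    # the series spans the mask stream; mask frames without keypoint records
    # classify as no_keypoints
    start, end = m_start, m_end

    provenance = getattr(masks, "provenance", None)
    perms = permutations(n)
    T = end - start
    H, W = masks.frames.shape[1:]
    scores = np.full((T, len(perms)), np.nan)
    hits = np.zeros((T, n, n), dtype=np.int64)
    category = np.zeros(T, dtype=np.uint8)
    resolved = np.full(T, -1, dtype=np.intp)

    for t in range(T):
        frame = masks.frames[start - m_start + t]
        kp_idx = start - k_start + t
        if 0 <= kp_idx < coords.shape[0]:
            pts = coords[kp_idx]                   # (n_tracks, k, 2)
        else:
            pts = np.full((kps.n_tracks, coords.shape[2], 2), np.nan)
        K = (~np.isnan(pts[..., 0])).sum(axis=1)   # valid per track
        no_masks = (provenance is not None and
                    provenance[start - m_start + t] == PROVENANCE_CODES["none"])
        no_masks = no_masks or not frame.any()
        if no_masks:
            category[t] = _CAT_CODE["no_valid_masks"]
            continue
        if K.sum() == 0:
            category[t] = _CAT_CODE["no_keypoints"]
            continue
        dil = dilate_masks(frame, radius)
        if dil.shape[0] < n:  # animals absent from this frame have empty masks
            pad = np.zeros((n - dil.shape[0], H, W), dtype=bool)
            dil = np.concatenate([dil, pad], axis=0)
        sc = np.zeros((kps.n_tracks, n), dtype=np.int64)
        for x in range(kps.n_tracks):
            valid = ~np.isnan(pts[x, :, 0])
            if not valid.any():
                continue
            px = np.rint(pts[x, valid, 0]).astype(np.intp)
            py = np.rint(pts[x, valid, 1]).astype(np.intp)
            inb = (px >= 0) & (px < W) & (py >= 0) & (py < H)
            for j in range(n):
                sc[x, j] = int(dil[j, py[inb], px[inb]].sum())
        hits[t, : kps.n_tracks] = sc
        if sc.sum() == 0:
            category[t] = _CAT_CODE["zero_overlap"]
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            acc = np.where(K[:, None] > 0, sc ** 2 / np.maximum(K[:, None], 1), 0.0)
        a_vals = np.array(
            [acc[np.arange(min(kps.n_tracks, n)),
                 np.asarray(p[: kps.n_tracks]) - 1].sum() for p in perms]
        )
        scores[t] = a_vals
        best = a_vals.max()
        argmaxes = np.flatnonzero(a_vals == best)
        if len(argmaxes) > 1:
            category[t] = _CAT_CODE["ambiguous"]
        else:
            category[t] = _CAT_CODE["definitive"]
            resolved[t] = argmaxes[0]
    return AlignmentSeries(
        scores=scores, hits=hits, category=category, resolved=resolved,
        perms=perms, frame_offset=start,
    )


@dataclass(frozen=True)
class SwapEvent:
    """A detected keypoint-track identity swap.

    ``localized`` events pin the swap to ``frame`` (the preceding frame was
    definitively aligned); ``unlocalized`` events follow an unalignable gap,
    so the swap lies somewhere inside it and the event is excluded from
    localized-swap counts.
    """

    frame: int
    type: str                      # {"localized", "unlocalized"}
    previous: tuple[int, ...]
    new: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "frame": int(self.frame),
            "type": self.type,
            "previous": list(self.previous),
            "new": list(self.new),
        }


def resolve_and_detect_swaps(
    series: AlignmentSeries,
) -> tuple[np.ndarray, list[SwapEvent]]:
    """Resolved mapping per frame plus keypoint-track swap events.

    The resolved mapping is the argmax permutation on definitive frames
    (carried unchanged through non-definitive frames).  An event fires when
    a definitive frame's mapping differs from the most recent definitive
    mapping; it is localized iff the immediately preceding frame was
    definitive.
    """
    T = len(series)
    resolved = series.resolved.copy()
    events: list[SwapEvent] = []
    last_def_map: int | None = None
    prev_definitive = False
    for t in range(T):
        if series.category[t] != _CAT_CODE["definitive"]:
            prev_definitive = False
            continue
        cur = int(series.resolved[t])
        if last_def_map is not None and cur != last_def_map:
            events.append(
                SwapEvent(
                    frame=t + series.frame_offset,
                    type="localized" if prev_definitive else "unlocalized",
                    previous=series.perms[last_def_map],
                    new=series.perms[cur],
                )
            )
        last_def_map = cur
        prev_definitive = True
    return resolved, events
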