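"""Permutational intersection-over-union between bidirectional mask streams.

Forward and reverse video-object-segmentation passes label the same animals
independently, so label ``i`` in one stream need not be label ``i`` in the
other.  For ``n`` animals every bijection pi of ``{1..n}`` is a candidate
identity mapping; the combined IOU under pi is

    IOU_t(pi) = sum_i |F_i ∩ R_pi(i)|  /  sum_i |F_i ∪ R_pi(i)|

where ``F_i`` (``R_j``) is the forward (reverse) binary mask of animal ``i``
(``j``) at frame ``t``.  The maximising permutation is the *dominant mapping*
pi*_t; its trajectory through time is the raw material for zone-of-disagreement
detection.  For two animals the pair (IOU under identity, IOU under the flip)
collapses into a single framewise quality score with a flip-aware suppression
term that zeroes the score around curve crossings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "permutations",
    "pairwise_overlap",
    "combined_iou",
    "iou_series",
    "IOUSeries",
    "quality_scores",
    "QualityScoreSeries",
]

#: practical upper bound on animals (n! permutations are enumerated densely)
MAX_ANIMALS = 6


def permutations(n: int) -> list[tuple[int, ...]]:
    """All n! identity mappings of labels ``{1..n}``, lexicographically ordered.

    Position ``i`` (0-based) of a mapping gives the reverse-stream label
    matched to forward-stream label ``i + 1``.  The identity mapping is
    always first.
    """
    if n < 1:
        raise ValueError(f"need at least one animal, got n={n}")
    if n > MAX_ANIMALS:
        raise ValueError(f"n={n} exceeds supported maximum of {MAX_ANIMALS}")
    return list(itertools.permutations(range(1, n + 1)))


def pairwise_overlap(
    fwd: np.ndarray, rev: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-label overlap table between two label images.

    Returns ``(inter, area_f, area_r)`` where ``inter[i, j]`` is the pixel
    count of forward label ``i+1`` intersected with reverse label ``j+1`` and
    the area vectors hold per-label pixel counts.  One joint ``bincount``
    serves all n! permutations.
    """
    if fwd.shape != rev.shape:
        raise ValueError(f"frame shapes differ: {fwd.shape} vs {rev.shape}")
    joint = fwd.astype(np.int64).ravel() * (n + 1) + rev.astype(np.int64).ravel()
    counts = np.bincount(joint, minlength=(n + 1) ** 2).reshape(n + 1, n + 1)
    area_f = counts.sum(axis=1)[1:]
    area_r = counts.sum(axis=0)[1:]
    return counts[1:, 1:], area_f, area_r


def combined_iou(
    fwd: np.ndarray, rev: np.ndarray, perm: Sequence[int]
) -> tuple[float, bool]:
    """Combined IOU of two label images under one identity mapping.

    Sums per-animal intersections and divides by the summed unions.  When
    every mask is empty in both images the union is zero; that frame is
    *degenerate* and scored 1.0 (perfect agreement on absence) with the
    degenerate flag set so downstream consumers can audit it.

    Returns ``(value, degenerate)``.
    """
    n = len(perm)
    inter, area_f, area_r = pairwise_overlap(fwd, rev, n)
    idx = np.asarray(perm, dtype=np.intp) - 1
    num = inter[np.arange(n), idx].sum()
    den = (area_f + area_r[idx]).sum() - num
    if den == 0:
        return 1.0, True
    return float(num) / float(den), False


@dataclass
class IOUSeries:
    """Per-frame combined IOU over every permutation, plus the dominant mapping.

    ``values[t, k]`` is IOU_t of ``perms[k]``; permutations are stored in
    lexicographic order so ``perms[0]`` is always the identity.  The dominant
    index is the argmax with lexicographic tie-breaking (ties therefore favour
    the identity mapping when it participates); exact ties raise the ``tie``
    flag, all-empty frames the ``degenerate`` flag.
    """

    values: np.ndarray            # (T, n!) float
    perms: list[tuple[int, ...]]
    dominant_index: np.ndarray    # (T,) intp
    tie: np.ndarray               # (T,) bool
    degenerate: np.ndarray        # (T,) bool
    n_animals: int
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.perms):
            raise ValueError("values must be (T, n!) matching perms")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def dominant_value(self) -> np.ndarray:
        """Framewise IOU of the dominant mapping, shape (T,)."""
        return self.values[np.arange(len(self)), self.dominant_index]

    @property
    def dominant_perms(self) -> list[tuple[int, ...]]:
        return [self.perms[k] for k in self.dominant_index]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"frame": np.arange(len(self)) + self.frame_offset}
        for k, p in enumerate(self.perms):
            cols["iou_" + "".join(map(str, p))] = self.values[:, k]
        cols["dominant"] = ["".join(map(str, p)) for p in self.dominant_perms]
        cols["dominant_value"] = self.dominant_value
        cols["tie"] = self.tie
        cols["degenerate"] = self.degenerate
        return pd.DataFrame(cols)


def iou_series(fwd, rev) -> IOUSeries:
    """Combined IOU of every permutation at every frame of two mask streams.

    ``fwd`` and ``rev`` are :class:`~bivos.mask_io.MaskStream` objects (or any
    objects with ``frames`` and ``n_animals``) of equal length, shape and
    animal count.
    """
    if fwd.n_animals != rev.n_animals:
        raise ValueError("streams disagree on n_animals")
    if len(fwd.frames) != len(rev.frames):
        raise ValueError(
            f"stream length mismatch: {len(fwd.frames)} vs {len(rev.frames)}"
        )
    n = fwd.n_animals
    perms = permutations(n)
    idx = np.asarray(perms, dtype=np.intp) - 1   # (n!, n)
    T = len(fwd.frames)
    values = np.empty((T, len(perms)))
    degenerate = np.zeros(T, dtype=bool)
    rng_n = np.arange(n)
    for t in range(T):
        inter, area_f, area_r = pairwise_overlap(fwd.frames[t], rev.frames[t], n)
        num = inter[rng_n, idx].sum(axis=1)                  # (n!,)
        den = (area_f[rng_n] + area_r[idx]).sum(axis=1) - num
        if area_f.sum() == 0 and area_r.sum() == 0:
            values[t] = 1.0
            degenerate[t] = True
        else:
            # den == 0 for a permutation only if all masks empty, handled above
            values[t] = num / den
    dominant = values.argmax(axis=1)  # first max = lexicographically smallest
    maxval = values[np.arange(T), dominant]
    tie = (values == maxval[:, None]).sum(axis=1) > 1
    offset = getattr(fwd, "frame_offset", 0)
    return IOUSeries(values, perms, dominant.astype(np.intp), tie, degenerate,
                     n, frame_offset=offset)


@dataclass
class QualityScoreSeries:
    """Two-animal framewise quality score Q_t with its suppression term chi_t.

    Q_t = chi_t * |IOU_t(identity) - IOU_t(flip)| where chi_t is 1 only when
    the ordering of the two IOU curves is the same at t-1, t and t+1
    (boundary frames consult their single existing neighbour).  An exact tie
    of the two curves counts as an ordering change on both sides, so the tied
    frame and its neighbours score 0.
    """

    q: np.ndarray          # (T,) float in [0, 1]
    chi: np.ndarray        # (T,) uint8
    iou_ident: np.ndarray  # (T,)
    iou_flip: np.ndarray   # (T,)
    frame_offset: int = 0

    def __len__(self) -> int:
        return self.q.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)) + self.frame_offset,
                "iou_ident": self.iou_ident,
                "iou_flip": self.iou_flip,
                "chi": self.chi,
                "quality": self.q,
            }
        )


def quality_scores(series: IOUSeries) -> QualityScoreSeries:
    """Flip-aware quality score for a two-animal IOU series.

    The score is high when one mapping dominates stably in both directions of
    time and is forced to zero on frames flanking a crossing of the identity
    and flip IOU curves — exactly where an identity mismatch may hide.
    """
    if series.n_animals != 2:
        raise ValueError(
            f"quality scores are defined for 2 animals, got {series.n_animals}"
        )
    ident = series.values[:, 0]
    flip = series.values[:, 1]
    d = ident - flip
    s = np.sign(d)
    T = len(d)
    chi = np.ones(T, dtype=np.uint8)
    chi[s == 0] = 0  # exact crossing: suppressed outright
    for t in range(T):
        if chi[t] == 0:
            continue
        left_ok = t == 0 or s[t - 1] == s[t]
        right_ok = t == T - 1 or s[t + 1] == s[t]
        if not (left_ok and right_ok):
            chi[t] = 0
    q = chi * np.abs(d)
    return QualityScoreSeries(q, chi, ident, flip, frame_offset=series.frame_offset)
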