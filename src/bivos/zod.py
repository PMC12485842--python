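"""Zones of disagreement: detection, ranking, and correction-effort accounting.

A ZOD is a frame interval where forward and reverse segmentations diverge and
human review is warranted.  Candidates come from two phases: (1) windows of
radius ``r`` around frames where the dominant permutation switches, and (2)
maximal runs where the dominant IOU falls below a threshold tau.  Candidates
from both phases are merged into disjoint, non-adjacent intervals, ranked by
the minimum quality score (two animals) or minimum dominant IOU (three or
more) inside each interval, and reviewed in ascending order of that minimum.

All intervals are half-open ``[start, end)`` in 0-based frame indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .iou import IOUSeries, QualityScoreSeries

__all__ = [
    "Interval",
    "ZOD",
    "EffortReport",
    "transition_intervals",
    "threshold_intervals",
    "merge_candidates",
    "rank_zods",
    "correction_effort",
]

#: default temporal window radius around a dominance transition (frames);
#: 0.5 s at the 50 fps acquisition rate this pipeline targets
DEFAULT_RADIUS = 25

#: default dominant-IOU review thresholds by animal count; the threshold must
#: rise with n because each animal contributes ~1/n of the total overlap
DEFAULT_TAU = {2: 0.5, 3: 0.8}


@dataclass(frozen=True)
class Interval:
    """Half-open frame interval ``[start, end)`` with its detection phase."""

    start: int
    end: int
    source: str = "transition"  # {"transition", "threshold", "merged"}

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class ZOD:
    """A ranked, optionally annotated zone of disagreement.

    ``q_min`` is the minimum of the ranking series (quality score for two
    animals, dominant IOU otherwise) over the interval.  Annotation fields are
    populated during review: which direction to keep (``forward``/``reverse``,
    or ``none`` for a double-garbage ZOD), an optional corrected permutation
    reassigning the kept direction's labels, and optional subdivisions, each
    itself an annotated :class:`ZOD` covering part of the parent interval.
    """

    interval: Interval
    q_min: float | None = None
    rank: int | None = None
    kept_direction: str | None = None          # {"forward", "reverse", "none"}
    corrected_permutation: list[int] | None = None
    subdivisions: list["ZOD"] | None = None

    def to_dict(self) -> dict:
        d = {
            "start": int(self.interval.start),
            "end": int(self.interval.end),
            "source": self.interval.source,
            "q_min": None if self.q_min is None else float(self.q_min),
            "rank": self.rank,
            "kept_direction": self.kept_direction,
            "corrected_permutation": self.corrected_permutation,
        }
        if self.subdivisions:
            d["subdivisions"] = [s.to_dict() for s in self.subdivisions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ZOD":
        return cls(
            interval=Interval(int(d["start"]), int(d["end"]),
                              d.get("source", "merged")),
            q_min=d.get("q_min"),
            rank=d.get("rank"),
            kept_direction=d.get("kept_direction"),
            corrected_permutation=d.get("corrected_permutation"),
            subdivisions=[cls.from_dict(s) for s in d["subdivisions"]]
            if d.get("subdivisions")
            else None,
        )


def _normalize(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and fuse overlapping or adjacent half-open intervals.

    Adjacent means a gap of exactly 0 frames (``a.end == b.start``); fused
    intervals inherit their common source, or ``merged`` when sources differ.
    """
    items = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    out: list[Interval] = []
    for iv in items:
        if out and iv.start <= out[-1].end:
            prev = out[-1]
            source = prev.source if prev.source == iv.source else "merged"
            out[-1] = Interval(prev.start, max(prev.end, iv.end), source)
        else:
            out.append(iv)
    return out


def transition_intervals(series: IOUSeries, r: int = DEFAULT_RADIUS) -> list[Interval]:
    """Phase 1: windows of radius ``r`` around dominant-permutation switches.

    Every frame ``t`` whose dominant mapping differs from frame ``t - 1``
    contributes the window ``[t - r, t + r + 1)`` clipped to the series;
    overlapping or adjacent windows are merged.
    """
    if r < 0:
        raise ValueError("radius must be nonnegative")
    T = len(series)
    dom = series.dominant_index
    switches = np.nonzero(dom[1:] != dom[:-1])[0] + 1
    windows = [
        Interval(max(0, int(t) - r), min(T, int(t) + r + 1), "transition")
        for t in switches
    ]
    return _normalize(windows)


def threshold_intervals(series: IOUSeries, tau: float) -> list[Interval]:
    """Phase 2: maximal runs of frames whose dominant IOU is below ``tau``.

    Catches bidirectional faults that never change the dominant mapping.  The
    comparison is strict (``< tau``).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    low = series.dominant_value < tau
    out: list[Interval] = []
    padded = np.diff(np.concatenate(([0], low.astype(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0]
    for s, e in zip(starts, ends):
        out.append(Interval(int(s), int(e), "threshold"))
    return out


def merge_candidates(
    a: Sequence[Interval], b: Sequence[Interval] = ()
) -> list[Interval]:
    """Consolidate the union of two candidate lists into disjoint intervals.

    Idempotent and commutative; output intervals are sorted, pairwise
    disjoint, and separated by at least one frame.
    """
    return _normalize(list(a) + list(b))


def _ranking_values(quality) -> np.ndarray:
    if isinstance(quality, QualityScoreSeries):
        return quality.q
    if isinstance(quality, IOUSeries):
        return quality.dominant_value
    return np.asarray(quality, dtype=float)


def rank_zods(candidates: Sequence[Interval], quality) -> list[ZOD]:
    """Attach per-interval minima and rank ZODs ascending by that minimum.

    ``quality`` is a :class:`QualityScoreSeries` (two animals), an
    :class:`IOUSeries` (ranking by minimum dominant IOU), or a plain array.
    Ties are broken by start frame; ranks are 1-based.
    """
    values = _ranking_values(quality)
    T = values.shape[0]
    zods = []
    for iv in candidates:
        if iv.end > T:
            raise ValueError(f"interval [{iv.start}, {iv.end}) exceeds series length {T}")
        zods.append(ZOD(interval=iv, q_min=float(values[iv.start : iv.end].min())))
    zods.sort(key=lambda z: (z.q_min, z.interval.start))
    for i, z in enumerate(zods, start=1):
        z.rank = i
    return zods


@dataclass
class EffortReport:
    """Cumulative review effort against swap discovery over a ZOD ranking.

    ``frames_reviewed[k]`` is the total frame count of the first ``k + 1``
    ranked ZODs; ``discovery_fraction[k]`` the fraction of ground-truth swap
    intervals overlapped by at least one of them.  ``n_star_all`` is the
    minimal review depth capturing every swap (0 when there are none);
    ``n_star_half`` counts ZODs whose minimum score does not exceed 0.5, the
    review criterion under which no real swap was ever missed.
    """

    frames_reviewed: np.ndarray      # (m,) cumulative
    discovery_fraction: np.ndarray   # (m,) in [0, 1]
    n_star_all: int
    n_star_half: int
    frames_at_all: int
    frames_at_half: int

    def to_dataframe(self) -> pd.DataFrame:
        m = len(self.frames_reviewed)
        return pd.DataFrame(
            {
                "n_zods": np.arange(1, m + 1),
                "frames_reviewed": self.frames_reviewed,
                "discovery_fraction": self.discovery_fraction,
            }
        )


def correction_effort(
    ranked: Sequence[ZOD],
    swap_intervals: Sequence[Interval],
    half_threshold: float = 0.5,
) -> EffortReport:
    """Quantify how much review the ranking demands before all swaps surface.

    A swap interval counts as discovered once it overlaps any reviewed ZOD.
    ``frames_at_all``/``frames_at_half`` are the cumulative frames at the
    all-swaps and score-threshold stopping criteria respectively.
    """
    m = len(ranked)
    lengths = np.array([len(z.interval) for z in ranked], dtype=np.int64)
    frames = np.cumsum(lengths) if m else np.zeros(0, dtype=np.int64)
    k = len(swap_intervals)
    found = np.zeros(k, dtype=bool)
    discovery = np.zeros(m)
    n_star_all = 0
    for i, z in enumerate(ranked):
        for j, sw in enumerate(swap_intervals):
            if not found[j] and z.interval.overlaps(sw):
                found[j] = True
        discovery[i] = found.mean() if k else 1.0
        if k and found.all() and n_star_all == 0:
            n_star_all = i + 1
    if k and not found.all():
        n_star_all = -1  # ranking never covers every swap
    n_star_half = int(sum(1 for z in ranked if z.q_min is not None
                          and z.q_min <= half_threshold))
    frames_at_all = int(frames[n_star_all - 1]) if n_star_all > 0 else 0
    frames_at_half = int(frames[n_star_half - 1]) if n_star_half > 0 else 0
    return EffortReport(
        frames_reviewed=frames,
        discovery_fraction=discovery,
        n_star_all=n_star_all,
        n_star_half=n_star_half,
        frames_at_all=frames_at_all,
        frames_at_half=frames_at_half,
    )
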