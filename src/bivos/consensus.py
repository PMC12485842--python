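"""Consensus mask assembly from annotated ZODs and cross-segment stitching.

Outside any ZOD the two inference directions agree up to pixel noise, so the
consensus simply takes the configured default direction.  Inside a ZOD the
annotated direction is kept, after applying the reviewer's corrected
permutation to its labels; a double-garbage ZOD (both directions rejected)
yields all-background frames with provenance ``none`` so the time axis stays
intact for keypoint alignment.

Long recordings are segmented for inference, with consecutive segments
overlapping on exactly one boundary keyframe.  Stitching resolves each
junction by choosing the label permutation that maximises summed pixelwise
intersection on the shared frame, composing relabelings across junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .iou import pairwise_overlap, permutations
from .mask_io import MaskStream
from .zod import Interval, ZOD

__all__ = [
    "ConsensusStream",
    "UnstitchableJunctionError",
    "apply_label_permutation",
    "assemble_consensus",
    "stitch_segments",
]

PROVENANCE_CODES = {"forward": 0, "reverse": 1, "none": 2}
PROVENANCE_NAMES = {v: k for k, v in PROVENANCE_CODES.items()}


class UnstitchableJunctionError(RuntimeError):
    """No label permutation yields any pixel intersection on a shared frame."""


@dataclass
class ConsensusStream:
    """An identity-validated mask stream with per-frame provenance.

    ``provenance`` codes which direction each frame came from (0 forward,
    1 reverse, 2 none); ``gaps`` lists the double-garbage intervals, whose
    frames are all-background.
    """

    frames: np.ndarray
    n_animals: int
    provenance: np.ndarray
    gaps: list[Interval] = field(default_factory=list)
    frame_offset: int = 0
    scale: int = 1

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.frames):
            raise ValueError("provenance must have one entry per frame")

    def __len__(self) -> int:
        return len(self.frames)

    def provenance_names(self) -> list[str]:
        return [PROVENANCE_NAMES[int(c)] for c in self.provenance]

    def to_mask_stream(self, direction: str = "forward") -> MaskStream:
        return MaskStream(
            self.frames.copy(), self.n_animals, direction,
            self.frame_offset, self.scale,
        )


def apply_label_permutation(frames: np.ndarray, perm: Sequence[int]) -> np.ndarray:
    """Relabel animal pixels: label ``i`` becomes ``perm[i-1]``; background fixed."""
    perm = list(perm)
    n = len(perm)
    if sorted(perm) != list(range(1, n + 1)):
        raise ValueError(f"corrected permutation {perm} is not a bijection of 1..{n}")
    lut = np.zeros(n + 1, dtype=frames.dtype)
    lut[1:] = perm
    return lut[frames]


def _paint(out_frames, out_prov, gaps, interval, fwd, rev, zod):
    """Apply one annotation (a ZOD or a subdivision) to the output arrays."""
    kept = zod.kept_direction
    if kept is None:
        raise ValueError(
            f"ZOD [{interval.start}, {interval.end}) has no annotation; "
            "every ZOD must be reviewed before consensus assembly"
        )
    sl = slice(interval.start, interval.end)
    if kept == "none":
        out_frames[sl] = 0
        out_prov[sl] = PROVENANCE_CODES["none"]
        gaps.append(Interval(interval.start, interval.end, interval.source))
        return
    if kept not in ("forward", "reverse"):
        raise ValueError(f"unknown kept_direction {kept!r}")
    src = fwd if kept == "forward" else rev
    chunk = src.frames[sl]
    if zod.corrected_permutation is not None:
        chunk = apply_label_permutation(chunk, zod.corrected_permutation)
    out_frames[sl] = chunk
    out_prov[sl] = PROVENANCE_CODES[kept]


def assemble_consensus(
    fwd: MaskStream,
    rev: MaskStream,
    zods: Sequence[ZOD],
    default_direction: str = "forward",
) -> ConsensusStream:
    """Assemble the identity-validated consensus stream.

    Non-ZOD frames come from ``default_direction`` (the directions are
    interchangeable there); each annotated ZOD contributes the kept
    direction's frames with its corrected permutation applied, subdivided
    ZODs being honoured per subdivision (each subdivision independent); a
    double-garbage ZOD contributes background-only frames with provenance
    ``none``.
    """
    if len(fwd) != len(rev) or fwd.shape != rev.shape:
        raise ValueError("forward and reverse streams must match in length and shape")
    if fwd.n_animals != rev.n_animals:
        raise ValueError("streams disagree on n_animals")
    if default_direction not in ("forward", "reverse"):
        raise ValueError(f"default_direction must be forward or reverse")
    base = fwd if default_direction == "forward" else rev
    out_frames = base.frames.copy()
    out_prov = np.full(len(base), PROVENANCE_CODES[default_direction], dtype=np.uint8)
    gaps: list[Interval] = []
    for zod in zods:
        if zod.interval.end > len(base):
            raise ValueError(
                f"ZOD [{zod.interval.start}, {zod.interval.end}) exceeds "
                f"stream length {len(base)}"
            )
        if zod.subdivisions:
            for sub in zod.subdivisions:
                _paint(out_frames, out_prov, gaps, sub.interval, fwd, rev, sub)
        else:
            _paint(out_frames, out_prov, gaps, zod.interval, fwd, rev, zod)
    return ConsensusStream(
        frames=out_frames,
        n_animals=fwd.n_animals,
        provenance=out_prov,
        gaps=sorted(gaps, key=lambda iv: iv.start),
        frame_offset=fwd.frame_offset,
        scale=fwd.scale,
    )


def stitch_segments(segments: Sequence[MaskStream]) -> MaskStream:
    """Concatenate inference segments that overlap on one boundary keyframe.

    At each junction the shared frame appears as the last frame of one
    segment and the first of the next; the label permutation maximising the
    summed pixel intersection between the two renderings of that frame is
    applied to the whole later segment, so relabelings compose across
    junctions.  The overlap frame is emitted once.  A junction where every
    permutation yields zero intersection is unstitchable.
    """
    if not segments:
        raise ValueError("no segments to stitch")
    n = segments[0].n_animals
    for s in segments[1:]:
        if s.n_animals != n:
            raise ValueError("segments disagree on n_animals")
        if s.shape != segments[0].shape:
            raise ValueError("segments disagree on frame shape")
    perms = permutations(n)
    idx = np.asarray(perms, dtype=np.intp) - 1
    rng_n = np.arange(n)
    out = [segments[0].frames]
    last_frame = segments[0].frames[-1]
    for k, seg in enumerate(segments[1:], start=1):
        inter, _, _ = pairwise_overlap(last_frame, seg.frames[0], n)
        # inter[i, j]: stitched label i+1 vs raw next-segment label j+1.
        # A candidate relabeling perm sends raw label p -> perm[p-1]; its
        # score is sum_i inter[i, perm^{-1}(i)] which equals indexing columns
        # by the permutation positions below.
        scores = inter[idx, rng_n].sum(axis=1)
        best = int(np.argmax(scores))
        if scores[best] == 0:
            raise UnstitchableJunctionError(
                f"junction {k}: no permutation overlaps on the shared frame"
            )
        relabeled = apply_label_permutation(seg.frames, perms[best])
        out.append(relabeled[1:])  # shared frame emitted once
        last_frame = relabeled[-1]
    first = segments[0]
    return MaskStream(
        np.concatenate(out, axis=0),
        n_animals=n,
        direction=first.direction,
        frame_offset=first.frame_offset,
        scale=first.scale,
    )
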