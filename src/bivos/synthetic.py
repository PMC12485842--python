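"""Synthetic behavioral scenes with injected segmentation failure modes.

Every downstream stage — permutational IOU, ZOD detection, consensus
assembly, keypoint alignment — is exercised against scenes generated here, in
place of the neural segmentation and pose networks.  Animals are axis-aligned
filled ellipses performing a reflected random walk inside a rectangular
arena, with a fixed body-relative keypoint template guaranteed to land inside
each animal's mask.  Forward and reverse "inference" streams are copies of the
ground truth with faults injected per direction:

* ``swap`` — a persistent relabeling of a pair of animals from a frame
  onward, mirroring how history-dependent VOS errors propagate;
* ``merged_mask`` — one animal's pixels temporarily absorbed into another's
  label, the other mask disappearing;
* ``partial_loss`` — a random fraction of one animal's pixels deleted.

The canned bidirectional scenarios reproduce the failure-mode taxonomy of
interest: a swap in one direction only (an X-shaped IOU crossing, trivially
detectable), the same swap in both directions offset by a frame (detectable
at exactly the offset frames), and the same swap synchronously in both
directions (invisible to stream comparison — the documented detection limit).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .mask_io import KeypointSet, MaskStream
import pandas as pd

__all__ = [
    "SceneSpec",
    "FaultEvent",
    "FaultPlan",
    "generate_scene",
    "apply_faults",
    "make_bidirectional_case",
    "annotations_from_fault_log",
]

SCENARIOS = ("clean", "unidirectional", "offset_bidirectional",
             "synchronous_symmetric")

#: body-relative keypoint template (fractions of the two semi-axes); nine
#: points mimicking a nose-spine-flanks-rump rodent skeleton, all strictly
#: interior to the unit ellipse
_KP_TEMPLATE = np.array(
    [
        (0.0, 0.0),      # body centre
        (0.8, 0.0),      # nose
        (0.45, 0.35),    # right ear
        (0.45, -0.35),   # left ear
        (0.4, 0.0),      # spine 1
        (-0.4, 0.0),     # spine 3
        (0.0, 0.55),     # right flank
        (0.0, -0.55),    # left flank
        (-0.8, 0.0),     # rump
    ]
)


@dataclass
class SceneSpec:
    """Parameters of a synthetic arena scene.

    The defaults emulate a desk-scale version of a top-view rodent dyad
    recording: two animals of roughly 1/10 arena-width body size moving a few
    pixels per frame, never touching (``min_separation`` is a hard Chebyshev
    gap between masks, in pixels).
    """

    n_animals: int = 2
    n_frames: int = 100
    height: int = 96
    width: int = 128
    radius_range: tuple[float, float] = (6.0, 10.0)
    step_std: float = 2.0
    min_separation: int = 3
    keypoints_per_animal: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("a scene needs at least 2 frames")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be positive and ordered")
        if self.min_separation < 0:
            raise ValueError("min_separation must be nonnegative")
        if not 1 <= self.keypoints_per_animal <= len(_KP_TEMPLATE):
            raise ValueError(
                f"keypoints_per_animal must be in 1..{len(_KP_TEMPLATE)}"
            )


@dataclass(frozen=True)
class FaultEvent:
    """One injected failure.

    ``pair`` is the ordered pair of animal labels involved (for ``swap`` and
    ``merged_mask``; ``partial_loss`` uses only ``pair[0]``).  ``offset`` is
    the inter-direction frame offset for bidirectional swaps.  ``duration``
    is the span in frames of ``merged_mask``/``partial_loss`` events (swaps
    are persistent and ignore it).  ``magnitude`` is the pixel fraction
    removed by ``partial_loss``.
    """

    kind: Literal["swap", "merged_mask", "partial_loss"]
    direction: Literal["forward", "reverse", "both"]
    t0: int
    pair: tuple[int, int] = (1, 2)
    offset: int = 0
    duration: int = 1
    magnitude: float = 0.5

    def __post_init__(self) -> None:
        if self.t0 < 0:
            raise ValueError("event frame must be nonnegative")
        if self.kind in ("swap", "merged_mask") and self.pair[0] == self.pair[1]:
            raise ValueError("fault pair must name two distinct animals")
        if self.offset < 0:
            raise ValueError("offset must be nonnegative")
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("magnitude must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FaultPlan:
    """A list of fault events plus the seed for their internal randomness."""

    events: list[FaultEvent] = field(default_factory=list)
    seed: int = 0


# ---------------------------------------------------------------------------
# scene generation

_MAX_RETRIES = 200


def _ellipse_mask(h, w, cy, cx, ry, rx) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _bbox_gap_ok(centers, radii, min_sep) -> bool:
    """Chebyshev gap between axis-aligned bounding boxes >= min_sep for all pairs.

    The Chebyshev distance between two pixel sets is at least the Chebyshev
    gap of their bounding boxes, so enforcing the box gap enforces the mask
    gap (checked exhaustively in tests).
    """
    n = len(centers)
    for i in range(n):
        for j in range(i + 1, n):
            dy = abs(centers[i][0] - centers[j][0]) - (radii[i][0] + radii[j][0])
            dx = abs(centers[i][1] - centers[j][1]) - (radii[i][1] + radii[j][1])
            if max(dy, dx) < min_sep + 1:
                return False
    return True


def generate_scene(spec: SceneSpec) -> tuple[MaskStream, KeypointSet]:
    """Generate a ground-truth mask stream and matching keypoint set.

    Deterministic given ``spec.seed``.  Every animal is a connected (filled
    ellipse) region; pairwise mask separation honours ``min_separation`` in
    every frame; every keypoint lies strictly inside its own animal's mask
    and is valid.  Raises ``RuntimeError`` if the requested packing cannot be
    realised within a bounded number of placement retries.
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_animals, spec.n_frames
    h, w = spec.height, spec.width
    radii = [
        (rng.uniform(*spec.radius_range), rng.uniform(*spec.radius_range))
        for _ in range(n)
    ]
    margin = [(ry + 1, rx + 1) for ry, rx in radii]

    def feasible(centers):
        return _bbox_gap_ok(centers, radii, spec.min_separation)

    for i in range(n):
        if margin[i][0] >= h - 1 - margin[i][0] or margin[i][1] >= w - 1 - margin[i][1]:
            raise RuntimeError(
                f"could not place {n} animals of radius up to "
                f"{spec.radius_range[1]} in a {h}x{w} arena"
            )

    # initial placement by rejection
    for _ in range(_MAX_RETRIES):
        centers = [
            (
                rng.uniform(margin[i][0], h - 1 - margin[i][0]),
                rng.uniform(margin[i][1], w - 1 - margin[i][1]),
            )
            for i in range(n)
        ]
        if feasible(centers):
            break
    else:
        raise RuntimeError(
            f"could not place {n} animals with separation "
            f"{spec.min_separation} in a {h}x{w} arena"
        )

    frames = np.zeros((T, h, w), dtype=np.uint8)
    kp_rows = []
    k = spec.keypoints_per_animal
    template = _KP_TEMPLATE[:k]
    trajectory = []
    for t in range(T):
        if t > 0:
            # propose reflected random-walk steps until separation holds
            prev = centers
            for _ in range(_MAX_RETRIES):
                proposal = []
                for i, (cy, cx) in enumerate(prev):
                    ny = cy + rng.normal(0.0, spec.step_std)
                    nx = cx + rng.normal(0.0, spec.step_std)
                    lo_y, hi_y = margin[i][0], h - 1 - margin[i][0]
                    lo_x, hi_x = margin[i][1], w - 1 - margin[i][1]
                    ny = _reflect(ny, lo_y, hi_y)
                    nx = _reflect(nx, lo_x, hi_x)
                    proposal.append((ny, nx))
                if feasible(proposal):
                    centers = proposal
                    break
            else:
                centers = prev  # animals pause rather than violate separation
        trajectory.append(list(centers))
        for i in range(n):
            cy, cx = centers[i]
            ry, rx = radii[i]
            frames[t][_ellipse_mask(h, w, cy, cx, ry, rx)] = i + 1
            pts_y = cy + template[:, 1] * ry
            pts_x = cx + template[:, 0] * rx
            for kk in range(k):
                kp_rows.append(
                    (t, i + 1, kk + 1, float(pts_x[kk]), float(pts_y[kk]))
                )

    truth = MaskStream(frames, n_animals=n, direction="forward")
    records = pd.DataFrame(
        kp_rows, columns=["frame", "track", "keypoint", "x", "y"]
    )
    kps = KeypointSet(records=records, n_tracks=n, n_keypoints=k, scale=1)
    return truth, kps


def _reflect(v: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return (lo + hi) / 2.0
    span = hi - lo
    v = (v - lo) % (2 * span)
    return lo + (span - abs(v - span))


# ---------------------------------------------------------------------------
# fault injection


def apply_faults(
    truth: MaskStream, plan: FaultPlan, direction: str
) -> MaskStream:
    """Derive one direction's (faulty) inference stream from the ground truth.

    Only events targeting ``direction`` (or ``both``) are applied; for
    bidirectional swaps the reverse stream swaps ``offset`` frames later than
    the forward stream.  The truth stream is never mutated.
    """
    frames = truth.frames.copy()
    T = len(frames)
    rng = np.random.default_rng(plan.seed)
    for ev in plan.events:
        if ev.direction not in ("both", direction):
            continue
        t0 = ev.t0
        if ev.kind == "swap" and ev.direction == "both" and direction == "reverse":
            t0 = ev.t0 + ev.offset
        if not 0 <= t0 < T:
            raise ValueError(f"fault frame {t0} outside stream of length {T}")
        if ev.kind == "swap":
            i, j = ev.pair
            _relabel_pair(frames, t0, T, i, j)
        elif ev.kind == "merged_mask":
            i, j = ev.pair
            span = slice(t0, min(T, t0 + ev.duration))
            sub = frames[span]
            sub[sub == i] = j   # animal i absorbed into animal j's mask
        elif ev.kind == "partial_loss":
            a = ev.pair[0]
            for t in range(t0, min(T, t0 + ev.duration)):
                pix = np.flatnonzero(frames[t] == a)
                n_drop = int(round(ev.magnitude * pix.size))
                drop = rng.choice(pix.size, size=n_drop, replace=False)
                flat = frames[t].ravel()
                flat[pix[drop]] = 0
        else:
            raise ValueError(f"unknown fault kind {ev.kind!r}")
    return MaskStream(
        frames, n_animals=truth.n_animals, direction=direction,
        frame_offset=truth.frame_offset, scale=truth.scale,
    )


def _relabel_pair(frames: np.ndarray, t0: int, t1: int, i: int, j: int) -> None:
    sub = frames[t0:t1]
    mi = sub == i
    mj = sub == j
    sub[mi] = j
    sub[mj] = i


# ---------------------------------------------------------------------------
# canned bidirectional scenarios


def make_bidirectional_case(
    spec: SceneSpec,
    scenario: str,
    swap_frame: int | None = None,
    offset: int = 1,
    pair: tuple[int, int] = (1, 2),
    fault_seed: int = 0,
) -> tuple[MaskStream, MaskStream, MaskStream, dict]:
    """Build a (forward, reverse, truth, fault_log) quadruple for one scenario.

    ``clean``: both streams equal the truth.  ``unidirectional``: the forward
    stream carries one persistent swap.  ``offset_bidirectional``: both
    streams carry the same swap, the reverse one ``offset`` frames later, so
    the streams disagree on exactly ``offset`` frames.
    ``synchronous_symmetric``: both streams swap the same pair on the same
    frame — zero disagreement frames despite both differing from truth, the
    scenario stream comparison cannot detect.

    The fault log records scenario, seeds, events, and per-direction
    ground-truth swap frames for downstream evaluation.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    truth, kps = generate_scene(spec)
    T = spec.n_frames
    if swap_frame is None:
        swap_frame = T // 2
    events: list[FaultEvent] = []
    swap_frames: dict[str, list[int]] = {"forward": [], "reverse": []}
    if scenario == "unidirectional":
        events.append(FaultEvent("swap", "forward", swap_frame, pair))
        swap_frames["forward"] = [swap_frame]
    elif scenario == "offset_bidirectional":
        events.append(FaultEvent("swap", "both", swap_frame, pair, offset=offset))
        swap_frames["forward"] = [swap_frame]
        swap_frames["reverse"] = [swap_frame + offset]
    elif scenario == "synchronous_symmetric":
        events.append(FaultEvent("swap", "both", swap_frame, pair, offset=0))
        swap_frames["forward"] = [swap_frame]
        swap_frames["reverse"] = [swap_frame]
    plan = FaultPlan(events=events, seed=fault_seed)
    fwd = apply_faults(truth, plan, "forward")
    rev = apply_faults(truth, plan, "reverse")
    log = {
        "scenario": scenario,
        "scene_seed": spec.seed,
        "fault_seed": fault_seed,
        "n_frames": T,
        "pair": list(pair),
        "offset": offset if scenario == "offset_bidirectional" else 0,
        "events": [ev.to_dict() for ev in events],
        "swap_frames": swap_frames,
    }
    return fwd, rev, truth, log


def annotations_from_fault_log(log: dict, n_frames: int) -> list:
    """Reviewer-style annotations that resolve a scenario's swaps exactly.

    Swaps are persistent, so the corrective annotation spans from the first
    swap frame to the end of the clip (the reviewer's boundary refinement).
    For a unidirectional swap the clean direction is kept; when both
    directions end up swapped (offset or synchronous case) the forward
    direction is kept with the corrected permutation that undoes the swap.
    Returns a list of :class:`bivos.zod.ZOD` suitable for consensus assembly;
    empty for a clean scenario.
    """
    from .zod import Interval, ZOD

    scenario = log["scenario"]
    if scenario == "clean":
        return []
    i, j = log["pair"]
    t_f = log["swap_frames"]["forward"][0]
    n = max(i, j)
    corrected = list(range(1, n + 1))
    corrected[i - 1], corrected[j - 1] = j, i
    if scenario == "unidirectional":
        return [
            ZOD(Interval(t_f, n_frames, "merged"), kept_direction="reverse")
        ]
    if scenario == "offset_bidirectional":
        # forward is swapped from t_f on; undo it there and keep forward
        return [
            ZOD(
                Interval(t_f, n_frames, "merged"),
                kept_direction="forward",
                corrected_permutation=corrected,
            )
        ]
    # synchronous_symmetric: stream comparison cannot localize it, but given
    # the log the honest fix is the same forward-correction
    return [
        ZOD(
            Interval(t_f, n_frames, "merged"),
            kept_direction="forward",
            corrected_permutation=corrected,
        )
    ]
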