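# Methods

## Setting and assumptions

The package operates on two label-image streams covering the same video
clip: a forward segmentation pass seeded at the clip's first keyframe and a
reverse pass seeded at its last, each assigning every pixel to background
(0) or one of `n` animals (`1..n`). The central assumption is *directional
independence*: because the two passes start from different prompts and
traverse memory in opposite orders, their (rare) errors almost never
coincide in time and form. Everything downstream — disagreement detection,
consensus assembly, keypoint alignment — rests on that assumption, and the
one failure mode that violates it (the same pairwise swap occurring on the
same frame in both directions) is undetectable by construction; the
synthetic suite asserts this limit rather than hiding it.

Frames are indexed from 0 and all intervals are half-open `[start, end)`.
Reverse-direction files may be stored back-to-front; I/O normalizes them to
forward temporal order and records the stored order as provenance.

## Permutational IOU and the dominant mapping

For each frame and each of the `n!` permutations π, the combined IOU sums
per-animal intersections and divides by the summed unions. It is computed
from a single `(n+1)×(n+1)` joint label histogram per frame, so all
permutations share one pass over the pixels; a per-pixel brute-force oracle
verifies the vectorized computation in the tests.

Degenerate frames (every mask empty in both directions) are defined to have
IOU 1.0 — agreement on absence — with a `degenerate` flag so consumers can
audit them; this avoids NaN propagation without hiding the condition.

The dominant mapping is the argmax over permutations. Exact ties are broken
toward the lexicographically smallest permutation (which is always the
identity when it participates) and flagged, making outputs deterministic and
insensitive to enumeration order.

## Two-animal quality score

With only two permutations the series collapses to
`Q_t = χ_t · |IOU_t(π_ident) − IOU_t(π_flip)|`. The suppression term χ
zeroes frames at and adjacent to a reversal of the curves' ordering — a
swap in one direction produces an X-shaped crossing, and the crossing frames
are exactly where identity is unreliable. Numerical choices:

- an exact tie of the two IOUs counts as an ordering change on both sides,
  so the tied frame and both neighbors score 0 (conservative flagging);
- boundary frames consult only their existing neighbor;
- the suppression window is the immediate neighbors (width 1 per side).

## ZOD detection, ranking, and effort

Phase 1 flags a window of radius `r` (default 25 frames, i.e. 0.5 s at the
50 fps acquisition rate this pipeline targets) around every change of the
dominant mapping. Phase 2 flags maximal runs where the dominant IOU falls
strictly below τ, catching bidirectional faults that never change the
argmax. Defaults: τ = 0.5 for two animals and 0.8 for three; τ must rise
with `n` because each animal contributes roughly `1/n` of the total overlap,
so a single-animal fault moves the combined IOU less. Candidates from both
phases are merged; "adjacent" means a gap of exactly zero frames between
half-open intervals, so distinct events separated by even one good frame
stay distinct.

ZODs are ranked ascending by the minimum quality score (two animals) or
minimum dominant IOU (`n ≥ 3`) over the interval, ties broken by start
frame. Correction effort is accounted both in ZODs reviewed and frames
reviewed, with two stopping criteria: all known swaps discovered (a swap
interval counts as discovered once it overlaps any reviewed ZOD), and all
ZODs with minimum score ≤ 0.5 reviewed. Manual boundary refinement of a ZOD
is represented as an annotation edit, not an algorithm.

## Consensus assembly

Outside ZODs the directions are interchangeable; the assembler takes a
configurable default (forward) for determinism. Inside a ZOD the annotated
direction is kept and the reviewer's corrected permutation, if any, is
applied to its labels (label `i` becomes `π[i]`). Sub-divided ZODs are
honored per subdivision, each independent. Double-garbage ZODs emit
all-background frames with provenance `none` rather than dropping frames,
keeping the time axis intact for alignment. Because injected swaps are
*persistent* relabelings (mirroring history-dependent VOS error
propagation), a correct annotation spans from the swap frame to the end of
the clip; the synthetic module derives such annotations from its fault log.

Segment stitching generalizes the two-animal aligned-vs-flipped
intersection test to all `n!` permutations: at each one-frame overlap the
permutation maximizing summed pixelwise intersection is applied to the whole
later segment, and relabelings compose across junctions. A junction with
zero intersection under every permutation raises an error naming the
junction rather than guessing.

## Keypoint displacement and alignment

Displacement for track `a` over frame pair `(t, t+1)` is the mean Euclidean
motion of the keypoints valid (non-NaN, non-negative coordinates) in both
frames; it is undefined (NaN) when no shared valid keypoints exist. The
keypoint subset used for displacement and alignment is configurable because
some skeleton points (e.g. frequently occluded tail points) are too
unreliable to help.

Alignment uses `A_t(π) = Σ_x SC² / K` with per-animal masks dilated by a
Euclidean disk (default radius 5 px at mask scale) so boundary keypoints can
belong to several adjoining masks instead of being wrongly exclusive.
Keypoints at acquisition resolution are divided by the mask stream's
downsampling factor before lookup, rounded to the nearest pixel;
out-of-bounds points are misses. Tracks with no valid keypoints contribute 0
to every permutation's score; the frame degrades to `no_keypoints` only
when every track is empty. The non-definitive categories are `no_keypoints`,
`no_valid_masks` (consensus gap or fully empty frame), `zero_overlap`, and
`ambiguous` (tied argmax).

Swap detection compares each definitive frame's argmax with the most recent
definitive mapping. The event is localized to the current frame only when
the immediately preceding frame was definitive; otherwise the swap lies
somewhere in the preceding unalignable gap and the event is marked
unlocalized and excluded from localized-swap counts.

## Detector evaluation

Discovery curves sort items by suspicion (stable sort, ties in frame order,
undefined scores last) and accumulate the fraction of known swaps found.
AUROC uses the Mann–Whitney midrank formulation (ties credited ½) and is
verified against exhaustive pair counting. Swap rates are reported per
100,000 frames. The benchmark suite runs three detectors over shared
synthetic cases: the quality score (lower = suspect; its ground-truth labels
mark both frames flanking a mask-swap transition, since a swap between
`t−1` and `t` implicates both), keypoint displacement (higher = suspect;
undefined displacement encoded `+inf` because missing keypoints co-occur
with swaps), and a consensus-alignment detector (change of the resolved
keypoint-to-mask mapping across a frame pair).

## The synthetic generator

Animals are axis-aligned filled ellipses (semi-axes drawn once per animal
from 6–10 px) performing a reflected Gaussian random walk (step σ = 2 px per
frame) in a 96×128 arena, with a hard Chebyshev separation (default 3 px)
enforced through bounding-box gaps — a proposal violating separation is
re-drawn, and after bounded retries the animals pause for that frame. Nine
keypoints per animal follow a fixed body-relative template (center, nose,
ears, spine, flanks, rump) scaled to lie strictly inside the ellipse, so
alignment ground truth is exact by construction. Scene and fault randomness
use separate seeds, both recorded in the fault log.

What the generator deliberately does *not* emulate: occlusion and mask
overlap during contact, deformable bodies, segmentation jitter at mask
boundaries, and keypoint detection noise. Passing tests therefore
demonstrate the correctness of the comparison/consensus/alignment machinery
under its stated assumptions (disjoint, well-formed masks), not the
segmentation network's behavior during prolonged physical contact — on real
data those regimes are precisely where ZODs concentrate and human review
remains necessary.

Problem sizes in the test and acceptance suites (20–100-frame scenes,
64×80 to 96×128 arenas, up to 50 seeded cases per property) were chosen as
the smallest scales at which every checked property is exact and
non-trivial; all fixtures are generated programmatically at run time.

## Known limitations

- The synchronous symmetric swap (same pair, same frame, both directions)
  is undetectable from stream comparison; the suite asserts the failure
  mode rather than claiming otherwise.
- Quality-score ranking applies only to `n = 2`; for `n ≥ 3` ZODs rank by
  minimum dominant IOU, and the threshold τ must be raised as `n` grows.
- Permutation enumeration is dense (`n!`), practical to `n = 6`.
- Automatic ZOD boundary refinement and annotation-free resolution are out
  of scope by design: the pipeline optimizes *where* humans look, not
  whether they look.
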