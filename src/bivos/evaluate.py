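"""Swap-detector scoring: discovery curves, AUROC, swap rates, benchmarks.

A swap detector assigns each frame (or adjacent frame pair) a suspicion
score; ground truth labels which items actually contain an identity swap.
Two complementary views are computed: the discovery curve (cumulative
fraction of known swaps found after reviewing the top-ranked items, i.e.
S(C) = (1/N) * sum_{i<=C} s_i) and the AUROC in its Mann-Whitney form (the
probability that a random swap item outranks a random non-swap item, ties
credited 1/2).  The benchmark harness runs the quality-score detector and
keypoint heuristics over a common synthetic suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DetectorScore",
    "DiscoveryCurve",
    "discovery_curve",
    "auroc",
    "swap_rate",
    "benchmark_report",
    "build_synthetic_suite",
    "plot_discovery_curves",
]


@dataclass
class DetectorScore:
    """Per-item suspicion scores with binary ground-truth labels.

    ``higher_is_suspect`` orients the detector: displacement-style heuristics
    rank descending, quality-score detectors ascending.  NaN marks an
    undefined score (ranked least suspect by the discovery curve; detectors
    that treat missing data as suspect, like displacement on frames with no
    shared keypoints, should encode that as +inf before construction).
    """

    scores: np.ndarray
    labels: np.ndarray
    higher_is_suspect: bool = True
    name: str = "detector"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def suspicion(self) -> np.ndarray:
        """Scores re-oriented so that larger always means more suspect."""
        return self.scores if self.higher_is_suspect else -self.scores


@dataclass
class DiscoveryCurve:
    """Cumulative swap-discovery fraction against review effort.

    ``effort[c] = c + 1`` items reviewed, ``fraction[c]`` of all swaps found.
    ``defined`` is False when there were no positive labels to discover.
    """

    effort: np.ndarray
    fraction: np.ndarray
    defined: bool = True


def discovery_curve(det: DetectorScore) -> DiscoveryCurve:
    """Rank items by suspicion and accumulate the fraction of swaps found.

    The sort is stable with ties kept in item (frame) order; undefined (NaN)
    scores rank last.  With no positive labels the curve is flagged
    undefined.
    """
    if det.scores.size == 0:
        raise ValueError("empty detector input")
    susp = det.suspicion.copy()
    susp[np.isnan(susp)] = -np.inf
    order = np.argsort(-susp, kind="stable")
    labels = det.labels[order].astype(float)
    n_pos = labels.sum()
    effort = np.arange(1, len(labels) + 1)
    if n_pos == 0:
        return DiscoveryCurve(effort, np.zeros(len(labels)), defined=False)
    return DiscoveryCurve(effort, np.cumsum(labels) / n_pos, defined=True)


def auroc(det: DetectorScore) -> float:
    """Probability a random swap item is more suspect than a random non-swap.

    Mann-Whitney formulation via midranks, so tied scores earn 1/2 credit.
    Requires both classes.
    """
    labels = det.labels.astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both swap and non-swap items")
    susp = det.suspicion
    if np.isnan(susp).any():
        raise ValueError("AUROC scores must be finite or encoded as +/-inf")
    ranks = rankdata(susp)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def swap_rate(events, total_frames: int) -> float:
    """Identity swaps per 100,000 frames; ``events`` is a count or a sequence."""
    if total_frames <= 0:
        raise ValueError("total_frames must be positive")
    count = events if isinstance(events, (int, np.integer)) else len(events)
    return 100_000.0 * count / total_frames


# ---------------------------------------------------------------------------
# synthetic benchmark suite


def build_synthetic_suite(
    n_cases: int = 10,
    seed: int = 0,
    scenario: str = "unidirectional",
    n_frames: int = 60,
    height: int = 64,
    width: int = 80,
) -> list[dict]:
    """Generate matched detector scores over a set of synthetic cases.

    Each case is one scene with a mask swap in the requested scenario and a
    keypoint-track swap injected at the same frame, scored by:

    * ``quality`` — two-animal framewise quality score, lower is suspect;
      labels mark both frames flanking each mask-swap transition (a swap
      between frames t-1 and t implicates both);
    * ``displacement`` — max-over-tracks keypoint displacement per adjacent
      frame pair, higher is suspect, undefined encoded +inf; labels mark the
      frame pair straddling the keypoint-track swap;
    * ``consensus_alignment`` — binary change of the keypoint-to-consensus
      resolved mapping per frame pair, higher is suspect; same pair labels.
    """
    from . import synthetic
    from .align import alignment_scores, displacement as _displacement
    from .consensus import assemble_consensus
    from .iou import iou_series, quality_scores
    from .mask_io import KeypointSet

    rng = np.random.default_rng(seed)
    cases = []
    for c in range(n_cases):
        spec = synthetic.SceneSpec(
            n_animals=2, n_frames=n_frames, height=height, width=width,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        swap_frame = int(rng.integers(n_frames // 4, 3 * n_frames // 4))
        fwd, rev, truth, log = synthetic.make_bidirectional_case(
            spec, scenario, swap_frame=swap_frame,
        )
        series = iou_series(fwd, rev)
        q = quality_scores(series)
        mask_labels = np.zeros(n_frames, dtype=int)
        for frames in log["swap_frames"].values():
            for t in frames:
                mask_labels[t] = 1
                if t > 0:
                    mask_labels[t - 1] = 1
        quality_det = DetectorScore(q.q, mask_labels, higher_is_suspect=False,
                                    name="quality")

        # keypoint tracks carrying a swap at the same frame (regenerating the
        # scene under the same seed reproduces the ground-truth keypoints)
        _, kps = synthetic.generate_scene(spec)
        rec = kps.records.copy()
        late = rec["frame"] >= swap_frame
        rec.loc[late, "track"] = rec.loc[late, "track"].map({1: 2, 2: 1})
        kps_swapped = KeypointSet(rec, kps.n_tracks, kps.n_keypoints, kps.scale)
        disp = _displacement(kps_swapped)
        disp_score = np.nanmax(np.where(np.isnan(disp.d), -np.inf, disp.d), axis=1)
        disp_score[np.isneginf(disp_score)] = np.inf  # no shared keypoints: suspect
        pair_labels = np.zeros(n_frames - 1, dtype=int)
        pair_labels[swap_frame - 1] = 1  # pair (swap_frame-1, swap_frame)
        disp_det = DetectorScore(disp_score, pair_labels,
                                 higher_is_suspect=True, name="displacement")

        annotations = synthetic.annotations_from_fault_log(log, n_frames)
        cons = assemble_consensus(fwd, rev, annotations)
        aln = alignment_scores(kps_swapped, cons, radius=5)
        flips = (aln.resolved[1:] != aln.resolved[:-1]).astype(float)
        cons_det = DetectorScore(flips, pair_labels, higher_is_suspect=True,
                                 name="consensus_alignment")
        cases.append(
            {
                "case": c,
                "detectors": {
                    "quality": quality_det,
                    "displacement": disp_det,
                    "consensus_alignment": cons_det,
                },
                "n_swaps": int(pair_labels.sum()),
                "total_frames": n_frames,
            }
        )
    return cases


def benchmark_report(cases: Sequence[Mapping]) -> pd.DataFrame:
    """Aggregate per-detector AUROC, full-discovery effort, and swap rates.

    ``cases`` is the output of :func:`build_synthetic_suite` (or any sequence
    of mappings with the same keys).  Returns one row per detector with mean
    AUROC, mean effort (items reviewed) to 100% swap discovery, and the
    pooled swap rate per 100,000 frames.  Deterministic given the suite.
    """
    if not cases:
        raise ValueError("empty benchmark suite")
    names = list(cases[0]["detectors"])
    for case in cases:
        if list(case["detectors"]) != names:
            raise ValueError("cases carry mismatched detector sets")
    rows = []
    total_swaps = sum(c["n_swaps"] for c in cases)
    total_frames = sum(c["total_frames"] for c in cases)
    for name in names:
        aurocs, efforts = [], []
        for case in cases:
            det = case["detectors"][name]
            aurocs.append(auroc(det))
            curve = discovery_curve(det)
            if curve.defined:
                efforts.append(int(curve.effort[np.argmax(curve.fraction >= 1.0)]))
        rows.append(
            {
                "detector": name,
                "mean_auroc": float(np.mean(aurocs)),
                "mean_effort_to_full_discovery": float(np.mean(efforts))
                if efforts else np.nan,
                "swap_rate_per_100k": swap_rate(total_swaps, total_frames),
            }
        )
    return pd.DataFrame(rows).set_index("detector")


def plot_discovery_curves(dets: Sequence[DetectorScore], path=None):
    """Plot discovery curves for several detectors; returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for det in dets:
        curve = discovery_curve(det)
        ax.step(curve.effort, curve.fraction, where="post", label=det.name)
    ax.set_xlabel("items reviewed")
    ax.set_ylabel("fraction of swaps discovered")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
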