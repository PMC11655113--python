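"""Confidence-based soft-voting fusion of segment proposals with a
semantic probability map.

The method assumes the segment proposals are the finest semantic
granularity available: all pixels of one proposal share one (hidden)
occlusion class.  Each surviving proposal therefore gets exactly one
class, chosen by *soft voting*: the per-pixel class probabilities of the
semantic map are summed over the proposal's pixels and the class with the
largest summed confidence wins.  Summing probabilities rather than hard
per-pixel labels bounds every pixel's influence at 1 and tempers an
overconfident semantic model trained on little data.

Proposals are first filtered on the generator's own quality metadata
(predicted confidence, stability score) and a minimum area, mirroring
standard automatic-mask-generator post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .masks_io import LabelMask, ProbabilityMap, SegmentStack

__all__ = [
    "FusionConfig",
    "VoteVector",
    "grid_prompt_points",
    "filter_segments",
    "segment_vote",
    "soss_fuse",
    "fused_soft_scores",
]

UNCOVERED_POLICIES = ("background", "semantic_argmax")
OVERLAP_POLICIES = ("smaller_wins", "larger_wins")


@dataclass(frozen=True)
class FusionConfig:
    """Filtering thresholds and fusion policies.

    Defaults follow the mask-generator settings the method was developed
    with: confidence >= 0.90, stability >= 0.85, area >= 5 px (all
    thresholds inclusive).  `uncovered_policy` decides what pixels covered
    by no surviving segment get: class 0 (``background``) or the semantic
    map's own per-pixel argmax (``semantic_argmax``).  `overlap_policy`
    resolves overlapping proposals; ``smaller_wins`` lets finer-detail
    segments overwrite coarser ones.
    """

    min_confidence: float = 0.90
    min_stability: float = 0.85
    min_area: int = 5
    uncovered_policy: str = "background"
    overlap_policy: str = "smaller_wins"
    tie_policy: str = "lowest_class"

    def __post_init__(self) -> None:
        for name in ("min_confidence", "min_stability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.min_area < 1:
            raise ValidationError("min_area must be >= 1")
        if self.uncovered_policy not in UNCOVERED_POLICIES:
            raise ValidationError(f"unknown uncovered_policy {self.uncovered_policy!r}")
        if self.overlap_policy not in OVERLAP_POLICIES:
            raise ValidationError(f"unknown overlap_policy {self.overlap_policy!r}")
        if self.tie_policy != "lowest_class":
            raise ValidationError("tie_policy must be 'lowest_class'")


@dataclass(frozen=True)
class VoteVector:
    """Per-class summed confidences for one segment and the winning class."""

    votes: np.ndarray
    winner: int


def grid_prompt_points(
    height: int, width: int, n_per_side: int = 40
) -> np.ndarray:
    """Cell-center prompt grid: ``n_per_side**2`` points strictly inside
    the image, point i along each axis at ``(i + 0.5)/n`` of the extent.

    Returns an ``(n_per_side**2, 2)`` array of ``(x, y)`` coordinates in
    row-major order (y varies slowest).
    """
    if height <= 0 or width <= 0:
        raise ValidationError("image extent must be positive")
    if n_per_side < 1:
        raise ValidationError("n_per_side must be >= 1")
    frac = (np.arange(n_per_side) + 0.5) / n_per_side
    xs = frac * width
    ys = frac * height
    gx, gy = np.meshgrid(xs, ys)
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def filter_segments(stack: SegmentStack, config: FusionConfig) -> SegmentStack:
    """Keep segments meeting all three inclusive thresholds, in order."""
    kept = [
        s
        for s in stack
        if s.predicted_confidence >= config.min_confidence
        and s.stability >= config.min_stability
        and s.area >= config.min_area
    ]
    return SegmentStack(height=stack.height, width=stack.width, segments=kept)


def segment_vote(probs: ProbabilityMap, segment_mask: np.ndarray) -> VoteVector:
    """Sum the semantic probabilities over a segment, per class.

    votes[n] = sum over the segment's pixels of probs[r, c, n]; the winner
    is the argmax with ties broken toward the lowest class id (so an exact
    tie defaults to non-occlusion).
    """
    mask = np.asarray(segment_mask, dtype=bool)
    if mask.shape != probs.shape:
        raise ValidationError(
            f"segment shape {mask.shape} != probability map shape {probs.shape}"
        )
    if not mask.any():
        raise ValidationError("cannot vote on an empty segment")
    votes = probs.probs[mask].sum(axis=0)
    return VoteVector(votes=votes, winner=int(np.argmax(votes)))


def _paint_order(stack: SegmentStack, config: FusionConfig) -> np.ndarray:
    """Paint sequence: the intended overlap winner is painted last.

    smaller_wins paints in decreasing area (stable, so equal-area segments
    keep stack order and the later-listed one wins); larger_wins paints in
    increasing area.
    """
    areas = np.array([s.area for s in stack], dtype=np.int64)
    key = -areas if config.overlap_policy == "smaller_wins" else areas
    return np.argsort(key, kind="stable")


def soss_fuse(
    probs: ProbabilityMap,
    stack: SegmentStack,
    config: FusionConfig | None = None,
) -> LabelMask:
    """Fuse a semantic probability map with a segment-proposal stack.

    Every pixel covered by at least one surviving (filtered) segment gets
    its segment's soft-vote winner; overlaps are resolved by the overlap
    policy and uncovered pixels by the uncovered policy.  Within a
    segment's non-overlapped pixels the output class is constant by
    construction.
    """
    config = config or FusionConfig()
    if (stack.height, stack.width) != probs.shape:
        raise ValidationError(
            f"stack extent {(stack.height, stack.width)} != map extent {probs.shape}"
        )
    surviving = filter_segments(stack, config)

    if config.uncovered_policy == "semantic_argmax":
        out = probs.argmax().astype(np.int64)
    else:
        out = np.zeros(probs.shape, dtype=np.int64)

    for idx in _paint_order(surviving, config):
        seg = surviving.segments[idx]
        out[seg.mask] = segment_vote(probs, seg.mask).winner
    return LabelMask(out, probs.n_classes)


def fused_soft_scores(
    probs: ProbabilityMap,
    stack: SegmentStack,
    config: FusionConfig | None = None,
) -> ProbabilityMap:
    """Per-pixel soft scores consistent with :func:`soss_fuse`.

    Covered pixels carry their segment's vote vector normalized by the
    segment area (so rows still sum to 1); uncovered pixels carry the
    original probabilities (``semantic_argmax`` policy) or the one-hot of
    class 0 (``background`` policy).  The per-pixel argmax of the result
    equals the hard fused mask everywhere, which makes threshold-sweep
    evaluation (ROC/AUC) of the fused output well defined.
    """
    config = config or FusionConfig()
    if (stack.height, stack.width) != probs.shape:
        raise ValidationError(
            f"stack extent {(stack.height, stack.width)} != map extent {probs.shape}"
        )
    surviving = filter_segments(stack, config)

    if config.uncovered_policy == "semantic_argmax":
        out = probs.probs.copy()
    else:
        out = np.zeros_like(probs.probs)
        out[..., 0] = 1.0

    for idx in _paint_order(surviving, config):
        seg = surviving.segments[idx]
        vv = segment_vote(probs, seg.mask)
        out[seg.mask] = vv.votes / seg.area
    return ProbabilityMap(out)
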