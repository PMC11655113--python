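import numpy as np
import pytest

from soss import ProbabilityMap, Segment, SegmentStack


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_probmap(rng, height, width, n_classes) -> ProbabilityMap:
    raw = rng.random((height, width, n_classes)) + 1e-3
    return ProbabilityMap(raw / raw.sum(axis=2, keepdims=True))


def random_stack(
    rng,
    height,
    width,
    max_segments=6,
    disjoint=False,
    score_range=(0.8, 1.0),
) -> SegmentStack:
    """Random nonempty binary masks; `disjoint=True` partitions a random
    subset of the frame instead."""
    n_seg = int(rng.integers(0, max_segments + 1))
    segments = []
    if disjoint and n_seg:
        owner = rng.integers(-1, n_seg, size=(height, width))  # -1 = uncovered
        for i in range(n_seg):
            mask = owner == i
            if not mask.any():
                continue
            segments.append(_seg(rng, mask, score_range))
    else:
        for _ in range(n_seg):
            mask = rng.random((height, width)) < rng.uniform(0.05, 0.6)
            if not mask.any():
                mask[rng.integers(height), rng.integers(width)] = True
            segments.append(_seg(rng, mask, score_range))
    return SegmentStack(height=height, width=width, segments=segments)


def _seg(rng, mask, score_range):
    return Segment(
        mask=mask,
        predicted_confidence=float(rng.uniform(*score_range)),
        stability=float(rng.uniform(*score_range)),
    )
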