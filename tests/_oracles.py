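"""Independent brute-force oracles used by the test suite.

Everything here is deliberately unvectorized pure Python so it shares no
code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def point_in_polygon_even_odd(x: float, y: float, verts) -> bool:
    """Crossing-number (even-odd) test for one point, one edge at a time."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


def rasterize_naive(annotations, height, width):
    """Last-polygon-wins rasterization by exhaustive pixel-center testing."""
    out = [[0] * width for _ in range(height)]
    for ann in annotations:
        verts = [(float(vx), float(vy)) for vx, vy in ann.vertices]
        for r in range(height):
            for c in range(width):
                if point_in_polygon_even_odd(c + 0.5, r + 0.5, verts):
                    out[r][c] = ann.class_id
    return np.array(out, dtype=np.int64)


def fuse_naive(probs, stack, config):
    """Per-pixel/per-class loop re-implementation of the soft-vote fusion."""
    arr = probs.probs
    height, width, n_classes = arr.shape

    kept = [
        s
        for s in stack.segments
        if s.predicted_confidence >= config.min_confidence
        and s.stability >= config.min_stability
        and s.area >= config.min_area
    ]
    # paint order: the overlap winner paints last; stable among equal areas
    reverse = config.overlap_policy == "smaller_wins"
    order = sorted(range(len(kept)), key=lambda i: -kept[i].area if reverse else kept[i].area)

    out = [[0] * width for _ in range(height)]
    if config.uncovered_policy == "semantic_argmax":
        for r in range(height):
            for c in range(width):
                best, best_v = 0, arr[r, c, 0]
                for k in range(1, n_classes):
                    if arr[r, c, k] > best_v:
                        best, best_v = k, arr[r, c, k]
                out[r][c] = best

    for idx in order:
        seg = kept[idx]
        votes = [0.0] * n_classes
        for r in range(height):
            for c in range(width):
                if seg.mask[r, c]:
                    for k in range(n_classes):
                        votes[k] += arr[r, c, k]
        winner, winner_v = 0, votes[0]
        for k in range(1, n_classes):
            if votes[k] > winner_v:
                winner, winner_v = k, votes[k]
        for r in range(height):
            for c in range(width):
                if seg.mask[r, c]:
                    out[r][c] = winner
    return np.array(out, dtype=np.int64)


def auc_pairwise(scores, labels) -> float:
    """Mann-Whitney AUC by exhaustive positive-negative pair counting,
    ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
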