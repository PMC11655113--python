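"""Seeded synthetic scenes with ground truth, plus degraded probability
maps and over-segmented partitions.

The generator emulates the statistical structure of the two model outputs
the fusion consumes, without any real imagery:

* :func:`make_scene` draws blob- (ellipse), bar- (rotated rectangle) and
  cable-shaped (dilated random-walk polyline) occlusions on a background,
  mimicking the mix of bulky and thin objects found around a monitored
  patient;
* :func:`degrade_to_probmap` stands in for a coarse semantic segmenter:
  ground-truth boundaries are jittered by per-object dilation/erosion
  (over-smoothing) and per-pixel labels are flipped i.i.d., then the label
  raster is softened to probabilities with a temperature;
* :func:`shatter_to_segments` stands in for an automatic mask generator:
  every connected ground-truth region is split into nearest-seed pieces
  (proposals cover parts of objects, never cross object boundaries — the
  fusion's granularity assumption holds by construction), and small
  objects can be dropped entirely to emulate missed thin structures.

Everything is a pure function of its spec: same seed, bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import measure
from skimage.morphology import disk

from .errors import ValidationError
from .fusion import FusionConfig, soss_fuse
from .masks_io import LabelMask, ProbabilityMap, Segment, SegmentStack
from .metrics import confusion, scalar_metrics

__all__ = [
    "SceneSpec",
    "DegradeSpec",
    "make_scene",
    "degrade_to_probmap",
    "shatter_to_segments",
    "improvement_experiment",
    "occlusion_iou",
]

_KINDS = ("blob", "bar", "cable")


@dataclass(frozen=True)
class SceneSpec:
    """What to draw.  Object sizes scale with the frame; `n_classes = 2`
    gives the binary occlusion/background regime."""

    height: int = 128
    width: int = 128
    n_objects_range: tuple[int, int] = (3, 6)
    object_kinds: tuple[str, ...] = ("blob", "bar", "cable")
    cable_thickness_range: tuple[int, int] = (1, 3)
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height, self.width) < 16:
            raise ValidationError("frame must be at least 16x16")
        if self.n_objects_range[0] > self.n_objects_range[1] or self.n_objects_range[0] < 0:
            raise ValidationError("n_objects_range must be an ordered non-negative interval")
        if not self.object_kinds or any(k not in _KINDS for k in self.object_kinds):
            raise ValidationError(f"object_kinds must be a non-empty subset of {_KINDS}")
        lo, hi = self.cable_thickness_range
        if lo < 1 or lo > hi:
            raise ValidationError("cable_thickness_range must be ordered with min >= 1")
        if hi >= min(self.height, self.width) // 2:
            raise ValidationError("cable thickness too large for the frame")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")


@dataclass(frozen=True)
class DegradeSpec:
    """How hard to corrupt the ground truth.

    `boundary_jitter_radius` is the largest per-object dilation/erosion
    radius (px); `label_flip_rate` the i.i.d. chance a pixel's label is
    replaced by a uniformly random other class; `confidence_temperature`
    softens the one-hot winner (smaller = more peaked).
    `segment_split_mean` is the Poisson mean of extra pieces per region;
    occlusion objects no larger than `min_dropped_object_area` are omitted
    entirely with probability `segment_drop_rate`.  `weak_score_rate` and
    `impurity_rate` are stress knobs: the first gives a segment
    sub-threshold confidence/stability scores, the second grows a segment
    one pixel across its region boundary (violating class purity) — both
    default off.
    """

    boundary_jitter_radius: int = 2
    label_flip_rate: float = 0.15
    confidence_temperature: float = 0.5
    segment_split_mean: float = 3.0
    segment_drop_rate: float = 0.0
    min_dropped_object_area: int = 64
    seed: int = 0
    weak_score_rate: float = 0.0
    impurity_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("label_flip_rate", "segment_drop_rate", "weak_score_rate",
                     "impurity_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.confidence_temperature <= 0:
            raise ValidationError("confidence_temperature must be positive")
        if self.boundary_jitter_radius < 0 or self.segment_split_mean < 0:
            raise ValidationError("jitter radius and split mean must be >= 0")


# ---------------------------------------------------------------------------
# scene


def _draw_blob(rng, height, width):
    scale = min(height, width)
    r0 = rng.uniform(0, height)
    c0 = rng.uniform(0, width)
    a = rng.uniform(scale / 16, scale / 6)
    b = rng.uniform(scale / 16, scale / 6)
    theta = rng.uniform(0, np.pi)
    rr, cc = skdraw.ellipse(r0, c0, a, b, shape=(height, width), rotation=theta)
    return rr, cc


def _draw_bar(rng, height, width):
    scale = min(height, width)
    length = rng.uniform(scale / 4, scale / 1.6)
    thick = rng.uniform(2, max(3, scale / 10))
    r0 = rng.uniform(0, height)
    c0 = rng.uniform(0, width)
    theta = rng.uniform(0, np.pi)
    d = np.array([np.cos(theta), np.sin(theta)])
    n = np.array([-np.sin(theta), np.cos(theta)])
    center = np.array([r0, c0])
    corners = [
        center + d * length / 2 + n * thick / 2,
        center + d * length / 2 - n * thick / 2,
        center - d * length / 2 - n * thick / 2,
        center - d * length / 2 + n * thick / 2,
    ]
    corners = np.array(corners)
    rr, cc = skdraw.polygon(corners[:, 0], corners[:, 1], shape=(height, width))
    return rr, cc


def _draw_cable(rng, height, width, thickness_range):
    scale = min(height, width)
    n_steps = int(rng.integers(scale, 2 * scale))
    r = rng.uniform(0, height)
    c = rng.uniform(0, width)
    theta = rng.uniform(0, 2 * np.pi)
    canvas = np.zeros((height, width), dtype=bool)
    for _ in range(n_steps):
        theta += rng.normal(0, 0.25)
        r += np.sin(theta)
        c += np.cos(theta)
        r = float(np.clip(r, 0, height - 1))
        c = float(np.clip(c, 0, width - 1))
        canvas[int(r), int(c)] = True
    thick = int(rng.integers(thickness_range[0], thickness_range[1] + 1))
    if thick > 1:
        canvas = ndimage.binary_dilation(canvas, structure=np.ones((thick, thick)))
    return np.nonzero(canvas)


def make_scene(spec: SceneSpec) -> tuple[LabelMask, np.ndarray]:
    """Render a scene: returns (ground-truth labels, RGB uint8 image).

    Objects are painted in draw order (later objects overwrite earlier
    ones), each with a random occlusion class >= 1 and a distinct mean
    color; Gaussian pixel noise is added on top.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    labels = np.zeros((h, w), dtype=np.int64)
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = rng.uniform(90, 160, size=3)  # background mean color

    n_objects = int(rng.integers(spec.n_objects_range[0], spec.n_objects_range[1] + 1))
    for _ in range(n_objects):
        kind = spec.object_kinds[int(rng.integers(len(spec.object_kinds)))]
        cls = 1 if spec.n_classes == 2 else int(rng.integers(1, spec.n_classes))
        if kind == "blob":
            rr, cc = _draw_blob(rng, h, w)
        elif kind == "bar":
            rr, cc = _draw_bar(rng, h, w)
        else:
            rr, cc = _draw_cable(rng, h, w, spec.cable_thickness_range)
        if len(rr) == 0:
            continue
        labels[rr, cc] = cls
        canvas[rr, cc] = rng.uniform(30, 225, size=3)

    canvas += rng.normal(0, 8.0, size=canvas.shape)
    image = np.clip(canvas, 0, 255).astype(np.uint8)
    return LabelMask(labels, spec.n_classes), image


# ---------------------------------------------------------------------------
# degradation


def _winner_prob(n_classes: int, temperature: float) -> float:
    # softmax of a one-hot divided by T, computed stably; -> 1 as T -> 0
    z = -1.0 / temperature
    if z < -700:
        return 1.0
    return float(1.0 / (1.0 + (n_classes - 1) * np.exp(z)))


def degrade_to_probmap(truth: LabelMask, spec: DegradeSpec) -> ProbabilityMap:
    """Corrupt ground truth into a blurry-boundary, noisy probability map.

    Per occlusion component, the boundary is displaced by a random
    dilation (positive radius, object grows) or erosion (negative, object
    shrinks) up to `boundary_jitter_radius`; then labels flip i.i.d. at
    `label_flip_rate`; finally the label raster becomes probabilities with
    the winning class at the temperature-controlled weight and the rest
    sharing the remainder equally.
    """
    rng = np.random.default_rng([spec.seed, 1])
    n = truth.n_classes
    labels = truth.labels.copy()

    if spec.boundary_jitter_radius > 0:
        comp, n_comp = ndimage.label(truth.labels > 0)
        for comp_id in range(1, n_comp + 1):
            radius = int(rng.integers(-spec.boundary_jitter_radius,
                                      spec.boundary_jitter_radius + 1))
            if radius == 0:
                continue
            mask = comp == comp_id
            cls = int(truth.labels[mask][0])
            if radius > 0:
                grown = ndimage.binary_dilation(mask, structure=disk(radius))
                labels[grown] = cls
            else:
                kept = ndimage.binary_erosion(mask, structure=disk(-radius))
                labels[mask & ~kept] = 0

    if spec.label_flip_rate > 0:
        flips = rng.random(labels.shape) < spec.label_flip_rate
        offsets = rng.integers(1, n, size=labels.shape)
        labels = np.where(flips, (labels + offsets) % n, labels)

    p_win = _winner_prob(n, spec.confidence_temperature)
    p_off = (1.0 - p_win) / (n - 1)
    probs = np.full((truth.height, truth.width, n), p_off, dtype=np.float64)
    rows, cols = np.indices(labels.shape)
    probs[rows, cols, labels] = p_win
    return ProbabilityMap(probs)


# ---------------------------------------------------------------------------
# shattering


def shatter_to_segments(truth: LabelMask, spec: DegradeSpec) -> SegmentStack:
    """Partition every connected ground-truth region (background included)
    into nearest-seed pieces, emulating part-of-object proposals.

    Pieces never cross ground-truth boundaries unless `impurity_rate` is
    raised, so the fusion's same-segment-same-class assumption holds by
    construction.  With `segment_drop_rate` > 0, occlusion objects of area
    <= `min_dropped_object_area` can be omitted entirely, emulating a mask
    generator missing thin structures.  Surviving segments draw confidence
    from [0.92, 1] and stability from [0.88, 1] (above the default filter
    thresholds) unless hit by `weak_score_rate`.
    """
    rng = np.random.default_rng([spec.seed, 2])
    regions = measure.label(truth.labels, background=-1, connectivity=1)
    segments: list[Segment] = []
    h, w = truth.shape

    for region_id in range(1, regions.max() + 1):
        mask = regions == region_id
        rows, cols = np.nonzero(mask)
        area = len(rows)
        cls = int(truth.labels[rows[0], cols[0]])
        if (
            cls >= 1
            and area <= spec.min_dropped_object_area
            and rng.random() < spec.segment_drop_rate
        ):
            continue
        n_pieces = min(1 + int(rng.poisson(spec.segment_split_mean)), area)
        seed_idx = rng.choice(area, size=n_pieces, replace=False)
        seed_pts = np.stack([rows[seed_idx], cols[seed_idx]], axis=1)
        pts = np.stack([rows, cols], axis=1)
        # nearest seed, ties to the lowest seed index
        d2 = ((pts[None, :, :] - seed_pts[:, None, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=0)
        for piece in range(n_pieces):
            sel = assign == piece
            if not sel.any():
                continue
            pm = np.zeros((h, w), dtype=bool)
            pm[rows[sel], cols[sel]] = True
            if spec.impurity_rate > 0 and rng.random() < spec.impurity_rate:
                grown = ndimage.binary_dilation(pm, structure=_cross()) & ~mask
                leak = np.nonzero(grown)
                if len(leak[0]):
                    pick = int(rng.integers(len(leak[0])))
                    pm[leak[0][pick], leak[1][pick]] = True
            if rng.random() < spec.weak_score_rate:
                conf = float(rng.uniform(0.3, 0.89))
                stab = float(rng.uniform(0.3, 0.84))
            else:
                conf = float(rng.uniform(0.92, 1.0))
                stab = float(rng.uniform(0.88, 1.0))
            segments.append(Segment(mask=pm, predicted_confidence=conf, stability=stab))
    return SegmentStack(height=h, width=w, segments=segments)


def _cross() -> np.ndarray:
    return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


# ---------------------------------------------------------------------------
# experiment


def occlusion_iou(pred: LabelMask, truth: LabelMask) -> float:
    """IoU of the binarized occlusion region (any class >= 1)."""
    pred_b = LabelMask((pred.labels >= 1).astype(np.int64), 2)
    truth_b = LabelMask((truth.labels >= 1).astype(np.int64), 2)
    return scalar_metrics(confusion(pred_b, truth_b, class_id=1)).iou


def improvement_experiment(
    scene_spec: SceneSpec,
    degrade_spec: DegradeSpec,
    n_seeds: int,
    config: FusionConfig | None = None,
) -> list[dict]:
    """Compare the semantic map's per-pixel argmax against the fused
    output over `n_seeds` seeded scenes.

    Returns one row per seed with the occlusion IoU of both routes; the
    fusion uses the ``semantic_argmax`` uncovered policy so dropped
    segments fall back to the semantic prediction.
    """
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    config = config or FusionConfig(uncovered_policy="semantic_argmax")
    rows = []
    for i in range(n_seeds):
        ss = replace(scene_spec, seed=scene_spec.seed + i)
        ds = replace(degrade_spec, seed=degrade_spec.seed + i)
        truth, _ = make_scene(ss)
        probs = degrade_to_probmap(truth, ds)
        stack = shatter_to_segments(truth, ds)
        sem_pred = LabelMask(probs.argmax(), truth.n_classes)
        fused = soss_fuse(probs, stack, config)
        rows.append(
            {
                "seed": ss.seed,
                "iou_semantic": occlusion_iou(sem_pred, truth),
                "iou_fused": occlusion_iou(fused, truth),
            }
        )
    return rows
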