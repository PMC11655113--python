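"""Raster containers, polygon annotations, and file round-trips.

Coordinate conventions used throughout the package:

* rasters are row-major numpy arrays: axis 0 is the image row (y), axis 1
  the column (x); everything is 0-based;
* polygon vertices are continuous ``(x, y)`` image coordinates;
* pixel ``(r, c)`` covers the unit square ``[c, c+1) x [r, r+1)`` and has
  center ``(c + 0.5, r + 0.5)``;
* rasterization assigns a pixel to a polygon iff the pixel *center* is
  inside under the even-odd rule; when polygons overlap, the last-listed
  polygon wins.

Label masks are single-channel PNGs whose pixel value is the class id
(class 0 = non-occlusion).  Segment stacks — the output shape of an
automatic mask generator such as SAM's — are persisted as one binary PNG
per segment plus a JSON manifest carrying per-segment confidence,
stability and area, so real mask-generator runs can be ingested offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from .errors import AnnotationParseError, IntegrityError, ValidationError

__all__ = [
    "LabelMask",
    "ProbabilityMap",
    "Segment",
    "SegmentStack",
    "PolygonAnnotation",
    "Roi",
    "read_polygon_annotations",
    "rasterize_polygons",
    "crop_and_pad",
    "write_label_mask",
    "read_label_mask",
    "write_segment_stack",
    "read_segment_stack",
    "write_probability_map",
    "read_probability_map",
]

_PROB_TOL = 1e-6


@dataclass
class LabelMask:
    """Integer class raster: one class id per pixel, 0 = non-occlusion."""

    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValidationError("labels must be a non-empty 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.labels.min() < 0 or self.labels.max() >= self.n_classes:
            raise ValidationError(
                f"labels must lie in [0, {self.n_classes}); "
                f"found range [{self.labels.min()}, {self.labels.max()}]"
            )

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class ProbabilityMap:
    """Per-pixel class-probability raster of shape (H, W, N).

    Every pixel's probabilities must be non-negative and sum to 1 within
    1e-6 — the container normalizes nothing; upstream softmax output is
    expected as-is.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[2] < 2:
            raise ValidationError("probs must have shape (H, W, N) with N >= 2")
        if self.probs.size == 0:
            raise ValidationError("probs must be non-empty")
        if self.probs.min() < 0:
            raise ValidationError("probabilities must be non-negative")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=_PROB_TOL, rtol=0):
            worst = float(np.abs(sums - 1.0).max())
            raise ValidationError(
                f"per-pixel probabilities must sum to 1 within {_PROB_TOL}; "
                f"worst deviation {worst:g}"
            )

    @property
    def height(self) -> int:
        return self.probs.shape[0]

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[:2]

    def argmax(self) -> np.ndarray:
        """Per-pixel winning class (ties go to the lowest class id)."""
        return np.argmax(self.probs, axis=2)


@dataclass
class Segment:
    """One binary mask proposal with its generator metadata."""

    mask: np.ndarray
    predicted_confidence: float
    stability: float
    area: int = -1  # -1 = derive from mask

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("segment mask must be 2-D")
        true_area = int(self.mask.sum())
        if self.area == -1:
            self.area = true_area
        if self.area != true_area:
            raise ValidationError(
                f"declared area {self.area} != mask area {true_area}"
            )
        if self.area < 1:
            raise ValidationError("segment mask must contain at least one pixel")
        for name in ("predicted_confidence", "stability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SegmentStack:
    """Ordered set of (possibly overlapping) binary segment proposals."""

    height: int
    width: int
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValidationError("stack extent must be at least 1x1")
        for i, seg in enumerate(self.segments):
            if seg.mask.shape != (self.height, self.width):
                raise ValidationError(
                    f"segment {i} has shape {seg.mask.shape}, "
                    f"stack is {(self.height, self.width)}"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


@dataclass
class PolygonAnnotation:
    """A labeled polygon in continuous (x, y) image coordinates."""

    vertices: np.ndarray
    class_id: int
    image_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("vertices must be an (n, 2) array of (x, y)")
        if self.vertices.shape[0] < 3:
            raise ValidationError(
                f"a polygon needs >= 3 vertices, got {self.vertices.shape[0]}"
            )
        if self.class_id < 1:
            raise ValidationError("polygon class_id must be >= 1 (occlusions only)")


@dataclass
class Roi:
    """Half-open pixel index window [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise ValidationError("need 0 <= row_start < row_end")
        if not (0 <= self.col_start < self.col_end):
            raise ValidationError("need 0 <= col_start < col_end")

    @property
    def extent(self) -> tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)

    def check_fits(self, height: int, width: int) -> None:
        if self.row_end > height or self.col_end > width:
            raise ValidationError(
                f"ROI {self} does not fit a {height}x{width} raster"
            )


# ---------------------------------------------------------------------------
# annotations


def read_polygon_annotations(
    path: str | Path,
    dialect: str = "labelstudio",
    class_map: Mapping[str, int] | None = None,
) -> list[PolygonAnnotation]:
    """Load polygon annotations from a JSON export.

    Parameters
    ----------
    path
        JSON file to read.
    dialect
        ``"labelstudio"`` for a Label-Studio task export (polygon points in
        percent of the original image size), or ``"generic_json"`` for the
        plain ``{"polygons": [{"points": [[x, y], ...], "class_id": k}]}``
        layout with absolute pixel coordinates.
    class_map
        Required for the Label-Studio dialect: maps the tool's label names
        (e.g. ``"tube"``) to class ids >= 1.  The category set is a user
        config choice, not something the export encodes.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(f"{path}: not valid JSON: {exc}") from exc

    if dialect == "labelstudio":
        if class_map is None:
            raise ValidationError(
                "the labelstudio dialect needs a class_map (label name -> class id)"
            )
        return _parse_labelstudio(doc, class_map, str(path))
    if dialect == "generic_json":
        return _parse_generic(doc, str(path))
    raise ValidationError(f"unknown annotation dialect {dialect!r}")


def _parse_labelstudio(
    doc: object, class_map: Mapping[str, int], src: str
) -> list[PolygonAnnotation]:
    if not isinstance(doc, list):
        raise AnnotationParseError(f"{src}: Label-Studio export must be a task list")
    out: list[PolygonAnnotation] = []
    for t_idx, task in enumerate(doc):
        image_id = str(task.get("data", {}).get("image", task.get("id", t_idx)))
        for ann in task.get("annotations", []):
            for r_idx, result in enumerate(ann.get("result", [])):
                if result.get("type") != "polygonlabels":
                    continue
                where = f"{src}: task {t_idx}, result {r_idx}"
                try:
                    value = result["value"]
                    points = value["points"]
                    label = value["polygonlabels"][0]
                    ow = float(result["original_width"])
                    oh = float(result["original_height"])
                except (KeyError, IndexError, TypeError) as exc:
                    raise AnnotationParseError(f"{where}: {exc!r}") from exc
                if label not in class_map:
                    raise ValidationError(
                        f"{where}: label {label!r} not in class_map"
                    )
                # percent -> absolute pixels; stays continuous, no rounding
                verts = np.asarray(points, dtype=np.float64)
                if verts.ndim != 2 or verts.shape[1] != 2:
                    raise AnnotationParseError(f"{where}: malformed points")
                verts = verts / 100.0 * np.array([ow, oh])
                out.append(
                    PolygonAnnotation(verts, int(class_map[label]), image_id)
                )
    return out


def _parse_generic(doc: object, src: str) -> list[PolygonAnnotation]:
    if not isinstance(doc, dict) or "polygons" not in doc:
        raise AnnotationParseError(f"{src}: expected an object with a 'polygons' key")
    out: list[PolygonAnnotation] = []
    image_id = str(doc.get("image_id", ""))
    for i, rec in enumerate(doc["polygons"]):
        try:
            pts = rec["points"]
            cid = int(rec["class_id"])
        except (KeyError, TypeError) as exc:
            raise AnnotationParseError(f"{src}: polygon {i}: {exc!r}") from exc
        out.append(PolygonAnnotation(np.asarray(pts, dtype=np.float64), cid, image_id))
    return out


# ---------------------------------------------------------------------------
# rasterization


def _even_odd_inside(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (crossing-number) point-in-polygon test."""
    inside = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        if not crosses.any():
            continue
        # y2 != y1 wherever crosses holds, so the guarded division is safe
        denom = y2 - y1 if y2 != y1 else 1.0
        x_int = x1 + (py - y1) * (x2 - x1) / denom
        inside ^= crosses & (px < x_int)
    return inside


def rasterize_polygons(
    annotations: Sequence[PolygonAnnotation],
    height: int,
    width: int,
    n_classes: int,
) -> LabelMask:
    """Paint polygons onto an integer label raster.

    A pixel takes the class of the *last* listed polygon whose interior
    (even-odd rule) contains the pixel center; pixels covered by no polygon
    keep class 0.
    """
    if height < 1 or width < 1:
        raise ValidationError("raster extent must be positive")
    labels = np.zeros((height, width), dtype=np.int64)
    if not annotations:
        return LabelMask(labels, n_classes)

    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    px = cols + 0.5
    py = rows + 0.5
    for i, ann in enumerate(annotations):
        if ann.class_id >= n_classes:
            raise ValidationError(
                f"polygon {i}: class_id {ann.class_id} >= n_classes {n_classes}"
            )
        v = ann.vertices
        if not np.isfinite(v).all():
            raise ValidationError(f"polygon {i}: non-finite vertex")
        if (
            v[:, 0].min() < -width
            or v[:, 0].max() > 2 * width
            or v[:, 1].min() < -height
            or v[:, 1].max() > 2 * height
        ):
            raise ValidationError(
                f"polygon {i}: vertex outside the +/- one-image tolerance band"
            )
        labels[_even_odd_inside(px, py, v)] = ann.class_id
    return LabelMask(labels, n_classes)


# ---------------------------------------------------------------------------
# ROI crop / pad


def pad_offsets(extent: tuple[int, int], target: tuple[int, int]) -> tuple[int, int]:
    """Top/left margins that center `extent` inside `target` (extra pixel
    goes to the bottom/right)."""
    return ((target[0] - extent[0]) // 2, (target[1] - extent[1]) // 2)


def crop_and_pad(raster, roi: Roi, target: tuple[int, int]):
    """Crop a raster to an ROI, then pad it symmetrically to `target`.

    Accepts a :class:`LabelMask` (padded with class 0), a
    :class:`ProbabilityMap` (padded with the one-hot of class 0) or a plain
    image array (padded with black); returns the same kind.
    """
    th, tw = target
    rh, rw = roi.extent
    if th < rh or tw < rw:
        raise ValidationError(f"target {target} smaller than ROI extent {(rh, rw)}")

    if isinstance(raster, LabelMask):
        roi.check_fits(raster.height, raster.width)
        core = raster.labels[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
        top, left = pad_offsets((rh, rw), target)
        out = np.zeros((th, tw), dtype=core.dtype)
        out[top : top + rh, left : left + rw] = core
        return LabelMask(out, raster.n_classes)

    if isinstance(raster, ProbabilityMap):
        roi.check_fits(raster.height, raster.width)
        core = raster.probs[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
        top, left = pad_offsets((rh, rw), target)
        out = np.zeros((th, tw, raster.n_classes), dtype=core.dtype)
        out[..., 0] = 1.0  # background one-hot everywhere, then overwrite
        out[top : top + rh, left : left + rw] = core
        return ProbabilityMap(out)

    arr = np.asarray(raster)
    if arr.ndim not in (2, 3):
        raise ValidationError("image raster must be 2-D or 3-D")
    roi.check_fits(arr.shape[0], arr.shape[1])
    core = arr[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
    top, left = pad_offsets((rh, rw), target)
    out = np.zeros((th, tw) + arr.shape[2:], dtype=arr.dtype)
    out[top : top + rh, left : left + rw] = core
    return out


# ---------------------------------------------------------------------------
# label-mask PNG round-trip


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as a single-channel PNG (pixel value = class id)."""
    path = Path(path)
    if mask.n_classes <= 256:
        img = Image.fromarray(mask.labels.astype(np.uint8), mode="L")
    else:
        img = Image.fromarray(mask.labels.astype(np.uint16))
    img.save(path, format="PNG")


def read_label_mask(path: str | Path, n_classes: int) -> LabelMask:
    """Read a label mask PNG written by :func:`write_label_mask`."""
    img = Image.open(path)
    if img.mode not in ("L", "I", "I;16", "P"):
        raise ValidationError(
            f"{path}: label masks must be single-channel PNG, got mode {img.mode!r}"
        )
    arr = np.asarray(img).astype(np.int64)
    if arr.size and arr.max() >= n_classes:
        raise ValidationError(
            f"{path}: pixel value {arr.max()} >= n_classes {n_classes}"
        )
    return LabelMask(arr, n_classes)


# ---------------------------------------------------------------------------
# segment-stack directory round-trip

_MANIFEST = "manifest.json"


def write_segment_stack(stack: SegmentStack, dir_path: str | Path) -> None:
    """Persist a stack as one 0/255 PNG per segment plus manifest.json."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    records = []
    for i, seg in enumerate(stack):
        fname = f"segment_{i:04d}.png"
        Image.fromarray(seg.mask.astype(np.uint8) * 255, mode="L").save(
            dir_path / fname, format="PNG"
        )
        records.append(
            {
                "filename": fname,
                "predicted_confidence": seg.predicted_confidence,
                "stability": seg.stability,
                "area": seg.area,
            }
        )
    manifest = {"height": stack.height, "width": stack.width, "segments": records}
    with open(dir_path / _MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_segment_stack(dir_path: str | Path) -> SegmentStack:
    """Read a stack directory, verifying manifest/mask agreement."""
    dir_path = Path(dir_path)
    try:
        with open(dir_path / _MANIFEST) as fh:
            manifest = json.load(fh)
    except FileNotFoundError as exc:
        raise IntegrityError(f"{dir_path}: missing {_MANIFEST}") from exc
    except json.JSONDecodeError as exc:
        raise IntegrityError(f"{dir_path}: unreadable manifest: {exc}") from exc

    height, width = int(manifest["height"]), int(manifest["width"])
    segments = []
    for rec in manifest["segments"]:
        fpath = dir_path / rec["filename"]
        if not fpath.exists():
            raise IntegrityError(f"{dir_path}: manifest names missing file {fpath.name}")
        arr = np.asarray(Image.open(fpath))
        if not np.isin(arr, (0, 255)).all():
            raise IntegrityError(f"{fpath.name}: segment PNGs must be 0/255 binary")
        mask = arr > 0
        if int(mask.sum()) != int(rec["area"]):
            raise IntegrityError(
                f"{fpath.name}: manifest area {rec['area']} != mask area {int(mask.sum())}"
            )
        segments.append(
            Segment(
                mask=mask,
                predicted_confidence=float(rec["predicted_confidence"]),
                stability=float(rec["stability"]),
                area=int(rec["area"]),
            )
        )
    return SegmentStack(height=height, width=width, segments=segments)


# ---------------------------------------------------------------------------
# probability-map container


def write_probability_map(pmap: ProbabilityMap, path: str | Path) -> None:
    """Store a probability map as a compressed .npz array container."""
    np.savez_compressed(path, probs=pmap.probs)


def read_probability_map(path: str | Path) -> ProbabilityMap:
    with np.load(path) as data:
        if "probs" not in data:
            raise IntegrityError(f"{path}: no 'probs' array in container")
        return ProbabilityMap(data["probs"])
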