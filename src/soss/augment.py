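"""Paired image+mask augmentations with deterministic seeding.

The pipeline order is fixed — geometric flips, then photometric jitter,
then copy-paste — so a single seeded generator replays bit-identically.
Photometric transforms never touch the mask; geometric transforms apply
the same permutation to both.  Copy-paste samples whole connected
occlusion components from a source pair and composites them onto the
destination at a random in-bounds offset, which grows the occlusion class
frequency without new annotation work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

from .errors import ValidationError
from .masks_io import LabelMask

__all__ = ["AugmentSpec", "flip", "photometric", "copy_paste", "augment_pair"]

logger = logging.getLogger(__name__)

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class AugmentSpec:
    """Augmentation strengths.  Magnitudes are conventional mid-strength
    defaults (the transform families, not their magnitudes, are fixed by
    the method); everything is configurable."""

    hflip_prob: float = 0.5
    vflip_prob: float = 0.25
    brightness_delta_range: tuple[float, float] = (-32.0, 32.0)
    contrast_factor_range: tuple[float, float] = (0.8, 1.2)
    hue_delta_range: tuple[float, float] = (-0.05, 0.05)
    saturation_factor_range: tuple[float, float] = (0.8, 1.2)
    copy_paste_prob: float = 0.5
    copy_paste_max_instances: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hflip_prob", "vflip_prob", "copy_paste_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "brightness_delta_range",
            "contrast_factor_range",
            "hue_delta_range",
            "saturation_factor_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} must be an ordered interval")
        if self.copy_paste_max_instances < 0:
            raise ValidationError("copy_paste_max_instances must be >= 0")

    @classmethod
    def identity(cls) -> "AugmentSpec":
        """A spec whose photometric step is the identity map."""
        return cls(
            hflip_prob=0.0,
            vflip_prob=0.0,
            brightness_delta_range=(0.0, 0.0),
            contrast_factor_range=(1.0, 1.0),
            hue_delta_range=(0.0, 0.0),
            saturation_factor_range=(1.0, 1.0),
            copy_paste_prob=0.0,
        )


def _check_pair(image: np.ndarray, mask: LabelMask) -> None:
    if image.shape[:2] != mask.shape:
        raise ValidationError(
            f"image extent {image.shape[:2]} != mask extent {mask.shape}"
        )


def flip(image: np.ndarray, mask: LabelMask, axis: str) -> tuple[np.ndarray, LabelMask]:
    """Flip image and mask together; flipping twice is the identity."""
    image = np.asarray(image)
    _check_pair(image, mask)
    if axis == "horizontal":
        ax = 1
    elif axis == "vertical":
        ax = 0
    else:
        raise ValidationError(f"axis must be horizontal or vertical, got {axis!r}")
    return (
        np.flip(image, axis=ax).copy(),
        LabelMask(np.flip(mask.labels, axis=ax).copy(), mask.n_classes),
    )


def photometric(
    image: np.ndarray, spec: AugmentSpec, rng: np.random.Generator
) -> np.ndarray:
    """Brightness/contrast plus hue/saturation jitter; mask untouched.

    out = clip(contrast * (in - mean) + mean + brightness, 0, 255) with the
    image's global mean as the contrast pivot; hue/saturation jitter is
    applied first in HSV space (skipped entirely when the sampled jitter is
    the identity, so an identity spec reproduces the input bit-exactly).
    """
    img = np.asarray(image)
    if img.min() < 0 or img.max() > 255:
        raise ValidationError("image channels must lie in [0, 255]")
    delta = rng.uniform(*spec.brightness_delta_range)
    factor = rng.uniform(*spec.contrast_factor_range)
    hue = rng.uniform(*spec.hue_delta_range)
    sat = rng.uniform(*spec.saturation_factor_range)

    out = img.astype(np.float64)
    if img.ndim == 3 and (hue != 0.0 or sat != 1.0):
        hsv = rgb2hsv(out / 255.0)
        hsv[..., 0] = (hsv[..., 0] + hue) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * sat, 0.0, 1.0)
        out = hsv2rgb(hsv) * 255.0
    mean = out.mean()
    out = np.clip(factor * (out - mean) + mean + delta, 0.0, 255.0)
    if np.issubdtype(img.dtype, np.integer):
        return np.round(out).astype(img.dtype)
    return out.astype(img.dtype)


def copy_paste(
    src_image: np.ndarray,
    src_mask: LabelMask,
    dst_image: np.ndarray,
    dst_mask: LabelMask,
    rng: np.random.Generator,
    max_instances: int,
    offsets: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, LabelMask]:
    """Paste up to `max_instances` occlusion components of the source pair
    onto the destination pair.

    Components are 4-connected regions of the source's occlusion pixels
    (class >= 1), sampled uniformly without replacement, each translated by
    a uniform random offset that keeps it fully in bounds.  Pasted pixels
    take the source image values and source classes, overwriting whatever
    was beneath.  `offsets` pins the per-instance (drow, dcol) translation,
    for reproducible pipelines and tests.
    """
    src_image = np.asarray(src_image)
    dst_image = np.asarray(dst_image)
    _check_pair(src_image, src_mask)
    _check_pair(dst_image, dst_mask)
    if src_image.shape != dst_image.shape:
        raise ValidationError("source and destination images must share a shape")

    out_image = dst_image.copy()
    out_labels = dst_mask.labels.copy()
    n_classes = max(src_mask.n_classes, dst_mask.n_classes)

    comp, n_comp = ndimage.label(src_mask.labels > 0, structure=_FOUR_CONN)
    k = min(max_instances, n_comp)
    if max_instances > 0 and n_comp == 0:
        logger.info("copy_paste: source has no occlusion component; no-op")
    if k <= 0:
        return out_image, LabelMask(out_labels, n_classes)

    chosen = rng.choice(n_comp, size=k, replace=False) + 1
    height, width = src_mask.shape
    for j, comp_id in enumerate(chosen):
        rows, cols = np.nonzero(comp == comp_id)
        if offsets is not None:
            dr, dc = offsets[j]
            if (rows + dr).min() < 0 or (rows + dr).max() >= height:
                raise ValidationError("forced offset moves component out of bounds")
            if (cols + dc).min() < 0 or (cols + dc).max() >= width:
                raise ValidationError("forced offset moves component out of bounds")
        else:
            dr = int(rng.integers(-rows.min(), height - rows.max()))
            dc = int(rng.integers(-cols.min(), width - cols.max()))
        out_image[rows + dr, cols + dc] = src_image[rows, cols]
        out_labels[rows + dr, cols + dc] = src_mask.labels[rows, cols]
    return out_image, LabelMask(out_labels, n_classes)


def augment_pair(
    image: np.ndarray,
    mask: LabelMask,
    spec: AugmentSpec,
    rng: np.random.Generator | None = None,
    copy_source: tuple[np.ndarray, LabelMask] | None = None,
) -> tuple[np.ndarray, LabelMask]:
    """Apply the full pipeline (flips -> photometric -> copy-paste) once.

    With `rng` omitted a fresh generator is seeded from `spec.seed`, so the
    same spec and inputs replay bit-identically.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    image = np.asarray(image)
    _check_pair(image, mask)
    if rng.random() < spec.hflip_prob:
        image, mask = flip(image, mask, "horizontal")
    if rng.random() < spec.vflip_prob:
        image, mask = flip(image, mask, "vertical")
    image = photometric(image, spec, rng)
    if copy_source is not None and rng.random() < spec.copy_paste_prob:
        src_img, src_msk = copy_source
        image, mask = copy_paste(
            src_img, src_msk, image, mask, rng, spec.copy_paste_max_instances
        )
    return image, mask
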