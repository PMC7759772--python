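"""Image augmentation pipelines and imbalance correction.

Two presets mirror the training recipes: ``table4`` for the phase/problem
classifier (rotation to 90 deg, shifts to 20%, shear to 5 deg, zoom to 10%,
channel shift to 100 intensity units, both flips, random erasing to 25% of
the area) and ``table6`` for the segmenter (same geometric set, zoom to
20%, no photometric transforms, no erasing — masks must stay consistent).

Each transform is applied independently with probability 0.5 and a
magnitude drawn uniformly within its limit. Order: geometric warps, then
channel shift (on the 0-255 scale), then random erasing, then [0, 1]
normalization — erasing after the warp keeps the erased box axis-aligned.
Borders exposed by rotation/shift are filled with black (surgical frames
have dark borders).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import AffineTransform, warp

from .phantom import MaskSet


@dataclass(frozen=True)
class AugmentConfig:
    rotation: float = 0.0        # degrees
    shift_h: float = 0.0         # fraction of width
    shift_v: float = 0.0         # fraction of height
    shear: float = 0.0           # degrees
    zoom: float = 0.0            # fraction
    channel_shift: float = 0.0   # intensity units on 0-255
    flip_h: bool = False
    flip_v: bool = False
    erasing: float = 0.0         # max erased-area fraction
    p_apply: float = 0.5         # per-transform application probability

    def __post_init__(self) -> None:
        limits = (self.rotation, self.shift_h, self.shift_v, self.shear,
                  self.zoom, self.channel_shift, self.erasing)
        if any(v < 0 for v in limits):
            raise ValueError("all augmentation limits must be >= 0")
        if self.erasing > 1.0:
            raise ValueError("erasing fraction must be <= 1")


TABLE4 = AugmentConfig(rotation=90, shift_h=0.2, shift_v=0.2, shear=5, zoom=0.1,
                       channel_shift=100, flip_h=True, flip_v=True, erasing=0.25)
TABLE6 = AugmentConfig(rotation=90, shift_h=0.2, shift_v=0.2, shear=5, zoom=0.2,
                       flip_h=True, flip_v=True)

# Quarter-strength variants for the reduced CPU-training profile: the full
# magnitudes are tuned to hundreds of thousands of pretrained-init images
# and keep a small from-scratch run from converging at all (the +-100
# per-channel shift in particular destroys the color statistics a freshly
# initialized network must first latch onto).
TABLE4_SMALL = AugmentConfig(rotation=22.5, shift_h=0.05, shift_v=0.05, shear=1.25,
                             zoom=0.025, channel_shift=25, flip_h=True, flip_v=True,
                             erasing=0.25)
TABLE6_SMALL = AugmentConfig(rotation=22.5, shift_h=0.05, shift_v=0.05, shear=1.25,
                             zoom=0.05, flip_h=True, flip_v=True)

PRESETS = {"table4": TABLE4, "table6": TABLE6,
           "table4-small": TABLE4_SMALL, "table6-small": TABLE6_SMALL,
           "none": AugmentConfig()}


def normalize(image: np.ndarray) -> np.ndarray:
    """Scale 8-bit pixel values into [0, 1]."""
    return np.asarray(image, dtype=np.float32) / 255.0


def sample_params(config: AugmentConfig, rng: np.random.Generator) -> dict:
    """Draw one set of transform magnitudes (exposed for auditing draws)."""
    def maybe(limit: float, signed: bool = True) -> float:
        if limit <= 0 or rng.random() >= config.p_apply:
            return 0.0
        return float(rng.uniform(-limit, limit) if signed else rng.uniform(0, limit))

    return {
        "rotation": maybe(config.rotation),
        "shift_h": maybe(config.shift_h),
        "shift_v": maybe(config.shift_v),
        "shear": maybe(config.shear),
        "zoom": maybe(config.zoom),
        "channel_shift": np.array([maybe(config.channel_shift) for _ in range(3)]),
        "flip_h": bool(config.flip_h and rng.random() < config.p_apply),
        "flip_v": bool(config.flip_v and rng.random() < config.p_apply),
        "erasing": maybe(config.erasing, signed=False),
        "erasing_draw": rng.random(4),
    }


def _affine(params: dict, shape: tuple[int, int]) -> AffineTransform | None:
    h, w = shape
    if not (params["rotation"] or params["shift_h"] or params["shift_v"]
            or params["shear"] or params["zoom"] or params["flip_h"]
            or params["flip_v"]):
        return None
    center = np.array([w / 2.0, h / 2.0])
    scale = 1.0 + params["zoom"]
    sx = -1.0 if params["flip_h"] else 1.0
    sy = -1.0 if params["flip_v"] else 1.0
    to_center = AffineTransform(translation=-center)
    core = AffineTransform(scale=(scale * sx, scale * sy),
                           rotation=np.deg2rad(params["rotation"]),
                           shear=np.deg2rad(params["shear"]))
    back = AffineTransform(translation=center + [params["shift_h"] * w,
                                                 params["shift_v"] * h])
    return to_center + core + back


def _warp_image(image: np.ndarray, tf: AffineTransform, order: int) -> np.ndarray:
    return warp(image.astype(np.float64), tf.inverse, order=order, cval=0.0,
                preserve_range=True)


def _erase(image: np.ndarray, area_frac: float, draw: np.ndarray,
           rng: np.random.Generator) -> np.ndarray:
    """Fill one random axis-aligned rectangle (area <= area_frac) with noise."""
    if area_frac <= 0:
        return image
    h, w = image.shape[:2]
    area = area_frac * h * w
    aspect = 0.3 + draw[0] * (3.33 - 0.3)
    eh = min(h, max(1, int(round(np.sqrt(area * aspect)))))
    ew = min(w, max(1, int(round(area / max(eh, 1)))))
    y0 = int(draw[1] * (h - eh + 1))
    x0 = int(draw[2] * (w - ew + 1))
    out = image.copy()
    out[y0: y0 + eh, x0: x0 + ew] = rng.integers(0, 256, size=(eh, ew) + image.shape[2:])
    return out


def augment_classification(image: np.ndarray, config: AugmentConfig,
                           rng: np.random.Generator) -> np.ndarray:
    """Augment one 8-bit RGB frame for classifier training (shape preserved)."""
    params = sample_params(config, rng)
    out = image.astype(np.float64)
    tf = _affine(params, image.shape[:2])
    if tf is not None:
        out = _warp_image(out, tf, order=1)
    shift = params["channel_shift"]
    if np.any(shift):
        out = np.clip(out + shift[None, None, :], 0.0, 255.0)
    out = np.clip(out, 0.0, 255.0).round().astype(np.uint8)
    if params["erasing"] > 0:
        out = _erase(out, params["erasing"], params["erasing_draw"], rng)
    return out


def augment_segmentation(image: np.ndarray, masks: MaskSet, config: AugmentConfig,
                         rng: np.random.Generator) -> tuple[np.ndarray, MaskSet]:
    """Apply one identical geometric transform to a frame and all its masks.

    Masks are warped with nearest-neighbour interpolation and re-binarized,
    so they stay exactly {0, 1}.
    """
    if masks.cornea.shape != image.shape[:2]:
        raise ValueError("image and masks must share spatial dimensions")
    if config.channel_shift or config.erasing:
        raise ValueError("segmentation augmentation is geometric-only")
    params = sample_params(config, rng)
    tf = _affine(params, image.shape[:2])
    if tf is None:
        return image, masks
    img = np.clip(_warp_image(image.astype(np.float64), tf, order=1),
                  0, 255).round().astype(np.uint8)
    warped = {}
    for cls in MaskSet.CLASSES:
        m = _warp_image(getattr(masks, cls).astype(np.float64), tf, order=0)
        warped[cls] = (m >= 0.5).astype(np.uint8)
    return img, MaskSet(**warped)


def oversample_epoch(per_class: dict[str, list], rng: np.random.Generator | None = None
                     ) -> list:
    """Balanced one-epoch sampling plan for imbalanced classes.

    Each minority class is repeated round(majority/count) (>= 1) times so
    per-epoch class counts balance within one repetition unit; the plan is
    shuffled with ``rng`` when given.
    """
    if not per_class or any(len(v) == 0 for v in per_class.values()):
        raise ValueError("every class needs at least one item")
    majority = max(len(v) for v in per_class.values())
    plan: list = []
    for items in per_class.values():
        factor = max(1, int(round(majority / len(items))))
        plan.extend(list(items) * factor)
    if rng is not None:
        plan = [plan[i] for i in rng.permutation(len(plan))]
    return plan
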