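"""Training-set-only geometric augmentation.

Each draw samples a random affine transform inside the configured
ranges — rotation, shear, isotropic zoom, horizontal/vertical shift —
plus optional flips, and applies it about the image centre with
bilinear interpolation and nearest-edge fill.  Edge fill (rather than
zero fill) avoids introducing black borders that would look like
zeroed connective-tissue patches downstream.

Augmentation is applied to the training split only; validation and
test images pass through byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from skimage.transform import AffineTransform, warp

from .dataset import TRAIN, SplitPlan
from .synthdata import LabeledImage


@dataclass(frozen=True)
class AugmentationConfig:
    """Augmentation ranges; defaults follow the training recipe.

    ``zoom_range`` z draws a scale factor uniformly from
    ``[1 - z, 1 + z]`` (factors below 1 zoom in).  Shift ranges are
    fractions of the image dimensions.  Width/height shift default to
    0.1 and are configurable.
    """

    shear_range: float = 0.2
    rotation_range: float = 20.0  # degrees
    horizontal_flip: bool = True
    vertical_flip: bool = False
    zoom_range: float = 0.5
    width_shift_range: float = 0.1
    height_shift_range: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "shear_range",
            "rotation_range",
            "zoom_range",
            "width_shift_range",
            "height_shift_range",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def is_identity(self) -> bool:
        return (
            self.shear_range == 0
            and self.rotation_range == 0
            and self.zoom_range == 0
            and self.width_shift_range == 0
            and self.height_shift_range == 0
            and not self.horizontal_flip
            and not self.vertical_flip
        )


def draw_parameters(config: AugmentationConfig, draw_seed: int) -> dict:
    """Sample one set of transform parameters, deterministically.

    The random stream is keyed on ``(config.seed, draw_seed)``, so the
    same pair always yields the same transform.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(draw_seed,))
    )
    return {
        "rotation_deg": rng.uniform(-config.rotation_range, config.rotation_range),
        "shear": rng.uniform(-config.shear_range, config.shear_range),
        "zoom": rng.uniform(1.0 - config.zoom_range, 1.0 + config.zoom_range),
        "shift_x": rng.uniform(-config.width_shift_range, config.width_shift_range),
        "shift_y": rng.uniform(-config.height_shift_range, config.height_shift_range),
        "flip_h": bool(config.horizontal_flip and rng.random() < 0.5),
        "flip_v": bool(config.vertical_flip and rng.random() < 0.5),
    }


def apply_augmentation(
    image: np.ndarray, config: AugmentationConfig, draw_seed: int
) -> np.ndarray:
    """Apply one random draw of the configured transforms to an image.

    Output has the same shape and dtype as the input and is a pure
    function of ``(image, config.seed, draw_seed)``.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    p = draw_parameters(config, draw_seed)

    if (
        config.is_identity()
    ):  # exact pass-through: no interpolation round-trip at all
        return image.copy()

    h, w = image.shape[:2]
    out = image
    if p["flip_h"]:
        out = out[:, ::-1]
    if p["flip_v"]:
        out = out[::-1]

    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (
        AffineTransform(translation=-centre)
        + AffineTransform(
            rotation=np.deg2rad(p["rotation_deg"]),
            shear=p["shear"],
            scale=(p["zoom"], p["zoom"]),
        )
        + AffineTransform(translation=centre)
        + AffineTransform(translation=(p["shift_x"] * w, p["shift_y"] * h))
    )
    warped = warp(
        out.astype(np.float64),
        tf.inverse,
        order=1,  # bilinear
        mode="edge",
        preserve_range=True,
    )
    return np.clip(np.rint(warped), 0, 255).astype(image.dtype)


class SplitViolationError(RuntimeError):
    """Raised on an attempt to augment a non-training split."""


def augment_split(
    images: Iterable[LabeledImage],
    plan: SplitPlan,
    config: AugmentationConfig,
    split: str = TRAIN,
    epoch: int = 0,
    augment: bool | None = None,
) -> Iterator[LabeledImage]:
    """Stream one epoch of a split, augmenting training images only.

    Training images receive a fresh random draw per (image, epoch);
    validation and test images are yielded with their pixel buffers
    untouched.  Forcing ``augment=True`` on a non-training split
    raises :class:`SplitViolationError` — the held-out data must reach
    the model exactly as stored.
    """
    if augment is None:
        augment = split == TRAIN
    if augment and split != TRAIN:
        raise SplitViolationError(
            f"augmentation may only be attached to the training split, not {split!r}"
        )
    for idx, img in enumerate(images):
        if plan.split_of(img.source_id) != split:
            continue
        if not augment:
            yield img
            continue
        draw_seed = epoch * 1_000_003 + idx
        yield LabeledImage(
            pixels=apply_augmentation(img.pixels, config, draw_seed),
            label=img.label,
            tile_truth=img.tile_truth,
            source_id=img.source_id,
        )
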