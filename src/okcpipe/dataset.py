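"""Labeled image folders, resizing, and the stratified 70/15/15 split.

Folder layout: ``root/{OKC,nonOKC}/*.png`` (JPEG also accepted).  The
split is drawn independently per class (stratified) with a seeded
shuffle; test and validation sizes are floored, the remainder goes to
training.  With 1384 positives and fractions (0.70, 0.15, 0.15) the
floor rule yields the 207-image positive test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .synthdata import LabeledImage

logger = logging.getLogger(__name__)

TRAIN, VAL, TEST = "train", "val", "test"
DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)
IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class SplitPlan:
    """Deterministic per-class assignment of ids to train/val/test."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    fractions: tuple[float, float, float]
    seed: int
    labels: dict[str, str]  # id -> class

    def split_of(self, image_id: str) -> str:
        if image_id in self._train_set:
            return TRAIN
        if image_id in self._val_set:
            return VAL
        if image_id in self._test_set:
            return TEST
        raise KeyError(image_id)

    def __post_init__(self) -> None:
        self._train_set = set(self.train_ids)
        self._val_set = set(self.val_ids)
        self._test_set = set(self.test_ids)

    def per_class_counts(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for ids, split in (
            (self.train_ids, TRAIN),
            (self.val_ids, VAL),
            (self.test_ids, TEST),
        ):
            for i in ids:
                key = (self.labels[i], split)
                counts[key] = counts.get(key, 0) + 1
        return counts

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tclass\tsplit\n")
            for ids, split in (
                (self.train_ids, TRAIN),
                (self.val_ids, VAL),
                (self.test_ids, TEST),
            ):
                for i in ids:
                    fh.write(f"{i}\t{self.labels[i]}\t{split}\n")


def make_split(
    manifest: list[tuple[str, str]],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitPlan:
    """Stratified train/val/test split of ``(id, label)`` pairs.

    Per class: shuffle with the seed, take ``floor(f_test * N)`` ids
    for test, ``floor(f_val * N)`` for validation, remainder for
    training.  Deterministic; the three sets partition the manifest.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0:
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")

    if not manifest:
        raise ValueError("manifest is empty")
    by_class: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    for image_id, label in manifest:
        by_class.setdefault(label, []).append(image_id)
        labels[image_id] = label

    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    val_ids: list[str] = []
    test_ids: list[str] = []
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        if not ids:
            raise ValueError(f"class {label!r} is empty")
        rng.shuffle(ids)
        n = len(ids)
        n_test = int(np.floor(f_test * n))
        n_val = int(np.floor(f_val * n))
        test_ids.extend(ids[:n_test])
        val_ids.extend(ids[n_test : n_test + n_val])
        train_ids.extend(ids[n_test + n_val :])

    return SplitPlan(
        train_ids=train_ids,
        val_ids=val_ids,
        test_ids=test_ids,
        fractions=fractions,
        seed=seed,
        labels=labels,
    )


def resize_image(pixels: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an RGB uint8 array to (width, height)."""
    im = Image.fromarray(np.asarray(pixels, dtype=np.uint8))
    return np.asarray(im.resize(target_size, Image.BILINEAR))


def load_images(
    root: str | Path,
    target_size: tuple[int, int] | None = (224, 224),
) -> list[LabeledImage]:
    """Load per-class image folders, optionally resized.

    Class labels come from the sub-folder names; files are visited in
    stable (sorted) order.  Unreadable files are skipped with a logged
    warning rather than aborting the run.
    """
    root = Path(root)
    records: list[LabeledImage] = []
    skipped = 0
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for path in sorted(class_dir.iterdir()):
            if path.suffix.lower() not in IMAGE_SUFFIXES:
                continue
            try:
                with Image.open(path) as im:
                    im = im.convert("RGB")
                    if target_size is not None:
                        im = im.resize(target_size, Image.BILINEAR)
                    pixels = np.asarray(im)
            except (OSError, UnidentifiedImageError) as exc:
                skipped += 1
                logger.warning("skipping unreadable image %s: %s", path, exc)
                continue
            records.append(
                LabeledImage(
                    pixels=pixels,
                    label=class_dir.name,
                    source_id=path.stem,
                )
            )
    if skipped:
        logger.warning("skipped %d unreadable image(s) under %s", skipped, root)
    return records
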