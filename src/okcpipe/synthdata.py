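"""Seeded synthetic histology-like images with known tissue layout.

Real jaw-cyst sections are private clinical data, so every downstream
stage is exercised on synthetic images that reproduce the two
statistical contrasts the pipeline exploits:

* an *epithelium* compartment — darker, strongly textured (high
  grayscale variance);
* a *connective-tissue / stroma* compartment — bright field with low
  variance and a left-skewed intensity histogram (a sparse scattering
  of dark fibre pixels pulls the mean below the bulk, so most pixels
  sit strictly above the mean — the property the region-selection
  confirmation step tests).

The class signal lives only in the epithelium texture: keratocyst
(OKC) epithelium carries a periodic horizontal banding that mimics the
palisaded basal-cell layer, while non-OKC epithelium is unstructured
noise at the same total variance.  Brightness and variance are matched
across classes, so a classifier must learn texture, not intensity.

Default canvas is 384 x 216, a 1/10-scale analogue of the 3840 x 2160
acquisition format; the 3x3 tiling logic is scale-free.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

OKC = "OKC"
NON_OKC = "nonOKC"
CLASSES = (OKC, NON_OKC)

#: Default epithelium layout: a band along the top of the canvas, the
#: way lining epithelium borders the cyst lumen in a section.
DEFAULT_EPITHELIUM_TILES = frozenset({(0, 0), (0, 1), (0, 2)})

# Per-channel tints (R, G, B offsets) giving epithelium a
# haematoxylin-purple cast and stroma an eosin-pink one.
_EPI_TINT = (10.0, -18.0, 14.0)
_STROMA_TINT = (6.0, -4.0, -2.0)

# Stroma fibre speckles: fraction of pixels darkened, and by how much.
_SPECKLE_FRACTION = 0.08
_SPECKLE_DEPTH = 60.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic section image.

    ``epithelium_tiles`` is the set of (row, col) grid cells, in
    {0,1,2}^2, rendered as epithelium; it must be a non-empty strict
    subset of the nine cells.  ``pattern_period`` (pixels) controls the
    basal-palisading stripe rendered iff the class is OKC.
    """

    width: int = 384
    height: int = 216
    class_label: str = OKC
    epithelium_tiles: frozenset[tuple[int, int]] = DEFAULT_EPITHELIUM_TILES
    epithelium_mean: float = 140.0
    epithelium_texture_sd: float = 40.0
    stroma_mean: float = 220.0
    stroma_texture_sd: float = 3.0
    pattern_period: float = 24.0
    stripe_amplitude: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width % 3 or self.height % 3:
            raise ValueError(
                f"width and height must be divisible by 3, got {self.width} x {self.height}"
            )
        tiles = frozenset(self.epithelium_tiles)
        if not tiles:
            raise ValueError("epithelium_tiles must be non-empty")
        if not all(0 <= r <= 2 and 0 <= c <= 2 for r, c in tiles):
            raise ValueError("epithelium_tiles must lie in {0,1,2} x {0,1,2}")
        if len(tiles) >= 9:
            raise ValueError("epithelium_tiles must be a strict subset of the 9 cells")
        if self.class_label not in CLASSES:
            raise ValueError(f"class_label must be one of {CLASSES}")
        object.__setattr__(self, "epithelium_tiles", tiles)


@dataclass
class LabeledImage:
    """An RGB image with its class and (synthetic) tile ground truth."""

    pixels: np.ndarray  # H x W x 3 uint8
    label: str
    tile_truth: np.ndarray | None = None  # 3x3 bool, True = epithelium
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got {self.pixels.shape}")


def _epithelium_texture(
    rng: np.random.Generator, shape: tuple[int, int], row0: int, spec: SyntheticSpec
) -> np.ndarray:
    """Grayscale epithelium patch: noise, plus palisading stripes iff OKC.

    The stripe is a horizontal sinusoid in absolute image coordinates
    (phase continues across tiles).  Its variance A^2/2 is subtracted
    from the noise budget so both classes have the same total variance.
    """
    sd = spec.epithelium_texture_sd
    if spec.class_label == OKC:
        amp = min(spec.stripe_amplitude, sd * np.sqrt(2.0) * 0.999)
        noise_sd = float(np.sqrt(max(sd**2 - amp**2 / 2.0, 0.0)))
        rows = row0 + np.arange(shape[0])
        stripe = amp * np.sin(2.0 * np.pi * rows / spec.pattern_period)
        base = spec.epithelium_mean + stripe[:, None]
    else:
        noise_sd = sd
        base = np.full((shape[0], 1), spec.epithelium_mean)
    return base + rng.normal(0.0, noise_sd, size=shape)


def _stroma_texture(rng: np.random.Generator, shape: tuple[int, int], spec: SyntheticSpec) -> np.ndarray:
    """Bright near-uniform stroma with sparse dark fibre speckles."""
    patch = spec.stroma_mean + rng.normal(0.0, spec.stroma_texture_sd, size=shape)
    speckle = rng.random(shape) < _SPECKLE_FRACTION
    patch[speckle] -= _SPECKLE_DEPTH * (0.5 + rng.random(int(speckle.sum())))
    return patch


def generate_image(spec: SyntheticSpec) -> LabeledImage:
    """Render one synthetic section; pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    th, tw = h // 3, w // 3

    gray = np.empty((h, w))
    truth = np.zeros((3, 3), dtype=bool)
    for r in range(3):
        for c in range(3):
            sl = (slice(r * th, (r + 1) * th), slice(c * tw, (c + 1) * tw))
            if (r, c) in spec.epithelium_tiles:
                truth[r, c] = True
                gray[sl] = _epithelium_texture(rng, (th, tw), r * th, spec)
            else:
                gray[sl] = _stroma_texture(rng, (th, tw), spec)

    tint = np.zeros((h, w, 3))
    epi_mask = np.zeros((h, w), dtype=bool)
    for r, c in spec.epithelium_tiles:
        epi_mask[r * th : (r + 1) * th, c * tw : (c + 1) * tw] = True
    for ch in range(3):
        tint[..., ch] = np.where(epi_mask, _EPI_TINT[ch], _STROMA_TINT[ch])

    pixels = np.clip(gray[..., None] + tint, 0, 255).astype(np.uint8)
    return LabeledImage(
        pixels=pixels,
        label=spec.class_label,
        tile_truth=truth,
        source_id=f"{spec.class_label}_{spec.seed}",
    )


def generate_dataset(
    n_per_class: int,
    out_dir: str | Path | None = None,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
) -> list[LabeledImage]:
    """Generate a balanced two-class synthetic dataset.

    Per-image seeds are spawned deterministically from ``seed``.  When
    ``out_dir`` is given, images are written as PNG under per-class
    subfolders plus a ``manifest.tsv`` with columns ``id``, ``label``
    and ``tile_truth`` (nine comma-separated 0/1 flags, row-major).
    Returns the in-memory images either way.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = spec or SyntheticSpec()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_per_class)

    images: list[LabeledImage] = []
    k = 0
    for label in CLASSES:
        for i in range(n_per_class):
            img_spec = replace(
                base, class_label=label, seed=int(child_seeds[k] % (2**31))
            )
            k += 1
            img = generate_image(img_spec)
            img.source_id = f"{label}_{i:04d}"
            images.append(img)

    if out_dir is not None:
        out = Path(out_dir)
        for label in CLASSES:
            (out / label).mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "label", "tile_truth"])
            for img in images:
                path = out / img.label / f"{img.source_id}.png"
                Image.fromarray(img.pixels).save(path)
                flags = ",".join(str(int(v)) for v in img.tile_truth.ravel())
                writer.writerow([img.source_id, img.label, flags])

    return images


def read_manifest(out_dir: str | Path) -> list[dict]:
    """Read a generated manifest back as a list of row dicts."""
    rows = []
    with open(Path(out_dir) / "manifest.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            row["tile_truth"] = np.array(
                [int(v) for v in row["tile_truth"].split(",")], dtype=bool
            ).reshape(3, 3)
            rows.append(row)
    return rows
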