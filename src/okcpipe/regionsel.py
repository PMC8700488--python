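"""Epithelial-region selection by tile-variance thresholding.

Histology images of jaw cysts contain two compartments: the lining
epithelium (textured, stain-dense) and the supporting connective tissue
(pale, nearly uniform).  The classifier benefits from seeing only the
epithelium, so each image is cut into a 3x3 grid of patches and every
patch is tested with two cheap statistics:

1. *Variance candidate* — a patch whose grayscale variance is strictly
   below the mean of the nine patch variances is marked as possible
   connective tissue (stroma is flat, epithelium is textured).
2. *Intensity confirmation* — on the candidate patch, a strict majority
   of pixels brighter than the patch's own mean intensity confirms it
   (stroma is bright-field with a few dark fibres, so its intensity
   histogram is left-skewed and most mass sits above the mean).

Confirmed patches are zeroed in all channels and the grid is
reassembled at the original resolution.  At the nominal acquisition
size of 3840 x 2160 each patch is 1280 x 720.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights used for every grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

GRID = 3  # the method tiles into a fixed 3x3 grid


class DimensionError(ValueError):
    """Image too small (or wrongly shaped) to tile."""


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an H x W x 3 RGB image to float grayscale in [0, 255].

    Uses the BT.601 luminance ``0.299 R + 0.587 G + 0.114 B``.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DimensionError(
            f"expected an H x W x 3 RGB image, got shape {image.shape}"
        )
    r, g, b = LUMA_WEIGHTS
    return (
        r * image[..., 0].astype(np.float64)
        + g * image[..., 1].astype(np.float64)
        + b * image[..., 2].astype(np.float64)
    )


def _tile_bounds(n: int) -> list[tuple[int, int]]:
    """Start/stop pairs splitting ``n`` pixels into GRID runs.

    Floor-division tiling; the last run absorbs any remainder, so the
    tiles always concatenate back to the full extent.
    """
    step = n // GRID
    bounds = []
    for i in range(GRID):
        start = i * step
        stop = (i + 1) * step if i < GRID - 1 else n
        bounds.append((start, stop))
    return bounds


@dataclass
class TileGrid:
    """A 3x3 decomposition of an image with per-patch statistics.

    ``variances`` are population (N-denominator) variances of the
    grayscale patch; ``mean_variance`` is their arithmetic mean and is
    the threshold for the connective-tissue candidate test.
    """

    tiles: list[list[np.ndarray]]
    row_bounds: list[tuple[int, int]]
    col_bounds: list[tuple[int, int]]
    variances: np.ndarray  # 3x3 float
    mean_variance: float
    mean_intensities: np.ndarray  # 3x3 float

    def reassemble(self) -> np.ndarray:
        """Concatenate the tiles row-major back into one image."""
        rows = [np.concatenate(r, axis=1) for r in self.tiles]
        return np.concatenate(rows, axis=0)


def tile(image: np.ndarray) -> TileGrid:
    """Cut an RGB image into the 3x3 patch grid with statistics.

    Patch (r, c) spans rows ``[r*floor(H/3), ...)`` and columns
    ``[c*floor(W/3), ...)``; the last patch of each row/column absorbs
    the remainder, so a 3840 x 2160 image yields nine 1280 x 720
    patches exactly.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DimensionError(
            f"expected an H x W x 3 RGB image, got shape {image.shape}"
        )
    h, w = image.shape[:2]
    if h < GRID or w < GRID:
        raise DimensionError(f"image {h} x {w} smaller than the {GRID} x {GRID} grid")

    gray = to_grayscale(image)
    row_bounds = _tile_bounds(h)
    col_bounds = _tile_bounds(w)

    tiles: list[list[np.ndarray]] = []
    variances = np.empty((GRID, GRID))
    means = np.empty((GRID, GRID))
    for r, (r0, r1) in enumerate(row_bounds):
        row = []
        for c, (c0, c1) in enumerate(col_bounds):
            row.append(image[r0:r1, c0:c1])
            patch_gray = gray[r0:r1, c0:c1]
            variances[r, c] = patch_gray.var()  # population variance
            means[r, c] = patch_gray.mean()
        tiles.append(row)

    return TileGrid(
        tiles=tiles,
        row_bounds=row_bounds,
        col_bounds=col_bounds,
        variances=variances,
        mean_variance=float(variances.mean()),
        mean_intensities=means,
    )


def confirm_by_intensity(tile_gray: np.ndarray) -> bool:
    """Intensity-histogram confirmation of a connective-tissue patch.

    True iff a strict majority of the patch's pixels are strictly
    brighter than the patch's own mean intensity.  Ties (exactly half
    above) do not confirm — the conservative outcome keeps tissue.
    """
    tile_gray = np.asarray(tile_gray, dtype=np.float64)
    if tile_gray.size == 0:
        raise ValueError("empty tile")
    mean = tile_gray.mean()
    above = int(np.count_nonzero(tile_gray > mean))
    return above > tile_gray.size - above


@dataclass
class TileDecision:
    """Per-patch record of the two tests and their inputs."""

    row: int
    col: int
    variance: float
    mean_intensity: float
    above_mean_fraction: float
    candidate: bool
    confirmed: bool


@dataclass
class RegionSelectionResult:
    """Output of :func:`select_region`.

    ``output`` equals the input everywhere except in confirmed
    connective-tissue patches, which are zero in all channels.
    ``confirmed_mask`` implies ``candidate_mask`` element-wise.
    """

    output: np.ndarray
    candidate_mask: np.ndarray  # 3x3 bool: variance < mean variance
    confirmed_mask: np.ndarray  # 3x3 bool: candidate AND intensity-confirmed
    trace: list[TileDecision] = field(default_factory=list)
    grid: TileGrid | None = None


def select_region(image: np.ndarray) -> RegionSelectionResult:
    """Zero the confirmed connective-tissue patches of an RGB image.

    Candidate test uses strict ``<`` against the mean of the nine patch
    variances; on a perfectly uniform image every variance equals the
    mean, nothing is a candidate, and the image passes through
    unchanged.  If all nine patches end up confirmed the (fully black)
    output is still produced, with a warning — some specimens carry no
    epithelium at all.
    """
    grid = tile(image)
    gray = to_grayscale(np.asarray(image))

    candidate = grid.variances < grid.mean_variance
    confirmed = np.zeros((GRID, GRID), dtype=bool)
    trace: list[TileDecision] = []

    output = np.array(image, copy=True)
    for r, (r0, r1) in enumerate(grid.row_bounds):
        for c, (c0, c1) in enumerate(grid.col_bounds):
            patch_gray = gray[r0:r1, c0:c1]
            above_frac = float(
                np.count_nonzero(patch_gray > patch_gray.mean()) / patch_gray.size
            )
            conf = bool(candidate[r, c]) and confirm_by_intensity(patch_gray)
            confirmed[r, c] = conf
            if conf:
                output[r0:r1, c0:c1] = 0
            trace.append(
                TileDecision(
                    row=r,
                    col=c,
                    variance=float(grid.variances[r, c]),
                    mean_intensity=float(grid.mean_intensities[r, c]),
                    above_mean_fraction=above_frac,
                    candidate=bool(candidate[r, c]),
                    confirmed=conf,
                )
            )

    if confirmed.all():
        logger.warning(
            "all nine patches confirmed as connective tissue; output fully zeroed"
        )

    return RegionSelectionResult(
        output=output,
        candidate_mask=candidate,
        confirmed_mask=confirmed,
        trace=trace,
        grid=grid,
    )
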