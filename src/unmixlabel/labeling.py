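"""Assigning histology labels to representative pixels within ink marks.

An H&E slide gives one binary label (malignant/healthy) for a whole
~5x5 mm ink mark — a 10x10-pixel patch at 0.5 mm/pixel — but a single
training spectrum must be chosen from those 100 pixels. Three strategies:

* ``unmixing``: the tumor prediction map of the patch selects the pixel
  with the highest (malignant label) or lowest (healthy label) estimated
  tumor abundance — the pixel most likely to match the histology.
* ``center``: the patch center pixel, assuming the H&E slice went through
  the middle of the mark.
* ``average``: the element-wise mean of all 100 spectra.

Patch extents are half-open, 0-based: rows [r-5, r+5), cols [c-5, c+5),
exactly 100 pixels; the center pixel of the even-sized patch is local
(5, 5), i.e. the mark center itself.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BorderPatchError, ShapeMismatchError
from .hypercube import Hypercube
from .unmixing import EndmemberSet, unmix_patch

PATCH_HALF = 5
PATCH_SIZE = 10
CENTER_LOCAL = (5, 5)
STRATEGIES = ("unmixing", "center", "average")


@dataclass
class InkMark:
    """A ~5x5 mm black ink mark at pixel ``center`` on a specimen side."""

    center: tuple[int, int]
    mark_id: str = ""
    side_id: str = ""


@dataclass
class PixelPatch:
    """10x10 block of spectra under an ink mark plus its histology label."""

    block: np.ndarray  # (10, 10, bands)
    mark: InkMark
    he_label: int
    patient_id: str = ""
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.block = np.asarray(self.block, dtype=float)
        if self.block.ndim != 3 or self.block.shape[:2] != (PATCH_SIZE, PATCH_SIZE):
            raise ShapeMismatchError(
                f"patch block must be {PATCH_SIZE}x{PATCH_SIZE}xbands, got {self.block.shape}"
            )
        if self.he_label not in (0, 1):
            raise ValueError(f"histology label must be 0 or 1, got {self.he_label!r}")


@dataclass
class LabeledSpectrum:
    """A representative spectrum carrying its histology label.

    ``source`` records (mark_id, row, col, strategy); row/col are global
    image coordinates of the selected pixel (the mark center for the
    ``average`` strategy).
    """

    spectrum: np.ndarray
    label: int
    source: tuple[str, int, int, str]


def extract_patch(cube: Hypercube, mark: InkMark) -> PixelPatch:
    """Cut the 10x10 patch under an ink mark out of a cube.

    Marks whose patch crosses the image border are rejected; the clinical
    protocol places marks interiorly.
    """
    r, c = mark.center
    r0, r1 = r - PATCH_HALF, r + PATCH_HALF
    c0, c1 = c - PATCH_HALF, c + PATCH_HALF
    if r0 < 0 or c0 < 0 or r1 > cube.rows or c1 > cube.cols:
        raise BorderPatchError(
            f"patch for mark at ({r}, {c}) crosses the border of a "
            f"{cube.rows}x{cube.cols} image"
        )
    return PixelPatch(
        cube.data[r0:r1, c0:c1].copy(),
        mark,
        he_label=0,
        wavelengths=cube.wavelengths.copy(),
    )


def _global_coords(patch: PixelPatch, local: tuple[int, int]) -> tuple[int, int]:
    r, c = patch.mark.center
    return r - PATCH_HALF + local[0], c - PATCH_HALF + local[1]


def assign_label_unmixing(
    patch: PixelPatch, E: EndmemberSet, sum_to_one: str = "rescaled"
) -> LabeledSpectrum:
    """Pick the patch pixel whose tumor abundance best matches the label.

    Malignant patches yield the argmax of the tumor prediction map,
    healthy patches the argmin. Ties break to the first pixel in
    row-major order (numpy argmax/argmin convention).
    """
    amap = unmix_patch(patch.block, E, sum_to_one=sum_to_one)
    tumor = amap.tumor_map
    flat = int(np.argmax(tumor) if patch.he_label == 1 else np.argmin(tumor))
    local = np.unravel_index(flat, tumor.shape)
    row, col = _global_coords(patch, local)
    return LabeledSpectrum(
        patch.block[local].copy(),
        patch.he_label,
        (patch.mark.mark_id, row, col, "unmixing"),
    )


def assign_label_center(patch: PixelPatch) -> LabeledSpectrum:
    """Take the spectrum at the patch-local center pixel (5, 5)."""
    row, col = _global_coords(patch, CENTER_LOCAL)
    return LabeledSpectrum(
        patch.block[CENTER_LOCAL].copy(),
        patch.he_label,
        (patch.mark.mark_id, row, col, "center"),
    )


def assign_label_average(patch: PixelPatch) -> LabeledSpectrum:
    """Take the element-wise mean of all 100 patch spectra."""
    row, col = patch.mark.center
    return LabeledSpectrum(
        patch.block.mean(axis=(0, 1)),
        patch.he_label,
        (patch.mark.mark_id, row, col, "average"),
    )


def assign_label(
    strategy: str,
    patch: PixelPatch,
    E: EndmemberSet | None = None,
    sum_to_one: str = "rescaled",
) -> LabeledSpectrum:
    """Dispatch to one of the three labeling strategies by name."""
    if strategy == "unmixing":
        if E is None:
            raise ValueError("the unmixing strategy requires an endmember set")
        return assign_label_unmixing(patch, E, sum_to_one=sum_to_one)
    if strategy == "center":
        return assign_label_center(patch)
    if strategy == "average":
        return assign_label_average(patch)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
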