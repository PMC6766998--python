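"""Seed segmentation: thresholding, per-seed labeling, outer-ring erosion,
and per-pixel spectrum extraction.

Seeds are isolated on the gray-scale image at a single band (1200 nm by
default), labeled as connected components, and the outer ring of each seed
-- pixels contaminated by edge effects and shadow -- is removed by
morphological erosion before spectra are read out.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .hsi_io import HyperspectralScene, nearest_band
from .spectra import SpectraTable

log = logging.getLogger(__name__)


@dataclass
class SeedMask:
    """Integer label image: 0 = background, k >= 1 = seed index."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_seeds(self) -> int:
        return int(self.labels.max())

    def area(self, seed: int) -> int:
        return int((self.labels == seed).sum())


def binarize_at_band(scene: HyperspectralScene, band_nm: float = 1200.0,
                     threshold: float | str = "otsu") -> np.ndarray:
    """Foreground mask from the gray-scale image at ``band_nm``.

    ``threshold`` is either a fixed reflectance value or ``"otsu"`` for
    automatic selection.  An empty foreground is legal but warned about.
    """
    if not scene.calibrated:
        raise ValueError("scene must be calibrated before segmentation")
    gray = scene.cube[:, :, nearest_band(scene, band_nm)]
    if threshold == "otsu":
        thr = threshold_otsu(gray)
    else:
        thr = float(threshold)
    binary = gray > thr
    if not binary.any():
        warnings.warn("segmentation found no foreground pixels", stacklevel=2)
    return binary


def label_seeds(binary: np.ndarray, min_area: int = 20,
                connectivity: int = 8) -> SeedMask:
    """Connected components of ``binary`` with area >= ``min_area``,
    numbered in raster order of each component's topmost-leftmost pixel.
    Smaller components are dropped (count logged)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    comp = cc_label(binary, connectivity=1 if connectivity == 4 else 2)
    out = np.zeros_like(comp)
    kept = []
    for value in range(1, comp.max() + 1):
        pix = comp == value
        area = int(pix.sum())
        if area < min_area:
            continue
        ys, xs = np.nonzero(pix)
        order = np.lexsort((xs, ys))  # topmost, then leftmost
        kept.append(((int(ys[order][0]), int(xs[order][0])), value))
    dropped = comp.max() - len(kept)
    if dropped:
        log.info("label_seeds: dropped %d components below %d px", dropped, min_area)
    kept.sort()
    for new_id, (_, value) in enumerate(kept, start=1):
        out[comp == value] = new_id
    return SeedMask(labels=out)


def erode_outer_ring(mask: SeedMask, ring_width: int = 2) -> SeedMask:
    """Erode each seed region by a disk of radius ``ring_width``; seeds that
    vanish are removed and the survivors renumbered consecutively."""
    if ring_width < 0:
        raise ValueError("ring_width must be nonnegative")
    if ring_width == 0:
        return SeedMask(labels=mask.labels.copy())
    footprint = disk(ring_width)
    out = np.zeros_like(mask.labels)
    next_id = 1
    for seed in range(1, mask.n_seeds + 1):
        region = mask.labels == seed
        eroded = ndimage.binary_erosion(region, structure=footprint)
        if eroded.any():
            out[eroded] = next_id
            next_id += 1
    return SeedMask(labels=out)


def extract_pixel_spectra(scene: HyperspectralScene, mask: SeedMask,
                          seed_labels: list[int]) -> SpectraTable:
    """One row per foreground pixel, tagged with its seed index and class.

    ``seed_labels[k-1]`` is the class of seed ``k``.  Rows are emitted seed
    by seed, pixels in raster order.
    """
    if len(seed_labels) != mask.n_seeds:
        raise ValueError(
            f"got {len(seed_labels)} labels for {mask.n_seeds} seeds")
    rows, labels, seed_ids = [], [], []
    for seed in range(1, mask.n_seeds + 1):
        pix = mask.labels == seed
        rows.append(scene.cube[pix])
        n = int(pix.sum())
        labels.extend([seed_labels[seed - 1]] * n)
        seed_ids.extend([seed] * n)
    matrix = np.vstack(rows) if rows else np.empty((0, scene.n_bands))
    return SpectraTable(
        matrix=matrix,
        wavelengths=scene.wavelengths,
        labels=np.asarray(labels, dtype=int),
        seed_ids=np.asarray(seed_ids, dtype=int),
        granularity="pixel",
        provenance=["extract_pixel_spectra"],
    )
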