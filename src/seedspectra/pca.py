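"""Pixel-wise PCA, score-image rendering, and effective-wavelength
selection from PC loadings.

PCA is fit on (optionally subsampled) centered pixel spectra; each pixel's
projection onto a component yields a false-color "score image" that makes
between-variety differences visible.  Wavelengths where the absolute
loading of one of the leading components has a prominent local extremum are
"effective wavelengths": a reduced band set that stands in for the full
spectrum in downstream classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps

from .hsi_io import HyperspectralScene
from .segmentation import SeedMask
from .spectra import SpectraTable


@dataclass
class PCAResult:
    mean_spectrum: np.ndarray        # (n_bands,)
    loadings: np.ndarray             # (n_bands, n_pcs), orthonormal columns
    scores: np.ndarray               # (n_rows, n_pcs)
    explained_fraction: np.ndarray   # (n_pcs,) fraction of total variance
    wavelengths: np.ndarray          # (n_bands,) nm

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean_spectrum) @ self.loadings


@dataclass
class WavelengthSelection:
    """Sorted effective wavelengths with the PCs that proposed each one."""

    wavelengths: np.ndarray          # (n_selected,) nm, sorted unique
    band_indices: np.ndarray         # (n_selected,) indices into the axis
    source_pcs: dict[int, list[int]] = field(default_factory=dict)  # band -> PCs
    n_pcs: int = 10
    theta: float = 0.5

    def __len__(self) -> int:
        return self.wavelengths.size


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude entry of each
    loading column is positive (first occurrence on ties)."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_pca(table: SpectraTable, n_components: int = 10,
            max_pixels: int = 100_000, rng_seed: int = 0) -> PCAResult:
    """Column-centered PCA of the spectra matrix.

    When the table holds more than ``max_pixels`` rows, a uniform subsample
    (seeded) is used to estimate the mean, loadings and explained variance;
    scores are still computed for every row.  Explained fractions are taken
    against the total variance, so they sum to 1 only over all possible
    components.
    """
    X = table.matrix
    n_rows, n_bands = X.shape
    if n_rows < 2:
        raise ValueError("PCA needs at least 2 rows")
    if n_components > min(n_rows, n_bands):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_rows, n_bands)="
            f"{min(n_rows, n_bands)}")
    fit_X = X
    if n_rows > max_pixels:
        rng = np.random.default_rng(rng_seed)
        idx = rng.choice(n_rows, size=max_pixels, replace=False)
        fit_X = X[np.sort(idx)]
    mean = fit_X.mean(axis=0)
    centered = fit_X - mean
    # economy SVD of the centered fit matrix: right singular vectors are the
    # loading directions, singular values give the variance spectrum
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    variances = s ** 2 / (fit_X.shape[0] - 1)
    total = variances.sum()
    loadings = _fix_signs(vt[:n_components].T)
    explained = variances[:n_components] / total if total > 0 else np.zeros(n_components)
    scores = (X - mean) @ loadings
    return PCAResult(mean_spectrum=mean, loadings=loadings, scores=scores,
                     explained_fraction=explained, wavelengths=table.wavelengths.copy())


def score_image(pca: PCAResult, scene: HyperspectralScene, mask: SeedMask,
                pc_index: int, cmap: str = "jet",
                background_gray: float = 0.5) -> tuple[np.ndarray, float]:
    """False-color rendering of one component's per-pixel scores.

    Foreground pixels are colored by score through a fixed colormap scaled
    to the foreground score range; background is neutral gray.  Returns the
    RGB uint8 image and the component's explained-variance percentage for
    annotation.
    """
    if pc_index >= pca.n_pcs:
        raise ValueError(f"pc_index {pc_index} out of range (n_pcs={pca.n_pcs})")
    fg = mask.labels > 0
    if not fg.any():
        raise ValueError("mask has no foreground pixels")
    scores = (scene.cube[fg] - pca.mean_spectrum) @ pca.loadings[:, pc_index]
    lo, hi = scores.min(), scores.max()
    span = hi - lo if hi > lo else 1.0
    normed = (scores - lo) / span
    colors = colormaps[cmap](normed)[:, :3]
    image = np.full(mask.labels.shape + (3,), background_gray)
    image[fg] = colors
    explained_pct = float(pca.explained_fraction[pc_index] * 100.0)
    return (image * 255).astype(np.uint8), explained_pct


def _local_extrema(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of ``values`` (endpoints included when
    they beat their single neighbor)."""
    n = values.size
    if n == 1:
        return np.array([0])
    keep = np.zeros(n, dtype=bool)
    keep[0] = values[0] > values[1]
    keep[-1] = values[-1] > values[-2]
    interior = (values[1:-1] > values[:-2]) & (values[1:-1] > values[2:])
    keep[1:-1] = interior
    return np.nonzero(keep)[0]


def select_effective_wavelengths(pca: PCAResult, n_pcs: int = 10,
                                 theta: float = 0.5) -> WavelengthSelection:
    """Effective wavelengths from loading extrema.

    Per component: local maxima of the absolute loading along the wavelength
    axis whose magnitude is at least ``theta`` times that component's
    largest absolute loading.  The union over the first ``n_pcs`` components
    is deduplicated and sorted; each wavelength remembers which components
    proposed it.
    """
    if not (0.0 < theta <= 1.0):
        raise ValueError("theta must lie in (0, 1]")
    if n_pcs > pca.n_pcs:
        raise ValueError(f"n_pcs={n_pcs} exceeds fitted components {pca.n_pcs}")
    source: dict[int, list[int]] = {}
    for pc in range(n_pcs):
        mag = np.abs(pca.loadings[:, pc])
        peak = mag.max()
        if peak == 0:
            continue
        for band in _local_extrema(mag):
            if mag[band] >= theta * peak:
                source.setdefault(int(band), []).append(pc)
    bands = np.array(sorted(source), dtype=int)
    return WavelengthSelection(
        wavelengths=pca.wavelengths[bands] if bands.size else np.empty(0),
        band_indices=bands,
        source_pcs=source,
        n_pcs=n_pcs,
        theta=theta,
    )
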