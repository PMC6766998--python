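"""Chemometric preprocessing of pixel spectra.

Pipeline order (pixel level): wavelet smoothing -> area normalization ->
per-seed mean spectrum.  Wavelet smoothing decomposes each spectrum with a
Daubechies-10 wavelet to level 3 and reconstructs from the approximation
coefficients only, which removes detector noise while keeping the broad NIR
absorption features.  Area normalization divides each spectrum by its
discrete sum so that multiplicative illumination differences between pixels
cancel.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt

from .spectra import SpectraTable

log = logging.getLogger(__name__)


def wavelet_smooth(table: SpectraTable, wavelet: str = "db10",
                   level: int = 3, mode: str = "symmetric",
                   threshold: float | None = None) -> SpectraTable:
    """Row-wise wavelet denoising.

    Detail coefficients at every level are zeroed (or soft-thresholded when
    ``threshold`` is given) and the signal reconstructed from the
    approximation, truncated back to the original band count.  ``level = 0``
    is the identity.
    """
    if level < 0:
        raise ValueError("level must be nonnegative")
    if level == 0:
        return table.with_matrix(table.matrix.copy(),
                                 step=f"wavelet_smooth({wavelet},level=0)")
    wav = pywt.Wavelet(wavelet)
    n_bands = table.n_bands
    max_level = pywt.dwt_max_level(n_bands, wav.dec_len)
    if max_level < level:
        min_len = (wav.dec_len - 1) * 2 ** level
        raise ValueError(
            f"spectra of {n_bands} bands are too short for {wavelet} at "
            f"level {level}; at least {min_len} bands are required")
    coeffs = pywt.wavedec(table.matrix, wav, mode=mode, level=level, axis=-1)
    for i in range(1, len(coeffs)):
        if threshold is None:
            coeffs[i] = np.zeros_like(coeffs[i])
        else:
            coeffs[i] = pywt.threshold(coeffs[i], threshold, mode="soft")
    smooth = pywt.waverec(coeffs, wav, mode=mode, axis=-1)[..., :n_bands]
    return table.with_matrix(smooth,
                             step=f"wavelet_smooth({wavelet},level={level})")


def area_normalize(table: SpectraTable) -> SpectraTable:
    """Divide each row by its (unit-spacing) discrete area so rows sum to 1.

    Rows with nonpositive sums cannot be normalized; they are dropped with a
    logged count.
    """
    sums = table.matrix.sum(axis=1)
    good = sums > 0
    n_bad = int((~good).sum())
    out = table
    if n_bad:
        log.warning("area_normalize: dropped %d rows with nonpositive area", n_bad)
        out = out.select_rows(np.nonzero(good)[0])
        sums = sums[good]
    normalized = out.matrix / sums[:, None]
    return out.with_matrix(normalized, step="area_normalize")


def mean_spectrum_per_seed(pixel_table: SpectraTable) -> SpectraTable:
    """Average the pixel spectra within each seed; one row per seed, class
    label inherited, preprocessing provenance carried over."""
    if pixel_table.seed_ids is None:
        raise ValueError("pixel table must carry seed ids")
    seeds = np.unique(pixel_table.seed_ids)
    means = np.empty((seeds.size, pixel_table.n_bands))
    labels = np.empty(seeds.size, dtype=int)
    for i, seed in enumerate(seeds):
        rows = pixel_table.seed_ids == seed
        means[i] = pixel_table.matrix[rows].mean(axis=0)
        labels[i] = pixel_table.labels[rows][0]
    return SpectraTable(
        matrix=means,
        wavelengths=pixel_table.wavelengths,
        labels=labels,
        seed_ids=seeds,
        granularity="seed-mean",
        provenance=list(pixel_table.provenance) + ["mean_spectrum_per_seed"],
    )


def class_average_curves(seed_table: SpectraTable,
                         n_classes: int | None = None
                         ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-class mean and (population) SD curves for reporting average
    variety spectra.  Classes with no seeds are omitted with a log warning."""
    if n_classes is None:
        n_classes = seed_table.n_classes
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for cid in range(n_classes):
        rows = seed_table.labels == cid
        if not rows.any():
            log.warning("class_average_curves: class %d has no seeds", cid)
            continue
        block = seed_table.matrix[rows]
        curves[cid] = (block.mean(axis=0), block.std(axis=0, ddof=0))
    return curves
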