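"""Synthetic NIR hyperspectral scenes and labeled spectra.

The generator emulates the statistical structure of line-scan NIR images of
single seeds laid out on a dark background: every variety (class) shares one
smooth base reflectance curve with peaks near 1119/1308 nm and valleys near
1204/1470 nm, and differs from the others only on a small set of
"discriminative" bands where its mean is offset by a fixed deviation.
Scenes are rendered as raw sensor intensities together with white/dark
reference frames so that the standard white/dark correction recovers
reflectance; pixel noise combines a per-pixel multiplicative (illumination)
factor and per-band additive (detector) noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import GenerationError
from .hsi_io import HyperspectralScene, ReferencePair, write_scene
from .spectra import SpectraTable

DEFAULT_WAVELENGTH_RANGE = (942.0, 1646.0)
# shared spectral landmarks of the base curve: (center nm, amplitude, width nm)
_BASE_FEATURES = (
    (1119.0, +0.060, 28.0),   # peak
    (1204.0, -0.050, 22.0),   # valley
    (1308.0, +0.070, 35.0),   # peak
    (1470.0, -0.090, 45.0),   # valley
)


def default_wavelengths(band_count: int,
                        wavelength_range: tuple[float, float] = DEFAULT_WAVELENGTH_RANGE
                        ) -> np.ndarray:
    return np.linspace(wavelength_range[0], wavelength_range[1], band_count)


@dataclass(frozen=True)
class VarietyProfile:
    """Mean reflectance curve of one variety plus its informative bands."""

    class_id: int
    mean_curve: np.ndarray
    discriminative_bands: frozenset[int]
    deviation_magnitude: float

    def __post_init__(self) -> None:
        curve = np.asarray(self.mean_curve, dtype=float)
        object.__setattr__(self, "mean_curve", curve)
        if not np.all((curve > 0.0) & (curve < 1.0)):
            raise ValueError("mean_curve must lie strictly inside (0, 1)")
        if self.discriminative_bands and (
                min(self.discriminative_bands) < 0
                or max(self.discriminative_bands) >= curve.size):
            raise ValueError("discriminative_bands outside the band axis")


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and noise parameters for one rendered scene."""

    image_shape: tuple[int, int] = (128, 128)
    band_count: int = 200
    wavelength_range: tuple[float, float] = DEFAULT_WAVELENGTH_RANGE
    seeds_per_image: int = 5
    seed_radius_range: tuple[float, float] = (8.0, 14.0)
    noise_sd_additive: float = 0.01
    noise_sd_multiplicative: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.band_count < 2:
            raise ValueError("band_count must be at least 2")
        if self.seeds_per_image < 1:
            raise ValueError("seeds_per_image must be at least 1")

    @property
    def wavelengths(self) -> np.ndarray:
        return default_wavelengths(self.band_count, self.wavelength_range)


@dataclass
class RenderedScene:
    """Raw cube + references + ground truth from :func:`render_scene`."""

    raw: HyperspectralScene
    references: ReferencePair
    mask: np.ndarray            # (rows, cols) int, 0 background, k>=1 seed index
    seed_classes: np.ndarray    # (n_seeds,) class id per seed index (1-based -> [k-1])
    profiles: list = field(default_factory=list)


def _base_curve(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth shared curve: gentle upward quadratic trend plus Gaussian
    bumps at the four landmark wavelengths."""
    t = (wavelengths - wavelengths[0]) / (wavelengths[-1] - wavelengths[0])
    curve = 0.35 + 0.18 * t - 0.10 * (t - 0.5) ** 2
    for center, amp, width in _BASE_FEATURES:
        curve = curve + amp * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return curve


def make_variety_profiles(n_classes: int, band_count: int,
                          n_discriminative: int, deviation: float,
                          rng_seed: int,
                          wavelength_range: tuple[float, float] = DEFAULT_WAVELENGTH_RANGE
                          ) -> list[VarietyProfile]:
    """Class mean curves: one shared smooth base plus, per class, a signed
    ``deviation`` offset on a random set of ``n_discriminative`` bands.

    Reproducible for a fixed ``rng_seed``.  ``deviation = 0`` yields
    identical classes (the null configuration).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_discriminative > band_count:
        raise ValueError("n_discriminative cannot exceed band_count")
    if deviation < 0:
        raise ValueError("deviation must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    wavelengths = default_wavelengths(band_count, wavelength_range)
    base = _base_curve(wavelengths)
    profiles = []
    for class_id in range(n_classes):
        bands = rng.choice(band_count, size=n_discriminative, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_discriminative)
        curve = base.copy()
        curve[bands] += signs * deviation
        if not np.all((curve > 0.0) & (curve < 1.0)):
            raise ValueError(
                f"deviation {deviation} pushes class {class_id} outside (0, 1)")
        profiles.append(VarietyProfile(
            class_id=class_id,
            mean_curve=curve,
            discriminative_bands=frozenset(int(b) for b in bands),
            deviation_magnitude=float(deviation),
        ))
    return profiles


def _place_ellipses(rng: np.random.Generator, shape: tuple[int, int],
                    n_seeds: int, radius_range: tuple[float, float],
                    max_tries: int = 500) -> np.ndarray:
    """Non-overlapping random ellipses; labels 1..n_seeds in placement order.

    Raises :class:`GenerationError` when a seed cannot be placed within the
    retry budget.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = np.zeros(shape, dtype=int)
    occupied = np.zeros(shape, dtype=bool)
    for k in range(1, n_seeds + 1):
        for _ in range(max_tries):
            a = rng.uniform(*radius_range)          # semi-major
            b = rng.uniform(radius_range[0] * 0.7, a)  # semi-minor
            theta = rng.uniform(0, np.pi)
            margin = a + 2
            if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
                raise GenerationError("image too small for the seed radius range")
            cy = rng.uniform(margin, rows - margin)
            cx = rng.uniform(margin, cols - margin)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            # 1-pixel safety ring keeps seeds disjoint under 8-connectivity
            ring = (u / (a + 2)) ** 2 + (v / (b + 2)) ** 2 <= 1.0
            if not (ring & occupied).any():
                mask[inside] = k
                occupied |= ring
                break
        else:
            raise GenerationError(
                f"could not place seed {k}/{n_seeds} without overlap "
                f"after {max_tries} tries")
    return mask


def render_scene(spec: SceneSpec, profiles: list[VarietyProfile],
                 class_assignment: list[int]) -> RenderedScene:
    """Render raw intensities so that white/dark correction recovers the
    class reflectance curves.

    Seed pixels: ``raw = dark + (white - dark) * (r * m + e)`` with
    ``r`` the class curve, ``m`` a per-pixel lognormal illumination factor
    and ``e`` per-pixel-per-band additive Gaussian noise.  Background pixels
    sit just above the dark level with small jitter.
    """
    if len(class_assignment) != spec.seeds_per_image:
        raise ValueError("one class per seed required")
    by_class = {p.class_id: p for p in profiles}
    for cid in class_assignment:
        if cid not in by_class:
            raise ValueError(f"no profile for class {cid}")
    rng = np.random.default_rng(spec.rng_seed)
    rows, cols = spec.image_shape
    bands = spec.band_count
    mask = _place_ellipses(rng, spec.image_shape, spec.seeds_per_image,
                           spec.seed_radius_range)

    dark = np.full((rows, cols, bands), 100.0)
    white = np.full((rows, cols, bands), 4000.0)

    reflectance = np.empty((rows, cols, bands))
    bg = mask == 0
    reflectance[bg] = 0.015 + 0.01 * rng.random((int(bg.sum()), 1))
    for k, cid in enumerate(class_assignment, start=1):
        pix = mask == k
        n_pix = int(pix.sum())
        curve = by_class[cid].mean_curve
        mult = (np.exp(rng.normal(0.0, spec.noise_sd_multiplicative, size=(n_pix, 1)))
                if spec.noise_sd_multiplicative > 0 else np.ones((n_pix, 1)))
        add = (rng.normal(0.0, spec.noise_sd_additive, size=(n_pix, bands))
               if spec.noise_sd_additive > 0 else 0.0)
        reflectance[pix] = curve[None, :] * mult + add

    raw_cube = dark + (white - dark) * reflectance
    raw = HyperspectralScene(cube=raw_cube, wavelengths=spec.wavelengths,
                             calibrated=False)
    refs = ReferencePair(white=white, dark=dark)
    return RenderedScene(raw=raw, references=refs, mask=mask,
                         seed_classes=np.asarray(class_assignment, dtype=int),
                         profiles=list(profiles))


def make_labeled_spectra(profiles: list[VarietyProfile], n_per_class: int,
                         noise_sd: float, rng_seed: int) -> SpectraTable:
    """Balanced labeled spectra: class mean curve + i.i.d. Gaussian band
    noise.  A fast stand-in for the full imaging path in model-level work."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    band_count = profiles[0].mean_curve.size
    rows, labels = [], []
    for profile in profiles:
        block = np.tile(profile.mean_curve, (n_per_class, 1))
        if noise_sd > 0:
            block = block + rng.normal(0.0, noise_sd, size=block.shape)
        rows.append(block)
        labels.extend([profile.class_id] * n_per_class)
    return SpectraTable(
        matrix=np.vstack(rows),
        wavelengths=default_wavelengths(band_count),
        labels=np.asarray(labels),
        granularity="synthetic",
        provenance=[f"make_labeled_spectra(noise_sd={noise_sd},seed={rng_seed})"],
    )


def write_scene_bundle(directory, rendered: RenderedScene, name: str = "scene") -> dict:
    """Persist a rendered scene: ENVI cube + references, 16-bit PNG ground
    truth mask, and a JSON sidecar with per-seed class labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_scene(directory / f"{name}_raw", rendered.raw)
    wl = rendered.raw.wavelengths
    write_scene(directory / f"{name}_white",
                HyperspectralScene(rendered.references.white, wl))
    write_scene(directory / f"{name}_dark",
                HyperspectralScene(rendered.references.dark, wl))
    mask_path = directory / f"{name}_mask.png"
    iio.imwrite(mask_path, rendered.mask.astype(np.uint16))
    sidecar = {
        "seed_classes": [int(c) for c in rendered.seed_classes],
        "mask": mask_path.name,
        "raw": f"{name}_raw.img",
        "white": f"{name}_white.img",
        "dark": f"{name}_dark.img",
    }
    sidecar_path = directory / f"{name}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar
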