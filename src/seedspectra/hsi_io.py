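"""Hyperspectral scene container, ENVI-style I/O and reflectance calibration.

A scene is a ``rows x cols x bands`` cube with a strictly increasing
wavelength axis in nm.  Raw sensor cubes are converted to relative
reflectance with matching white (near-100 % reflectance target) and dark
(shutter closed) reference frames:

    R = (I_raw - I_dark) / (I_white - I_dark)

On disk a scene is a plain-text ENVI header (``.hdr``) next to a raw binary
cube (``.img``); BSQ, BIL and BIP interleaves are read, BSQ is written.
Internal storage is always band-last.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, StateError

log = logging.getLogger(__name__)

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperspectralScene:
    """Calibrated or raw cube plus wavelength metadata."""

    cube: np.ndarray          # (rows, cols, bands)
    wavelengths: np.ndarray   # (bands,) nm
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if self.cube.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"cube has {self.cube.shape[2]} bands, header lists "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.calibrated and not np.all(np.isfinite(self.cube)):
            raise ValueError("calibrated cube must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape

    @property
    def n_bands(self) -> int:
        return self.cube.shape[2]


@dataclass
class ReferencePair:
    """White and dark reference frames matching a scene's geometry.

    Frames may be full images (rows, cols, bands) or a single scan line
    (cols, bands) that is broadcast down the scan axis, which is how
    line-scan systems usually record their references.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share a shape")

    def as_full_frames(self, shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        if self.white.shape == shape:
            return self.white, self.dark
        if self.white.ndim == 2 and self.white.shape == shape[1:]:
            return (np.broadcast_to(self.white, shape),
                    np.broadcast_to(self.dark, shape))
        raise ValueError(
            f"reference shape {self.white.shape} incompatible with cube {shape}"
        )


# --------------------------------------------------------------------- ENVI
def write_scene(path, scene: HyperspectralScene, dtype=np.float64) -> None:
    """Write ``<path>.hdr`` + ``<path>.img`` (BSQ interleave)."""
    base = Path(path)
    rows, cols, bands = scene.cube.shape
    data = np.ascontiguousarray(
        np.transpose(scene.cube, (2, 0, 1)).astype(dtype))  # BSQ: band, line, sample
    data.tofile(base.with_suffix(".img"))
    wl = ", ".join(f"{w:.17g}" for w in scene.wavelengths)
    header = (
        "ENVI\n"
        "description = {seedspectra scene}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"calibrated = {int(scene.calibrated)}\n"
        "wavelength = {" + wl + "}\n"
    )
    base.with_suffix(".hdr").write_text(header)


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_braces:
            buf.append(line)
            if line.endswith("}"):
                fields[key] = " ".join(buf).strip("{} ")
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip().lower(), value.strip()
        if value.startswith("{") and not value.endswith("}"):
            buf, in_braces = [value], True
        else:
            fields[key] = value.strip("{} ")
    return fields


def read_scene(path) -> HyperspectralScene:
    """Load an ENVI header/binary pair; the calibrated flag defaults to raw."""
    base = Path(path)
    hdr_path = base.with_suffix(".hdr")
    img_path = base.with_suffix(".img")
    if not hdr_path.exists():
        raise FormatError(f"missing header file {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as exc:
        raise FormatError(f"header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError(f"{hdr_path} has no wavelength metadata")
    wavelengths = np.array([float(v) for v in fields["wavelength"].split(",")])
    if wavelengths.size != bands:
        raise FormatError(
            f"header lists {bands} bands but {wavelengths.size} wavelengths")
    dtype = _ENVI_DTYPES.get(code)
    if dtype is None:
        raise FormatError(f"unsupported ENVI data type code {code}")
    data = np.fromfile(img_path, dtype=dtype)
    if data.size != rows * cols * bands:
        raise FormatError(
            f"{img_path} holds {data.size} values; header implies "
            f"{rows * cols * bands}"
        )
    if interleave == "bsq":
        cube = data.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = data.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = data.reshape(rows, cols, bands)
    else:
        raise FormatError(f"unknown interleave '{interleave}'")
    calibrated = bool(int(fields.get("calibrated", "0")))
    return HyperspectralScene(cube=cube.astype(float), wavelengths=wavelengths,
                              calibrated=calibrated)


# -------------------------------------------------------------- calibration
def correct_reflectance(scene: HyperspectralScene, refs: ReferencePair,
                        clip: bool = True) -> HyperspectralScene:
    """White/dark reflectance correction, R = (raw - dark) / (white - dark).

    Pixels where white == dark (dead pixels) are set to 0 and counted in the
    log rather than raising.  With ``clip`` the output is clamped to [0, 1];
    specular pixels can otherwise exceed 1.
    """
    if scene.calibrated:
        raise StateError("scene is already calibrated")
    white, dark = refs.as_full_frames(scene.cube.shape)
    denom = white - dark
    dead = denom == 0
    n_dead = int(dead.sum())
    if n_dead:
        log.warning("reflectance correction: %d dead entries set to 0", n_dead)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(dead, 0.0, (scene.cube - dark) / np.where(dead, 1.0, denom))
    if clip:
        corrected = np.clip(corrected, 0.0, 1.0)
    return replace(scene, cube=corrected, calibrated=True)


def nearest_band(scene_or_wavelengths, target_nm: float) -> int:
    """Index of the band closest to ``target_nm``; ties go to the lower index.

    Targets beyond the axis by more than one mean band spacing trigger a
    warning but still resolve to the nearest band.
    """
    if isinstance(scene_or_wavelengths, HyperspectralScene):
        wavelengths = scene_or_wavelengths.wavelengths
    else:
        wavelengths = np.asarray(scene_or_wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty wavelength axis")
    spacing = (np.diff(wavelengths).mean() if wavelengths.size > 1 else np.inf)
    if (target_nm < wavelengths[0] - spacing) or (target_nm > wavelengths[-1] + spacing):
        warnings.warn(
            f"target {target_nm} nm lies outside the {wavelengths[0]:.0f}-"
            f"{wavelengths[-1]:.0f} nm axis", stacklevel=2)
    return int(np.argmin(np.abs(wavelengths - target_nm)))
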