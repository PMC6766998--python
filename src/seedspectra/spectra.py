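"""Labeled spectra container shared by every modelling stage.

A :class:`SpectraTable` holds an ``n_rows x n_bands`` reflectance matrix with
its wavelength axis, integer class labels, optional per-row seed indices, a
row-granularity tag (``"pixel"`` or ``"seed-mean"`` or ``"synthetic"``) and a
provenance list recording the preprocessing steps applied, in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class SpectraTable:
    matrix: np.ndarray          # (n_rows, n_bands) reflectance, unitless
    wavelengths: np.ndarray     # (n_bands,) nm, strictly increasing
    labels: np.ndarray          # (n_rows,) integer class ids in 0..C-1
    seed_ids: np.ndarray | None = None   # (n_rows,) seed index, if pixel rows
    granularity: str = "pixel"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (rows x bands)")
        if self.matrix.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} bands but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if self.labels.size != self.matrix.shape[0]:
            raise ValueError("one label per row required")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.seed_ids is not None:
            self.seed_ids = np.asarray(self.seed_ids, dtype=int)
            if self.seed_ids.size != self.matrix.shape[0]:
                raise ValueError("one seed id per row required")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bands(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def with_matrix(self, matrix: np.ndarray, step: str | None = None) -> "SpectraTable":
        """Copy of the table with a new matrix and, optionally, one more
        provenance entry."""
        prov = list(self.provenance) + ([step] if step else [])
        return replace(self, matrix=np.asarray(matrix, dtype=float), provenance=prov)

    def select_rows(self, index: np.ndarray) -> "SpectraTable":
        index = np.asarray(index)
        return replace(
            self,
            matrix=self.matrix[index],
            labels=self.labels[index],
            seed_ids=None if self.seed_ids is None else self.seed_ids[index],
            provenance=list(self.provenance),
        )

    def select_bands(self, band_index: np.ndarray, step: str | None = None) -> "SpectraTable":
        band_index = np.asarray(band_index, dtype=int)
        prov = list(self.provenance) + ([step] if step else [])
        return replace(
            self,
            matrix=self.matrix[:, band_index],
            wavelengths=self.wavelengths[band_index],
            provenance=prov,
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """CSV layout: optional seed_id column, class label column, then one
        column per wavelength (header = wavelength in nm)."""
        cols = {}
        if self.seed_ids is not None:
            cols["seed_id"] = self.seed_ids
        cols["class"] = self.labels
        frame = pd.DataFrame(cols)
        spec = pd.DataFrame(self.matrix, columns=[f"{w:.6g}" for w in self.wavelengths])
        pd.concat([frame, spec], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, granularity: str = "pixel") -> "SpectraTable":
        frame = pd.read_csv(path)
        seed_ids = None
        if "seed_id" in frame.columns:
            seed_ids = frame.pop("seed_id").to_numpy()
        labels = frame.pop("class").to_numpy()
        wavelengths = np.array([float(c) for c in frame.columns])
        return cls(
            matrix=frame.to_numpy(dtype=float),
            wavelengths=wavelengths,
            labels=labels,
            seed_ids=seed_ids,
            granularity=granularity,
        )
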