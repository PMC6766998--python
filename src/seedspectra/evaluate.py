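"""Dataset splitting, metrics, and the 11-model x 2-feature-set experiment.

The experiment mirrors a standard chemometric model comparison: pure LR /
PLS-DA / SVM on the spectra, the two deep networks trained end-to-end with
a softmax head, and hybrid models where LR / PLS-DA / SVM are fit on the
frozen deep features — each evaluated on full spectra and on the selected
effective wavelengths, over shared calibration (3) / validation (1) /
prediction (1) partitions.

The grid is exposed model-style: build a :class:`SeedGridExperiment` from a
seed-level spectra table, call ``fit()``, and read accuracies, confusion
matrices and a Table-2-like ``summary()`` off the returned
:class:`GridResults`.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classical import LRClassifier, PLSDAClassifier, SVMClassifier, default_svm_grid
from .errors import SplitError
from .nn.networks import NetworkSpec, build_network
from .nn.training import TrainingConfig, extract_features, train
from .pca import WavelengthSelection, fit_pca, select_effective_wavelengths
from .spectra import SpectraTable

SPLIT_NAMES = ("calibration", "validation", "prediction")
MODEL_NAMES = (
    "CNN-SoftMax", "CNN-LR", "CNN-PLS-DA", "CNN-SVM",
    "ResNet-SoftMax", "ResNet-LR", "ResNet-PLS-DA", "ResNet-SVM",
    "LR", "PLS-DA", "SVM",
)
FEATURE_SETS = ("full-spectra", "effective-wavelengths")


# ------------------------------------------------------------------ splits
@dataclass
class DatasetSplit:
    calibration: np.ndarray
    validation: np.ndarray
    prediction: np.ndarray
    ratio: tuple[int, int, int] = (3, 1, 1)
    rng_seed: int = 0
    stratified: bool = True

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"calibration": self.calibration, "validation": self.validation,
                "prediction": self.prediction}


def _allocate(n: int, ratio: tuple[int, ...]) -> list[int]:
    """Largest-remainder apportionment of n items to the ratio parts."""
    total = sum(ratio)
    exact = [n * r / total for r in ratio]
    counts = [int(e) for e in exact]
    rest = n - sum(counts)
    order = sorted(range(len(ratio)), key=lambda i: exact[i] - counts[i],
                   reverse=True)
    for i in order[:rest]:
        counts[i] += 1
    return counts


def split_dataset(labels_or_table, ratio: tuple[int, int, int] = (3, 1, 1),
                  rng_seed: int = 0, stratified: bool = True) -> DatasetSplit:
    """Random calibration/validation/prediction split, stratified by class
    by default, reproducible under ``rng_seed``."""
    labels = (labels_or_table.labels if isinstance(labels_or_table, SpectraTable)
              else np.asarray(labels_or_table, dtype=int))
    rng = np.random.default_rng(rng_seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    if stratified:
        for cid in np.unique(labels):
            idx = np.nonzero(labels == cid)[0]
            if idx.size < sum(ratio):
                raise SplitError(
                    f"class {cid} has only {idx.size} rows; a {ratio} split "
                    f"needs at least {sum(ratio)}")
            idx = rng.permutation(idx)
            counts = _allocate(idx.size, ratio)
            bounds = np.cumsum(counts)[:-1]
            for part, chunk in zip(parts, np.split(idx, bounds)):
                part.append(chunk)
    else:
        idx = rng.permutation(labels.size)
        counts = _allocate(idx.size, ratio)
        bounds = np.cumsum(counts)[:-1]
        for part, chunk in zip(parts, np.split(idx, bounds)):
            part.append(chunk)
    cal, val, pred = (np.sort(np.concatenate(p)) for p in parts)
    return DatasetSplit(calibration=cal, validation=val, prediction=pred,
                        ratio=ratio, rng_seed=rng_seed, stratified=stratified)


# ----------------------------------------------------------------- metrics
def accuracy(y_true, y_pred) -> float:
    """Percentage of correctly classified samples."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("label vectors differ in length")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    return 100.0 * float(np.mean(y_true == y_pred))


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix with entry (i, j) = true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError("labels out of range 0..n_classes-1")
    out = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(out, (y_true, y_pred), 1)
    return out


# ----------------------------------------------------------------- results
@dataclass
class CellResult:
    model: str
    feature_set: str
    n_features: int
    accuracies: dict[str, float]                # split -> %
    confusions: dict[str, np.ndarray]           # split -> KxK counts
    hyperparameters: dict = field(default_factory=dict)


@dataclass
class GridResults:
    """Accuracies and confusion matrices for every grid cell, plus the
    provenance needed to reproduce the run."""

    cells: dict[tuple[str, str], CellResult]
    split: DatasetSplit
    n_classes: int
    master_seed: int
    selection: WavelengthSelection | None = None

    def cell(self, model: str, feature_set: str = "full-spectra") -> CellResult:
        return self.cells[(model, feature_set)]

    def summary(self) -> pd.DataFrame:
        """Accuracy table shaped like the classical model-comparison layout:
        one row per classifier, split columns per feature set."""
        columns = pd.MultiIndex.from_product([FEATURE_SETS, SPLIT_NAMES])
        data = []
        for model in MODEL_NAMES:
            row = []
            for fs in FEATURE_SETS:
                cell = self.cells.get((model, fs))
                row.extend([cell.accuracies[s] if cell else np.nan
                            for s in SPLIT_NAMES])
            data.append(row)
        return pd.DataFrame(data, index=list(MODEL_NAMES), columns=columns)

    def to_json(self) -> str:
        payload = {
            "master_seed": self.master_seed,
            "n_classes": self.n_classes,
            "split": {name: idx.tolist()
                      for name, idx in self.split.as_dict().items()},
            "selection": (self.selection.wavelengths.tolist()
                          if self.selection is not None else None),
            "cells": {
                f"{model}|{fs}": {
                    "n_features": cell.n_features,
                    "accuracies": {k: round(v, 6)
                                   for k, v in cell.accuracies.items()},
                    "confusions": {k: v.tolist()
                                   for k, v in cell.confusions.items()},
                    "hyperparameters": cell.hyperparameters,
                }
                for (model, fs), cell in sorted(self.cells.items())
            },
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def save_confusion_heatmaps(self, directory, model: str,
                                feature_set: str = "full-spectra") -> list:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cell = self.cell(model, feature_set)
        paths = []
        for split_name in SPLIT_NAMES:
            fig, ax = plt.subplots(figsize=(4.5, 4))
            cm = cell.confusions[split_name]
            ax.imshow(cm, cmap="Blues")
            for i in range(cm.shape[0]):
                for j in range(cm.shape[1]):
                    ax.text(j, i, str(cm[i, j]), ha="center", va="center",
                            fontsize=7)
            ax.set_xlabel("predicted class")
            ax.set_ylabel("true class")
            ax.set_title(f"{model} / {feature_set}\n{split_name} "
                         f"({cell.accuracies[split_name]:.2f}%)")
            out = directory / f"confusion_{model}_{feature_set}_{split_name}.png"
            fig.tight_layout()
            fig.savefig(out, dpi=120)
            plt.close(fig)
            paths.append(out)
        return paths


# -------------------------------------------------------------- experiment
@dataclass(frozen=True)
class GridConfig:
    """Hyperparameters shared by every cell of one experiment run.

    The SVM search grid here is a coarser 4x4 log-spaced subset of the
    classifier's default 7x7 ranges: the experiment fits six SVMs per run,
    and the coarse grid keeps the sweep tractable without leaving the
    standard (C, gamma) decades.
    """

    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 0.01
    momentum: float = 0.9
    patience: int = 10
    pls_max_lv: int = 30
    lr_C: float = 1.0
    svm_C_grid: tuple = (1e-2, 1e0, 1e2, 1e4)
    svm_gamma_grid: tuple = (1e-4, 1e-2, 1e0, 1e2)
    svm_folds: int = 5
    selection_n_pcs: int = 10
    selection_theta: float = 0.5


def _cell_seed(master_seed: int, name: str) -> int:
    return (master_seed * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


class SeedGridExperiment:
    """The full model-comparison experiment on a seed-level spectra table.

    Parameters
    ----------
    table:
        Seed-mean (or synthetic seed-level) spectra with class labels.
    selection:
        Effective wavelengths; computed from a 10-PC loading-extremum
        selection on the table itself when not supplied.
    config:
        Hyperparameters shared by every grid cell.
    """

    def __init__(self, table: SpectraTable,
                 selection: WavelengthSelection | None = None,
                 config: GridConfig = GridConfig()):
        self.table = table
        self.config = config
        if selection is None:
            pca = fit_pca(table, n_components=min(config.selection_n_pcs,
                                                  table.n_bands, table.n_rows - 1))
            selection = select_effective_wavelengths(
                pca, n_pcs=pca.n_pcs, theta=config.selection_theta)
        self.selection = selection

    # ------------------------------------------------------------ internals
    def _evaluate_cell(self, model_name: str, fs: str, n_features: int,
                       predict, split_data, hyper: dict) -> CellResult:
        accs, cms = {}, {}
        for split_name, (X, y) in split_data.items():
            pred = predict(X)
            accs[split_name] = accuracy(y, pred)
            cms[split_name] = confusion_matrix(y, pred, self.n_classes)
        return CellResult(model=model_name, feature_set=fs,
                          n_features=n_features, accuracies=accs,
                          confusions=cms, hyperparameters=hyper)

    def _fit_classical(self, name: str, X_cal, y_cal, seed: int):
        cfg = self.config
        if name == "LR":
            model = LRClassifier(C=cfg.lr_C)
            model.fit(X_cal, y_cal)
            hyper = {"penalty": "l2", "C": cfg.lr_C}
        elif name == "PLS-DA":
            model = PLSDAClassifier(max_lv=cfg.pls_max_lv)
            model.fit(X_cal, y_cal)
            hyper = {"n_lv": model.n_lv_}
        elif name == "SVM":
            model = SVMClassifier(C_grid=np.asarray(cfg.svm_C_grid),
                                  gamma_grid=np.asarray(cfg.svm_gamma_grid),
                                  folds=cfg.svm_folds)
            model.fit(X_cal, y_cal)
            hyper = {"C": model.C_, "gamma": model.gamma_}
        else:
            raise ValueError(name)
        return model, hyper

    # ----------------------------------------------------------------- fit
    def fit(self, master_seed: int = 0) -> GridResults:
        table = self.table
        self.n_classes = table.n_classes
        split = split_dataset(table.labels, ratio=(3, 1, 1),
                              rng_seed=master_seed, stratified=True)
        idx = split.as_dict()
        cells: dict[tuple[str, str], CellResult] = {}
        feature_matrices = {
            "full-spectra": table.matrix,
            "effective-wavelengths": table.matrix[:, self.selection.band_indices],
        }
        cfg = self.config
        for fs, X_all in feature_matrices.items():
            split_data = {name: (X_all[i], table.labels[i])
                          for name, i in idx.items()}
            X_cal, y_cal = split_data["calibration"]
            X_val, y_val = split_data["validation"]

            # pure classical models on the spectra directly
            for name in ("LR", "PLS-DA", "SVM"):
                seed = _cell_seed(master_seed, f"{name}|{fs}")
                model, hyper = self._fit_classical(name, X_cal, y_cal, seed)
                cells[(name, fs)] = self._evaluate_cell(
                    name, fs, X_all.shape[1], model.predict, split_data, hyper)

            # deep networks: one per architecture, shared by the softmax
            # head and the three hybrid cells
            for arch, prefix in (("self-design-cnn", "CNN"),
                                 ("resnet-1d", "ResNet")):
                seed = _cell_seed(master_seed, f"{prefix}|{fs}")
                net = build_network(
                    NetworkSpec(architecture=arch, n_classes=self.n_classes),
                    n_bands=X_all.shape[1], rng_seed=seed)
                history = train(net, X_cal, y_cal, X_val, y_val,
                                TrainingConfig(
                                    learning_rate=cfg.learning_rate,
                                    momentum=cfg.momentum,
                                    batch_size=cfg.batch_size,
                                    epochs=cfg.epochs,
                                    patience=cfg.patience,
                                    rng_seed=seed))
                hyper = {"epochs_run": history.n_epochs,
                         "best_epoch": history.best_epoch,
                         "learning_rate": cfg.learning_rate}
                cells[(f"{prefix}-SoftMax", fs)] = self._evaluate_cell(
                    f"{prefix}-SoftMax", fs, X_all.shape[1],
                    net.predict_classes, split_data, hyper)

                # frozen deep features for the hybrid classifiers; the
                # network saw only calibration (+validation for stopping)
                feats = {name: extract_features(net, X, y).matrix
                         for name, (X, y) in split_data.items()}
                feat_split = {name: (feats[name], split_data[name][1])
                              for name in split_data}
                for name in ("LR", "PLS-DA", "SVM"):
                    cell_name = f"{prefix}-{name}"
                    cseed = _cell_seed(master_seed, f"{cell_name}|{fs}")
                    model, chyper = self._fit_classical(
                        name, feats["calibration"], y_cal, cseed)
                    chyper["feature_source"] = ("cnn-dense2" if prefix == "CNN"
                                                else "resnet-gap")
                    cells[(cell_name, fs)] = self._evaluate_cell(
                        cell_name, fs, net.feature_dim, model.predict,
                        {k: v for k, v in feat_split.items()}, chyper)

        return GridResults(cells=cells, split=split, n_classes=self.n_classes,
                           master_seed=master_seed, selection=self.selection)


def run_experiment_grid(seed_table: SpectraTable,
                        selection: WavelengthSelection | None = None,
                        config: GridConfig = GridConfig(),
                        master_seed: int = 0) -> GridResults:
    """Functional wrapper around :class:`SeedGridExperiment`."""
    return SeedGridExperiment(seed_table, selection, config).fit(master_seed)
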