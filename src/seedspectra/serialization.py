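"""Persistence for fitted models and PCA results.

Classical classifiers are stored as a pickle next to a JSON summary (kind,
hyperparameters, provenance, format version) so a run's model zoo is
auditable without unpickling.  Networks are stored as an ``.npz`` of their
weight arrays next to a JSON architecture manifest and can be rebuilt
without retraining.  PCA models are an ``.npz`` of coefficients plus JSON
metadata.
"""

from __future__ import annotations

import dataclasses
import json
import pickle
from pathlib import Path

import numpy as np

from .nn.networks import NetworkSpec, SpectralNetwork, build_network
from .nn.training import TrainingHistory
from .pca import PCAResult

FORMAT_VERSION = 1


# ------------------------------------------------------------- classical
def save_classifier(model, path) -> None:
    """Write ``<path>.pkl`` (the fitted model) + ``<path>.json`` (summary)."""
    base = Path(path)
    base.with_suffix(".pkl").write_bytes(pickle.dumps(model))
    summary = {
        "format_version": FORMAT_VERSION,
        "kind": model.kind,
        "provenance": model.provenance,
        "hyperparameters": {
            k: v for k, v in vars(model).items()
            if k.endswith("_") and isinstance(v, (int, float, str))
        },
    }
    base.with_suffix(".json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True))


def load_classifier(path):
    return pickle.loads(Path(path).with_suffix(".pkl").read_bytes())


# -------------------------------------------------------------- networks
def save_network(model: SpectralNetwork, path,
                 history: TrainingHistory | None = None) -> None:
    """Write ``<path>.npz`` (weights + optional standardizer) and
    ``<path>.json`` (architecture manifest); optionally the training
    history as ``<path>_history.csv``."""
    base = Path(path)
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    if model.band_mean is not None:
        arrays["band_mean"] = model.band_mean
        arrays["band_scale"] = model.band_scale
    np.savez(base.with_suffix(".npz"), **arrays)
    manifest = {
        "format_version": FORMAT_VERSION,
        "spec": dataclasses.asdict(model.spec),
        "n_bands": model.n_bands,
        "trained": model.trained,
        "audit": model.architecture_audit(),
    }
    base.with_suffix(".json").write_text(json.dumps(manifest, indent=2,
                                                    sort_keys=True))
    if history is not None:
        import pandas as pd

        frame = pd.DataFrame({
            "epoch": np.arange(1, history.n_epochs + 1),
            "train_loss": history.train_loss,
            "train_accuracy": history.train_accuracy,
            "val_loss": history.val_loss,
            "val_accuracy": history.val_accuracy,
        })
        frame.to_csv(base.parent / f"{base.stem}_history.csv", index=False)


def load_network(path) -> SpectralNetwork:
    base = Path(path)
    manifest = json.loads(base.with_suffix(".json").read_text())
    spec_fields = manifest["spec"]
    for key in ("cnn_channels", "dense_sizes", "resnet_channels"):
        spec_fields[key] = tuple(spec_fields[key])
    model = build_network(NetworkSpec(**spec_fields), manifest["n_bands"])
    data = np.load(base.with_suffix(".npz"))
    for i, target in enumerate(model.state_arrays()):
        target[...] = data[f"arr_{i}"]
    if "band_mean" in data:
        model.band_mean = data["band_mean"]
        model.band_scale = data["band_scale"]
    model.trained = bool(manifest["trained"])
    return model


# ------------------------------------------------------------------- PCA
def save_pca(pca: PCAResult, path) -> None:
    base = Path(path)
    np.savez(base.with_suffix(".npz"), mean_spectrum=pca.mean_spectrum,
             loadings=pca.loadings, scores=pca.scores,
             explained_fraction=pca.explained_fraction,
             wavelengths=pca.wavelengths)
    meta = {
        "format_version": FORMAT_VERSION,
        "n_pcs": pca.n_pcs,
        "explained_pct": [float(100 * f) for f in pca.explained_fraction],
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_pca(path) -> PCAResult:
    data = np.load(Path(path).with_suffix(".npz"))
    return PCAResult(mean_spectrum=data["mean_spectrum"],
                     loadings=data["loadings"], scores=data["scores"],
                     explained_fraction=data["explained_fraction"],
                     wavelengths=data["wavelengths"])
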