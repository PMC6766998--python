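"""The two 1-D spectral classification architectures.

Self-design CNN: two convolution blocks (conv k3/s1 + ReLU + max-pool 2/2)
with 64 and 128 kernels, then dense layers of 512, 128 and K neurons with a
softmax output.  The ReLU-activated output of the 128-neuron dense layer is
the network's deep-feature representation.

ResNet-1D: a 1x1 entry convolution, four residual blocks with channel
counts 64/128/256/512 (blocks 2-4 downsample by stride 2 with projection
shortcuts), global average pooling, and a K-neuron dense softmax head.  The
512-element pooled vector is the deep-feature representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import StateError
from . import layers as L


@dataclass(frozen=True)
class NetworkSpec:
    architecture: str = "self-design-cnn"   # or "resnet-1d"
    n_classes: int = 7
    kernel_size: int = 3
    stride: int = 1
    cnn_channels: tuple[int, int] = (64, 128)
    dense_sizes: tuple[int, int] = (512, 128)
    resnet_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    resnet_batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.architecture not in ("self-design-cnn", "resnet-1d"):
            raise ValueError(f"unknown architecture '{self.architecture}'")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


@dataclass
class SpectralNetwork:
    """A built (possibly trained) spectral classifier network."""

    spec: NetworkSpec
    n_bands: int
    layers: list = field(repr=False, default_factory=list)
    feature_index: int = -1     # layer whose output is the deep feature
    feature_dim: int = 0
    trained: bool = False
    band_mean: np.ndarray | None = None   # optional input standardization
    band_scale: np.ndarray | None = None

    # ------------------------------------------------------------- forward
    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=L.DTYPE)
        if X.ndim == 2:
            if X.shape[1] != self.n_bands:
                raise ValueError(
                    f"expected {self.n_bands} bands, got {X.shape[1]}")
            X = X[:, None, :]
        if self.band_mean is not None:
            X = (X - self.band_mean[None, None, :]) / self.band_scale[None, None, :]
        return X.astype(L.DTYPE)

    def forward(self, x: np.ndarray, train: bool = False,
                with_features: bool = False):
        feats = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if with_features and i == self.feature_index:
                feats = x
        return (x, feats) if with_features else x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state_arrays(self):
        out = [a for layer in self.layers for a in layer.state_arrays()]
        return out

    def snapshot(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def restore(self, snap: list[np.ndarray]) -> None:
        for a, saved in zip(self.state_arrays(), snap):
            a[...] = saved

    # ----------------------------------------------------------- inference
    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = self._prepare(X)
        out = [L.softmax(self.forward(X[i:i + batch_size]))
               for i in range(0, X.shape[0], batch_size)]
        return np.vstack(out) if out else np.empty((0, self.spec.n_classes))

    def predict_classes(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Argmax of the softmax output; ties resolve to the lowest class."""
        proba = self.predict_proba(X, batch_size=batch_size)
        return proba.argmax(axis=1)

    def features(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        if not self.trained:
            raise StateError("extracting features from an untrained network")
        X = self._prepare(X)
        out = []
        for i in range(0, X.shape[0], batch_size):
            _, feats = self.forward(X[i:i + batch_size], with_features=True)
            out.append(feats)
        return np.vstack(out) if out else np.empty((0, self.feature_dim))

    # --------------------------------------------------------------- audit
    def architecture_audit(self) -> dict:
        """Layer widths for programmatic verification of the design."""
        conv_channels = [layer.c_out for layer in self.layers
                         if isinstance(layer, L.Conv1d)]
        dense_sizes = [layer.W.shape[1] for layer in self.layers
                       if isinstance(layer, L.Dense)]
        block_channels = [layer.c_out for layer in self.layers
                          if isinstance(layer, L.ResidualBlock)]
        return {
            "architecture": self.spec.architecture,
            "conv_channels": conv_channels,
            "residual_block_channels": block_channels,
            "dense_sizes": dense_sizes,
            "feature_dim": self.feature_dim,
            "n_classes": self.spec.n_classes,
        }


def build_network(spec: NetworkSpec, n_bands: int,
                  rng_seed: int = 0) -> SpectralNetwork:
    """Deterministically initialized network for ``n_bands``-long spectra."""
    rng = np.random.default_rng(rng_seed)
    k, s = spec.kernel_size, spec.stride
    if spec.architecture == "self-design-cnn":
        if n_bands < 4:
            raise ValueError(
                f"self-design CNN needs at least 4 bands to survive two "
                f"2x max-pool stages; got {n_bands}")
        c1, c2 = spec.cnn_channels
        d1, d2 = spec.dense_sizes
        flat = c2 * (n_bands // 2 // 2)
        layer_list = [
            L.Conv1d(1, c1, k, stride=s, rng=rng), L.ReLU(), L.MaxPool1d(2),
            L.Conv1d(c1, c2, k, stride=s, rng=rng), L.ReLU(), L.MaxPool1d(2),
            L.Flatten(),
            L.Dense(flat, d1, rng=rng), L.ReLU(),
            L.Dense(d1, d2, rng=rng), L.ReLU(),
            L.Dense(d2, spec.n_classes, rng=rng),
        ]
        feature_index = 10      # ReLU after the second dense layer
        feature_dim = d2
    else:
        if n_bands < 8:
            raise ValueError(
                f"ResNet-1D needs at least 8 bands for its three stride-2 "
                f"stages; got {n_bands}")
        ch = spec.resnet_channels
        bn = spec.resnet_batchnorm
        entry: list = [L.Conv1d(1, ch[0], 1, stride=1, rng=rng)]
        if bn:
            entry.append(L.BatchNorm1d(ch[0]))
        entry.append(L.ReLU())
        blocks = [
            L.ResidualBlock(ch[0], ch[0], kernel=k, stride=1, batchnorm=bn, rng=rng),
            L.ResidualBlock(ch[0], ch[1], kernel=k, stride=2, batchnorm=bn, rng=rng),
            L.ResidualBlock(ch[1], ch[2], kernel=k, stride=2, batchnorm=bn, rng=rng),
            L.ResidualBlock(ch[2], ch[3], kernel=k, stride=2, batchnorm=bn, rng=rng),
        ]
        layer_list = entry + blocks + [
            L.GlobalAvgPool1d(),
            L.Dense(ch[3], spec.n_classes, rng=rng),
        ]
        feature_index = len(layer_list) - 2   # the GlobalAvgPool output
        feature_dim = ch[3]
    return SpectralNetwork(spec=spec, n_bands=n_bands, layers=layer_list,
                           feature_index=feature_index, feature_dim=feature_dim)
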