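"""Convolutional shape encoder-decoder for stenosis rasters.

The network compresses a binary stenosis raster (214x214 in 2D, 61^3 in
3D) into a low-dimensional feature vector at a fully-connected bottleneck
(16 features in 2D; 8, 16 or 32 in 3D) and is supervised by reconstructing
surface coordinates: the 201 wall ordinates in 2D, 400 (radius, axial)
surface points in 3D.  Three conv stages (32/64/128 filters, kernel 4 per
axis, ReLU) with 3x max pooling after the first two stages give spatial
trajectories 214 -> 71 -> 23 (2D) and 61 -> 21 -> 7 (3D); the five
fully-connected layers (128, 128, n_f, 128, 128, tanh) surround the
bottleneck.  Loss is the mean squared coordinate error; Adam with a fixed
seed makes training runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .geometry import ShapeImage

__all__ = [
    "ShapeNetSpec",
    "ShapeNet",
    "FeatureVector",
    "build_shape_net",
    "shape_loss",
    "train_shape_net",
    "extract_features",
    "feature_count_study",
]


@dataclass(frozen=True)
class ShapeNetSpec:
    """Architecture of the shape encoder-decoder."""

    dimension: int = 2
    n_features: int = 16
    resolution: int = 214           # 61 for 3D
    conv_filters: tuple = (32, 64, 128)
    kernel: int = 4
    pool: int = 3
    fc_width: int = 128

    def __post_init__(self):
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.n_features >= self.output_size:
            raise ValueError("bottleneck must be smaller than the output")

    @property
    def output_size(self) -> int:
        return 201 if self.dimension == 2 else 800

    @property
    def output_points(self):
        return None if self.dimension == 2 else (400, 2)

    @property
    def spatial_trajectory(self) -> tuple:
        # pooling after conv1 and conv2 only; 2D floors (214 -> 71 -> 23),
        # 3D ceils (61 -> 21 -> 7)
        s = self.resolution
        out = [s]
        for _ in range(2):
            s = -(-s // self.pool) if self.dimension == 3 else s // self.pool
            out.append(s)
        return tuple(out)

    @classmethod
    def default(cls, dimension: int, n_features: int | None = None) -> "ShapeNetSpec":
        if dimension == 2:
            return cls(dimension=2, n_features=n_features or 16, resolution=214)
        return cls(dimension=3, n_features=n_features or 8, resolution=61)


@dataclass(frozen=True)
class FeatureVector:
    """Bottleneck activations of one raster."""

    values: np.ndarray
    source_id: object = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("feature vector must be finite")


class ShapeNet:
    """Encoder (raster -> features) + decoder (features -> coordinates)."""

    def __init__(self, spec: ShapeNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        d = spec.dimension
        ceil = d == 3
        f1, f2, f3 = spec.conv_filters
        traj = spec.spatial_trajectory
        flat = traj[-1] ** d * f3
        enc = [
            nn.Conv(d, 1, f1, spec.kernel, rng),
            nn.ReLU(),
            nn.MaxPool(d, spec.pool, ceil_mode=ceil),
            nn.Conv(d, f1, f2, spec.kernel, rng),
            nn.ReLU(),
            nn.MaxPool(d, spec.pool, ceil_mode=ceil),
            nn.Conv(d, f2, f3, spec.kernel, rng),
            nn.ReLU(),
            nn.Flatten(),
            nn.Dense(flat, spec.fc_width, rng),
            nn.Tanh(),
            nn.Dense(spec.fc_width, spec.fc_width, rng),
            nn.Tanh(),
            nn.Dense(spec.fc_width, spec.n_features, rng),
            nn.Tanh(),
        ]
        dec = [
            nn.Dense(spec.n_features, spec.fc_width, rng),
            nn.Tanh(),
            nn.Dense(spec.fc_width, spec.fc_width, rng),
            nn.Tanh(),
            nn.Dense(spec.fc_width, spec.output_size, rng),
        ]
        if spec.output_points:
            dec.append(nn.Reshape(spec.output_points))
        self.encoder = nn.Sequential(enc)
        self.decoder = nn.Sequential(dec)
        self.model = nn.Sequential(self.encoder.layers + self.decoder.layers)
        # per-entry label statistics (set during training): the optimizer
        # works on standardized coordinates so that the entries that vary
        # across shapes carry weight -- otherwise the decoder fits the
        # dataset-mean surface and the encoder receives no gradient
        self.label_mean = 0.0
        self.label_std = 1.0

    def n_parameters(self) -> int:
        return self.model.n_parameters()

    def stage_shapes(self):
        """Per-stage spatial sizes (before flattening)."""
        t = self.spec.spatial_trajectory
        return {"conv1": t[0], "conv2": t[1], "conv3": t[2]}

    def encode(self, rasters: np.ndarray) -> np.ndarray:
        return self.encoder.forward(self._prep(rasters))

    def forward(self, rasters: np.ndarray) -> np.ndarray:
        out = self.model.forward(self._prep(rasters))
        return out * self.label_std + self.label_mean

    def _prep(self, rasters: np.ndarray) -> np.ndarray:
        x = np.asarray(rasters, dtype=np.float32)
        d = self.spec.dimension
        if x.ndim == d:  # single raster
            x = x[None]
        if x.shape[1] != self.spec.resolution:
            raise ValueError(
                f"raster resolution {x.shape[1:]} does not match spec {self.spec.resolution}"
            )
        return x[..., None]


def build_shape_net(spec: ShapeNetSpec, seed: int = 0) -> ShapeNet:
    """Instantiate the encoder-decoder for ``spec`` with seeded init."""
    return ShapeNet(spec, seed=seed)


def shape_loss(pred, label):
    """Mean squared surface-coordinate error (over every coordinate entry)."""
    pred = np.asarray(pred)
    label = np.asarray(label)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {label.shape}")
    return float(((pred - label) ** 2).mean())


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)

    def as_arrays(self):
        return (np.array(self.train_loss), np.array(self.val_loss))


def train_shape_net(
    net: ShapeNet,
    images: np.ndarray,
    labels: np.ndarray,
    val_images=None,
    val_labels=None,
    lr: float = 1e-4,
    epochs: int = 50,
    batch_size: int = 8,
    seed: int = 0,
) -> TrainingHistory:
    """Train the encoder-decoder on (raster, surface-coordinate) pairs.

    Deterministic for a fixed seed (shuffling and init both seeded).
    Raises on divergence (non-finite loss).
    """
    rng = np.random.default_rng(seed)
    x = net._prep(images)
    raw = np.asarray(labels, dtype=np.float32)
    mean = raw.mean(axis=0)
    std = raw.std(axis=0)
    net.label_mean = mean
    net.label_std = np.where(std > 1e-8, std, 1.0).astype(np.float32)
    y = ((raw - net.label_mean) / net.label_std).astype(np.float32)
    opt = nn.Adam(net.model.params(), lr=lr)
    hist = TrainingHistory()
    n = x.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, batch_size):
            idx = order[s : s + batch_size]
            net.model.zero_grad()
            out = net.model.forward(x[idx])
            loss, grad = nn.mse_loss(out, y[idx])  # standardized scale
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            net.model.backward(grad.astype(np.float32))
            opt.step()
            losses.append(loss)
        hist.train_loss.append(float(np.mean(losses)))
        hist.learning_rate.append(opt.lr)
        if val_images is not None:
            vout = net.forward(val_images)
            hist.val_loss.append(shape_loss(vout, val_labels))
    return hist


def extract_features(net: ShapeNet, raster) -> FeatureVector:
    """Bottleneck feature vector of one raster (deterministic)."""
    values = np.asarray(raster.values if isinstance(raster, ShapeImage) else raster)
    feats = net.encode(values)
    return FeatureVector(values=feats[0].astype(float))


def feature_count_study(
    images,
    labels,
    val_images,
    val_labels,
    counts=(8, 16, 32),
    seed: int = 0,
    **train_kw,
):
    """Train one 3D net per bottleneck size; report final losses and MAE.

    Returns {count: {"history": ..., "final_val_loss": ..., "mae": ...}}.
    """
    out = {}
    for c in counts:
        spec = ShapeNetSpec.default(3, n_features=c)
        net = build_shape_net(spec, seed=seed)
        hist = train_shape_net(
            net, images, labels, val_images, val_labels, seed=seed, **train_kw
        )
        pred = net.forward(val_images)
        mae = float(np.abs(pred - np.asarray(val_labels)).mean())
        out[c] = {
            "history": hist,
            "final_val_loss": hist.val_loss[-1] if hist.val_loss else None,
            "mae": mae,
        }
    return out
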