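"""Pointwise fully-connected surrogate for mean stenosed-artery flow.

Each training row maps (stenosis feature vector, fluid-node coordinates)
to the mean outputs at that node: (u_m, v_m, c_p) in 2D, (u_m, v_m, w_m,
c_p) in 3D.  The network has 5 hidden layers of 128 rectified units, a
linear output, RMSE loss and Adam with the learning rate decayed from
1e-3 toward a 4e-5 floor on validation plateaus.  Splits are by whole
simulations, never by node, so no shape's field leaks into validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .pipeline import MeanFlowField

__all__ = [
    "SurrogateSpec",
    "TrainTable",
    "Surrogate",
    "assemble_dataset",
    "build_surrogate",
    "rms_loss",
    "train_surrogate",
    "predict_field",
    "error_report",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Architecture/optimization contract of the pointwise surrogate."""

    n_features: int
    dimension: int = 2
    hidden_layers: int = 5
    hidden_width: int = 128
    lr_initial: float = 1e-3
    lr_floor: float = 4e-5
    lr_decay: float = 0.5
    lr_patience: int = 10

    @property
    def input_size(self) -> int:
        return self.n_features + self.dimension

    @property
    def output_size(self) -> int:
        return 3 if self.dimension == 2 else 4


@dataclass
class TrainTable:
    """Flat training table with per-row simulation ids and split tags."""

    features: np.ndarray      # (n, n_f)
    coords: np.ndarray        # (n, d)
    outputs: np.ndarray       # (n, 3|4)
    sim_id: np.ndarray        # (n,)
    split: np.ndarray         # (n,) 'train' | 'val'

    def __post_init__(self):
        n = self.features.shape[0]
        for a in (self.coords, self.outputs, self.sim_id, self.split):
            if a.shape[0] != n:
                raise ValueError("inconsistent row counts in TrainTable")
        both = set(np.unique(self.sim_id[self.split == "train"])) & set(
            np.unique(self.sim_id[self.split == "val"])
        )
        if both:
            raise ValueError(f"simulations {both} appear in both splits")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    def rows(self, split: str):
        m = self.split == split
        return self.features[m], self.coords[m], self.outputs[m]

    @property
    def inputs(self) -> np.ndarray:
        return np.concatenate([self.features, self.coords], axis=1)


def assemble_dataset(
    simulations: list[MeanFlowField],
    features: list[np.ndarray],
    n_validation: int = 0,
    split_seed: int = 0,
    rows_per_sim: int | None = None,
) -> TrainTable:
    """Build the training table, one row per extraction-region node.

    ``features`` holds one feature vector per simulation (all rows of a
    simulation share it).  ``n_validation`` whole simulations are held out
    at random under ``split_seed``.  ``rows_per_sim`` optionally subsamples
    the training rows of each simulation (validation fields are kept
    complete); the subsampling is seeded and reproducible.
    """
    if len(simulations) != len(features):
        raise ValueError(
            f"{len(simulations)} simulations but {len(features)} feature vectors"
        )
    rng = np.random.default_rng(split_seed)
    ids = np.arange(len(simulations))
    val_ids = set(rng.choice(ids, size=n_validation, replace=False).tolist()) if n_validation else set()
    F, C, Y, S, T = [], [], [], [], []
    for i, (fld, feat) in enumerate(zip(simulations, features)):
        feat = np.asarray(getattr(feat, "values", feat), dtype=float)
        n = fld.n_nodes
        sel = np.arange(n)
        if rows_per_sim is not None and i not in val_ids and n > rows_per_sim:
            sel = np.sort(rng.choice(n, size=rows_per_sim, replace=False))
        F.append(np.broadcast_to(feat, (len(sel), feat.size)))
        C.append(fld.coords[sel])
        Y.append(fld.outputs()[sel])
        S.append(np.full(len(sel), i))
        T.append(np.full(len(sel), "val" if i in val_ids else "train"))
    return TrainTable(
        features=np.concatenate(F),
        coords=np.concatenate(C),
        outputs=np.concatenate(Y),
        sim_id=np.concatenate(S),
        split=np.concatenate(T),
    )


class Surrogate:
    """The pointwise MLP plus its input normalization statistics."""

    def __init__(self, spec: SurrogateSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers = [nn.Dense(spec.input_size, spec.hidden_width, rng), nn.ReLU()]
        for _ in range(spec.hidden_layers - 1):
            layers += [nn.Dense(spec.hidden_width, spec.hidden_width, rng), nn.ReLU()]
        layers.append(nn.Dense(spec.hidden_width, spec.output_size, rng))
        self.model = nn.Sequential(layers)
        self.feat_mean = np.zeros(spec.n_features)
        self.feat_std = np.ones(spec.n_features)
        self.feat_lo = None   # training-hull bounding box (set in training)
        self.feat_hi = None
        # per-output scale: losses are computed on scaled targets so the
        # large pressure-coefficient range does not drown the velocities
        self.out_scale = np.ones(spec.output_size)

    def n_parameters(self) -> int:
        return self.model.n_parameters()

    def set_normalization(self, features: np.ndarray, standardize: bool = True):
        if standardize:
            self.feat_mean = features.mean(axis=0)
            self.feat_std = np.where(features.std(axis=0) > 1e-12, features.std(axis=0), 1.0)
        else:
            self.feat_mean = np.zeros(features.shape[1])
            self.feat_std = np.ones(features.shape[1])
        self.feat_lo = features.min(axis=0)
        self.feat_hi = features.max(axis=0)

    def set_output_scale(self, outputs: np.ndarray, standardize: bool = True):
        if standardize:
            std = outputs.std(axis=0)
            self.out_scale = np.where(std > 1e-12, std, 1.0)
        else:
            self.out_scale = np.ones(outputs.shape[1])

    def _inputs(self, features, coords, clip: bool = False):
        f = np.asarray(features, dtype=float)
        if clip and self.feat_lo is not None:
            clipped = np.clip(f, self.feat_lo, self.feat_hi)
            if not np.allclose(clipped, f):
                import warnings

                warnings.warn(
                    "shape features outside the training hull were clipped "
                    "(rectifier networks extrapolate without bound; the "
                    "prediction degrades to the nearest trained shapes)"
                )
            f = clipped
        f = (f - self.feat_mean) / self.feat_std
        return np.concatenate([f, np.asarray(coords)], axis=1).astype(np.float32)

    def predict_clipped(self, features, coords):
        return self.model.forward(self._inputs(features, coords, clip=True)) * self.out_scale.astype(
            np.float32
        )

    def predict(self, features, coords):
        return self.model.forward(self._inputs(features, coords)) * self.out_scale.astype(
            np.float32
        )


def build_surrogate(spec: SurrogateSpec, seed: int = 0) -> Surrogate:
    return Surrogate(spec, seed=seed)


def rms_loss(pred, target):
    """Root-mean-square componentwise error."""
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.sqrt(((pred - target) ** 2).mean()))


@dataclass
class SurrogateHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_mae: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)


def train_surrogate(
    sur: Surrogate,
    table: TrainTable,
    epochs: int = 100,
    batch_size: int = 4096,
    seed: int = 0,
    standardize_features: bool = True,
    standardize_outputs: bool = True,
) -> SurrogateHistory:
    """Train with RMSE loss, Adam, plateau learning-rate decay.

    The learning rate starts at the spec's 1e-3 and halves when the
    monitored loss (validation if present, else training) has not improved
    for ``lr_patience`` epochs, floored at 4e-5.  Targets are scaled by
    their per-output training standard deviation during optimization (the
    recorded losses are on that scale; predictions are rescaled).
    Deterministic per seed.
    """
    spec = sur.spec
    rng = np.random.default_rng(seed)
    ftr, ctr, ytr = table.rows("train")
    if ftr.shape[0] == 0:
        raise ValueError("empty training split")
    sur.set_normalization(ftr, standardize=standardize_features)
    sur.set_output_scale(ytr, standardize=standardize_outputs)
    Xtr = sur._inputs(ftr, ctr)
    Ytr = (ytr / sur.out_scale).astype(np.float32)
    has_val = (table.split == "val").any()
    if has_val:
        fv, cv, yv = table.rows("val")
        Xv = sur._inputs(fv, cv)
        Yv = (yv / sur.out_scale).astype(np.float32)
    opt = nn.Adam(sur.model.params(), lr=spec.lr_initial)
    hist = SurrogateHistory()
    best = np.inf
    stall = 0
    n = Xtr.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, batch_size):
            idx = order[s : s + batch_size]
            sur.model.zero_grad()
            out = sur.model.forward(Xtr[idx])
            loss, grad = nn.rmse_loss(out, Ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            sur.model.backward(grad.astype(np.float32))
            opt.step()
            losses.append(loss)
        hist.train_loss.append(float(np.mean(losses)))
        hist.learning_rate.append(opt.lr)
        if has_val:
            pv = sur.model.forward(Xv)
            hist.val_loss.append(rms_loss(pv, Yv))
            hist.val_mae.append(float(np.abs(pv - Yv).mean()))
        monitored = hist.val_loss[-1] if has_val else hist.train_loss[-1]
        if monitored < best - 1e-12:
            best = monitored
            stall = 0
        else:
            stall += 1
            if stall >= spec.lr_patience:
                opt.lr = max(opt.lr * spec.lr_decay, spec.lr_floor)
                stall = 0
    return hist


def predict_field(sur: Surrogate, features, coords, bounds=None) -> MeanFlowField:
    """Predict the mean-flow outputs at ``coords`` for one shape.

    Coordinates outside ``bounds`` (streamwise window in units of D) are
    flagged as extrapolation with a warning.
    """
    feats = np.asarray(getattr(features, "values", features), dtype=float)
    coords = np.asarray(coords, dtype=float)
    if bounds is not None:
        lo, hi = bounds
        if (coords[:, 0] < lo - 1e-9).any() or (coords[:, 0] > hi + 1e-9).any():
            import warnings

            warnings.warn("predicting outside the training region (extrapolation)")
    F = np.broadcast_to(feats, (coords.shape[0], feats.size))
    out = sur.predict_clipped(F, coords).astype(float)
    d = sur.spec.dimension
    return MeanFlowField(
        coords=coords,
        u_m=out[:, 0],
        v_m=out[:, 1],
        w_m=out[:, 2] if d == 3 else None,
        cp_m=out[:, -1],
        bounds=bounds,
    )


def error_report(pred: MeanFlowField, ref: MeanFlowField, centre_band=None, probes=()):
    """Pointwise error maps and summary metrics against a reference field.

    Returns a dict with absolute-error maps per output, the maximum local
    velocity-error magnitude as a percentage of the maximum reference
    velocity magnitude (optionally restricted to a transverse band around
    the centre), and the mean absolute error as a percentage of each
    output's reference dynamic range.  ``probes`` are (axis_index, value)
    line extractions, e.g. (1, 0.2) for y = 0.2 D.
    """
    if pred.coords.shape != ref.coords.shape or not np.allclose(
        pred.coords, ref.coords, atol=1e-9
    ):
        raise ValueError("prediction and reference are on different node sets")
    dp = pred.outputs()
    dr = ref.outputs()
    err = dp - dr
    names = ["u_m", "v_m"] + (["w_m"] if ref.w_m is not None else []) + ["cp_m"]
    maps = {n: err[:, i] for i, n in enumerate(names)}
    nvel = len(names) - 1
    vel_err = np.linalg.norm(err[:, :nvel], axis=1)
    vel_ref_max = float(np.linalg.norm(dr[:, :nvel], axis=1).max())
    sel = np.ones(len(vel_err), dtype=bool)
    if centre_band is not None:
        axis, lo, hi = centre_band
        sel = (ref.coords[:, axis] >= lo) & (ref.coords[:, axis] <= hi)
    max_local_pct = float(vel_err[sel].max() / vel_ref_max * 100.0)
    ranges = dr.max(axis=0) - dr.min(axis=0)
    ranges = np.where(ranges > 1e-12, ranges, 1.0)
    mae_pct = float((np.abs(err).mean(axis=0) / ranges).mean() * 100.0)
    lines = {}
    for axis, value in probes:
        m = np.abs(ref.coords[:, axis] - value) < 1e-6
        order = np.argsort(ref.coords[m, 0])
        lines[(axis, value)] = {
            "x": ref.coords[m, 0][order],
            "pred": dp[m][order],
            "ref": dr[m][order],
        }
    return {
        "error_maps": maps,
        "max_local_velocity_error_pct": max_local_pct,
        "mae_pct_of_range": mae_pct,
        "rms": rms_loss(dp, dr),
        "lines": lines,
    }
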