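"""Desk-scale reproductions of the 2D and 3D surrogate experiments.

These drivers chain the full method at reduced size: sample stenosis
shapes, run the IB-LBM cases, train the shape encoder on rasters, train
the pointwise surrogate on the extracted mean fields, and evaluate the
prediction error on held-out shapes.  The full-scale study uses hundreds
of simulations and tens of millions of training rows; these functions
keep the same structure at sizes a workstation completes in minutes
(problem sizes are parameters with the defaults below).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    rasterize_2d,
    rasterize_3d,
    sample_asymmetric,
    sample_stenosis,
    sample_surface_points,
)
from .pipeline import SimConfig, extract_region, run_case
from .shape_cnn import ShapeNetSpec, build_shape_net, extract_features, train_shape_net
from .surrogate import (
    SurrogateSpec,
    build_surrogate,
    error_report,
    predict_field,
    train_surrogate,
)

__all__ = ["Study2D", "prepare_2d_study", "evaluate_surrogate", "run_3d_smoke_study"]


@dataclass
class Study2D:
    """Artifacts of the reduced 2D chain, reusable across evaluations."""

    shapes: list
    fields: list
    rasters: np.ndarray
    cnn_rasters: np.ndarray
    cnn_labels: np.ndarray
    net: object
    cnn_history: object
    feats_cnn: list
    feats_poly: list
    val_ids: list
    seed: int
    config: SimConfig
    sim_seconds: float = 0.0


def _sim_config_2d(mesh: int) -> SimConfig:
    return SimConfig(
        dimension=2,
        Re=100.0,
        U0=0.05,
        cells_per_D=mesh,
        length_D=8.0,
        x_start_D=2.0,
        T_avg=8.0,
        dev_tol=1e-3,
        dev_max_D=20.0,
        max_steps=60_000,
    )


def prepare_2d_study(
    seed: int = 1,
    n_shapes: int = 10,
    n_validation: int = 2,
    mesh: int = 25,
    h_range=(0.3, 0.7),
    x_star_range=(0.4, 0.6),
    cnn_extra_shapes: int = 48,
    cnn_epochs: int = 8,
    cnn_lr: float = 3e-4,
) -> Study2D:
    """Simulate ``n_shapes`` 2D stenoses at Re=100 and train the 16-feature
    shape encoder.

    The encoder's own dataset adds ``cnn_extra_shapes`` geometry-only
    shapes over a wider depth range (the encoder should span shape space
    beyond the simulated samples, including near-healthy walls).  The last
    ``n_validation`` shapes are held out of the surrogate's training split.
    """
    import time

    rng = np.random.default_rng(seed)
    cfg = _sim_config_2d(mesh)
    shapes = [sample_stenosis(rng, h_range=h_range, x_star_range=x_star_range) for _ in range(n_shapes)]
    extra = [
        sample_stenosis(rng, h_range=(0.05, 0.8), x_star_range=x_star_range)
        for _ in range(cnn_extra_shapes)
    ]
    t0 = time.time()
    fields = []
    for sh in shapes:
        res = run_case(cfg, sh)
        fields.append(extract_region(res))
    sim_seconds = time.time() - t0

    all_shapes = shapes + extra
    rasters = np.stack([rasterize_2d(sh).values for sh in all_shapes])
    labels = np.stack([sample_surface_points(sh, 201) for sh in all_shapes])
    spec = ShapeNetSpec.default(2)
    net = build_shape_net(spec, seed=seed)
    hist = train_shape_net(
        net, rasters, labels, lr=cnn_lr, epochs=cnn_epochs, batch_size=8, seed=seed
    )
    feats_cnn = [extract_features(net, rasters[i]).values for i in range(n_shapes)]
    feats_poly = [sh.coefficients.copy() for sh in shapes]
    val_ids = list(range(n_shapes - n_validation, n_shapes))
    return Study2D(
        shapes=shapes,
        fields=fields,
        rasters=rasters[:n_shapes],
        cnn_rasters=rasters,
        cnn_labels=labels,
        net=net,
        cnn_history=hist,
        feats_cnn=feats_cnn,
        feats_poly=feats_poly,
        val_ids=val_ids,
        seed=seed,
        config=cfg,
        sim_seconds=sim_seconds,
    )


def _table_with_fixed_validation(study: Study2D, feats, rows_per_sim):
    """Assemble the table holding out study.val_ids (deterministic)."""
    from .surrogate import TrainTable

    rng = np.random.default_rng(study.seed)
    F, C, Y, S, T = [], [], [], [], []
    for i, fld in enumerate(study.fields):
        feat = np.asarray(feats[i], dtype=float)
        n = fld.n_nodes
        sel = np.arange(n)
        is_val = i in study.val_ids
        if rows_per_sim is not None and not is_val and n > rows_per_sim:
            sel = np.sort(rng.choice(n, size=rows_per_sim, replace=False))
        F.append(np.broadcast_to(feat, (len(sel), feat.size)))
        C.append(fld.coords[sel])
        Y.append(fld.outputs()[sel])
        S.append(np.full(len(sel), i))
        T.append(np.full(len(sel), "val" if is_val else "train"))
    return TrainTable(
        features=np.concatenate(F),
        coords=np.concatenate(C),
        outputs=np.concatenate(Y),
        sim_id=np.concatenate(S),
        split=np.concatenate(T),
    )


def evaluate_surrogate(
    study: Study2D,
    features: str = "cnn",
    epochs: int = 150,
    batch_size: int = 1024,
    rows_per_sim: int | None = 2000,
    centre_band=(1, 0.25, 0.75),
):
    """Train the pointwise surrogate on the study and report held-out errors.

    ``features`` selects the shape representation: "cnn" (standardized
    encoder features) or "poly" (the raw quintic coefficients, fed as-is).
    Returns a dict with the training history, the per-held-out-shape error
    reports, and the worst near-centre local velocity error (percent of
    the maximum reference velocity in the band |y - 0.5D| < 0.25D).
    """
    feats = study.feats_cnn if features == "cnn" else study.feats_poly
    table = _table_with_fixed_validation(study, feats, rows_per_sim)
    spec = SurrogateSpec(n_features=len(feats[0]), dimension=2)
    sur = build_surrogate(spec, seed=study.seed)
    hist = train_surrogate(
        sur,
        table,
        epochs=epochs,
        batch_size=batch_size,
        seed=study.seed,
        standardize_features=features == "cnn",
    )
    reports = {}
    worst = 0.0
    for vid in study.val_ids:
        ref = study.fields[vid]
        pred = predict_field(sur, feats[vid], ref.coords, bounds=ref.bounds)
        rep = error_report(pred, ref, centre_band=centre_band)
        reports[vid] = rep
        worst = max(worst, rep["max_local_velocity_error_pct"])
    return {
        "surrogate": sur,
        "table": table,
        "history": hist,
        "reports": reports,
        "max_local_velocity_error_pct": worst,
        "final_val_loss": hist.val_loss[-1] if hist.val_loss else None,
    }


def run_3d_smoke_study(
    seed: int = 1,
    n_sims: int = 5,
    mesh: int = 12,
    U0: float = 0.08,
    n_features: int = 8,
    cnn_extra_shapes: int = 3,
    cnn_epochs: int = 8,
    cnn_lr: float = 2e-4,
    dnn_epochs: int = 150,
    dnn_batch: int = 512,
    rows_per_sim: int | None = 2000,
):
    """Coarse asymmetric-tube study: n_sims IB-LBM runs, the 8-feature 3D
    encoder, and the 4-output surrogate; one simulation is held out.

    Returns metrics including the held-out mean absolute error as a
    percent of each output's dynamic range.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        dimension=3,
        Re=100.0,
        U0=U0,
        cells_per_D=mesh,
        length_D=7.0,
        x_start_D=1.5,
        margin_cells=3,
        T_avg=3.0,
        dev_tol=1e-3,
        dev_max_D=12.0,
        max_steps=30_000,
    )
    shapes = [
        sample_asymmetric(
            rng, h_range=(0.3, 0.7), x_star_range=(0.4, 0.6),
            sigma_range=(0.8, 1.2), amplitude_range=(0.7, 1.0),
        )
        for _ in range(n_sims)
    ]
    extra = [
        sample_asymmetric(
            rng, h_range=(0.1, 0.8), x_star_range=(0.4, 0.6),
            sigma_range=(0.6, 1.4), amplitude_range=(0.5, 1.0),
        )
        for _ in range(cnn_extra_shapes)
    ]
    fields = [extract_region(run_case(cfg, sh)) for sh in shapes]

    all_shapes = shapes + extra
    rasters = np.stack([rasterize_3d(sh).values for sh in all_shapes])
    labels = np.stack([sample_surface_points(sh, 400) for sh in all_shapes])
    spec = ShapeNetSpec.default(3, n_features=n_features)
    net = build_shape_net(spec, seed=seed)
    hist = train_shape_net(
        net, rasters, labels, lr=cnn_lr, epochs=cnn_epochs, batch_size=2, seed=seed
    )
    feats = [extract_features(net, rasters[i]).values for i in range(n_sims)]

    study = Study2D(
        shapes=shapes, fields=fields, rasters=rasters[:n_sims],
        cnn_rasters=rasters, cnn_labels=labels, net=net, cnn_history=hist,
        feats_cnn=feats, feats_poly=None, val_ids=[n_sims - 1], seed=seed, config=cfg,
    )
    table = _table_with_fixed_validation(study, feats, rows_per_sim)
    sspec = SurrogateSpec(n_features=n_features, dimension=3)
    sur = build_surrogate(sspec, seed=seed)
    dh = train_surrogate(sur, table, epochs=dnn_epochs, batch_size=dnn_batch, seed=seed)
    vid = n_sims - 1
    ref = fields[vid]
    pred = predict_field(sur, feats[vid], ref.coords, bounds=ref.bounds)
    rep = error_report(pred, ref)
    return {
        "fields": fields,
        "net": net,
        "surrogate": sur,
        "cnn_history": hist,
        "dnn_history": dh,
        "report": rep,
        "mae_pct_of_range": rep["mae_pct_of_range"],
    }
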