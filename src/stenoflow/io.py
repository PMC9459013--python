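"""Configuration, dataset and field I/O, and run manifests.

Configs are YAML with a strict schema (unknown keys rejected, defaults
filled).  Shape archives and mean-field tables use HDF5; mean fields on
grids can be exported as legacy-ASCII VTK structured points for external
viewers; 2D rasters can be written as PNG.  Manifests are append-only
JSON records keyed by content hashes so pipeline stages can be skipped
when their inputs are unchanged.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import yaml

from .geometry import AsymmetricShape3D, ShapeImage, StenosisShape
from .pipeline import MeanFlowField

__all__ = [
    "ConfigError",
    "load_config",
    "dump_config",
    "save_shapes",
    "load_shapes",
    "save_fields",
    "load_fields",
    "write_vtk_structured",
    "save_raster_png",
    "save_checkpoint",
    "load_checkpoint",
    "file_sha256",
    "Manifest",
]


class ConfigError(ValueError):
    pass


# schema: {key: (default_or_REQUIRED, type)}; nested dicts are sub-schemas
_REQUIRED = object()

_SIM_SCHEMA = {
    "Re": (_REQUIRED, (int, float)),
    "U0": (0.05, (int, float)),
    "cells_per_D": (25, int),
    "length_D": (8.0, (int, float)),
    "x_start_D": (2.0, (int, float)),
    "T_avg": (5.0, (int, float)),
    "dev_tol": (1e-4, (int, float)),
    "max_steps": (400_000, int),
}

_SCHEMA = {
    "seed": (0, int),
    "dimension": (2, int),
    "n_shapes": (5, int),
    "n_validation": (1, int),
    "asymmetric": (False, bool),
    "h_range": ([0.3, 0.7], list),
    "x_star_range": ([0.35, 0.65], list),
    "sim": (_SIM_SCHEMA, dict),
    "cnn": (
        {
            "n_features": (None, (int, type(None))),
            "epochs": (10, int),
            "lr": (1e-4, (int, float)),
            "batch_size": (8, int),
            "extra_shapes": (8, int),
        },
        dict,
    ),
    "dnn": (
        {
            "epochs": (60, int),
            "batch_size": (4096, int),
            "rows_per_sim": (2500, (int, type(None))),
            "features": ("cnn", str),
        },
        dict,
    ),
}


def _validate(data, schema, path=""):
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'} must be a mapping")
    out = {}
    for key, (default, typ) in schema.items():
        here = f"{path}.{key}" if path else key
        if isinstance(default, dict) and typ is dict:
            out[key] = _validate(data.get(key, {}), default, here)
            continue
        if key not in data:
            if default is _REQUIRED:
                raise ConfigError(f"missing required field: {here}")
            out[key] = default
        else:
            value = data[key]
            if typ is not None and value is not None and not isinstance(value, typ):
                raise ConfigError(f"field {here} has wrong type {type(value).__name__}")
            out[key] = value
    unknown = set(data) - set(schema)
    if unknown:
        raise ConfigError(f"unknown field(s) {sorted(unknown)} under {path or 'config'}")
    return out


def load_config(path) -> dict:
    """Load and validate a pipeline YAML config; defaults filled in."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return _validate(raw, _SCHEMA)


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)


# ---------------------------------------------------------------------------
# shapes


def save_shapes(path, shapes, rasters=None, surface_points=None) -> None:
    """Archive StenosisShape / AsymmetricShape3D lists to HDF5."""
    with h5py.File(path, "w") as f:
        for i, sh in enumerate(shapes):
            g = f.create_group(f"shape_{i:04d}")
            prof = sh.axial_profile if isinstance(sh, AsymmetricShape3D) else sh
            g.attrs["D"] = prof.D
            g.attrs["x_start"] = prof.x_start
            g.create_dataset("coefficients", data=prof.coefficients)
            if isinstance(sh, AsymmetricShape3D):
                g.attrs["theta0"] = sh.theta0
                g.attrs["sigma"] = sh.sigma
                g.attrs["amplitude"] = sh.amplitude
            if rasters is not None:
                g.create_dataset("raster", data=rasters[i].values, compression="gzip")
                g.attrs["pixel_spacing"] = rasters[i].pixel_spacing
            if surface_points is not None:
                g.create_dataset("surface_points", data=surface_points[i])


def load_shapes(path):
    shapes = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            prof = StenosisShape(
                D=float(g.attrs["D"]),
                coefficients=g["coefficients"][:],
                x_start=float(g.attrs["x_start"]),
            )
            if "theta0" in g.attrs:
                shapes.append(
                    AsymmetricShape3D(
                        axial_profile=prof,
                        theta0=float(g.attrs["theta0"]),
                        sigma=float(g.attrs["sigma"]),
                        amplitude=float(g.attrs["amplitude"]),
                    )
                )
            else:
                shapes.append(prof)
    return shapes


# ---------------------------------------------------------------------------
# mean flow fields


def save_fields(path, fields: list[MeanFlowField]) -> None:
    with h5py.File(path, "w") as f:
        for i, fld in enumerate(fields):
            g = f.create_group(f"field_{i:04d}")
            g.create_dataset("coords", data=fld.coords)
            g.create_dataset("u_m", data=fld.u_m)
            g.create_dataset("v_m", data=fld.v_m)
            if fld.w_m is not None:
                g.create_dataset("w_m", data=fld.w_m)
            g.create_dataset("cp_m", data=fld.cp_m)
            if fld.bounds is not None:
                g.attrs["bounds"] = fld.bounds


def load_fields(path) -> list[MeanFlowField]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            out.append(
                MeanFlowField(
                    coords=g["coords"][:],
                    u_m=g["u_m"][:],
                    v_m=g["v_m"][:],
                    w_m=g["w_m"][:] if "w_m" in g else None,
                    cp_m=g["cp_m"][:],
                    bounds=tuple(g.attrs["bounds"]) if "bounds" in g.attrs else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# VTK / PNG export


def write_vtk_structured(path, arrays: dict, spacing=1.0, origin=(0.0, 0.0, 0.0)) -> None:
    """Write scalar fields on a Cartesian grid as legacy-ASCII VTK
    STRUCTURED_POINTS (2D grids are written with a single z plane)."""
    first = next(iter(arrays.values()))
    shape = first.shape
    dims = tuple(shape) + (1,) * (3 - len(shape))
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nstenoflow field export\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        f.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2] if len(origin) > 2 else 0.0}\n")
        f.write(f"SPACING {spacing} {spacing} {spacing}\n")
        f.write(f"POINT_DATA {int(np.prod(dims))}\n")
        for name, arr in arrays.items():
            if arr.shape != shape:
                raise ValueError("all exported fields must share one grid")
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK expects x varying fastest
            flat = np.transpose(arr.reshape(dims, order="C"), (2, 1, 0)).ravel()
            np.savetxt(f, flat[None] if flat.ndim == 1 else flat, fmt="%.7g", delimiter="\n")


def save_raster_png(path, image: ShapeImage) -> None:
    from PIL import Image

    arr = (np.asarray(image.values).T[::-1] * 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# checkpoints (network weights + metadata sidecar)


def save_checkpoint(path, model, meta: dict) -> None:
    """Weights as NPZ with a JSON metadata sidecar (spec, seed, hashes)."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path.with_suffix(".npz"), **arrays)
    with open(path.with_suffix(".json"), "w") as f:
        json.dump(meta, f, indent=2, default=str)


def load_checkpoint(path, model) -> dict:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    params = model.params()
    if len(params) != len(data.files):
        raise ValueError("checkpoint does not match the model architecture")
    for i, p in enumerate(params):
        arr = data[f"p{i}"]
        if arr.shape != p.value.shape:
            raise ValueError(f"parameter {i} shape mismatch")
        p.value[:] = arr
    with open(path.with_suffix(".json")) as f:
        return json.load(f)


# ---------------------------------------------------------------------------
# manifests


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Append-only JSON run manifest with per-stage artifact hashes."""

    def __init__(self, path):
        self.path = Path(path)
        if self.path.exists():
            with open(self.path) as f:
                self.data = json.load(f)
        else:
            self.data = {"stages": [], "created": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def stage_done(self, name: str, outputs: dict) -> bool:
        """True if a recorded stage ``name`` has intact outputs."""
        for rec in reversed(self.data["stages"]):
            if rec["name"] == name:
                return all(
                    Path(p).exists() and file_sha256(p) == h
                    for p, h in rec["outputs"].items()
                )
        return False

    def record(self, name: str, outputs: list, extra: dict | None = None) -> None:
        rec = {
            "name": name,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {str(p): file_sha256(p) for p in outputs},
        }
        if extra:
            rec["extra"] = extra
        self.data["stages"].append(rec)
        with open(self.path, "w") as f:
            json.dump(self.data, f, indent=2)
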