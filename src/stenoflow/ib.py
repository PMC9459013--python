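"""Feedback immersed-boundary coupling.

No-slip on the arterial wall is enforced by Lagrangian markers: the fluid
velocity is interpolated to each marker with a regularized delta function,
a feedback (Goldstein-type) force

    F = alpha * int_0^t (U_marker - U_wall) dt' + beta * (U_marker - U_wall)

drives the slip to zero (alpha, beta < 0, rigid walls with U_wall = 0),
and the force is spread back to the grid with the same kernel.  The
4-point Peskin kernel is used in every dimension; interpolation and
spreading are exact adjoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MarkerSet
from .lbm import kernels as _k

__all__ = [
    "DeltaKernel",
    "PESKIN4",
    "interpolate_velocity",
    "feedback_force",
    "spread_force",
    "DEFAULT_ALPHA",
    "DEFAULT_BETA",
]

# feedback gains in lattice units (dt = 1); restoring, hence negative
DEFAULT_ALPHA = -0.15
DEFAULT_BETA = -1.5


@dataclass(frozen=True)
class DeltaKernel:
    """Regularized delta function with compact support (lattice units)."""

    support_width: float = 4.0

    def phi(self, r):
        """1D weight; the d-dimensional kernel is the tensor product / dx^d."""
        r = np.asarray(r, dtype=float)
        a = np.abs(r)
        out = np.zeros_like(a)
        m1 = a < 1.0
        m2 = (a >= 1.0) & (a < 2.0)
        out[m1] = 0.125 * (3.0 - 2.0 * a[m1] + np.sqrt(1.0 + 4.0 * a[m1] - 4.0 * a[m1] ** 2))
        out[m2] = 0.125 * (5.0 - 2.0 * a[m2] - np.sqrt(-7.0 + 12.0 * a[m2] - 4.0 * a[m2] ** 2))
        return out


PESKIN4 = DeltaKernel()


def interpolate_velocity(u_grid, markers: MarkerSet, kernel: DeltaKernel = PESKIN4, wrap_x: bool = False):
    """Velocity at the markers, U_m = sum_nodes u(node) phi(...) (dx = 1).

    ``u_grid`` is a tuple/array of velocity components, component axis
    first; marker positions are in lattice units.  ``wrap_x`` treats the
    streamwise axis as periodic.
    """
    u_grid = [np.ascontiguousarray(c) for c in u_grid]
    d = len(u_grid)
    pos = markers.positions
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    shape = np.array(u_grid[0].shape)
    bad_lo = lo < 1.0
    bad_hi = hi > shape - 2.0
    # the streamwise faces may truncate the kernel support: the face
    # closure re-imposes the wall-consistent profile there anyway
    bad_lo[0] = bad_hi[0] = False
    if bad_lo.any() or bad_hi.any():
        raise ValueError("marker outside the interpolable grid interior")
    out = np.empty((len(markers), d))
    if d == 2:
        _k.interp_2d(u_grid[0], u_grid[1], pos, out, wrap_x)
    else:
        _k.interp_3d(u_grid[0], u_grid[1], u_grid[2], pos, out, wrap_x)
    return out


def feedback_force(
    markers: MarkerSet,
    marker_velocity: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    dt: float = 1.0,
    integral_cap: float | None = None,
):
    """Feedback force density per marker; updates the slip integral in place.

    One rectangle step of the slip integral is accumulated per call.  Gains
    must be restoring (<= 0); magnitudes beyond the explicit-coupling
    stability bound trigger a warning-level error.  ``integral_cap`` is an
    optional anti-windup clamp on |integral| (lattice units).
    """
    if alpha > 0 or beta > 0:
        raise ValueError("feedback gains must be restoring (alpha, beta <= 0)")
    if abs(alpha) * dt * dt > 2.0 or abs(beta) * dt > 2.0:
        raise ValueError("feedback gains beyond the explicit stability bound")
    slip = marker_velocity - markers.target_velocity
    markers.slip_integral += slip * dt
    if integral_cap is not None:
        np.clip(markers.slip_integral, -integral_cap, integral_cap, out=markers.slip_integral)
    return alpha * markers.slip_integral + beta * slip


def spread_force(
    markers: MarkerSet,
    marker_forces: np.ndarray,
    grid_shape,
    kernel: DeltaKernel = PESKIN4,
    weights=None,
    out=None,
    wrap_x: bool = False,
):
    """Spread marker forces to a grid force-density field (adjoint of interp).

    f(node) = sum_m F_m * w_m * phi(node - X_m) with dx = 1, so the total
    spread force equals sum_m F_m w_m.  ``weights`` defaults to 1 per
    marker; the flow pipeline passes each marker's wetted patch volume.
    """
    d = markers.positions.shape[1]
    if out is None:
        out = np.zeros((d,) + tuple(grid_shape))
    w = np.ones(len(markers)) if weights is None else np.ascontiguousarray(weights, dtype=float)
    F = np.ascontiguousarray(marker_forces, dtype=float)
    if d == 2:
        _k.spread_2d(out[0], out[1], markers.positions, F, w, wrap_x)
    else:
        _k.spread_3d(out[0], out[1], out[2], markers.positions, F, w, wrap_x)
    return out
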