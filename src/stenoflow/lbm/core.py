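"""Reference MRT-LBM operations in pure numpy.

Conventions: lattice units dx = dt = 1, cs^2 = 1/3.  Distribution arrays
carry the population axis first, ``g[q, ...grid]``; velocities and forces
carry the component axis first, ``u[d, ...grid]``.  The Guo half-force
convention is used throughout: the macroscopic velocity is
u = (sum_i g_i e_i + f/2) / rho, the equilibrium and force term are
evaluated at that velocity, and collision adds dt * M^-1 (I - S/2) M F.

These routines are the readable contract; the production time stepper in
``kernels.py`` is checked against them step-for-step in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import LatticeModel

__all__ = [
    "FluidState",
    "equilibrium",
    "guo_force_term",
    "compute_macros",
    "mrt_collide",
    "stream",
    "viscosity_to_tau",
    "tau_to_viscosity",
]


def viscosity_to_tau(nu: float, dx: float = 1.0, dt: float = 1.0) -> float:
    """Relaxation time from kinematic viscosity, nu = (tau - 1/2) cs^2 dt."""
    if nu < 0:
        raise ValueError("viscosity must be non-negative")
    cs2 = dx * dx / (3.0 * dt * dt)
    return nu / (cs2 * dt) + 0.5


def tau_to_viscosity(tau: float, dx: float = 1.0, dt: float = 1.0) -> float:
    cs2 = dx * dx / (3.0 * dt * dt)
    return (tau - 0.5) * cs2 * dt


def equilibrium(rho, u, model: LatticeModel):
    """Second-order Maxwellian g_eq_i(rho, u), population axis first."""
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    cs2 = model.cs2
    eu = np.tensordot(model.e.astype(float), u, axes=(1, 0))  # (q, ...)
    u2 = (u * u).sum(axis=0)
    shape = (model.q,) + (1,) * rho.ndim
    w = model.w.reshape(shape)
    return w * rho * (1.0 + eu / cs2 + 0.5 * eu**2 / cs2**2 - 0.5 * u2 / cs2)


def guo_force_term(u, f, model: LatticeModel):
    """Guo body-force population term F_i(u, f), population axis first."""
    u = np.asarray(u, dtype=float)
    f = np.asarray(f, dtype=float)
    cs2 = model.cs2
    ef = np.tensordot(model.e.astype(float), f, axes=(1, 0))
    uf = (u * f).sum(axis=0)
    eu = np.tensordot(model.e.astype(float), u, axes=(1, 0))
    shape = (model.q,) + (1,) * uf.ndim
    w = model.w.reshape(shape)
    return w * (ef / cs2 - uf / cs2 + eu * ef / cs2**2)


def compute_macros(g, f, model: LatticeModel):
    """Density and half-force-corrected velocity from the populations."""
    g = np.asarray(g, dtype=float)
    rho = g.sum(axis=0)
    if np.any(rho <= 0.0):
        raise FloatingPointError("non-positive density encountered")
    mom = np.tensordot(model.e.astype(float).T, g, axes=(1, 0))
    if f is not None:
        mom = mom + 0.5 * np.asarray(f, dtype=float)
    return rho, mom / rho


def mrt_collide(g, rho, u, f, model: LatticeModel, tau: float, s_free=None):
    """One MRT collision: g+ = g - M^-1 S M (g - g_eq) + dt M^-1 (I-S/2) M F."""
    A, B = model.relaxation_matrices(tau, s_free)
    geq = equilibrium(rho, u, model)
    F = guo_force_term(u, f, model) if f is not None else np.zeros_like(g)
    dg = np.tensordot(A, g - geq, axes=(1, 0))
    gf = np.tensordot(B, F, axes=(1, 0))
    return g - dg + gf


def stream(g, model: LatticeModel):
    """Advect each population one lattice link (periodic closure)."""
    out = np.empty_like(g)
    for i in range(model.q):
        out[i] = g[i]
        for axis, s in enumerate(model.e[i]):
            if s:
                out[i] = np.roll(out[i], s, axis=axis)
    return out


@dataclass
class FluidState:
    """Populations and macroscopic fields on a Cartesian grid."""

    model: LatticeModel
    g: np.ndarray          # (q, *grid)
    tau: float
    f: np.ndarray = field(default=None)  # (d, *grid) body-force density
    dx: float = 1.0
    dt: float = 1.0

    def __post_init__(self):
        if self.f is None:
            self.f = np.zeros((self.model.dimension,) + self.grid_shape)
        if not (tau_to_viscosity(self.tau, self.dx, self.dt) >= 0.0):
            raise ValueError("tau must be >= 1/2")

    @property
    def grid_shape(self):
        return self.g.shape[1:]

    @property
    def nu(self) -> float:
        return tau_to_viscosity(self.tau, self.dx, self.dt)

    def macros(self):
        return compute_macros(self.g, self.f, self.model)

    @classmethod
    def from_velocity(cls, model, grid_shape, tau, u0=None, rho0=1.0):
        """Equilibrium initialization at uniform or given velocity."""
        d = model.dimension
        u = np.zeros((d,) + tuple(grid_shape))
        if u0 is not None:
            u0 = np.asarray(u0, dtype=float)
            if u0.shape == (d,):
                u += u0.reshape((d,) + (1,) * len(grid_shape))
            else:
                u[:] = u0
        rho = np.full(tuple(grid_shape), float(rho0))
        return cls(model=model, g=equilibrium(rho, u, model), tau=tau)
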