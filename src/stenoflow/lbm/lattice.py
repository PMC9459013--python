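"""Discrete velocity sets and MRT matrices for D2Q9 and D3Q19.

The moment basis follows Lallemand & Luo (2D: rho, e, eps, jx, qx, jy, qy,
pxx, pxy) and d'Humieres et al. (3D, 19 moments).  Equilibrium moments are
taken as M g_eq with g_eq the second-order Maxwellian, so the collision can
be applied in population space through the precomputed matrices
A = M^-1 S M and B = M^-1 (I - S/2) M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LatticeModel", "build_lattice", "relaxation_vector"]


@dataclass(frozen=True)
class LatticeModel:
    """One discrete-velocity model: speeds, weights, and MRT transform."""

    dimension: int
    q: int
    e: np.ndarray  # (q, dimension) int lattice speeds
    w: np.ndarray  # (q,) weights
    M: np.ndarray  # (q, q) moment transform
    Minv: np.ndarray
    cs2: float = 1.0 / 3.0  # sound speed squared, dx = dt = 1

    @property
    def cs(self) -> float:
        return float(np.sqrt(self.cs2))

    def relaxation_matrices(self, tau: float, s_free: dict | None = None):
        """Population-space collision matrices (A, B) for relaxation time tau.

        A = M^-1 S M applies the moment-wise relaxation; B = M^-1 (I-S/2) M
        applies the Guo forcing correction.  Viscous modes relax at 1/tau;
        conserved modes at 0; the free (ghost) rates default to documented
        literature values and can be overridden via ``s_free``.
        """
        s = relaxation_vector(self.dimension, tau, s_free)
        if np.any(s < 0.0) or np.any(s >= 2.0):
            raise ValueError("relaxation rates must lie in [0, 2) for linear stability")
        S = np.diag(s)
        A = self.Minv @ S @ self.M
        B = self.Minv @ (np.eye(self.q) - 0.5 * S) @ self.M
        return A, B


_E2D = np.array(
    [[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1], [1, 1], [-1, 1], [-1, -1], [1, -1]]
)
_W2D = np.array([4 / 9] + [1 / 9] * 4 + [1 / 36] * 4)

_DEFAULT_FREE_2D = {"s_e": 1.4, "s_eps": 1.4, "s_q": 1.2}
_DEFAULT_FREE_3D = {"s_e": 1.19, "s_eps": 1.4, "s_q": 1.2, "s_pi": 1.4, "s_m": 1.98}


def _moment_matrix_2d() -> np.ndarray:
    ex, ey = _E2D[:, 0].astype(float), _E2D[:, 1].astype(float)
    e2 = ex**2 + ey**2
    rows = [
        np.ones(9),          # rho
        -4 + 3 * e2,         # energy e
        4 - 21 / 2 * e2 + 9 / 2 * e2**2,  # energy squared eps
        ex,                  # jx
        (-5 + 3 * e2) * ex,  # qx
        ey,                  # jy
        (-5 + 3 * e2) * ey,  # qy
        ex**2 - ey**2,       # pxx
        ex * ey,             # pxy
    ]
    return np.array(rows)


def _velocities_3d() -> np.ndarray:
    e = [[0, 0, 0]]
    for a in range(3):
        for s in (1, -1):
            v = [0, 0, 0]
            v[a] = s
            e.append(v)
    for a in range(3):
        b = (a + 1) % 3
        for sa in (1, -1):
            for sb in (1, -1):
                v = [0, 0, 0]
                v[a], v[b] = sa, sb
                e.append(v)
    return np.array(e)


def _moment_matrix_3d(e: np.ndarray) -> np.ndarray:
    ex, ey, ez = (e[:, k].astype(float) for k in range(3))
    e2 = ex**2 + ey**2 + ez**2
    rows = [
        np.ones(19),
        19 * e2 - 30,
        (21 * e2**2 - 53 * e2 + 24) / 2,
        ex,
        (5 * e2 - 9) * ex,
        ey,
        (5 * e2 - 9) * ey,
        ez,
        (5 * e2 - 9) * ez,
        3 * ex**2 - e2,
        (3 * e2 - 5) * (3 * ex**2 - e2),
        ey**2 - ez**2,
        (3 * e2 - 5) * (ey**2 - ez**2),
        ex * ey,
        ey * ez,
        ex * ez,
        (ey**2 - ez**2) * ex,
        (ez**2 - ex**2) * ey,
        (ex**2 - ey**2) * ez,
    ]
    return np.array(rows)


def relaxation_vector(dimension: int, tau: float, s_free: dict | None = None) -> np.ndarray:
    """Diagonal of S: conserved modes 0, viscous modes 1/tau, ghosts free."""
    snu = 1.0 / tau
    if dimension == 2:
        f = dict(_DEFAULT_FREE_2D, **(s_free or {}))
        return np.array([0.0, f["s_e"], f["s_eps"], 0.0, f["s_q"], 0.0, f["s_q"], snu, snu])
    f = dict(_DEFAULT_FREE_3D, **(s_free or {}))
    return np.array(
        [0.0, f["s_e"], f["s_eps"], 0.0, f["s_q"], 0.0, f["s_q"], 0.0, f["s_q"],
         snu, f["s_pi"], snu, f["s_pi"], snu, snu, snu, f["s_m"], f["s_m"], f["s_m"]]
    )


def build_lattice(dimension: int) -> LatticeModel:
    """Construct the D2Q9 (dimension=2) or D3Q19 (dimension=3) model."""
    if dimension == 2:
        e, w = _E2D, _W2D
        M = _moment_matrix_2d()
    elif dimension == 3:
        e = _velocities_3d()
        w = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)
        M = _moment_matrix_3d(e)
    else:
        raise ValueError(f"unsupported dimension {dimension}; need 2 or 3")
    return LatticeModel(
        dimension=dimension, q=len(w), e=e, w=w, M=M, Minv=np.linalg.inv(M)
    )
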