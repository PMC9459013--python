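"""Numba time-stepping kernels (D2Q9 / D3Q19 fused collide-stream, NEE faces,
IB interpolation/spreading).

All kernels work in lattice units (dx = dt = 1) on population arrays with the
population axis first.  They are deterministic and single-threaded; the pure
numpy routines in ``core.py`` define the semantics and the test suite checks
one full step of these kernels against them.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# macroscopic moments


@njit(cache=True, fastmath=True)
def macros_2d(g, ex, ey, rho, momx, momy):
    q, nx, ny = g.shape
    for x in range(nx):
        for y in range(ny):
            r = 0.0
            mx = 0.0
            my = 0.0
            for i in range(q):
                gi = g[i, x, y]
                r += gi
                mx += gi * ex[i]
                my += gi * ey[i]
            rho[x, y] = r
            momx[x, y] = mx
            momy[x, y] = my


@njit(cache=True, fastmath=True)
def macros_3d(g, ex, ey, ez, rho, momx, momy, momz):
    q, nx, ny, nz = g.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                r = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(q):
                    gi = g[i, x, y, z]
                    r += gi
                    mx += gi * ex[i]
                    my += gi * ey[i]
                    mz += gi * ez[i]
                rho[x, y, z] = r
                momx[x, y, z] = mx
                momy[x, y, z] = my
                momz[x, y, z] = mz


# ---------------------------------------------------------------------------
# fused MRT collide + push stream (periodic wrap; x faces overwritten by NEE)


@njit(cache=True, fastmath=True)
def collide_stream_2d(g, gnew, rho, momx, momy, fx, fy, A, B, w, ex, ey):
    q, nx, ny = g.shape
    dg = np.empty((q, ny))
    Fi = np.empty((q, ny))
    gp = np.empty((q, ny))
    ux = np.empty(ny)
    uy = np.empty(ny)
    u2 = np.empty(ny)
    for x in range(nx):
        forced = False
        for y in range(ny):
            ffx = fx[x, y]
            ffy = fy[x, y]
            if ffx != 0.0 or ffy != 0.0:
                forced = True
            r = rho[x, y]
            ux[y] = (momx[x, y] + 0.5 * ffx) / r
            uy[y] = (momy[x, y] + 0.5 * ffy) / r
            u2[y] = ux[y] * ux[y] + uy[y] * uy[y]
        for i in range(q):
            exi = ex[i]
            eyi = ey[i]
            wi = w[i]
            for y in range(ny):
                eu = exi * ux[y] + eyi * uy[y]
                geq = wi * rho[x, y] * (1.0 + 3.0 * eu + 4.5 * eu * eu - 1.5 * u2[y])
                dg[i, y] = g[i, x, y] - geq
                gp[i, y] = g[i, x, y]
            if forced:
                for y in range(ny):
                    eu = exi * ux[y] + eyi * uy[y]
                    ef = exi * fx[x, y] + eyi * fy[x, y]
                    uf = ux[y] * fx[x, y] + uy[y] * fy[x, y]
                    Fi[i, y] = wi * (3.0 * ef - 3.0 * uf + 9.0 * eu * ef)
        if forced:
            for i in range(q):
                for j in range(q):
                    a = A[i, j]
                    b = B[i, j]
                    for y in range(ny):
                        gp[i, y] += -a * dg[j, y] + b * Fi[j, y]
        else:
            for i in range(q):
                for j in range(q):
                    a = A[i, j]
                    for y in range(ny):
                        gp[i, y] -= a * dg[j, y]
        for i in range(q):
            xn = x + ex[i]
            if xn < 0:
                xn += nx
            elif xn >= nx:
                xn -= nx
            yi = ey[i]
            if yi == 0:
                for y in range(ny):
                    gnew[i, xn, y] = gp[i, y]
            else:
                for y in range(ny):
                    yn = y + yi
                    if yn < 0:
                        yn += ny
                    elif yn >= ny:
                        yn -= ny
                    gnew[i, xn, yn] = gp[i, y]


@njit(cache=True, fastmath=True)
def collide_stream_3d(g, gnew, rho, momx, momy, momz, fx, fy, fz, A, B, w, ex, ey, ez):
    q, nx, ny, nz = g.shape
    dg = np.empty((q, nz))
    Fi = np.empty((q, nz))
    gp = np.empty((q, nz))
    ux = np.empty(nz)
    uy = np.empty(nz)
    uz = np.empty(nz)
    u2 = np.empty(nz)
    for x in range(nx):
        for y in range(ny):
            forced = False
            for z in range(nz):
                ffx = fx[x, y, z]
                ffy = fy[x, y, z]
                ffz = fz[x, y, z]
                if ffx != 0.0 or ffy != 0.0 or ffz != 0.0:
                    forced = True
                r = rho[x, y, z]
                ux[z] = (momx[x, y, z] + 0.5 * ffx) / r
                uy[z] = (momy[x, y, z] + 0.5 * ffy) / r
                uz[z] = (momz[x, y, z] + 0.5 * ffz) / r
                u2[z] = ux[z] * ux[z] + uy[z] * uy[z] + uz[z] * uz[z]
            for i in range(q):
                exi = ex[i]
                eyi = ey[i]
                ezi = ez[i]
                wi = w[i]
                for z in range(nz):
                    eu = exi * ux[z] + eyi * uy[z] + ezi * uz[z]
                    geq = wi * rho[x, y, z] * (
                        1.0 + 3.0 * eu + 4.5 * eu * eu - 1.5 * u2[z]
                    )
                    dg[i, z] = g[i, x, y, z] - geq
                    gp[i, z] = g[i, x, y, z]
                if forced:
                    for z in range(nz):
                        eu = exi * ux[z] + eyi * uy[z] + ezi * uz[z]
                        ef = exi * fx[x, y, z] + eyi * fy[x, y, z] + ezi * fz[x, y, z]
                        uf = ux[z] * fx[x, y, z] + uy[z] * fy[x, y, z] + uz[z] * fz[x, y, z]
                        Fi[i, z] = wi * (3.0 * ef - 3.0 * uf + 9.0 * eu * ef)
            if forced:
                for i in range(q):
                    for j in range(q):
                        a = A[i, j]
                        b = B[i, j]
                        for z in range(nz):
                            gp[i, z] += -a * dg[j, z] + b * Fi[j, z]
            else:
                for i in range(q):
                    for j in range(q):
                        a = A[i, j]
                        for z in range(nz):
                            gp[i, z] -= a * dg[j, z]
            for i in range(q):
                xn = x + ex[i]
                if xn < 0:
                    xn += nx
                elif xn >= nx:
                    xn -= nx
                yn = y + ey[i]
                if yn < 0:
                    yn += ny
                elif yn >= ny:
                    yn -= ny
                zi = ez[i]
                if zi == 0:
                    for z in range(nz):
                        gnew[i, xn, yn, z] = gp[i, z]
                else:
                    for z in range(nz):
                        zn = z + zi
                        if zn < 0:
                            zn += nz
                        elif zn >= nz:
                            zn -= nz
                        gnew[i, xn, yn, zn] = gp[i, z]


# ---------------------------------------------------------------------------
# non-equilibrium extrapolation on the x faces
# inlet (x=0): equilibrium at (rho_neighbour, U0) + neighbour non-equilibrium
# outlet (x=nx-1): equilibrium at (rho_ref, u_neighbour) + neighbour non-eq.


@njit(cache=True, fastmath=True)
def _eq_i(w_i, exi, eyi, r, ux, uy):
    cs2 = 1.0 / 3.0
    eu = exi * ux + eyi * uy
    u2 = ux * ux + uy * uy
    return w_i * r * (1.0 + eu / cs2 + 0.5 * eu * eu / (cs2 * cs2) - 0.5 * u2 / cs2)


@njit(cache=True, fastmath=True)
def nee_faces_2d(g, w, ex, ey, u_inlet, rho_outlet, lumen):
    # u_inlet: per-node inlet velocity profile over the face, shape (ny,)
    # lumen: uint8 flags; outlet nodes outside the lumen close as u=0 walls
    q, nx, ny = g.shape
    for y in range(ny):
        # inlet
        rn = 0.0
        mx = 0.0
        my = 0.0
        for i in range(q):
            gi = g[i, 1, y]
            rn += gi
            mx += gi * ex[i]
            my += gi * ey[i]
        ux = mx / rn
        uy = my / rn
        for i in range(q):
            g[i, 0, y] = _eq_i(w[i], ex[i], ey[i], rn, u_inlet[y], 0.0) + (
                g[i, 1, y] - _eq_i(w[i], ex[i], ey[i], rn, ux, uy)
            )
        # outlet
        rn = 0.0
        mx = 0.0
        my = 0.0
        for i in range(q):
            gi = g[i, nx - 2, y]
            rn += gi
            mx += gi * ex[i]
            my += gi * ey[i]
        ux = mx / rn
        uy = my / rn
        if lumen[y]:
            for i in range(q):
                g[i, nx - 1, y] = _eq_i(w[i], ex[i], ey[i], rho_outlet, ux, uy) + (
                    g[i, nx - 2, y] - _eq_i(w[i], ex[i], ey[i], rn, ux, uy)
                )
        else:
            for i in range(q):
                g[i, nx - 1, y] = _eq_i(w[i], ex[i], ey[i], rn, 0.0, 0.0) + (
                    g[i, nx - 2, y] - _eq_i(w[i], ex[i], ey[i], rn, ux, uy)
                )


@njit(cache=True, fastmath=True)
def _eq_i3(w_i, exi, eyi, ezi, r, ux, uy, uz):
    cs2 = 1.0 / 3.0
    eu = exi * ux + eyi * uy + ezi * uz
    u2 = ux * ux + uy * uy + uz * uz
    return w_i * r * (1.0 + eu / cs2 + 0.5 * eu * eu / (cs2 * cs2) - 0.5 * u2 / cs2)


@njit(cache=True, fastmath=True)
def nee_faces_3d(g, w, ex, ey, ez, u_inlet, rho_outlet, lumen):
    # u_inlet: per-node inlet velocity profile over the face, shape (ny, nz)
    # lumen: uint8 flags; outlet nodes outside the lumen close as u=0 walls
    q, nx, ny, nz = g.shape
    for y in range(ny):
        for z in range(nz):
            rn = 0.0
            mx = 0.0
            my = 0.0
            mz = 0.0
            for i in range(q):
                gi = g[i, 1, y, z]
                rn += gi
                mx += gi * ex[i]
                my += gi * ey[i]
                mz += gi * ez[i]
            ux = mx / rn
            uy = my / rn
            uz = mz / rn
            for i in range(q):
                g[i, 0, y, z] = _eq_i3(w[i], ex[i], ey[i], ez[i], rn, u_inlet[y, z], 0.0, 0.0) + (
                    g[i, 1, y, z] - _eq_i3(w[i], ex[i], ey[i], ez[i], rn, ux, uy, uz)
                )
            rn = 0.0
            mx = 0.0
            my = 0.0
            mz = 0.0
            for i in range(q):
                gi = g[i, nx - 2, y, z]
                rn += gi
                mx += gi * ex[i]
                my += gi * ey[i]
                mz += gi * ez[i]
            ux = mx / rn
            uy = my / rn
            uz = mz / rn
            if lumen[y, z]:
                for i in range(q):
                    g[i, nx - 1, y, z] = _eq_i3(
                        w[i], ex[i], ey[i], ez[i], rho_outlet, ux, uy, uz
                    ) + (g[i, nx - 2, y, z] - _eq_i3(w[i], ex[i], ey[i], ez[i], rn, ux, uy, uz))
            else:
                for i in range(q):
                    g[i, nx - 1, y, z] = _eq_i3(
                        w[i], ex[i], ey[i], ez[i], rn, 0.0, 0.0, 0.0
                    ) + (g[i, nx - 2, y, z] - _eq_i3(w[i], ex[i], ey[i], ez[i], rn, ux, uy, uz))


# ---------------------------------------------------------------------------
# immersed boundary: 4-point Peskin kernel, interpolation and spreading


@njit(cache=True, fastmath=True)
def peskin4(r):
    a = abs(r)
    if a < 1.0:
        return 0.125 * (3.0 - 2.0 * a + np.sqrt(1.0 + 4.0 * a - 4.0 * a * a))
    if a < 2.0:
        return 0.125 * (5.0 - 2.0 * a - np.sqrt(-7.0 + 12.0 * a - 4.0 * a * a))
    return 0.0


@njit(cache=True, fastmath=True)
def interp_2d(ux, uy, pos, out, wrapx=False):
    nx, ny = ux.shape
    n = pos.shape[0]
    for m in range(n):
        px = pos[m, 0]
        py = pos[m, 1]
        ix0 = int(np.floor(px)) - 1
        iy0 = int(np.floor(py)) - 1
        vx = 0.0
        vy = 0.0
        for a in range(4):
            xg = ix0 + a
            wx = peskin4(px - xg)
            if wrapx:
                xg = xg % nx
            if wx == 0.0 or xg < 0 or xg >= nx:
                continue
            for b in range(4):
                yg = iy0 + b
                if yg < 0 or yg >= ny:
                    continue
                wxy = wx * peskin4(py - yg)
                vx += ux[xg, yg] * wxy
                vy += uy[xg, yg] * wxy
        out[m, 0] = vx
        out[m, 1] = vy


@njit(cache=True, fastmath=True)
def spread_2d(fx, fy, pos, force, scale, wrapx=False):
    nx, ny = fx.shape
    n = pos.shape[0]
    for m in range(n):
        px = pos[m, 0]
        py = pos[m, 1]
        sfx = force[m, 0] * scale[m]
        sfy = force[m, 1] * scale[m]
        ix0 = int(np.floor(px)) - 1
        iy0 = int(np.floor(py)) - 1
        for a in range(4):
            xg = ix0 + a
            wx = peskin4(px - xg)
            if wrapx:
                xg = xg % nx
            if wx == 0.0 or xg < 0 or xg >= nx:
                continue
            for b in range(4):
                yg = iy0 + b
                if yg < 0 or yg >= ny:
                    continue
                wxy = wx * peskin4(py - yg)
                fx[xg, yg] += sfx * wxy
                fy[xg, yg] += sfy * wxy


@njit(cache=True, fastmath=True)
def interp_3d(ux, uy, uz, pos, out, wrapx=False):
    nx, ny, nz = ux.shape
    n = pos.shape[0]
    for m in range(n):
        px = pos[m, 0]
        py = pos[m, 1]
        pz = pos[m, 2]
        ix0 = int(np.floor(px)) - 1
        iy0 = int(np.floor(py)) - 1
        iz0 = int(np.floor(pz)) - 1
        vx = 0.0
        vy = 0.0
        vz = 0.0
        for a in range(4):
            xg = ix0 + a
            wx = peskin4(px - xg)
            if wrapx:
                xg = xg % nx
            if wx == 0.0 or xg < 0 or xg >= nx:
                continue
            for b in range(4):
                yg = iy0 + b
                wy = peskin4(py - yg)
                if wy == 0.0 or yg < 0 or yg >= ny:
                    continue
                wxy = wx * wy
                for c in range(4):
                    zg = iz0 + c
                    if zg < 0 or zg >= nz:
                        continue
                    wxyz = wxy * peskin4(pz - zg)
                    vx += ux[xg, yg, zg] * wxyz
                    vy += uy[xg, yg, zg] * wxyz
                    vz += uz[xg, yg, zg] * wxyz
        out[m, 0] = vx
        out[m, 1] = vy
        out[m, 2] = vz


@njit(cache=True, fastmath=True)
def spread_3d(fx, fy, fz, pos, force, scale, wrapx=False):
    nx, ny, nz = fx.shape
    n = pos.shape[0]
    for m in range(n):
        px = pos[m, 0]
        py = pos[m, 1]
        pz = pos[m, 2]
        sfx = force[m, 0] * scale[m]
        sfy = force[m, 1] * scale[m]
        sfz = force[m, 2] * scale[m]
        ix0 = int(np.floor(px)) - 1
        iy0 = int(np.floor(py)) - 1
        iz0 = int(np.floor(pz)) - 1
        for a in range(4):
            xg = ix0 + a
            wx = peskin4(px - xg)
            if wrapx:
                xg = xg % nx
            if wx == 0.0 or xg < 0 or xg >= nx:
                continue
            for b in range(4):
                yg = iy0 + b
                wy = peskin4(py - yg)
                if wy == 0.0 or yg < 0 or yg >= ny:
                    continue
                wxy = wx * wy
                for c in range(4):
                    zg = iz0 + c
                    if zg < 0 or zg >= nz:
                        continue
                    wxyz = wxy * peskin4(pz - zg)
                    fx[xg, yg, zg] += sfx * wxyz
                    fy[xg, yg, zg] += sfy * wxyz
                    fz[xg, yg, zg] += sfz * wxyz


# ---------------------------------------------------------------------------
# no-slip NEE closure on the lateral (transverse) faces


@njit(cache=True, fastmath=True)
def nee_lateral_2d(g, w, ex, ey):
    q, nx, ny = g.shape
    for x in range(nx):
        for yb, yn in ((0, 1), (ny - 1, ny - 2)):
            rn = 0.0
            mx = 0.0
            my = 0.0
            for i in range(q):
                gi = g[i, x, yn]
                rn += gi
                mx += gi * ex[i]
                my += gi * ey[i]
            ux = mx / rn
            uy = my / rn
            for i in range(q):
                g[i, x, yb] = _eq_i(w[i], ex[i], ey[i], rn, 0.0, 0.0) + (
                    g[i, x, yn] - _eq_i(w[i], ex[i], ey[i], rn, ux, uy)
                )


@njit(cache=True, fastmath=True)
def nee_lateral_3d(g, w, ex, ey, ez):
    q, nx, ny, nz = g.shape
    for x in range(nx):
        for z in range(nz):
            for yb, yn in ((0, 1), (ny - 1, ny - 2)):
                rn = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(q):
                    gi = g[i, x, yn, z]
                    rn += gi
                    mx += gi * ex[i]
                    my += gi * ey[i]
                    mz += gi * ez[i]
                ux = mx / rn
                uy = my / rn
                uz = mz / rn
                for i in range(q):
                    g[i, x, yb, z] = _eq_i3(w[i], ex[i], ey[i], ez[i], rn, 0.0, 0.0, 0.0) + (
                        g[i, x, yn, z] - _eq_i3(w[i], ex[i], ey[i], ez[i], rn, ux, uy, uz)
                    )
        for y in range(ny):
            for zb, zn in ((0, 1), (nz - 1, nz - 2)):
                rn = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(q):
                    gi = g[i, x, y, zn]
                    rn += gi
                    mx += gi * ex[i]
                    my += gi * ey[i]
                    mz += gi * ez[i]
                ux = mx / rn
                uy = my / rn
                uz = mz / rn
                for i in range(q):
                    g[i, x, y, zb] = _eq_i3(w[i], ex[i], ey[i], ez[i], rn, 0.0, 0.0, 0.0) + (
                        g[i, x, y, zn] - _eq_i3(w[i], ex[i], ey[i], ez[i], rn, ux, uy, uz)
                    )
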