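"""Parametric stenosed-artery geometry.

A stenosis of axial extent ``D`` (the unobstructed artery diameter) is
described by a fifth-order polynomial wall profile

    y(x) = a1 x^5 + a2 x^4 + a3 x^3 + a4 x^2 + a5 x + a6,   x in [0, D],

clamped to the healthy wall at both ends, y(0) = y(D) = D and
y'(0) = y'(D) = 0.  Those four conditions leave two degrees of freedom,
which are parameterized physically by the stenosis depth ``h`` and the
throat location ``x_star`` through y(x_star) = D - h, y'(x_star) = 0,
making the 6x6 linear system uniquely solvable and guaranteeing a
single-throat narrowing.

3D arteries reuse the same axial profile: axisymmetric tubes have local
radius y(x)/2, and asymmetric ones modulate the wall invasion around the
circumference with a periodized Gaussian weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StenosisShape",
    "AsymmetricShape3D",
    "ShapeImage",
    "MarkerSet",
    "DegenerateParameterError",
    "RejectedSampleError",
    "solve_stenosis_polynomial",
    "sample_stenosis",
    "sample_asymmetric",
    "evaluate_profile",
    "radius_axisymmetric",
    "radius_asymmetric",
    "rasterize_2d",
    "rasterize_3d",
    "sample_surface_points",
    "markers_channel_2d",
    "markers_tube_3d",
]


class DegenerateParameterError(ValueError):
    """Throat location coincides with a clamped end: the system is singular."""


class RejectedSampleError(ValueError):
    """The solved profile leaves (0, D] and is not a valid stenosis."""


@dataclass(frozen=True)
class StenosisShape:
    """Quintic wall profile of one stenosis.

    coefficients are ordered a1..a6 (x^5 down to the constant term) in the
    local axial coordinate xi = x - x_start, xi in [0, D].
    """

    D: float
    coefficients: np.ndarray
    x_start: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=float))
        if self.coefficients.shape != (6,):
            raise ValueError("need exactly six polynomial coefficients")

    @property
    def x_end(self) -> float:
        return self.x_start + self.D

    def _poly(self, xi):
        return np.polyval(self.coefficients, xi)

    def _critical_points(self):
        der = np.polyder(self.coefficients)
        roots = np.roots(der)
        real = roots[np.abs(roots.imag) < 1e-9].real
        return real[(real > 0.0) & (real < self.D)]

    @property
    def depth(self) -> float:
        """Stenosis depth h = D - min y over the extent (exact extrema)."""
        cand = np.concatenate([[0.0, self.D], self._critical_points()])
        return float(self.D - self._poly(cand).min())

    @property
    def throat(self) -> float:
        """Axial location of the minimum gap (absolute x)."""
        cand = np.concatenate([[0.0, self.D], self._critical_points()])
        return self.x_start + float(cand[np.argmin(self._poly(cand))])

    def constraint_residuals(self) -> np.ndarray:
        """Residuals of (y(0)-D, y(D)-D, y'(0), y'(D))."""
        der = np.polyder(self.coefficients)
        return np.array(
            [
                self._poly(0.0) - self.D,
                self._poly(self.D) - self.D,
                np.polyval(der, 0.0),
                np.polyval(der, self.D),
            ]
        )


@dataclass(frozen=True)
class AsymmetricShape3D:
    """Axial quintic profile plus a circumferential invasion weight.

    The local tube radius is

        r(x, theta) = D/2 - (D/2 - y(x)/2) * w(theta),

    with ``w`` a periodized Gaussian bump centered at ``theta0`` of spread
    ``sigma`` whose maximum is normalized to ``amplitude`` (0..1).  With
    amplitude 1 and sigma -> inf the tube degenerates to the axisymmetric
    stenosis of the same axial profile.
    """

    axial_profile: StenosisShape
    theta0: float = 0.0
    sigma: float = 0.8
    amplitude: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError("amplitude must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def D(self) -> float:
        return self.axial_profile.D

    def weight(self, theta):
        """Periodized Gaussian angular weight, peak normalized to amplitude."""
        theta = np.asarray(theta, dtype=float)
        K = max(6, int(np.ceil(4.0 * self.sigma / (2.0 * np.pi))) + 2)
        ks = np.arange(-K, K + 1)
        d = theta[..., None] - self.theta0 + 2.0 * np.pi * ks
        s = np.exp(-0.5 * (d / self.sigma) ** 2).sum(axis=-1)
        peak = np.exp(-0.5 * (2.0 * np.pi * ks / self.sigma) ** 2).sum()
        return self.amplitude * s / peak


@dataclass(frozen=True)
class ShapeImage:
    """Binary raster of a stenosis (2D: 214x214 pixels, 3D: 61^3 voxels)."""

    values: np.ndarray
    pixel_spacing: float
    origin: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        v = self.values
        if not np.isin(v, (0, 1)).all():
            raise ValueError("raster must be binary")


@dataclass
class MarkerSet:
    """Lagrangian wall markers with feedback-force state.

    positions: (N, d) marker coordinates on the analytic wall surface.
    weights: per-marker wetted length (2D) or area (3D) used when
        spreading the feedback force back onto the grid.
    slip_integral: running rectangle-rule integral of the marker slip
        velocity, the 'spring' part of the feedback (Goldstein) force law.
    """

    positions: np.ndarray
    weights: np.ndarray
    spacing: float
    target_velocity: np.ndarray = field(default=None)
    slip_integral: np.ndarray = field(default=None)

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.weights = np.ascontiguousarray(self.weights, dtype=float)
        if self.target_velocity is None:
            self.target_velocity = np.zeros_like(self.positions)
        if self.slip_integral is None:
            self.slip_integral = np.zeros_like(self.positions)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def reset_feedback(self) -> None:
        self.slip_integral[:] = 0.0


# ---------------------------------------------------------------------------
# construction and evaluation


def solve_stenosis_polynomial(D: float, h: float, x_star: float) -> StenosisShape:
    """Solve the six clamped-quintic conditions for one stenosis profile.

    Raises DegenerateParameterError when x_star coincides with a clamped
    end and RejectedSampleError when the resulting profile leaves (0, D].
    """
    if not (0.0 < h < D):
        raise ValueError(f"depth h must lie in (0, D); got h={h}, D={D}")
    if not (0.0 < x_star < D):
        raise DegenerateParameterError(f"throat x_star must lie strictly inside (0, D); got {x_star}")
    # guard against near-singular systems very close to the ends
    if min(x_star, D - x_star) < 1e-6 * D:
        raise DegenerateParameterError("throat too close to a clamped end")

    def row_y(x):
        return [x**5, x**4, x**3, x**2, x, 1.0]

    def row_dy(x):
        return [5 * x**4, 4 * x**3, 3 * x**2, 2 * x, 1.0, 0.0]

    A = np.array(
        [row_y(0.0), row_y(D), row_dy(0.0), row_dy(D), row_y(x_star), row_dy(x_star)]
    )
    b = np.array([D, D, 0.0, 0.0, D - h, 0.0])
    coeffs = np.linalg.solve(A, b)
    shape = StenosisShape(D=D, coefficients=coeffs)
    _validate_profile(shape)
    return shape


def _validate_profile(shape: StenosisShape) -> None:
    xi = np.linspace(0.0, shape.D, 2001)
    y = shape._poly(xi)
    if y.min() <= 0.0:
        raise RejectedSampleError("profile reaches a non-positive gap")
    if y.max() > shape.D * (1.0 + 1e-10):
        raise RejectedSampleError("profile bulges beyond the healthy wall")


def sample_stenosis(
    rng,
    D: float = 1.0,
    h_range=(0.3, 0.7),
    x_star_range=(0.3, 0.7),
    max_tries: int = 1000,
) -> StenosisShape:
    """Draw one valid stenosis with depth and throat uniform over the ranges.

    ``h_range``/``x_star_range`` are in units of D.  Profiles whose quintic
    leaves (0, D] are rejected and redrawn.  ``rng`` is an integer seed or a
    numpy Generator; a fixed seed reproduces the shape bitwise.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    for _ in range(max_tries):
        h = D * rng.uniform(*h_range)
        x_star = D * rng.uniform(*x_star_range)
        try:
            return solve_stenosis_polynomial(D, h, x_star)
        except (RejectedSampleError, DegenerateParameterError):
            continue
    raise RejectedSampleError(
        f"rejection rate too high: no valid profile in {max_tries} draws "
        f"for h_range={h_range}, x_star_range={x_star_range}"
    )


def sample_asymmetric(
    rng,
    D: float = 1.0,
    h_range=(0.3, 0.7),
    x_star_range=(0.3, 0.7),
    sigma_range=(0.5, 1.5),
    amplitude_range=(0.6, 1.0),
) -> AsymmetricShape3D:
    """Draw one asymmetric 3D stenosis (axial quintic + angular Gaussian)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    axial = sample_stenosis(rng, D=D, h_range=h_range, x_star_range=x_star_range)
    return AsymmetricShape3D(
        axial_profile=axial,
        theta0=rng.uniform(0.0, 2.0 * np.pi),
        sigma=rng.uniform(*sigma_range),
        amplitude=rng.uniform(*amplitude_range),
    )


def evaluate_profile(shape: StenosisShape, x):
    """Wall gap y at absolute axial position(s) x; D outside the extent."""
    x = np.asarray(x, dtype=float)
    xi = x - shape.x_start
    inside = (xi >= 0.0) & (xi <= shape.D)
    y = np.where(inside, shape._poly(np.clip(xi, 0.0, shape.D)), shape.D)
    return y if y.ndim else float(y)


def radius_axisymmetric(shape: StenosisShape, x):
    """Local tube radius R(x) = y(x)/2 of the axisymmetric artery."""
    return evaluate_profile(shape, x) / 2.0


def radius_asymmetric(shape3d: AsymmetricShape3D, x, theta):
    """Local radius r(x, theta) of the asymmetric artery."""
    prof = shape3d.axial_profile
    y = evaluate_profile(prof, x)
    invasion = (prof.D - np.asarray(y)) / 2.0  # radial invasion depth at x
    r = prof.D / 2.0 - invasion * shape3d.weight(theta)
    return r if np.ndim(r) else float(r)


# ---------------------------------------------------------------------------
# rasterization

RASTER_2D = 214
RASTER_3D = 61


def rasterize_2d(shape: StenosisShape, resolution: int = RASTER_2D) -> ShapeImage:
    """Binary supercover raster of the wall curve over the stenosis extent.

    The frame covers [x_start, x_start + D] x [0, D]; a pixel is 1 iff the
    curve passes through it.  The wall is a polynomial graph, so the exact
    y-range over each column follows from endpoint values plus interior
    derivative roots; every row meeting that range is crossed (intermediate
    value theorem), which makes the supercover exact and scale-consistent.
    Axis order is (column i = x, row j = y), pixel centers at
    (index + 1/2) * spacing.
    """
    n = resolution
    dp = shape.D / n
    img = np.zeros((n, n), dtype=np.uint8)
    crit = shape._critical_points()
    edges = np.linspace(0.0, shape.D, n + 1)
    for i in range(n):
        lo, hi = edges[i], edges[i + 1]
        cand = [lo, hi] + [c for c in crit if lo < c < hi]
        yv = shape._poly(np.asarray(cand))
        j0 = int(np.clip(yv.min() / dp, 0, n - 1e-9))
        j1 = int(np.clip(yv.max() / dp, 0, n - 1e-9))
        img[i, j0 : j1 + 1] = 1
    return ShapeImage(values=img, pixel_spacing=dp, origin=np.array([shape.x_start + dp / 2, dp / 2]))


def rasterize_3d(shape3d: AsymmetricShape3D, resolution: int = RASTER_3D) -> ShapeImage:
    """Binary voxel shell of the (possibly asymmetric) tube wall.

    The 61^3 frame has voxel spacing 0.02 D; its 1.2 D box is centered on
    the tube axis and on the stenosis extent, so the healthy shell of
    radius D/2 and a 0.1 D margin on each axial side are imaged.
    """
    n = resolution
    D = shape3d.D
    dp = 1.2 * D / (n - 1)  # spacing x (n-1) spans the imaged box
    x0 = shape3d.axial_profile.x_start - 0.1 * D
    c = 0.6 * D  # axis offset inside the frame (y and z)
    vol = np.zeros((n, n, n), dtype=np.uint8)
    # sample the wall surface densely (step < 1/3 voxel) and mark voxels
    nx = int(np.ceil(1.2 * D / (dp / 3.0))) + 1
    nth = int(np.ceil(np.pi * D / (dp / 3.0))) + 1
    xs = x0 + np.linspace(0.0, 1.2 * D, nx)
    ths = np.linspace(0.0, 2.0 * np.pi, nth, endpoint=False)
    r = radius_asymmetric(shape3d, xs[:, None], ths[None, :])
    y = c + r * np.cos(ths)[None, :]
    z = c + r * np.sin(ths)[None, :]
    xg = ((xs - x0 + dp / 2) / dp).astype(int)  # voxel centers at origin + i*dp
    xg = np.clip(xg, 0, n - 1)
    yg = np.clip(((y + dp / 2) / dp).astype(int), 0, n - 1)
    zg = np.clip(((z + dp / 2) / dp).astype(int), 0, n - 1)
    vol[xg[:, None] * np.ones_like(zg, dtype=int), yg, zg] = 1
    return ShapeImage(
        values=vol,
        pixel_spacing=dp,
        origin=np.array([x0, -c, -c]),
    )


# ---------------------------------------------------------------------------
# surface sampling (CNN labels)


def sample_surface_points(shape, n: int):
    """Evenly distributed surface samples used as shape-decoder labels.

    2D: ``n`` wall gap values y at equispaced x over the stenosis extent
    (shape (n,)).  3D: ``n`` points stratified uniformly in (x, theta),
    reported as (radius, axial) pairs, shape (n, 2); n must factor as
    n_x * n_theta with n_theta = n_x (square stratification).
    """
    if n < 2:
        raise ValueError("need at least two surface samples")
    if isinstance(shape, StenosisShape):
        xs = shape.x_start + np.linspace(0.0, shape.D, n)
        return evaluate_profile(shape, xs)
    prof = shape.axial_profile
    n_x = int(round(np.sqrt(n)))
    if n_x * n_x != n:
        raise ValueError("3D surface sampling expects a square point count")
    xs = prof.x_start + np.linspace(0.0, prof.D, n_x)
    ths = np.linspace(0.0, 2.0 * np.pi, n_x, endpoint=False)
    r = radius_asymmetric(shape, xs[:, None], ths[None, :])
    x = np.broadcast_to(xs[:, None], r.shape)
    return np.stack([r.ravel(), x.ravel()], axis=1)


# ---------------------------------------------------------------------------
# IB wall markers


def _resample_polyline(pts: np.ndarray, ds: float, params: np.ndarray | None = None):
    """Arc-length-uniform resampling of a dense polyline at spacing ds.

    With ``params`` given, returns the resampled parameter values instead
    of interpolated points, so the caller can re-evaluate the exact curve.
    """
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    m = max(int(round(total / ds)), 1)
    si = np.linspace(0.0, total, m + 1)
    if params is not None:
        return np.interp(si, s, params), total / m
    out = np.empty((m + 1, pts.shape[1]))
    for k in range(pts.shape[1]):
        out[:, k] = np.interp(si, s, pts[:, k])
    return out, total / m


def markers_channel_2d(
    shape: StenosisShape,
    fluid_spacing: float,
    x_lo: float,
    x_hi: float,
    y_bottom: float,
    width: float | None = None,
    normal_offset: float = 0.0,
) -> MarkerSet:
    """Markers for a 2D channel with the stenosis bump on the bottom wall.

    The lumen occupies y in [y_bottom + (D - y(x)), y_bottom + D] (one-wall
    stenosis; the top wall stays flat).  Marker spacing is half the fluid
    mesh spacing, arc-length uniform along each wall.  ``normal_offset``
    displaces the marker surface outward along the local wall normal (the
    diffuse-interface calibration; see the flow pipeline).
    """
    D = width if width is not None else shape.D
    ds = fluid_spacing / 2.0
    xs = np.linspace(x_lo, x_hi, int(np.ceil((x_hi - x_lo) / (ds / 8.0))) + 1)

    def bottom_points(xb):
        yw = y_bottom + (D - evaluate_profile(shape, xb))
        if normal_offset == 0.0:
            return np.stack([xb, yw], axis=1)
        der = np.polyder(shape.coefficients)
        inside = (xb >= shape.x_start) & (xb <= shape.x_end)
        slope = np.where(inside, -np.polyval(der, np.clip(xb - shape.x_start, 0, shape.D)), 0.0)
        norm = np.sqrt(1.0 + slope**2)
        return np.stack([xb + normal_offset * slope / norm, yw - normal_offset / norm], axis=1)

    xb, dsb = _resample_polyline(bottom_points(xs), ds, params=xs)
    pb = bottom_points(xb)
    y_top = y_bottom + D + normal_offset
    m_top = max(int(round((x_hi - x_lo) / ds)), 1)
    pt = np.stack(
        [np.linspace(x_lo, x_hi, m_top + 1), np.full(m_top + 1, y_top)], axis=1
    )
    dst = (x_hi - x_lo) / m_top
    positions = np.concatenate([pb, pt], axis=0)
    weights = np.concatenate([np.full(len(pb), dsb), np.full(len(pt), dst)])
    return MarkerSet(positions=positions, weights=weights, spacing=ds)


def markers_tube_3d(
    shape,
    fluid_spacing: float,
    x_lo: float,
    x_hi: float,
    center_y: float,
    center_z: float,
    normal_offset: float = 0.0,
) -> MarkerSet:
    """Rings of markers on the (possibly asymmetric) tube wall.

    Rings are placed every ``fluid_spacing/2`` axially; each ring carries
    round(2 pi r / ds) markers so the surface density is uniform.
    """
    if isinstance(shape, StenosisShape):
        shape = AsymmetricShape3D(axial_profile=shape, amplitude=1.0, sigma=50.0)
    ds = fluid_spacing / 2.0
    nring = max(int(round((x_hi - x_lo) / ds)), 1)
    xs = np.linspace(x_lo, x_hi, nring + 1)
    dx_ring = (x_hi - x_lo) / nring
    pos, wts = [], []
    for x in xs:
        rmax = radius_asymmetric(shape, x, 0.0) + normal_offset
        nth = max(int(round(2.0 * np.pi * max(rmax, ds) / ds)), 6)
        th = np.linspace(0.0, 2.0 * np.pi, nth, endpoint=False)
        r = radius_asymmetric(shape, x, th) + normal_offset
        ring = np.stack(
            [np.full(nth, x), center_y + r * np.cos(th), center_z + r * np.sin(th)], axis=1
        )
        pos.append(ring)
        wts.append(np.full(nth, (2.0 * np.pi * np.mean(r) / nth) * dx_ring))
    return MarkerSet(positions=np.concatenate(pos), weights=np.concatenate(wts), spacing=ds)
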