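"""Time-parameterised simulation domains.

All domains share one interface (:class:`MovingDomain`): a strict membership
test, a closest-boundary-point projection, the outward normal, and the
boundary velocity, each defined for every time in the domain's validity
interval.  The three concrete geometries are

* :class:`ShrinkingCircle` -- a disc in the plane whose radius changes
  linearly in time (the benchmark geometry),
* :class:`Dumbbell` -- two spheres joined by a cylindrical bridge that
  elongates on a piecewise-linear schedule (dividing-cell caricature),
* :class:`DividingNucleus` -- two truncated prolate ellipsoids joined by a
  cylindrical bridge, driven by a time-stamped parameter table and recentred
  so the volume centroid sits at the origin (budding-yeast nucleus in
  anaphase, closed mitosis).

The dumbbell and nucleus are rotationally symmetric about the x-axis, so all
boundary queries reduce to a projection onto a 2-D profile curve in the
(x, rho) half-plane, rho = sqrt(y^2 + z^2) >= 0.  The profile is a union of
primitives (circular arc, ellipse arc, horizontal segment); the closest
point is the global minimum over per-primitive projections.
"""
from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MovingDomain",
    "ShrinkingCircle",
    "static_circle",
    "Dumbbell",
    "DividingNucleus",
    "StaticDomain",
    "read_frames",
    "write_frames",
    "synthetic_division_frames",
    "load_synthetic_frames",
]

#: Columns of a dividing-nucleus frame table (lengths in the table's units,
#: times in seconds).
FRAME_COLUMNS = ["time_s", "r_xm", "r_ym", "r_xd", "r_yd", "l", "w"]


def _as_points(x, dim):
    """Coerce ``x`` to an (n, dim) float array; remember if it was a single point."""
    a = np.asarray(x, dtype=float)
    single = a.ndim == 1
    a = np.atleast_2d(a)
    if a.shape[-1] != dim:
        raise ValueError(f"expected positions with {dim} coordinates, got shape {a.shape}")
    return a, single


# ---------------------------------------------------------------------------
# Profile primitives (axisymmetric geometries)
# ---------------------------------------------------------------------------

class _Seg:
    """Horizontal segment rho = c for x in [x0, x1]; outward normal (0, +1)."""

    def __init__(self, c, x0, x1):
        self.c, self.x0, self.x1 = float(c), float(x0), float(x1)

    def project(self, px, prho):
        bx = np.clip(px, self.x0, self.x1)
        brho = np.full_like(px, self.c)
        d2 = (px - bx) ** 2 + (prho - brho) ** 2
        nx = np.zeros_like(px)
        nrho = np.ones_like(px)
        return bx, brho, d2, nx, nrho


class _CircArc:
    """Arc of a circle of radius r centred at (cx, 0), polar angle in [lo, hi] subset [0, pi]."""

    def __init__(self, cx, r, lo, hi):
        self.cx, self.r, self.lo, self.hi = float(cx), float(r), float(lo), float(hi)

    def project(self, px, prho):
        # Radial projection is exact; clamping handles the truncation because
        # the distance to a circle point is unimodal in the angle difference.
        th = np.clip(np.arctan2(prho, px - self.cx), self.lo, self.hi)
        nx, nrho = np.cos(th), np.sin(th)
        bx = self.cx + self.r * nx
        brho = self.r * nrho
        d2 = (px - bx) ** 2 + (prho - brho) ** 2
        return bx, brho, d2, nx, nrho


class _EllArc:
    """Arc of the ellipse ((x-cx)/a)^2 + (rho/b)^2 = 1, angle in [lo, hi] subset [0, pi].

    Projection is found per point by a coarse angular scan followed by
    safeguarded Newton refinement of the stationarity condition; endpoints
    are always candidates.  Accuracy is limited only by Newton convergence
    (machine precision away from the evolute).
    """

    _K = 33  # coarse-scan resolution

    def __init__(self, cx, a, b, lo, hi):
        self.cx, self.a, self.b = float(cx), float(a), float(b)
        self.lo, self.hi = float(lo), float(hi)
        self._grid = np.linspace(self.lo, self.hi, self._K)
        self._gx = self.cx + self.a * np.cos(self._grid)[:, None]
        self._gr = self.b * np.sin(self._grid)[:, None]

    def _f(self, th, px, prho):
        dx = self.cx + self.a * np.cos(th) - px
        dr = self.b * np.sin(th) - prho
        return dx * dx + dr * dr

    def project(self, px, prho):
        a, b, cx = self.a, self.b, self.cx
        fg = (self._gx - px[None, :]) ** 2 + (self._gr - prho[None, :]) ** 2
        th = self._grid[np.argmin(fg, axis=0)]
        for _ in range(12):
            s, c = np.sin(th), np.cos(th)
            dx = cx + a * c - px
            dr = b * s - prho
            g = -a * s * dx + b * c * dr          # d/dth of f/2
            gp = -a * c * dx + a * a * s * s - b * s * dr + b * b * c * c
            step = np.where(gp > 1e-14, g / np.maximum(gp, 1e-14), 0.0)
            th = np.minimum(np.maximum(th - step, self.lo), self.hi)
        # best of refined angle and the two endpoints
        cand = np.stack([th, np.full_like(th, self.lo), np.full_like(th, self.hi)])
        fc = self._f(cand, px[None, :], prho[None, :])
        th = cand[np.argmin(fc, axis=0), np.arange(th.size)]
        s, c = np.sin(th), np.cos(th)
        bx = cx + a * c
        brho = b * s
        d2 = (px - bx) ** 2 + (prho - brho) ** 2
        # outward normal from the implicit-form gradient
        nx = c / a
        nrho = s / b
        nn = np.hypot(nx, nrho)
        return bx, brho, d2, nx / nn, nrho / nn


def _project_profile(primitives, px, prho):
    """Global closest point over a list of profile primitives."""
    best = None
    for prim in primitives:
        bx, brho, d2, nx, nrho = prim.project(px, prho)
        if best is None:
            best = [bx, brho, d2, nx, nrho]
        else:
            m = d2 < best[2]
            for i, v in enumerate((bx, brho, d2, nx, nrho)):
                best[i] = np.where(m, v, best[i])
    return best


# ---------------------------------------------------------------------------
# Base class
# ---------------------------------------------------------------------------

class MovingDomain(ABC):
    """A closed time-dependent region Omega_t with boundary Gamma_t."""

    dim: int
    t_span: tuple  # validity interval (seconds)

    def _check_time(self, t):
        t = float(t)
        lo, hi = self.t_span
        eps = 1e-9 * max(1.0, abs(hi) if np.isfinite(hi) else 1.0)
        if not (lo - eps <= t <= hi + eps):
            raise ValueError(f"time {t} outside validity interval {self.t_span}")
        return min(max(t, lo), hi) if np.isfinite(hi) else max(t, lo)

    @abstractmethod
    def contains(self, x, t):
        """True iff each position is strictly inside Omega_t."""

    @abstractmethod
    def project_boundary(self, x, t):
        """Closest point on Gamma_t and outward unit normal there.

        Returns ``(points, normals)`` with the same leading shape as ``x``.
        """

    def closest_boundary_point(self, x, t):
        return self.project_boundary(x, t)[0]

    def boundary_distance(self, x, t):
        """Unsigned Euclidean distance to Gamma_t."""
        a, single = _as_points(x, self.dim)
        p, _ = self.project_boundary(a, t)
        d = np.linalg.norm(a - p, axis=-1)
        return float(d[0]) if single else d

    def boundary_velocity(self, x, t, dt=1e-3):
        """Velocity of the boundary at points ``x`` on Gamma_t.

        Default: the nearest-point map, ``(closest point on Gamma_{t+dt} - x)/dt``,
        which carries each membrane point to its nearest point at the
        subsequent time.  Subclasses override where an analytic form exists.
        """
        t = self._check_time(t)
        a, single = _as_points(x, self.dim)
        if t + dt <= self.t_span[1]:
            p, _ = self.project_boundary(a, t + dt)
            v = (p - a) / dt
        else:  # backward difference at the end of the validity interval
            p, _ = self.project_boundary(a, t - dt)
            v = (a - p) / dt
        return v[0] if single else v

    def boundary_kinematics(self, x, t, dt=1e-3, tol=1e-6):
        """Outward unit normal and boundary velocity at points on Gamma_t.

        Raises ``ValueError`` if a point is further than ``tol`` from Gamma_t.
        """
        a, single = _as_points(x, self.dim)
        p, n = self.project_boundary(a, t)
        d = np.linalg.norm(a - p, axis=-1)
        if np.any(d > tol):
            raise ValueError(f"point not on the boundary (distance {d.max():.3g} > tol {tol:g})")
        v = np.atleast_2d(self.boundary_velocity(a, t, dt=dt))
        if single:
            return n[0], v[0]
        return n, v


# ---------------------------------------------------------------------------
# Shrinking circle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShrinkingCircle(MovingDomain):
    """Disc in the plane whose radius moves linearly from r_s to r_e over [0, t_e].

    The radius is clamped at ``r_e`` after ``t_e``; the boundary speed during
    the shrink (or growth) is ``(r_e - r_s)/t_e``.
    """

    r_s: float
    r_e: float
    t_e: float

    dim = 2

    def __post_init__(self):
        if self.r_s <= 0 or self.r_e <= 0 or self.t_e <= 0:
            raise ValueError("radii and end time must be positive")

    @property
    def t_span(self):
        return (0.0, np.inf)

    def radius_at(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative time")
        frac = np.minimum(t, self.t_e) / self.t_e
        r = self.r_s + (self.r_e - self.r_s) * frac
        return float(r) if r.ndim == 0 else r

    def radius_rate(self, t):
        """dr/dt: constant during the shrink, zero afterwards."""
        t = np.asarray(t, dtype=float)
        rate = np.where(t < self.t_e, (self.r_e - self.r_s) / self.t_e, 0.0)
        return float(rate) if rate.ndim == 0 else rate

    def contains(self, x, t):
        a, single = _as_points(x, 2)
        r = self.radius_at(t)
        inside = np.einsum("ij,ij->i", a, a) < r * r
        return bool(inside[0]) if single else inside

    def _unit(self, a):
        nrm = np.linalg.norm(a, axis=-1, keepdims=True)
        u = np.divide(a, nrm, out=np.zeros_like(a), where=nrm > 0)
        # non-unique projection at the exact centre: deterministic tie-break
        # (smallest x, then smallest y)
        deg = (nrm[..., 0] == 0)
        u[deg, 0] = -1.0
        return u

    def project_boundary(self, x, t):
        a, single = _as_points(x, 2)
        r = self.radius_at(t)
        u = self._unit(a)
        p = r * u
        return (p[0], u[0]) if single else (p, u)

    def boundary_velocity(self, x, t, dt=None):
        a, single = _as_points(x, 2)
        v = self.radius_rate(t) * self._unit(a)
        return v[0] if single else v


def static_circle(r):
    """A circle of fixed radius ``r`` (zero boundary velocity)."""
    return ShrinkingCircle(r_s=r, r_e=r, t_e=1.0)


# ---------------------------------------------------------------------------
# Elongating dumbbell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dumbbell(MovingDomain):
    """Two spheres of radius R joined by an open cylinder of radius d.

    The bridge spans x in (-l(t)/2, l(t)/2); the bridge length follows the
    piecewise-linear schedule ``l(t) = 0`` for ``t < T1``, ``L (t - T1)`` for
    ``T1 <= t < T2`` and ``L (T2 - T1)`` thereafter.  The sphere centres sit
    at ``+-(l/2 + R - o)`` with the offset ``o = R - sqrt(R^2 - d^2)`` chosen
    so that the sphere cross-section at the bridge aperture has radius
    exactly ``d`` -- sphere and cylinder meet without gaps.  The domain is
    rotationally symmetric about the x-axis and mirror-symmetric in x.
    """

    R: float
    d: float
    L: float
    T1: float
    T2: float

    dim = 3

    def __post_init__(self):
        if not (0 < self.d < self.R):
            raise ValueError("need 0 < d < R")
        if not (0 <= self.T1 <= self.T2):
            raise ValueError("need 0 <= T1 <= T2")
        if self.L < 0:
            raise ValueError("growth rate must be non-negative")

    @property
    def t_span(self):
        return (0.0, np.inf)

    @property
    def offset(self):
        """Sphere-centre pull-in o = R - sqrt(R^2 - d^2)."""
        return self.R - np.sqrt(self.R ** 2 - self.d ** 2)

    def bridge_length(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative time")
        l = np.where(t < self.T1, 0.0,
                     np.where(t < self.T2, self.L * (t - self.T1),
                              self.L * (self.T2 - self.T1)))
        return float(l) if l.ndim == 0 else l

    def centre_x(self, t):
        """x-coordinate of the right sphere centre (left is mirrored)."""
        return self.bridge_length(t) / 2.0 + self.R - self.offset

    def contains(self, x, t):
        a, single = _as_points(x, 3)
        l = self.bridge_length(t)
        c = self.centre_x(t)
        rho2 = a[:, 1] ** 2 + a[:, 2] ** 2
        in_cyl = (np.abs(a[:, 0]) < l / 2) & (rho2 < self.d ** 2)
        in_l = (a[:, 0] + c) ** 2 + rho2 < self.R ** 2
        in_r = (a[:, 0] - c) ** 2 + rho2 < self.R ** 2
        inside = in_cyl | in_l | in_r
        return bool(inside[0]) if single else inside

    def _profile(self, t):
        l = self.bridge_length(t)
        c = self.centre_x(t)
        th_ap = np.arcsin(self.d / self.R)  # aperture angle on the sphere
        prims = [
            _CircArc(-c, self.R, th_ap, np.pi),
            _CircArc(c, self.R, 0.0, np.pi - th_ap),
        ]
        if l > 0:
            prims.append(_Seg(self.d, -l / 2, l / 2))
        return prims

    def project_boundary(self, x, t):
        a, single = _as_points(x, 3)
        p, n = _project_axisym(self._profile(t), a)
        return (p[0], n[0]) if single else (p, n)


def _project_axisym(primitives, a):
    """Project 3-D points onto an axisymmetric boundary given its profile."""
    px = a[:, 0]
    prho = np.hypot(a[:, 1], a[:, 2])
    bx, brho, _, nx, nrho = _project_profile(primitives, px, prho)
    # azimuthal direction; on-axis points break the tie toward smallest y
    uy = np.divide(a[:, 1], prho, out=np.full_like(prho, -1.0), where=prho > 0)
    uz = np.divide(a[:, 2], prho, out=np.zeros_like(prho), where=prho > 0)
    p = np.stack([bx, brho * uy, brho * uz], axis=-1)
    n = np.stack([nx, nrho * uy, nrho * uz], axis=-1)
    return p, n


# ---------------------------------------------------------------------------
# Dividing nucleus
# ---------------------------------------------------------------------------

class DividingNucleus(MovingDomain):
    """Mother and daughter nuclear lobes (truncated prolate ellipsoids) joined
    by a cylindrical bridge, with parameters interpolated linearly between
    time-stamped frames and the whole shape recentred so the volume centroid
    lies at the origin at every time.

    Construction frame (primed coordinates): the mother lobe starts at
    ``x' = 0``; its ellipsoid is centred at ``x' = r_xm`` with semi-axes
    ``(r_xm, r_ym)`` and is truncated on the right at
    ``x'_cut = r_xm (1 + cos(asin(w / r_ym)))`` where its cross-section
    radius equals the bridge radius ``w``; the bridge spans
    ``[x'_cut, x'_cut + l)``; the daughter ellipsoid (semi-axes
    ``(r_xd, r_yd)``) is truncated on its bridge side the same way.  The
    recentring offset subtracts the centroid, computed in closed form from
    the piecewise-quadratic cross-section profile.
    """

    dim = 3

    def __init__(self, frames: pd.DataFrame):
        frames = frames.reset_index(drop=True)
        missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
        if missing:
            raise ValueError(f"frame table missing columns {missing}")
        t = frames["time_s"].to_numpy(dtype=float)
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing with >= 2 frames")
        vals = frames[FRAME_COLUMNS[1:]].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError("geometry parameters must be positive")
        if np.any(frames["w"].to_numpy() >= frames[["r_ym", "r_yd"]].to_numpy().min(axis=1)):
            raise ValueError("bridge radius w must be smaller than both minor radii")
        self.frames = frames[FRAME_COLUMNS].copy()
        self._t = t
        self._vals = vals
        self._cache = {}  # per-time layout/offset/profile (steppers revisit times)

    @property
    def t_span(self):
        return (float(self._t[0]), float(self._t[-1]))

    def params_at(self, t):
        """(r_xm, r_ym, r_xd, r_yd, l, w) linearly interpolated between frames."""
        t = self._check_time(t)
        return tuple(np.interp(t, self._t, self._vals[:, j]) for j in range(6))

    # -- construction-frame layout ------------------------------------------
    def _layout(self, t):
        key = ("layout", float(t))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        rxm, rym, rxd, ryd, l, w = self.params_at(t)
        cm = np.cos(np.arcsin(w / rym))          # mother truncation angle
        cd = np.cos(np.arcsin(w / ryd))          # daughter truncation angle
        x_cut = rxm * (1.0 + cm)                 # mother/bridge junction
        c_d = x_cut + l + rxd * cd               # daughter ellipsoid centre
        out = (rxm, rym, rxd, ryd, l, w, cm, cd, x_cut, c_d)
        if len(self._cache) > 64:
            self._cache.clear()
        self._cache[key] = out
        return out

    @staticmethod
    def _ell_moments(cx, a, b, xi0, xi1):
        """(volume, x-moment)/pi of an ellipsoid-of-revolution slab xi in [xi0, xi1]."""
        def F(xi):   # integral of (1 - xi^2)
            return xi - xi ** 3 / 3.0
        def G(xi):   # integral of xi (1 - xi^2)
            return xi ** 2 / 2.0 - xi ** 4 / 4.0
        vol = a * b * b * (F(xi1) - F(xi0))
        mx = a * b * b * (cx * (F(xi1) - F(xi0)) + a * (G(xi1) - G(xi0)))
        return vol, mx

    def centroid_offset(self, t):
        """x'-coordinate of the volume centroid in the construction frame."""
        rxm, rym, rxd, ryd, l, w, cm, cd, x_cut, c_d = self._layout(t)
        vm, mm = self._ell_moments(rxm, rxm, rym, -1.0, cm)
        vb = w * w * l
        mb = vb * (x_cut + l / 2.0)
        vd, md = self._ell_moments(c_d, rxd, ryd, -cd, 1.0)
        return (mm + mb + md) / (vm + vb + vd)

    def bridge_midplane(self, t):
        """x-coordinate (recentred frame) of the mother/daughter dividing plane."""
        _, _, _, _, l, _, _, _, x_cut, _ = self._layout(t)
        return x_cut + l / 2.0 - self.centroid_offset(t)

    def bleach_centre(self, t):
        """Recentred position of the bleach-spot centre (r_xm, r_ym, 0).

        The spot is glued to the membrane above the mother-lobe centre: it is
        defined in the construction frame and co-moves with the recentring
        translation.
        """
        rxm, rym, *_ = self.params_at(t)
        return np.array([rxm - self.centroid_offset(t), rym, 0.0])

    def region_of(self, x, t):
        """0 = mother, 1 = bridge, 2 = daughter, -1 = outside Omega_t."""
        a, single = _as_points(x, 3)
        rxm, rym, rxd, ryd, l, w, cm, cd, x_cut, c_d = self._layout(t)
        xp = a[:, 0] + self.centroid_offset(t)
        rho2 = a[:, 1] ** 2 + a[:, 2] ** 2
        mother = (xp < x_cut) & (((xp - rxm) / rxm) ** 2 + rho2 / rym ** 2 < 1.0)
        bridge = (xp >= x_cut) & (xp < x_cut + l) & (rho2 < w * w)
        daughter = (xp >= x_cut + l) & (((xp - c_d) / rxd) ** 2 + rho2 / ryd ** 2 < 1.0)
        out = np.full(len(a), -1, dtype=int)
        out[mother] = 0
        out[bridge] = 1
        out[daughter] = 2
        return int(out[0]) if single else out

    def contains(self, x, t):
        r = self.region_of(x, t)
        return r >= 0

    def _profile(self, t):
        key = ("profile", float(t))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        rxm, rym, rxd, ryd, l, w, cm, cd, x_cut, c_d = self._layout(t)
        off = self.centroid_offset(t)
        th_m = np.arccos(cm)
        th_d = np.arccos(cd)
        prims = [
            _EllArc(rxm - off, rxm, rym, th_m, np.pi),
            _EllArc(c_d - off, rxd, ryd, 0.0, np.pi - th_d),
        ]
        if l > 0:
            prims.append(_Seg(w, x_cut - off, x_cut + l - off))
        self._cache[key] = prims
        return prims

    def project_boundary(self, x, t):
        a, single = _as_points(x, 3)
        p, n = _project_axisym(self._profile(t), a)
        return (p[0], n[0]) if single else (p, n)

    def nucleus_at(self, t):
        """Instantaneous geometry snapshot: region tests plus recentring offset."""
        t = self._check_time(t)
        off = self.centroid_offset(t)
        return _NucleusSnapshot(self, t, off)


@dataclass(frozen=True)
class _NucleusSnapshot:
    domain: DividingNucleus
    t: float
    offset: float

    def region_of(self, x):
        return self.domain.region_of(x, self.t)

    def contains(self, x):
        return self.domain.contains(x, self.t)


# ---------------------------------------------------------------------------
# Static wrapper
# ---------------------------------------------------------------------------

class StaticDomain(MovingDomain):
    """Freeze a moving domain at one instant; the boundary velocity is zero."""

    def __init__(self, inner: MovingDomain, t_freeze: float):
        self.inner = inner
        self.t_freeze = inner._check_time(t_freeze)
        self.dim = inner.dim

    @property
    def t_span(self):
        return (0.0, np.inf)

    def contains(self, x, t=0.0):
        return self.inner.contains(x, self.t_freeze)

    def project_boundary(self, x, t=0.0):
        return self.inner.project_boundary(x, self.t_freeze)

    def boundary_velocity(self, x, t=0.0, dt=None):
        a, single = _as_points(x, self.dim)
        v = np.zeros_like(a)
        return v[0] if single else v

    def __getattr__(self, name):
        # delegate geometry-specific helpers (region_of, bleach_centre, ...)
        attr = getattr(self.inner, name)
        if callable(attr):
            def frozen(*args, **kwargs):
                # replace any time argument with the freeze time
                if "t" in kwargs:
                    kwargs["t"] = self.t_freeze
                    return attr(*args, **kwargs)
                return attr(*args[:-1], self.t_freeze) if args else attr(self.t_freeze)
            return frozen
        return attr


# ---------------------------------------------------------------------------
# Frame-table I/O and the synthetic division trajectory
# ---------------------------------------------------------------------------

def read_frames(path) -> pd.DataFrame:
    """Read a dividing-nucleus parameter table (tab-delimited, header row)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"frame table {path} missing columns {missing}")
    return df[FRAME_COLUMNS]


def write_frames(df: pd.DataFrame, path):
    df[FRAME_COLUMNS].to_csv(path, sep="\t", index=False)


def synthetic_division_frames(n_frames=5, spacing_s=50.0):
    """Synthetic anaphase geometry trajectory (micrometres).

    The published experiment measured lobe and bridge dimensions from
    confocal frames 50 s apart; those measurements are unpublished, so this
    package ships a synthetic stand-in with the same structure: the bridge
    elongates, the daughter lobe grows, and the mother lobe shrinks
    slightly.  Dimensions are typical of a budding-yeast nucleus (~2 um
    mother diameter).
    """
    u = np.linspace(0.0, 1.0, n_frames)
    return pd.DataFrame({
        "time_s": u * spacing_s * (n_frames - 1),
        "r_xm": 1.30 - 0.15 * u,
        "r_ym": 1.00 - 0.12 * u,
        "r_xd": 0.55 + 0.45 * u,
        "r_yd": 0.48 + 0.32 * u,
        "l": 0.50 + 2.30 * u,
        "w": 0.30 - 0.06 * u,
    })


def load_synthetic_frames() -> pd.DataFrame:
    """Load the packaged synthetic frame table (see ``synthetic_division_frames``)."""
    from importlib.resources import files
    path = files("mobosim").joinpath("data/synthetic_nucleus_frames.tsv")
    with path.open("r") as fh:
        return read_frames(fh)
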