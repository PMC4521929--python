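"""Deterministic reference solutions for the shrinking-circle benchmarks.

Two solvers and two families of closed forms:

* :func:`solve_surface_pde` -- diffusion on the shrinking circle mapped to
  arc-angle coordinates, where the moving-boundary problem becomes a
  diffusion equation with the time-varying coefficient ``D / r_t^2`` on a
  fixed periodic grid, integrated with the explicit scheme
  ``P_i^{t+dt} = (1 - 2 a) P_i^t + a (P_{i-1}^t + P_{i+1}^t)``,
  ``a = dt D / (r_t^2 h^2)``, with circular index wrap.

* :func:`solve_volume_pde_radial` -- radial diffusion inside the shrinking
  disc.  On the rescaled coordinate ``u = r / s(t)`` (``s = r_t - rho`` is
  the effective boundary for particles of radius ``rho``) the moving
  boundary becomes fixed and the per-``u`` mass density ``m(u, t)`` obeys a
  conservation law ``dm/dt = dF/du`` with flux
  ``F = 2 pi D u dQ/du + 2 pi s s' u^2 Q`` (``Q`` the probability density).
  The flux-balance boundary condition ``D dP/dn = -(v.n) P`` -- the form
  probability conservation dictates -- makes ``F`` vanish identically at
  ``u = 1``, so the conservative finite-volume update preserves total
  probability to round-off.

* :func:`uniform_cdf` / :func:`slow_diffusion_cdf` -- the fast- and
  slow-diffusion analytic limits of the radial CDF.

* :func:`msd_volume_theory` / :func:`msd_surface_limits` -- closed-form MSD
  decompositions in the slow-diffusion regime, and the fast/zero-diffusion
  limits on the circle.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .geometry import ShrinkingCircle

__all__ = [
    "solve_surface_pde",
    "solve_volume_pde_radial",
    "uniform_cdf",
    "slow_diffusion_cdf",
    "msd_volume_theory",
    "msd_surface_limits",
    "surface_stability_dt",
]


# ---------------------------------------------------------------------------
# Surface (angular) solver
# ---------------------------------------------------------------------------

def surface_stability_dt(D, circle: ShrinkingCircle, N, t_end):
    """Largest stable explicit time step: h^2 min_t(r_t^2) / (2 D)."""
    h = 2.0 * np.pi / (N - 1)
    r_min = min(circle.radius_at(0.0), circle.radius_at(min(t_end, circle.t_e)))
    return h * h * r_min * r_min / (2.0 * D)


def solve_surface_pde(D, circle: ShrinkingCircle, t_out, N=401, dt=None,
                      initial="point"):
    """Angular densities and CDFs on the shrinking circle at times ``t_out``.

    ``N`` grid nodes span [-pi, pi] with spacing ``h = 2 pi / (N - 1)`` and
    circular wrap (the first and last node are the same physical point; the
    angle is measured from the positive y-axis, positive toward positive x).
    ``initial`` is ``"point"`` (all mass at angle 0, the top of the circle),
    ``"uniform"``, or an array of node densities.  Returns
    ``(theta, densities, cdfs)`` with one row per output time.
    """
    t_out = np.atleast_1d(np.asarray(t_out, dtype=float))
    h = 2.0 * np.pi / (N - 1)
    theta = -np.pi + h * np.arange(N)
    bound = surface_stability_dt(D, circle, N, t_out.max())
    if dt is None:
        dt = 0.5 * bound
    elif dt > bound:
        raise ValueError(f"dt = {dt} violates the stability bound {bound:.3g}")

    if isinstance(initial, str) and initial == "point":
        P = np.zeros(N)
        P[(N - 1) // 2] = 1.0 / h
    elif isinstance(initial, str) and initial == "uniform":
        P = np.full(N, 1.0 / (2.0 * np.pi))
    else:
        P = np.asarray(initial, dtype=float).copy()
        if P.shape != (N,):
            raise ValueError("initial density must have one value per node")

    # The first and last node are the same physical point of the circle; the
    # state advances on the N-1 distinct nodes with circular wrap, and the
    # duplicated endpoint is restored as a ghost for output and integration.
    Q = P[:-1].copy()
    dens, cdfs = [], []
    t = 0.0
    for target in np.sort(t_out):
        while t < target - 1e-12:
            step = min(dt, target - t)
            r = circle.radius_at(t)
            a = step * D / (r * r * h * h)
            Q = (1.0 - 2.0 * a) * Q + a * (np.roll(Q, 1) + np.roll(Q, -1))
            t += step
        P = np.concatenate([Q, Q[:1]])
        dens.append(P)
        cdfs.append(cumulative_trapezoid(P, theta, initial=0.0))
    order = np.argsort(np.argsort(t_out))
    dens = np.asarray(dens)[order]
    cdfs = np.asarray(cdfs)[order]
    return theta, dens, cdfs


# ---------------------------------------------------------------------------
# Radial (volume) solver
# ---------------------------------------------------------------------------

def solve_volume_pde_radial(D, circle: ShrinkingCircle, t_out, rho=0.0,
                            n_cells=200, dt=None, initial="uniform",
                            mass_tol=1e-6):
    """Radial CDFs of a particle diffusing inside the shrinking disc.

    Returns ``(u_centres, cdf_fn)`` where ``cdf_fn(i, radii)`` evaluates the
    CDF ``P(R < r)`` of the i-th output time at physical radii, plus the
    list of output times -- packaged as a :class:`RadialSolution`.
    """
    t_out = np.atleast_1d(np.asarray(t_out, dtype=float))
    s = lambda t: circle.radius_at(t) - rho
    sdot = lambda t: circle.radius_rate(t)
    if s(0.0) <= 0 or s(float(t_out.max())) <= 0:
        raise ValueError("effective radius r_t - rho must stay positive")

    du = 1.0 / n_cells
    u_f = du * np.arange(n_cells + 1)          # faces
    u_c = 0.5 * (u_f[:-1] + u_f[1:])           # centres
    s_min = min(s(0.0), s(min(float(t_out.max()), circle.t_e)))
    bound = du * du * s_min * s_min / (2.0 * D) if D > 0 else np.inf
    adv = abs(sdot(0.0)) / s_min
    if adv > 0:
        bound = min(bound, du / adv)
    if dt is None:
        dt = 0.4 * bound
    elif dt > bound:
        raise ValueError(f"dt = {dt} violates the stability bound {bound:.3g}")

    if isinstance(initial, str) and initial == "uniform":
        Q = np.full(n_cells, 1.0 / (np.pi * s(0.0) ** 2))
    else:
        Q = np.asarray(initial, dtype=float).copy()
    m = 2.0 * np.pi * u_c * s(0.0) ** 2 * Q * du
    m /= m.sum()

    out = []
    t = 0.0
    for target in np.sort(t_out):
        while t < target - 1e-12:
            step = min(dt, target - t)
            st, sd = s(t), sdot(t)
            Q = m / (2.0 * np.pi * u_c * st * st * du)
            Qf = 0.5 * (Q[:-1] + Q[1:])                    # interior faces
            dQ = (Q[1:] - Q[:-1]) / du
            F = np.zeros(n_cells + 1)
            F[1:-1] = 2.0 * np.pi * (D * u_f[1:-1] * dQ
                                     + st * sd * u_f[1:-1] ** 2 * Qf)
            # F[0] = F[-1] = 0: axis regularity and the conservative
            # flux-balance boundary condition
            m = m + step * (F[1:] - F[:-1])
            t += step
        out.append((t, m.copy()))
    drift = abs(sum(mi.sum() for _, mi in out) / len(out) - 1.0)
    if drift > mass_tol:
        raise RuntimeError(f"probability drift {drift:.2e} exceeds {mass_tol}")
    order = np.argsort(np.argsort(t_out))
    out = [out[i] for i in order]
    return RadialSolution(u_f=u_f, masses=[mi for _, mi in out],
                          times=[ti for ti, _ in out], s=s)


class RadialSolution:
    """Finite-volume radial solution: per-cell masses at each output time."""

    def __init__(self, u_f, masses, times, s):
        self.u_f, self.masses, self.times, self._s = u_f, masses, times, s

    def cdf(self, i, radii):
        """P(R < r) at output time ``i`` evaluated at physical radii."""
        st = self._s(self.times[i])
        cum = np.concatenate([[0.0], np.cumsum(self.masses[i])])
        return np.interp(np.asarray(radii, dtype=float) / st, self.u_f, cum)

    def total_mass(self, i):
        return float(self.masses[i].sum())


# ---------------------------------------------------------------------------
# Analytic limits
# ---------------------------------------------------------------------------

def uniform_cdf(radii, r_t, rho=0.0):
    """Fast-diffusion limit: P(R < r) = R^2 / (r_t - rho)^2 on the disc."""
    s = r_t - rho
    return np.clip(np.asarray(radii, dtype=float) ** 2 / s ** 2, 0.0, 1.0)


def slow_diffusion_cdf(radii, circle: ShrinkingCircle, t, rho=0.0):
    """Slow-diffusion limit: uniform over the initial disc, rising to one at
    the swept boundary: P(R < r) = R^d/(r_s - rho)^d for R < r_t - rho, 1 there."""
    r = np.asarray(radii, dtype=float)
    s_t = circle.radius_at(t) - rho
    cdf = r ** 2 / (circle.r_s - rho) ** 2
    return np.where(r >= s_t, 1.0, np.clip(cdf, 0.0, 1.0))


def msd_volume_theory(D, circle: ShrinkingCircle, t):
    """Slow-diffusion MSD decomposition inside the shrinking circle.

    First term: the fraction of particles still diffusing freely
    (``r_t^2 / r_s^2``) times the free-space MSD ``4 D t``; second term: the
    particles swept from their initial positions by the boundary,
    ``(2 / r_s^2) [ (r_s^4 - r_t^4)/4 - (2/3) r_t (r_s^3 - r_t^3)
    + (r_t^2 / 2)(r_s^2 - r_t^2) ]``.
    """
    t = np.asarray(t, dtype=float)
    rs = circle.r_s
    rt = np.asarray(circle.radius_at(t))
    free = 4.0 * (rt ** 2 / rs ** 2) * D * t
    swept = (2.0 / rs ** 2) * ((rs ** 4 - rt ** 4) / 4.0
                               - (2.0 / 3.0) * rt * (rs ** 3 - rt ** 3)
                               + (rt ** 2 / 2.0) * (rs ** 2 - rt ** 2))
    out = free + swept
    return float(out) if out.ndim == 0 else out


def msd_surface_limits(circle: ShrinkingCircle, t=None, regime="fast"):
    """Closed-form MSD limits for diffusion on the shrinking circle.

    ``regime="fast"``: the uniform-at-end-time bound ``r_s^2 + r_e^2``.
    ``regime="zero"``: the zero-diffusion curve ``(r_s - r_t)^2`` for a
    particle carried by the boundary from (0, r_s).
    """
    if regime == "fast":
        return circle.r_s ** 2 + circle.r_e ** 2
    if regime == "zero":
        if t is None:
            raise ValueError("the zero-diffusion curve needs a time")
        rt = np.asarray(circle.radius_at(t))
        out = (circle.r_s - rt) ** 2
        return float(out) if out.ndim == 0 else out
    raise ValueError("regime must be 'fast' or 'zero'")
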