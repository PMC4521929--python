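"""Benchmark pipelines: the validation experiments run end to end.

These functions wire geometry, steppers, reference solvers and estimators
into the shrinking-circle, elongating-dumbbell and dividing-nucleus
experiments, at configurable problem sizes.  They are used by the test
suite and the acceptance script; the scenario presets call into them too.

All randomness is keyed by an integer seed; a given (seed, parameters)
combination is bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (ShrinkingCircle, Dumbbell, DividingNucleus, StaticDomain,
                       load_synthetic_frames, _Seg)
from .volume import ParticleSet, SimulationConfig, simulate_volume
from .surface import simulate_surface
from .reactions import BleachRegion
from .reference import (solve_surface_pde, solve_volume_pde_radial,
                        uniform_cdf, slow_diffusion_cdf)
from .stats import empirical_cdf, msd_curve, Z99

__all__ = [
    "BENCH_CIRCLE",
    "SNAP_TIMES",
    "sample_uniform_disc",
    "circle_volume_run",
    "volume_cdf_vs_reference",
    "volume_cdf_vs_limit",
    "volume_msd",
    "k_scheme_differences",
    "surface_circle_run",
    "surface_cdf_vs_pde",
    "surface_msd",
    "dumbbell_reaction_experiment",
    "dumbbell_bridge_volume_fraction",
    "nucleus_photobleach_run",
]

#: the benchmark circle: radius 5 -> 3 length units linearly over 5 s
BENCH_CIRCLE = ShrinkingCircle(r_s=5.0, r_e=3.0, t_e=5.0)

#: snapshot times of the published CDF comparisons
SNAP_TIMES = (1.25, 2.5, 3.75, 5.0)


# ---------------------------------------------------------------------------
# Volume benchmarks on the shrinking circle
# ---------------------------------------------------------------------------

def sample_uniform_disc(n, radius, rng):
    """Uniform positions in a disc of the given radius."""
    r = radius * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)


def circle_volume_run(D, dt, n, seed, k=1.0, rho=0.0, snapshot_times=SNAP_TIMES,
                      circle=BENCH_CIRCLE, t_end=None):
    """n independent particles in the shrinking circle; returns (x0, trajectory)."""
    cfg = SimulationConfig(dt=dt, t_end=t_end if t_end is not None else max(snapshot_times),
                           k=k, seed=seed)
    rng = cfg.rng(0)
    x0 = sample_uniform_disc(n, circle.r_s - rho, rng)
    p = ParticleSet.single_species(x0, D=D, radius=rho)
    traj = simulate_volume(circle, p, cfg, snapshot_times=snapshot_times, rng=rng)
    return x0, traj


def _band_coverage(samples, eval_points, ref_cdf_values, n):
    """Fraction of evaluation points where the empirical CDF lies inside the
    99% binomial band around the reference CDF, plus the maximum deviation."""
    emp = empirical_cdf(samples, eval_points)
    ref_cdf_values = np.clip(ref_cdf_values, 0.0, 1.0)
    band = Z99 * np.sqrt(ref_cdf_values * (1.0 - ref_cdf_values) / n)
    dev = np.abs(emp.estimate - ref_cdf_values)
    return float(np.mean(dev <= band + 1e-12)), float(dev.max())


def volume_cdf_vs_reference(D, dt, n, seed, k=1.0, rho=0.0,
                            snapshot_times=SNAP_TIMES, circle=BENCH_CIRCLE,
                            n_eval=200, n_cells=200):
    """Empirical radial CDFs against the moving-boundary radial solver.

    Returns a DataFrame with one row per snapshot time: band coverage
    fraction and maximum CDF deviation.
    """
    _, traj = circle_volume_run(D, dt, n, seed, k=k, rho=rho,
                                snapshot_times=snapshot_times, circle=circle)
    sol = solve_volume_pde_radial(D, circle, snapshot_times, rho=rho,
                                  n_cells=n_cells)
    rows = []
    for i, t in enumerate(snapshot_times):
        radii = np.linalg.norm(traj.positions_at(t), axis=1)
        s_t = circle.radius_at(t) - rho
        ev = np.linspace(0.0, s_t, n_eval + 1)[1:]
        cov, dev = _band_coverage(radii, ev, sol.cdf(i, ev), n)
        rows.append({"time_s": t, "coverage": cov, "max_dev": dev})
    return pd.DataFrame(rows)


def volume_cdf_vs_limit(D, dt, n, seed, limit, rho=0.0,
                        snapshot_times=SNAP_TIMES, circle=BENCH_CIRCLE,
                        n_eval=200):
    """Empirical radial CDFs against an analytic limit ('uniform' or 'slow')."""
    _, traj = circle_volume_run(D, dt, n, seed, rho=rho,
                                snapshot_times=snapshot_times, circle=circle)
    rows = []
    for t in snapshot_times:
        radii = np.linalg.norm(traj.positions_at(t), axis=1)
        s_t = circle.radius_at(t) - rho
        ev = np.linspace(0.0, s_t, n_eval + 1)[1:]
        if limit == "uniform":
            ref = uniform_cdf(ev, circle.radius_at(t), rho=rho)
        elif limit == "slow":
            ref = slow_diffusion_cdf(ev, circle, t, rho=rho)
        else:
            raise ValueError("limit must be 'uniform' or 'slow'")
        cov, dev = _band_coverage(radii, ev, ref, n)
        rows.append({"time_s": t, "coverage": cov, "max_dev": dev})
    return pd.DataFrame(rows)


def volume_msd(D, dt, n, seed, times, circle=BENCH_CIRCLE, convention="ci99"):
    """MSD curve (with 99% half-widths) for the shrinking-circle volume run."""
    times = np.asarray(times, dtype=float)
    x0, traj = circle_volume_run(D, dt, n, seed, snapshot_times=times,
                                 circle=circle, t_end=float(times.max()))
    sq = np.empty((n, times.size))
    for j, t in enumerate(times):
        xt = traj.positions_at(t)
        sq[:, j] = np.sum((xt - x0) ** 2, axis=1)
    return msd_curve(sq, times, convention=convention)


def k_scheme_differences(dts, D=0.5, n=2000, seed=0, at_radius=2.75,
                         circle=BENCH_CIRCLE, t=5.0):
    """Percentage CDF difference at one radius between k=1 and k=2 runs.

    The two runs of each time step share a seed (common random numbers), so
    the difference isolates the boundary-correction scheme.
    """
    out = []
    for dt in dts:
        cdfs = {}
        for k in (1.0, 2.0):
            _, traj = circle_volume_run(D, dt, n, seed, k=k,
                                        snapshot_times=(t,), circle=circle)
            radii = np.linalg.norm(traj.positions_at(t), axis=1)
            cdfs[k] = float(np.mean(radii <= at_radius))
        out.append({"dt": dt, "cdf_k1": cdfs[1.0], "cdf_k2": cdfs[2.0],
                    "pct_diff": abs(cdfs[1.0] - cdfs[2.0]) / cdfs[1.0] * 100.0})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Surface benchmarks on the shrinking circle
# ---------------------------------------------------------------------------

def surface_circle_run(D, dt, n, seed, snapshot_times=SNAP_TIMES,
                       circle=BENCH_CIRCLE, t_end=None):
    """n independent surface diffusers starting as a point mass at (0, r_s)."""
    cfg = SimulationConfig(dt=dt, t_end=t_end if t_end is not None else max(snapshot_times),
                           seed=seed)
    rng = cfg.rng(0)
    x0 = np.tile([0.0, circle.r_s], (n, 1))
    p = ParticleSet.single_species(x0, D=D)
    traj = simulate_surface(circle, p, cfg, snapshot_times=snapshot_times, rng=rng)
    return x0, traj


def _angles(positions):
    """Angle from the positive y-axis, positive toward positive x, in (-pi, pi]."""
    return np.arctan2(positions[:, 0], positions[:, 1])


def surface_cdf_vs_pde(D, dt, n, seed, snapshot_times=SNAP_TIMES,
                       circle=BENCH_CIRCLE, n_eval=200, N=401):
    """Empirical angular CDFs against the explicit finite-difference solution."""
    _, traj = surface_circle_run(D, dt, n, seed, snapshot_times=snapshot_times,
                                 circle=circle)
    theta, _, cdfs = solve_surface_pde(D, circle, snapshot_times, N=N)
    rows = []
    ev = np.linspace(-np.pi, np.pi, n_eval + 2)[1:-1]
    for i, t in enumerate(snapshot_times):
        ang = _angles(traj.positions_at(t))
        ref = np.interp(ev, theta, cdfs[i])
        cov, dev = _band_coverage(ang, ev, ref, n)
        rows.append({"time_s": t, "coverage": cov, "max_dev": dev})
    return pd.DataFrame(rows)


def surface_msd(D, dt, n, seed, times, circle=BENCH_CIRCLE, convention="ci99"):
    """MSD curve for surface diffusion on the shrinking circle."""
    times = np.asarray(times, dtype=float)
    x0, traj = surface_circle_run(D, dt, n, seed, snapshot_times=times,
                                  circle=circle, t_end=float(times.max()))
    sq = np.empty((n, times.size))
    for j, t in enumerate(times):
        sq[:, j] = np.sum((traj.positions_at(t) - x0) ** 2, axis=1)
    return msd_curve(sq, times, convention=convention)


# ---------------------------------------------------------------------------
# Elongating dumbbell: bimolecular decay A + B -> 0
# ---------------------------------------------------------------------------

#: the published dumbbell experiment
BENCH_DUMBBELL = Dumbbell(R=3.0, d=0.5, L=0.01, T1=200000.0, T2=201000.0)


def dumbbell_reaction_experiment(n_events, seed, dt=1.0 / 3.0, D=0.0025,
                                 threshold=0.2, t_max=400000.0,
                                 domain=BENCH_DUMBBELL):
    """Reaction times of A + B -> 0 pairs started at the two sphere centres.

    Each replicate holds one A at the left sphere centre and one B at the
    right; pairs react with probability one when their separation is at or
    below ``threshold`` at the end of a step.  All replicates advance in
    lockstep through one vectorised loop; finished replicates drop out.
    Replicates that have not reacted by ``t_max`` are censored (NaN time).

    Returns a DataFrame with columns time_s, x, y, z (event = midpoint of
    the reactants), in_bridge (event inside the instantaneous bridge
    region), censored.
    """
    rng = np.random.default_rng([int(seed), 1])
    n = int(n_events)
    c0 = domain.centre_x(0.0)
    # X[i, 0] is the A of pair i, X[i, 1] its B
    X = np.tile([[-c0, 0.0, 0.0], [c0, 0.0, 0.0]], (n, 1, 1))
    active = np.arange(n)
    times = np.full(n, np.nan)
    pos = np.full((n, 3), np.nan)
    sig = np.sqrt(2.0 * D * dt)
    n_steps = int(round(t_max / dt))
    for step in range(1, n_steps + 1):
        if active.size == 0:
            break
        t = step * dt
        sub = X[active]
        flat = sub.reshape(-1, 3)
        flat += sig * rng.standard_normal(flat.shape)
        inside = domain.contains(flat, t)
        if not inside.all():
            esc = np.flatnonzero(~inside)
            proj, _ = domain.project_boundary(flat[esc], t)
            flat[esc] = proj  # k = 1 mapping
        d = np.linalg.norm(sub[:, 0] - sub[:, 1], axis=1)
        hit = d <= threshold
        X[active] = sub
        if hit.any():
            fin = active[hit]
            times[fin] = t
            pos[fin] = 0.5 * (X[fin, 0] + X[fin, 1])
            active = active[~hit]
    l_at = domain.bridge_length(np.nan_to_num(times, nan=t_max))
    in_bridge = np.abs(pos[:, 0]) < l_at / 2.0
    return pd.DataFrame({"time_s": times, "x": pos[:, 0], "y": pos[:, 1],
                         "z": pos[:, 2], "in_bridge": in_bridge,
                         "censored": ~np.isfinite(times)})


def dumbbell_bridge_volume_fraction(domain, t):
    """Volume fraction of the bridge region |x| < l(t)/2."""
    l = domain.bridge_length(t)
    R, o = domain.R, domain.offset
    v_bridge = np.pi * domain.d ** 2 * l
    cap_h = o                                   # truncated cap height
    v_cap = np.pi * cap_h ** 2 * (3.0 * R - cap_h) / 3.0
    v_sphere_part = 4.0 / 3.0 * np.pi * R ** 3 - v_cap
    return v_bridge / (2.0 * v_sphere_part + v_bridge)


# ---------------------------------------------------------------------------
# Dividing nucleus: photobleaching (FLIP) experiment
# ---------------------------------------------------------------------------

def _profile_polyline(primitives, pts_per=400):
    """Sample each profile primitive into a polyline in the (x, rho) plane."""
    segs = []
    for prim in primitives:
        if isinstance(prim, _Seg):
            x = np.linspace(prim.x0, prim.x1, pts_per)
            segs.append(np.stack([x, np.full_like(x, prim.c)], axis=1))
        else:
            th = np.linspace(prim.lo, prim.hi, pts_per)
            if hasattr(prim, "a"):
                segs.append(np.stack([prim.cx + prim.a * np.cos(th),
                                      prim.b * np.sin(th)], axis=1))
            else:
                segs.append(np.stack([prim.cx + prim.r * np.cos(th),
                                      prim.r * np.sin(th)], axis=1))
    return np.vstack(segs)


def sample_surface_axisym(domain, t, n, rng):
    """Uniform sample of a rotationally symmetric boundary surface.

    The area element of a surface of revolution is rho ds d(azimuth), so
    profile arc-length segments are weighted by their mid-point radius.
    """
    poly = _profile_polyline(domain._profile(t))
    d = np.diff(poly, axis=0)
    ds = np.linalg.norm(d, axis=1)
    rho_mid = 0.5 * (poly[:-1, 1] + poly[1:, 1])
    w = ds * rho_mid
    w_ok = w > 0
    idx = rng.choice(np.flatnonzero(w_ok), size=n, p=w[w_ok] / w[w_ok].sum())
    frac = rng.random(n)[:, None]
    xy = poly[idx] + frac * d[idx]
    phi = 2.0 * np.pi * rng.random(n)
    pts = np.stack([xy[:, 0], xy[:, 1] * np.cos(phi), xy[:, 1] * np.sin(phi)], axis=1)
    p, _ = domain.project_boundary(pts, t)   # snap onto the exact surface
    return p


def sample_volume_axisym(domain, t, n, rng, max_tries=200):
    """Uniform sample of the interior by rejection in the bounding box."""
    poly = _profile_polyline(domain._profile(t), pts_per=100)
    lo = np.array([poly[:, 0].min(), -poly[:, 1].max(), -poly[:, 1].max()])
    hi = np.array([poly[:, 0].max(), poly[:, 1].max(), poly[:, 1].max()])
    out = np.empty((0, 3))
    for _ in range(max_tries):
        cand = lo + (hi - lo) * rng.random((2 * n, 3))
        cand = cand[domain.contains(cand, t)]
        out = np.vstack([out, cand])
        if len(out) >= n:
            return out[:n]
    raise RuntimeError("rejection sampling failed to fill the request")


def nucleus_photobleach_run(mode="volume", moving=True, n=300, seed=0,
                            dt=0.01, D=0.25, r_photo=0.17, k_deg=2.0,
                            frames=None, snapshot_every=5.0, replicate=0):
    """One FLIP run in (or on) the dividing nucleus.

    Proteins start uniformly distributed through the nucleus volume
    (``mode="volume"``) or over the nuclear membrane (``mode="surface"``);
    a spherical bleach spot of radius ``r_photo`` glued to the membrane
    above the mother-lobe centre removes particles at rate ``k_deg``.  With
    ``moving=False`` the geometry is frozen at the first frame.  Returns a
    DataFrame of per-snapshot mother/daughter lobe counts (the dividing
    plane is the middle of the bridge; a particle exactly on the plane
    counts as mother).
    """
    nuc = DividingNucleus(frames if frames is not None else load_synthetic_frames())
    t0, t1 = nuc.t_span
    domain = nuc if moving else StaticDomain(nuc, t0)
    cfg = SimulationConfig(dt=dt, t_end=t1 - t0, seed=seed)
    rng = cfg.rng(replicate)
    if mode == "volume":
        x0 = sample_volume_axisym(nuc, t0, n, rng)
        sim = simulate_volume
    elif mode == "surface":
        x0 = sample_surface_axisym(nuc, t0, n, rng)
        sim = simulate_surface
    else:
        raise ValueError("mode must be 'volume' or 'surface'")
    p = ParticleSet.single_species(x0, D=D, independent=False)
    centre = nuc.bleach_centre if moving else (lambda t: nuc.bleach_centre(t0))
    bleach = BleachRegion(centre=centre, r_photo=r_photo, k_deg=k_deg)
    snaps = np.arange(0.0, t1 - t0 + 1e-9, snapshot_every)
    traj = sim(domain, p, cfg, bleach=bleach, snapshot_times=snaps, rng=rng)

    rows = []
    for t in np.unique(traj.frames["time_s"]):
        sub = traj.frames[traj.frames["time_s"] == t]
        plane = nuc.bridge_midplane(t0 + t) if moving else nuc.bridge_midplane(t0)
        mother = int((sub["x"] <= plane).sum())
        rows.append({"time_s": t, "mother": mother,
                     "daughter": int(len(sub) - mother), "total": int(len(sub))})
    return pd.DataFrame(rows)
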