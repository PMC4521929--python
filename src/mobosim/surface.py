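"""Diffusion of particles constrained to a moving boundary surface.

Each step propagates a surface-bound particle by a full-dimensional
Gaussian displacement (per-coordinate variance ``2 D dt``), carries it with
the boundary by the advective displacement ``v_t(x) dt``, and projects the
result onto the closest point of the surface at the *new* time, so the
on-surface invariant holds at each timestamp.  The Gaussian step is taken in
the ambient space, not the tangent plane: in the small-``dt`` limit the
surface is locally flat and the projection of a Brownian motion is itself
Brownian, so the projected walk samples intrinsic surface diffusion.
"""
from __future__ import annotations

import numpy as np

from .geometry import MovingDomain, _as_points
from .volume import ParticleSet, SimulationConfig, Trajectory, \
    diffusive_step, _record, _frames_df, _snap_to_steps, _events_df

__all__ = ["surface_step", "simulate_surface"]

#: acceptable off-surface distance for initial conditions / invariants
ON_SURFACE_TOL = 1e-9


def surface_step(x, D, domain: MovingDomain, t, dt, rng):
    """One step for surface-bound particles: Gaussian + advective carry + projection.

    ``x`` may be one point or an (n, dim) batch on Gamma_t; the result lies
    on Gamma_{t+dt}.
    """
    a, single = _as_points(x, domain.dim)
    v = np.atleast_2d(domain.boundary_velocity(a, t, dt=dt))
    moved = diffusive_step(a, D, dt, rng) + v * dt
    p, _ = domain.project_boundary(moved, t + dt)
    return p[0] if single else p


def simulate_surface(domain: MovingDomain, particles: ParticleSet,
                     config: SimulationConfig, reactions=None, bleach=None,
                     snapshot_times=None, rng=None) -> Trajectory:
    """Run the moving-boundary surface stepper.

    Same per-step order as the volume simulator (movement first, then
    reactions and bleaching); snapshots snap to the nearest completed step
    and runs are seed-deterministic.
    """
    from .reactions import detect_and_execute, photobleach

    p = particles
    t0 = max(0.0, domain.t_span[0])
    d0 = domain.boundary_distance(p.x, t0)
    if np.any(d0 > 1e-6):
        raise ValueError("initial particle off the surface beyond tolerance")
    if rng is None:
        rng = config.rng(0)
    n_steps = int(round(config.t_end / config.dt))
    snap_steps = _snap_to_steps(snapshot_times, config.dt, n_steps)

    records, events = [], []
    if 0 in snap_steps:
        _record(records, t0, p)
    for step in range(1, n_steps + 1):
        t = t0 + (step - 1) * config.dt
        t_new = t0 + step * config.dt
        idx = np.flatnonzero(p.alive)
        if idx.size:
            p.x[idx] = surface_step(p.x[idx], p.D[idx], domain, t, config.dt, rng)
        if reactions:
            detect_and_execute(p, reactions, t_new, rng, events=events)
        if bleach is not None:
            photobleach(p, bleach, t_new, config.dt, rng, events=events)
        if step in snap_steps:
            _record(records, t_new, p)
    return Trajectory(frames=_frames_df(records, domain.dim),
                      events=_events_df(events, domain.dim), surface=True)
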