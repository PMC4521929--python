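"""Brownian propagation of particles inside a moving domain.

The stepper advances every particle by an independent Gaussian displacement
(per-coordinate variance ``2 D dt``), advances the clock, re-inserts any
particle that has escaped the domain or come closer to the boundary than its
own radius, resolves hard-sphere overlaps, and only then executes reactions
and photobleaching.  Escaped point particles are mapped with the parameter
``k``: the corrected position is ``(1 - k) x + k p`` where ``p`` is the
closest boundary point, so ``k = 1`` places the particle on the boundary and
``k = 2`` reflects it through the closest point.  Finite-radius particles
are placed at ``p`` and then moved inward along the normal by their radius.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import MovingDomain, _as_points

__all__ = [
    "SimulationConfig",
    "ParticleSet",
    "StepFailure",
    "diffusive_step",
    "map_into_domain",
    "resolve_overlaps",
    "simulate_volume",
]

_MAX_REMAP = 10  # re-mapping attempts for non-convex domains before failing


class StepFailure(RuntimeError):
    """A particle could not be returned to the domain within the iteration cap."""

    def __init__(self, particle_ids, t):
        self.particle_ids = np.atleast_1d(particle_ids)
        self.t = t
        super().__init__(f"mapping failed for particles {self.particle_ids.tolist()} at t={t}")


@dataclass(frozen=True)
class SimulationConfig:
    """Time stepping and reproducibility parameters.

    ``k`` is the escape-mapping parameter (>= 1).  A run is fully determined
    by (seed, replicate index): each replicate owns an independent
    counter-based random stream seeded as ``(seed, replicate)``.
    """

    dt: float
    t_end: float
    k: float = 1.0
    seed: int = 0
    replicates: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.k < 1:
            raise ValueError("mapping parameter k must be >= 1")
        if self.t_end < 0:
            raise ValueError("end time must be non-negative")

    def rng(self, replicate=0):
        return np.random.default_rng([int(self.seed), int(replicate)])


@dataclass
class ParticleSet:
    """Flat arrays describing the particles of one run.

    ``rep`` partitions particles into independent replicates: pairwise
    interactions (reactions, overlap pushes) only act within a replicate,
    which lets many single-particle or single-pair experiments advance in
    lockstep through one vectorised loop.
    """

    x: np.ndarray                      # (n, dim) positions
    D: np.ndarray                      # (n,) diffusion coefficients
    radius: np.ndarray                 # (n,) hard-sphere radii (0 = point)
    species: np.ndarray                # (n,) integer species codes
    rep: np.ndarray                    # (n,) replicate index
    ids: np.ndarray = None             # (n,) stable particle identifiers
    alive: np.ndarray = None           # (n,) bool

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float)).copy()
        n = len(self.x)
        self.D = np.broadcast_to(np.asarray(self.D, dtype=float), (n,)).copy()
        self.radius = np.broadcast_to(np.asarray(self.radius, dtype=float), (n,)).copy()
        self.species = np.broadcast_to(np.asarray(self.species), (n,)).copy()
        self.rep = np.broadcast_to(np.asarray(self.rep, dtype=int), (n,)).copy()
        if np.any(self.D < 0):
            raise ValueError("diffusion coefficients must be non-negative")
        if np.any(self.radius < 0):
            raise ValueError("particle radii must be non-negative")
        if self.ids is None:
            self.ids = np.arange(n)
        if self.alive is None:
            self.alive = np.ones(n, dtype=bool)

    @classmethod
    def single_species(cls, x, D, radius=0.0, species=0, independent=True):
        """Convenience constructor: one particle per replicate when ``independent``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = len(x)
        rep = np.arange(n) if independent else np.zeros(n, dtype=int)
        return cls(x=x, D=D, radius=radius, species=species, rep=rep)

    @property
    def n(self):
        return len(self.x)


def diffusive_step(positions, D, dt, rng):
    """Displace positions by independent Normal(0, 2 D dt) per coordinate.

    The draw order is fixed as (particle, coordinate) so identical seeds give
    bit-identical trajectories.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("diffusion coefficient must be non-negative")
    sigma = np.sqrt(2.0 * D * dt)
    if sigma.ndim == 1:
        sigma = sigma[:, None]
    return positions + sigma * rng.standard_normal(positions.shape)


def map_into_domain(x, domain: MovingDomain, t, k=1.0, rho=0.0):
    """Return escaped (or too-close) particles to the interior of Omega_t.

    Point particles (``rho = 0``) move to ``(1 - k) x + k p``; finite-radius
    particles are placed at the closest boundary point and pushed inward by
    ``rho`` along the normal.  On non-convex domains the mapped point can
    land outside again; the mapping is reapplied up to a bounded number of
    times, after which a :class:`StepFailure` is raised.
    """
    a, single = _as_points(x, domain.dim)
    rho_arr = np.broadcast_to(np.asarray(rho, dtype=float), (len(a),))
    out = a.copy()
    pending = np.ones(len(a), dtype=bool)
    for _ in range(_MAX_REMAP):
        idx = np.flatnonzero(pending)
        if idx.size == 0:
            break
        p, nrm = domain.project_boundary(out[idx], t)
        r = rho_arr[idx][:, None]
        ri = rho_arr[idx]
        mapped = np.where(r > 0, p - r * nrm, (1.0 - k) * out[idx] + k * p)
        out[idx] = mapped
        if k == 1.0 and not np.any(ri > 0):
            # k = 1 places point particles exactly on the closed boundary
            pending[idx] = False
            break
        ok = domain.contains(mapped, t)
        # k = 1 point particles land on the closed boundary: accept
        ok |= (k == 1.0) & (ri == 0)
        with_clearance = ri > 0
        if np.any(with_clearance):
            d = domain.boundary_distance(mapped, t)
            ok &= np.where(with_clearance, d >= ri * (1 - 1e-9), True)
        pending[idx] = ~ok
    if np.any(pending):
        raise StepFailure(np.flatnonzero(pending), t)
    return out[0] if single else out


def resolve_overlaps(positions, radii, rep=None, rng=None, max_iter=50):
    """Push overlapping hard spheres apart symmetrically along their centre line.

    Any pair (same replicate) with centre distance below the sum of radii is
    moved apart by equal amounts until the distance equals the radius sum;
    the check is repeated until no overlaps remain or the iteration cap is
    reached.  Coincident centres are separated along a deterministic random
    direction drawn from ``rng``.
    """
    x = np.atleast_2d(np.asarray(positions, dtype=float)).copy()
    r = np.broadcast_to(np.asarray(radii, dtype=float), (len(x),))
    if rep is None:
        rep = np.zeros(len(x), dtype=int)
    if not np.any(r > 0) or len(x) < 2:
        return x
    for _ in range(max_iter):
        diff = x[:, None, :] - x[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        target = r[:, None] + r[None, :]
        same_rep = rep[:, None] == rep[None, :]
        iu = np.triu_indices(len(x), k=1)
        overlap = (dist[iu] < target[iu] * (1 - 1e-12)) & same_rep[iu]
        if not np.any(overlap):
            break
        for i, j in zip(iu[0][overlap], iu[1][overlap]):
            v = x[i] - x[j]
            dn = np.linalg.norm(v)
            if dn == 0:
                if rng is None:
                    rng = np.random.default_rng(0)
                v = rng.standard_normal(x.shape[1])
                v /= np.linalg.norm(v)
                dn = 0.0
            else:
                v = v / dn
            push = (r[i] + r[j] - dn) / 2.0
            x[i] += push * v
            x[j] -= push * v
    return x


@dataclass
class Trajectory:
    """Recorded snapshots plus the event log of one run."""

    frames: pd.DataFrame               # columns: time_s, particle_id, species, rep, x, y[, z]
    events: pd.DataFrame = None
    surface: bool = False

    def positions_at(self, time):
        f = self.frames
        ts = f["time_s"].unique()
        t = ts[np.argmin(np.abs(ts - time))]
        sub = f[f["time_s"] == t]
        cols = [c for c in ("x", "y", "z") if c in f.columns]
        return sub[cols].to_numpy()


def _record(records, t, p: ParticleSet):
    alive = p.alive
    records.append({
        "time_s": np.full(alive.sum(), t),
        "particle_id": p.ids[alive].copy(),
        "species": p.species[alive].copy(),
        "rep": p.rep[alive].copy(),
        "pos": p.x[alive].copy(),
    })


def _frames_df(records, dim):
    cols = ["x", "y", "z"][:dim]
    parts = []
    for r in records:
        d = {"time_s": r["time_s"], "particle_id": r["particle_id"],
             "species": r["species"], "rep": r["rep"]}
        for j, c in enumerate(cols):
            d[c] = r["pos"][:, j]
        parts.append(pd.DataFrame(d))
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["time_s", "particle_id", "species", "rep", *cols])


def simulate_volume(domain: MovingDomain, particles: ParticleSet,
                    config: SimulationConfig, reactions=None, bleach=None,
                    snapshot_times=None, rng=None) -> Trajectory:
    """Run the moving-boundary volume stepper.

    Per-step order: diffuse -> map escaped / too-close particles back into
    Omega_t -> resolve hard-sphere overlaps -> reactions and bleaching ->
    record.  Snapshots snap to the nearest completed step.  Identical seed
    and configuration give bit-identical trajectories.
    """
    from .reactions import detect_and_execute, photobleach  # local import, no cycle at load

    p = particles
    t = 0.0
    if not np.all(domain.contains(p.x, t)):
        raise ValueError("initial particle outside the domain")
    if np.any(p.radius > 0):
        d0 = domain.boundary_distance(p.x, t)
        if np.any(d0 < p.radius * (1 - 1e-9)):
            raise ValueError("initial particle closer to the boundary than its radius")
    if rng is None:
        rng = config.rng(0)
    n_steps = int(round(config.t_end / config.dt))
    snap_steps = _snap_to_steps(snapshot_times, config.dt, n_steps)
    # hard-sphere pushes only apply when some replicate holds several
    # finite-radius particles; skip the pairwise sweep otherwise
    pairwise = bool(np.any(p.radius > 0)) and np.any(np.bincount(p.rep) > 1)

    records, events = [], []
    if 0 in snap_steps:
        _record(records, 0.0, p)
    for step in range(1, n_steps + 1):
        t_new = step * config.dt
        alive = p.alive
        idx = np.flatnonzero(alive)
        if idx.size:
            p.x[idx] = diffusive_step(p.x[idx], p.D[idx], config.dt, rng)
            inside = domain.contains(p.x[idx], t_new)
            needs = ~inside
            finite = p.radius[idx] > 0
            if np.any(finite):
                d = domain.boundary_distance(p.x[idx], t_new)
                needs |= finite & (d < p.radius[idx])
            if np.any(needs):
                sel = idx[needs]
                p.x[sel] = map_into_domain(p.x[sel], domain, t_new,
                                           k=config.k, rho=p.radius[sel])
            if pairwise and idx.size > 1:
                p.x[idx] = resolve_overlaps(p.x[idx], p.radius[idx], p.rep[idx], rng)
        if reactions:
            detect_and_execute(p, reactions, t_new, rng, events=events)
        if bleach is not None:
            photobleach(p, bleach, t_new, config.dt, rng, events=events)
        if step in snap_steps:
            _record(records, t_new, p)
        t = t_new
    return Trajectory(frames=_frames_df(records, domain.dim),
                      events=_events_df(events, domain.dim))


def _snap_to_steps(snapshot_times, dt, n_steps):
    if snapshot_times is None:
        return {n_steps}
    return {int(np.clip(round(ts / dt), 0, n_steps)) for ts in np.atleast_1d(snapshot_times)}


def _events_df(events, dim):
    cols = ["x", "y", "z"][:dim]
    if not events:
        return pd.DataFrame(columns=["time_s", "event_type", "species_in", "species_out", *cols])
    df = pd.DataFrame(events)
    pos = np.vstack(df.pop("pos").to_numpy())
    for j, c in enumerate(cols):
        df[c] = pos[:, j]
    return df
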