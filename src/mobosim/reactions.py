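"""Distance-threshold reactions and Bernoulli photobleaching.

Reactions are executed after movement each step: any eligible pair whose
centre distance is at or below the reaction threshold fires with the
specified probability.  Eligible pairs are processed in ascending order of
distance (closer pairs first) and a particle consumed by one reaction is
removed from later pairs in the same step, so each particle participates in
at most one reaction per step.

Photobleaching removes each particle inside a spherical bleach region
independently with probability ``k_deg * dt`` (a Bernoulli trial) at the end
of each step.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .volume import ParticleSet

__all__ = ["ReactionSpec", "BleachRegion", "detect_and_execute", "photobleach"]

_PLACEMENTS = {"same", "midpoint", "reactants", "poles"}


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction channel.

    ``reactants`` holds one species (unary) or two (binary, possibly equal).
    Placement rules: unary -> one product at the reactant's position
    (``"same"``); binary -> one product at the midpoint of the reactants
    (``"midpoint"``); binary -> two products at the reactants' positions
    (``"reactants"``); unary -> two products at randomly opposite poles of a
    small sphere centred on the reactant (``"poles"``), the sphere diameter
    being of the order of the largest reaction threshold in the system.
    """

    reactants: tuple
    threshold: float
    probability: float = 1.0
    products: tuple = ()
    placement: str = None

    def __post_init__(self):
        r = tuple(np.atleast_1d(self.reactants))
        object.__setattr__(self, "reactants", r)
        object.__setattr__(self, "products", tuple(np.atleast_1d(self.products)))
        if len(r) not in (1, 2):
            raise ValueError("a reaction takes one or two reactant species")
        if self.threshold < 0:
            raise ValueError("reaction threshold must be non-negative")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("reaction probability must lie in [0, 1]")
        if self.placement is None:
            default = {(1, 1): "same", (2, 1): "midpoint",
                       (2, 2): "reactants", (1, 2): "poles"}
            object.__setattr__(self, "placement",
                               default.get((len(r), len(self.products)), "same"))
        if self.placement not in _PLACEMENTS:
            raise ValueError(f"unknown placement rule {self.placement!r}")
        if len(self.products) > 2:
            raise ValueError("at most two products are supported")

    @property
    def unary(self):
        return len(self.reactants) == 1


@dataclass
class BleachRegion:
    """Spherical photobleaching sink.

    ``centre`` is a fixed position or a callable ``t -> position`` (for a
    bleach spot glued to a moving membrane).  A particle inside the sphere
    decays with probability ``k_deg * dt`` per step.
    """

    centre: object
    r_photo: float
    k_deg: float

    def __post_init__(self):
        if self.r_photo <= 0 or self.k_deg < 0:
            raise ValueError("need r_photo > 0 and k_deg >= 0")

    def centre_at(self, t):
        c = self.centre(t) if callable(self.centre) else self.centre
        return np.asarray(c, dtype=float)


def _log(events, t, event_type, species_in, species_out, pos):
    if events is not None:
        events.append({"time_s": t, "event_type": event_type,
                       "species_in": species_in, "species_out": species_out,
                       "pos": np.asarray(pos, dtype=float)})


def _spawn(p: ParticleSet, positions, species, like_idx):
    """Append product particles, inheriting D and radius from ``like_idx``."""
    positions = np.atleast_2d(positions)
    m = len(positions)
    p.x = np.vstack([p.x, positions])
    p.D = np.concatenate([p.D, np.full(m, p.D[like_idx])])
    p.radius = np.concatenate([p.radius, np.full(m, p.radius[like_idx])])
    p.species = np.concatenate([p.species, np.asarray(species)])
    p.rep = np.concatenate([p.rep, np.full(m, p.rep[like_idx])])
    next_id = p.ids.max() + 1 if len(p.ids) else 0
    p.ids = np.concatenate([p.ids, np.arange(next_id, next_id + m)])
    p.alive = np.concatenate([p.alive, np.ones(m, dtype=bool)])


def detect_and_execute(p: ParticleSet, specs: Sequence[ReactionSpec], t, rng,
                       events=None):
    """Execute all reaction channels on a particle set (in place).

    Product particles are appended after all channels have been processed,
    so products never react again within the step in which they are created.
    Returns the list of event records appended this step.
    """
    if isinstance(specs, ReactionSpec):
        specs = [specs]
    new_events = []
    sink = events if events is not None else new_events
    consumed = np.zeros(p.n, dtype=bool)
    max_thr = max((s.threshold for s in specs), default=0.0)
    spawns = []  # (positions, species list, index to inherit D/radius from)
    for spec in specs:
        if spec.unary:
            _do_unary(p, spec, t, rng, sink, consumed, max_thr, spawns)
        else:
            _do_binary(p, spec, t, rng, sink, consumed, spawns)
    for pos, sp, like in spawns:
        _spawn(p, pos, sp, like)
    return sink


def _do_unary(p, spec, t, rng, events, consumed, max_thr, spawns):
    (a,) = spec.reactants
    idx = np.flatnonzero(p.alive & ~consumed & (p.species == a))
    if idx.size == 0:
        return
    fire = rng.random(idx.size) < spec.probability
    for i in idx[fire]:
        consumed[i] = True
        p.alive[i] = False
        pos = p.x[i]
        if len(spec.products) == 1:
            spawns.append((pos[None, :].copy(), [spec.products[0]], i))
        elif len(spec.products) == 2:
            # two products at randomly opposite poles of a small sphere whose
            # diameter is the largest reaction threshold in the system
            u = rng.standard_normal(p.x.shape[1])
            u /= np.linalg.norm(u)
            r = (max_thr or spec.threshold) / 2.0
            spawns.append((np.stack([pos + r * u, pos - r * u]),
                           list(spec.products), i))
        _log(events, t, "reaction", str(a),
             "+".join(map(str, spec.products)) or "0", pos)


def _do_binary(p, spec, t, rng, events, consumed, spawns):
    a, b = spec.reactants
    ia = np.flatnonzero(p.alive & ~consumed & (p.species == a))
    ib = np.flatnonzero(p.alive & ~consumed & (p.species == b))
    if ia.size == 0 or ib.size == 0:
        return
    d = cdist(p.x[ia], p.x[ib])
    same_rep = p.rep[ia][:, None] == p.rep[ib][None, :]
    elig = (d <= spec.threshold) & same_rep
    if a == b:
        elig &= ia[:, None] < ib[None, :]
    else:
        elig &= ia[:, None] != ib[None, :]
    ii, jj = np.nonzero(elig)
    if ii.size == 0:
        return
    order = np.argsort(d[ii, jj], kind="stable")
    for m in order:
        i, j = ia[ii[m]], ib[jj[m]]
        if consumed[i] or consumed[j]:
            continue
        if rng.random() >= spec.probability:
            continue
        consumed[i] = consumed[j] = True
        p.alive[i] = p.alive[j] = False
        mid = 0.5 * (p.x[i] + p.x[j])
        if len(spec.products) == 1:
            spawns.append((mid[None, :].copy(), [spec.products[0]], i))
        elif len(spec.products) == 2:
            spawns.append((np.stack([p.x[i], p.x[j]]), list(spec.products), i))
        _log(events, t, "reaction", f"{a}+{b}",
             "+".join(map(str, spec.products)) or "0", mid)


def photobleach(p: ParticleSet, region: BleachRegion, t, dt, rng, events=None):
    """Bernoulli decay of particles inside the bleach sphere (in place).

    Each alive particle inside the sphere is removed independently with
    probability ``k_deg * dt``; particles outside are untouched.
    """
    prob = region.k_deg * dt
    if prob > 1.0:
        raise ValueError(f"k_deg * dt = {prob} exceeds 1; reduce the time step")
    idx = np.flatnonzero(p.alive)
    if idx.size == 0:
        return []
    c = region.centre_at(t)
    d2 = np.einsum("ij,ij->i", p.x[idx] - c, p.x[idx] - c)
    inside = d2 < region.r_photo ** 2
    hit = idx[inside][rng.random(int(inside.sum())) < prob]
    p.alive[hit] = False
    new_events = []
    sink = events if events is not None else new_events
    for i in hit:
        _log(sink, t, "bleach", str(p.species[i]), "0", p.x[i])
    return sink
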