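"""Reaction channels and photobleaching sinks."""
import numpy as np
import pytest

from mobosim.geometry import static_circle
from mobosim.reactions import (ReactionSpec, BleachRegion, detect_and_execute,
                               photobleach)
from mobosim.volume import ParticleSet, SimulationConfig, simulate_volume

A, B, C = 0, 1, 2


def make_set(positions, species, rep=None):
    positions = np.atleast_2d(positions)
    rep = np.zeros(len(positions), dtype=int) if rep is None else rep
    return ParticleSet(x=positions, D=0.1, radius=0.0, species=species, rep=rep)


class TestReactionSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            ReactionSpec(reactants=(A, B), threshold=-1.0)
        with pytest.raises(ValueError):
            ReactionSpec(reactants=(A, B), threshold=0.1, probability=1.5)
        with pytest.raises(ValueError):
            ReactionSpec(reactants=(A, B, C), threshold=0.1)

    def test_default_placements(self):
        assert ReactionSpec((A, B), 0.1, products=(C,)).placement == "midpoint"
        assert ReactionSpec((A,), 0.1, products=(B, C)).placement == "poles"


class TestBinaryAnnihilation:
    def test_pair_within_threshold_reacts_at_midpoint(self, rng):
        p = make_set([[0, 0, 0], [0.3, 0, 0]], [A, B])
        spec = ReactionSpec((A, B), threshold=0.4, probability=1.0)
        events = detect_and_execute(p, [spec], 1.0, rng)
        assert not p.alive.any()
        assert len(events) == 1
        np.testing.assert_allclose(events[0]["pos"], [0.15, 0, 0])

    def test_pair_beyond_threshold_untouched(self, rng):
        p = make_set([[0, 0, 0], [0.5, 0, 0]], [A, B])
        spec = ReactionSpec((A, B), threshold=0.4, probability=1.0)
        assert detect_and_execute(p, [spec], 1.0, rng) == []
        assert p.alive.all()

    def test_cross_replicate_pairs_ignored(self, rng):
        p = make_set([[0, 0, 0], [0.1, 0, 0]], [A, B], rep=np.array([0, 1]))
        spec = ReactionSpec((A, B), threshold=0.4, probability=1.0)
        detect_and_execute(p, [spec], 1.0, rng)
        assert p.alive.all()

    def test_each_particle_reacts_at_most_once(self, rng):
        # one B between two As: only the closer pair fires
        p = make_set([[0, 0, 0], [0.1, 0, 0], [0.25, 0, 0]], [A, B, A])
        spec = ReactionSpec((A, B), threshold=0.4, probability=1.0)
        events = detect_and_execute(p, [spec], 1.0, rng)
        assert len(events) == 1
        assert p.alive.tolist() == [False, False, True]

    def test_matches_brute_force_pairing_oracle(self, rng):
        # independent O(n^2) reimplementation of the pairing rule: eligible
        # pairs sorted by distance, closer pairs first, single use per particle
        for trial in range(20):
            n = 12
            pos = rng.random((n, 3)) * 2.0
            species = rng.integers(0, 2, size=n)
            lam = float(rng.uniform(0.2, 1.0))
            p = make_set(pos.copy(), species.copy())
            spec = ReactionSpec((A, B), threshold=lam, probability=1.0)
            detect_and_execute(p, [spec], 0.0, rng)

            used = np.zeros(n, dtype=bool)
            pairs = [(np.linalg.norm(pos[i] - pos[j]), i, j)
                     for i in range(n) for j in range(n)
                     if species[i] == A and species[j] == B]
            for d, i, j in sorted(pairs):
                if d <= lam and not used[i] and not used[j]:
                    used[i] = used[j] = True
            np.testing.assert_array_equal(p.alive, ~used)

    def test_two_products_placed_at_reactant_positions(self, rng):
        p = make_set([[0, 0, 0], [0.2, 0, 0]], [A, B])
        spec = ReactionSpec((A, B), threshold=0.4, products=(C, C))
        detect_and_execute(p, [spec], 0.0, rng)
        new = p.x[p.alive]
        np.testing.assert_allclose(sorted(new[:, 0]), [0.0, 0.2])
        assert (p.species[p.alive] == C).all()


class TestUnaryChannels:
    def test_unary_two_products_at_opposite_poles(self, rng):
        p = make_set([[1.0, 1.0, 1.0]], [A])
        spec = ReactionSpec((A,), threshold=0.3, products=(B, C))
        detect_and_execute(p, [spec], 0.0, rng)
        new = p.x[p.alive]
        assert len(new) == 2
        # poles are antipodal on a sphere whose diameter is the largest
        # threshold in the system
        np.testing.assert_allclose(0.5 * (new[0] + new[1]), [1, 1, 1], atol=1e-12)
        assert np.linalg.norm(new[0] - new[1]) == pytest.approx(0.3)

    def test_unary_decay_survival(self, rng):
        n, prob, steps = 5000, 0.1, 10
        p = make_set(np.zeros((n, 3)), [A] * n)
        spec = ReactionSpec((A,), threshold=0.0, probability=prob)
        for _ in range(steps):
            detect_and_execute(p, [spec], 0.0, rng)
        expect = n * (1 - prob) ** steps
        assert abs(p.alive.sum() - expect) < 4 * np.sqrt(expect)


class TestPhotobleach:
    def test_outside_region_always_survives(self, rng):
        p = make_set([[5.0, 0, 0]], [A])
        region = BleachRegion(np.zeros(3), r_photo=1.0, k_deg=2.0)
        for _ in range(100):
            photobleach(p, region, 0.0, 0.4, rng)
        assert p.alive.all()

    def test_per_step_probability_is_kdeg_dt(self):
        region = BleachRegion(np.zeros(3), r_photo=1.0, k_deg=2.0)
        assert region.k_deg * 0.00005 == pytest.approx(0.0001)

    def test_kdeg_dt_above_one_rejected(self, rng):
        p = make_set([[0.0, 0, 0]], [A])
        region = BleachRegion(np.zeros(3), r_photo=1.0, k_deg=2.0)
        with pytest.raises(ValueError):
            photobleach(p, region, 0.0, 0.6, rng)

    def test_pinned_particles_decay_exponentially(self, rng):
        # closed form in the always-inside limit: survival (1 - k dt)^m ~ e^-kt
        n, k_deg, dt, steps = 10_000, 2.0, 0.001, 500
        p = make_set(np.zeros((n, 3)), [A] * n)
        region = BleachRegion(np.zeros(3), r_photo=1.0, k_deg=k_deg)
        for _ in range(steps):
            photobleach(p, region, 0.0, dt, rng)
        expect = n * np.exp(-k_deg * dt * steps)
        assert abs(p.alive.sum() - expect) < 4 * np.sqrt(expect)

    def test_bleaching_monotone_in_kdeg_with_coupled_seeds(self):
        survivors = []
        for k_deg in (0.5, 1.0, 2.0):
            cfg = SimulationConfig(dt=0.01, t_end=2.0, seed=17)
            rng = cfg.rng(0)
            p = make_set(np.zeros((500, 2)), [A] * 500)
            p.x += 0.01 * rng.standard_normal(p.x.shape)
            region = BleachRegion(np.zeros(2), r_photo=5.0, k_deg=k_deg)
            traj = simulate_volume(static_circle(3.0), p, cfg, bleach=region,
                                   rng=cfg.rng(1))
            survivors.append(len(traj.frames))
        assert survivors[0] >= survivors[1] >= survivors[2]

    def test_species_balance_against_event_log(self, rng):
        cfg = SimulationConfig(dt=0.01, t_end=1.0, seed=23)
        p = make_set(np.zeros((300, 2)), [A] * 300)
        region = BleachRegion(np.zeros(2), r_photo=0.5, k_deg=5.0)
        traj = simulate_volume(static_circle(3.0),
                               ParticleSet(x=p.x, D=0.5, radius=0.0,
                                           species=p.species, rep=p.rep),
                               cfg, bleach=region, rng=cfg.rng(0))
        survivors = len(traj.frames)
        bleached = (traj.events["event_type"] == "bleach").sum()
        assert survivors + bleached == 300
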