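"""Uniformization coupling, acceptance maps and the SSA reference simulator."""

import numpy as np
import pytest

from scrncmp import (
    GroupStructure,
    PropensityPair,
    build_generator,
    couple_paths,
    derive_transition_structure,
    enumerate_states,
    leq_A,
    make_example,
    parse_network,
    phi,
    psi,
    ssa_path,
    transient_distribution,
    uniformization_rate,
)


def _birth_death(L=6, birth=1.0, death=1.0):
    net = parse_network({
        "species": ["X"], "parameters": {},
        "reactions": [
            {"reactant": {}, "product": {"X": 1},
             "rate": {"type": "mass_action", "kappa": birth}},
            {"reactant": {"X": 1}, "product": {},
             "rate": {"type": "mass_action", "kappa": death}},
        ],
    })
    space = enumerate_states(net, (0,), bound=L)
    ts = derive_transition_structure(net, space)
    return ts


class TestUniformizationRate:
    def test_exceeds_strict_bound(self, ek1_pair):
        # sup of the total rate over the 9 states is 6 (at s), n = 3
        lam = uniformization_rate(ek1_pair)
        assert lam > 18.0
        n = ek1_pair.n
        for x in ek1_pair.space.states:
            for r in ek1_pair.base.rates(x) + ek1_pair.modified.rates(x):
                assert r / lam < 1.0 / n

    def test_frozen_pair_gets_unit_rate(self):
        net = parse_network({
            "species": ["X"], "parameters": {},
            "reactions": [{"reactant": {"X": 2}, "product": {"X": 3},
                           "rate": {"type": "mass_action", "kappa": 1.0}}],
        })
        space = enumerate_states(net, (0,), bound=1)
        ts = derive_transition_structure(net, space)
        pair = PropensityPair(ts, derive_transition_structure(net, space, ts.vectors))
        assert uniformization_rate(pair) == 1.0


class TestPhi:
    def test_interval_placement(self):
        # two directions, first interval [0, 1/20): u below jumps, u above loops
        ts = _birth_death(L=6)
        lam = 20.0
        x = (3,)  # rates (1, 3)
        assert phi(ts, lam, x, 0.04) == (4,)
        assert phi(ts, lam, x, 0.2) == (3,)
        # second block starts at 1/2 with length 3/20
        assert phi(ts, lam, x, 0.5) == (2,)
        assert phi(ts, lam, x, 0.64) == (2,)
        assert phi(ts, lam, x, 0.66) == (3,)

    def test_zero_rates_identity(self):
        ts = _birth_death(L=4)
        lam = 20.0
        # with the boundary-contract rates, birth is forced to zero at the
        # upper bound: only death can fire there
        for u in np.linspace(0, 1, 33):
            out = phi(ts, lam, (4,), u, truncated=False)
            assert out in {(4,), (3,)}
        # a state with no active direction is a fixed point of the map
        net = parse_network({
            "species": ["X"], "parameters": {},
            "reactions": [{"reactant": {"X": 3}, "product": {"X": 4},
                           "rate": {"type": "mass_action", "kappa": 1.0}}],
        })
        space = enumerate_states(net, (1,), bound=2)
        frozen = derive_transition_structure(net, space)
        for u in np.linspace(0, 1, 17):
            assert phi(frozen, 5.0, (1,), u) == (1,)
        # u = 1 is remapped to the self-loop
        assert phi(ts, lam, (2,), 1.0) == (2,)

    def test_jump_fraction_matches_interval_lengths(self):
        ts = _birth_death(L=6)
        lam = 20.0
        x = (2,)
        grid = (np.arange(20000) + 0.5) / 20000
        outcomes = [phi(ts, lam, x, u) for u in grid]
        up = sum(o == (3,) for o in outcomes) / grid.size
        down = sum(o == (1,) for o in outcomes) / grid.size
        assert up == pytest.approx(1.0 / lam, abs=1e-4)
        assert down == pytest.approx(2.0 / lam, abs=1e-4)

    def test_ordered_pair_nesting(self, ek1_pair, ek1):
        # the one-step maps of a verified pair preserve the cone order for
        # every shared draw (the coupling's inductive step)
        lam = uniformization_rate(ek1_pair)
        grid = np.linspace(0, 1, 201)
        for x in ek1_pair.space.states:
            for y in ek1_pair.space.states:
                if not leq_A(ek1.A, x, y):
                    continue
                for u in grid:
                    nx = phi(ek1_pair.base, lam, x, u)
                    ny = phi(ek1_pair.modified, lam, y, u)
                    assert leq_A(ek1.A, nx, ny)


class TestPsi:
    def test_singleton_groups_reduce_to_phi(self, ek1_pair, ek1):
        lam = uniformization_rate(ek1_pair)
        gs = GroupStructure.from_vectors(ek1.A, ek1_pair.vectors)
        assert all(len(g) == 1 for g in gs.groups)
        for x in ek1_pair.space.states:
            for u in np.linspace(0, 1, 101):
                assert psi(ek1_pair.base, lam, gs, x, u) == phi(
                    ek1_pair.base, lam, x, u
                )

    def test_braess_grouped_nesting(self, braess):
        pair = braess.pair()
        lam = uniformization_rate(pair)
        gs = GroupStructure.from_vectors(braess.A, pair.vectors)
        assert sorted(len(g) for g in gs.groups) == [1, 2, 2]
        grid = np.linspace(0, 1, 201)
        for x in pair.space.states:
            for y in pair.space.states:
                if not leq_A(braess.A, x, y):
                    continue
                for u in grid:
                    nx = psi(pair.base, lam, gs, x, u)
                    ny = psi(pair.modified, lam, gs, y, u)
                    assert leq_A(braess.A, nx, ny)

    def test_group_block_lengths(self, braess):
        pair = braess.pair()
        lam = uniformization_rate(pair)
        gs = GroupStructure.from_vectors(braess.A, pair.vectors)
        n = pair.n
        for x in pair.space.states:
            rates = pair.base.rates(x)
            for k, g in enumerate(gs.groups):
                assert sum(rates[j] for j in g) / lam < len(g) / n


class TestCouplePaths:
    def test_verified_pair_stays_ordered(self, ek1, ek1_pair):
        s = ek1.states["s"]
        for k in range(50):
            tr = couple_paths(ek1_pair, ek1.A, s, s, 10.0, seed=[101, k])
            assert tr.ordered
            assert not tr.violation_times

    def test_identical_dynamics_identical_paths(self):
        b = make_example("ek1", kappa3_breve=1.0)
        pair = b.pair()
        s = b.states["s"]
        tr = couple_paths(pair, b.A, s, s, 10.0, seed=7)
        assert tr.states_base == tr.states_modified
        assert tr.ordered

    def test_same_seed_bit_identical(self, ek1, ek1_pair):
        s = ek1.states["s"]
        t1 = couple_paths(ek1_pair, ek1.A, s, s, 5.0, seed=99)
        t2 = couple_paths(ek1_pair, ek1.A, s, s, 5.0, seed=99)
        assert t1.times == t2.times
        assert t1.states_base == t2.states_base
        assert t1.states_modified == t2.states_modified

    def test_unverified_pair_can_violate(self, ek1_neg):
        pair = ek1_neg.pair()
        s = ek1_neg.states["s"]
        violated = 0
        for k in range(50):
            tr = couple_paths(
                pair, ek1_neg.A, s, s, 10.0, seed=[13, k], require_ordered=False
            )
            violated += not tr.ordered
        assert violated > 0

    def test_unordered_start_rejected(self, ek1, ek1_pair):
        with pytest.raises(ValueError, match="initial"):
            couple_paths(ek1_pair, ek1.A, ek1.states["p"], ek1.states["s"], 1.0, 0)

    def test_truncation_exit_flagged(self):
        # pure birth at rate 5 with bound 3: the chain exits the truncation
        # by one step and freezes
        net = parse_network({
            "species": ["X"], "parameters": {},
            "reactions": [{"reactant": {}, "product": {"X": 1},
                           "rate": {"type": "mass_action", "kappa": 5.0}}],
        })
        space = enumerate_states(net, (0,), bound=3)
        ts = derive_transition_structure(net, space)
        pair = PropensityPair(ts, derive_transition_structure(net, space, ts.vectors))
        tr = couple_paths(pair, [[1]], (0,), (0,), 10.0, seed=1)
        assert tr.exited_base and tr.exited_modified
        assert tr.states_base[-1] == (4,)
        assert tr.exit_time is not None

    def test_marginal_matches_exact_law(self, ek1, ek1_pair):
        # occupancy of the base marginal at t=1 vs the uniformized series
        space = ek1_pair.space
        s = ek1.states["s"]
        gen = build_generator(ek1_pair.base, space)
        exact = transient_distribution(gen, s, 1.0)
        n_rep = 2000
        counts = np.zeros(len(space))
        for k in range(n_rep):
            tr = couple_paths(ek1_pair, ek1.A, s, s, 1.0, seed=[202, k])
            counts[space.index[tr.states_base[-1]]] += 1
        phat = counts / n_rep
        se = np.sqrt(exact * (1 - exact) / n_rep)
        assert np.all(np.abs(phat - exact) <= 3.5 * se + 1e-9)


class TestSSA:
    def test_single_conversion_hitting_time_exponential(self):
        kappa = 2.0
        net = parse_network({
            "species": ["S", "P"], "parameters": {},
            "reactions": [{"reactant": {"S": 1}, "product": {"P": 1},
                           "rate": {"type": "mass_action", "kappa": kappa}}],
        })
        space = enumerate_states(net, (1, 0))
        ts = derive_transition_structure(net, space)
        n_rep = 10_000
        samples = np.empty(n_rep)
        for k in range(n_rep):
            path = ssa_path(ts, (1, 0), 1e6, seed=[303, k])
            samples[k] = path.times[1]
        mean, se = samples.mean(), samples.std(ddof=1) / np.sqrt(n_rep)
        assert abs(mean - 1.0 / kappa) < 3 * se

    def test_absorbed_state_constant_path(self):
        net = parse_network({
            "species": ["S", "P"], "parameters": {},
            "reactions": [{"reactant": {"S": 1}, "product": {"P": 1},
                           "rate": {"type": "mass_action", "kappa": 1.0}}],
        })
        space = enumerate_states(net, (1, 0))
        ts = derive_transition_structure(net, space)
        path = ssa_path(ts, (0, 1), 10.0, seed=4)
        assert path.times == [0.0]
        assert path.states == [(0, 1)]

    def test_embedded_jump_frequencies(self):
        # at x=2 the birth-death chain jumps up with probability 1/3
        ts = _birth_death(L=10, birth=1.0, death=1.0)
        n_rep = 6000
        ups = 0
        for k in range(n_rep):
            # short horizon: only the first jump from x0 is inspected
            path = ssa_path(ts, (2,), 30.0, seed=[404, k])
            assert len(path.states) > 1
            ups += path.states[1] == (3,)
        p_up = 1.0 / 3.0
        se = np.sqrt(p_up * (1 - p_up) / n_rep)
        assert abs(ups / n_rep - p_up) < 3 * se

    def test_state_at_lookup(self):
        ts = _birth_death(L=5)
        path = ssa_path(ts, (0,), 5.0, seed=8)
        assert path.state_at(0.0) == (0,)
        assert path.state_at(1e9) == path.states[-1]
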