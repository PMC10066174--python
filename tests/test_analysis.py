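"""Stationary laws, first-passage times and transient probabilities."""

import numpy as np
import pytest
from scipy.integrate import quad

from scrncmp import (
    ReducibleChainError,
    build_generator,
    check_boundary,
    derive_transition_structure,
    enumerate_increasing_sets,
    enumerate_states,
    hitting_dominance,
    make_example,
    mfpt,
    parse_network,
    product_form_pi,
    stationary,
    transient_prob,
)


def _two_state(a=2.0, b=3.0):
    net = parse_network({
        "species": ["X"], "parameters": {},
        "reactions": [
            {"reactant": {}, "product": {"X": 1},
             "rate": {"type": "mass_action", "kappa": a}},
            {"reactant": {"X": 1}, "product": {},
             "rate": {"type": "mass_action", "kappa": b}},
        ],
    })
    space = enumerate_states(net, (0,), bound=1)
    ts = derive_transition_structure(net, space)
    return build_generator(ts, space), space


class TestStationary:
    def test_two_state_closed_form(self):
        gen, space = _two_state(a=2.0, b=3.0)
        pi = stationary(gen)
        assert pi[(0,)] == pytest.approx(3.0 / 5.0, rel=1e-12)
        assert pi[(1,)] == pytest.approx(2.0 / 5.0, rel=1e-12)
        assert pi.pi.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(pi.pi >= 0)

    def test_reducible_chain_rejected(self, ek1):
        # the closed enzyme chain absorbs at the all-product state
        space = ek1.space()
        gen = build_generator(derive_transition_structure(ek1.base, space), space)
        with pytest.raises(ReducibleChainError, match="closed"):
            stationary(gen)

    def test_balance_residual(self, chromatin):
        space = chromatin.space()
        gen = build_generator(derive_transition_structure(chromatin.base, space), space)
        pi = stationary(gen)
        assert np.abs(pi.pi @ gen.Q.toarray()).max() < 1e-12


class TestProductForm:
    def test_unit_rates_equilibrium(self):
        dist = product_form_pi([1] * 6, E_tot=2, bound=12)
        pf = dist.product_form
        assert (pf.c1, pf.c2, pf.c3, pf.c4) == (1.0, 1.0, 0.5, 0.5)

    @pytest.mark.parametrize("kappas", [(1, 2, 3, 4, 5, 6), (0.5, 1.5, 2.0, 0.7, 1.1, 0.9)])
    def test_enzyme_split_is_complementary(self, kappas):
        dist = product_form_pi(kappas, E_tot=3, bound=10)
        pf = dist.product_form
        assert pf.c3 + pf.c4 == pytest.approx(1.0, abs=1e-12)

    def test_enzyme_marginal_is_binomial(self):
        from scipy.stats import binom

        E = 2
        dist = product_form_pi([1, 2, 1, 1, 2, 1], E_tot=E, bound=25)
        pf = dist.product_form
        marg = np.zeros(E + 1)
        for (x1, x2, x3, x4), p in zip(dist.space.states, dist.pi):
            marg[x4] += p
        expected = binom.pmf(np.arange(E + 1), E, pf.c4)
        assert np.abs(marg - expected).max() < 1e-9

    def test_matches_truncated_linear_solve(self):
        b = make_example("ek2")
        space = b.space(bound=25)
        gen = build_generator(derive_transition_structure(b.base, space), space)
        pi = stationary(gen)
        pf = product_form_pi([1] * 6, E_tot=2, space=space)
        assert np.abs(pi.pi - pf.pi).max() < 1e-8
        assert pi.boundary_mass < 1e-8

    def test_truncation_error_nonincreasing_in_bound(self):
        b = make_example("ek2")
        diffs = []
        for M in (8, 14, 20):
            space = b.space(bound=M)
            gen = build_generator(derive_transition_structure(b.base, space), space)
            pi = stationary(gen)
            pf = product_form_pi([1] * 6, E_tot=2, space=space)
            diffs.append(np.abs(pi.pi - pf.pi).max())
        assert diffs[1] <= diffs[0] + 1e-12
        assert diffs[2] <= diffs[1] + 1e-12


class TestMFPT:
    def test_single_conversion_mean(self):
        kappa = 4.0
        net = parse_network({
            "species": ["S", "P"], "parameters": {},
            "reactions": [{"reactant": {"S": 1}, "product": {"P": 1},
                           "rate": {"type": "mass_action", "kappa": kappa}}],
        })
        space = enumerate_states(net, (1, 0))
        gen = build_generator(derive_transition_structure(net, space), space)
        h = mfpt(gen, [(0, 1)])
        assert h[space.index[(1, 0)]] == pytest.approx(1.0 / kappa, rel=1e-12)

    def test_target_equals_space_gives_zero(self, chromatin):
        space = chromatin.space()
        gen = build_generator(derive_transition_structure(chromatin.base, space), space)
        assert np.all(mfpt(gen, space.states) == 0.0)

    def test_unreachable_target_is_infinite(self, braess):
        space = braess.space()
        gen = build_generator(derive_transition_structure(braess.base, space), space)
        # nothing flows backwards from the sink species to the source
        h = mfpt(gen, [braess.states["start"]])
        assert np.isinf(h[space.index[braess.states["target"]]])

    def test_decreasing_in_catalytic_constant(self):
        means = []
        for k3 in (0.5, 1.0, 2.0, 4.0):
            b = make_example("ek1", kappa3=k3)
            space = b.space()
            gen = build_generator(derive_transition_structure(b.base, space), space)
            h = mfpt(gen, [b.states["p"]])
            means.append(h[space.index[b.states["s"]]])
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_agrees_with_survival_quadrature(self):
        # E[T] = ∫ P(T > t) dt, with the survival function evaluated through
        # the absorbing chain's transient probabilities
        gen, space = _two_state(a=1.0, b=2.5)
        target = [(1,)]
        h = mfpt(gen, target)[space.index[(0,)]]
        import scipy.sparse as sp

        Q = gen.Q.tolil(copy=True)
        Q.rows[space.index[(1,)]] = []
        Q.data[space.index[(1,)]] = []
        from scrncmp import GeneratorMatrix

        gen_abs = GeneratorMatrix(Q.tocsr(), space)
        integral, err = quad(
            lambda t: 1.0 - transient_prob(gen_abs, (0,), t, target), 0, 60,
            limit=200,
        )
        assert integral == pytest.approx(h, rel=1e-6)


class TestBraessInsensitivity:
    def test_equal_exit_rates_make_passage_time_insensitive(self):
        means = []
        for k5 in (0.0, 1.0, 5.0):
            b = make_example(
                "braess", S_tot=3, kappa1=1.0, kappa2=2.0, kappa3=1.0,
                kappa4=2.0, kappa5=k5,
            )
            space = b.space()
            gen = build_generator(derive_transition_structure(b.base, space), space)
            h = mfpt(gen, [b.states["target"]])
            means.append(h[space.index[b.states["start"]]])
        ref = means[0]
        assert all(abs(m - ref) <= 1e-8 * ref for m in means)

    @pytest.mark.parametrize(
        "k2, k4, expect_increase", [(3.0, 1.0, True), (1.0, 3.0, False)]
    )
    def test_unequal_exit_rates_break_the_tie(self, k2, k4, expect_increase):
        means = []
        for k5 in (0.0, 1.0):
            b = make_example(
                "braess", S_tot=3, kappa2=k2, kappa4=k4, kappa5=k5
            )
            space = b.space()
            gen = build_generator(derive_transition_structure(b.base, space), space)
            h = mfpt(gen, [b.states["target"]])
            means.append(h[space.index[b.states["start"]]])
        if expect_increase:
            assert means[1] > means[0] * (1 + 1e-9)
        else:
            assert means[1] < means[0] * (1 - 1e-9)


class TestTransient:
    def test_time_zero_is_indicator(self, chromatin):
        space = chromatin.space()
        gen = build_generator(derive_transition_structure(chromatin.base, space), space)
        a = chromatin.states["a"]
        r = chromatin.states["r"]
        assert transient_prob(gen, a, 0.0, [a]) == 1.0
        assert transient_prob(gen, a, 0.0, [r]) == 0.0

    def test_long_time_approaches_stationarity(self):
        gen, space = _two_state(a=2.0, b=3.0)
        pi = stationary(gen)
        p = transient_prob(gen, (0,), 50.0, [(1,)])
        assert p == pytest.approx(pi[(1,)], abs=1e-10)

    def test_dominance_under_verified_conditions(self, chromatin):
        pair = chromatin.pair()
        assert check_boundary(pair, chromatin.A).verdict
        space = pair.space
        gen = build_generator(pair.base, space)
        gen_b = build_generator(pair.modified, space)
        a = chromatin.states["a"]
        gamma = [a]  # the fully active state is maximal, hence increasing
        for t in (0.1, 1.0, 10.0):
            p = transient_prob(gen, chromatin.states["r"], t, gamma)
            pb = transient_prob(gen_b, chromatin.states["r"], t, gamma)
            assert p <= pb + 1e-9


class TestHittingDominance:
    def test_enzyme_completion_dominance(self, ek1):
        pair = ek1.pair()
        rep = hitting_dominance(
            pair, ek1.A, [ek1.states["p"]],
            (ek1.states["s"], ek1.states["s"]), [0.5, 1, 2, 5, 10],
        )
        assert rep.direction == "increasing"
        assert rep.pointwise_ok and rep.mean_ok
        assert rep.mean_modified < rep.mean_base

    def test_identical_chains_coincide(self):
        b = make_example("ek1", kappa3_breve=1.0)
        rep = hitting_dominance(
            b.pair(), b.A, [b.states["p"]], (b.states["s"], b.states["s"]), [1, 3]
        )
        assert rep.survival_base == pytest.approx(rep.survival_modified, abs=1e-12)
        assert rep.mean_base == pytest.approx(rep.mean_modified, rel=1e-12)

    def test_chromatin_memory_loss_times(self, chromatin):
        pair = chromatin.pair()
        a, r = chromatin.states["a"], chromatin.states["r"]
        to_active = hitting_dominance(pair, chromatin.A, [a], (r, r), [1, 5])
        assert to_active.direction == "increasing"
        assert to_active.mean_modified <= to_active.mean_base
        to_repressed = hitting_dominance(pair, chromatin.A, [r], (a, a), [1, 5])
        assert to_repressed.direction == "decreasing"
        assert to_repressed.mean_base <= to_repressed.mean_modified

    def test_non_monotone_target_rejected(self, ek1):
        with pytest.raises(ValueError, match="neither"):
            hitting_dominance(
                ek1.pair(), ek1.A, [(2, 1, 2, 0)],
                (ek1.states["s"], ek1.states["s"]), [1.0],
            )


class TestStationaryMonotonicity:
    def test_exhaustive_over_increasing_sets(self):
        b = make_example("chromatin", D_tot=2)
        pair = b.pair()
        assert check_boundary(pair, b.A).verdict
        space = pair.space
        pi = stationary(build_generator(pair.base, space))
        pi_b = stationary(build_generator(pair.modified, space))
        for gamma in enumerate_increasing_sets(b.A, space):
            if gamma:
                assert pi.prob(gamma) <= pi_b.prob(gamma) + 1e-9
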