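"""Ready-made comparison bundles for five benchmark reaction networks.

Each bundle packages a base network, a modified network differing in one
distinguished rate parameter, the comparison matrix under which the modified
chain dominates the base chain, canonical initial states and named target
sets, and the condition set (theorem tag) that certifies the ordering:

* ``ek1`` — closed Michaelis–Menten enzyme kinetics (S, P, E, SE); raising
  the catalytic constant k3 speeds conversion of substrate to product.
* ``ek2`` — open enzyme kinetics with substrate inflow/outflow and reverse
  conversion; raising the inflow constant k5 shifts the stationary law.  The
  chain is countably infinite: a sup-norm truncation bound is required.
* ``braess`` — a four-species relay inspired by Braess' paradox; with equal
  exit constants k2 = k4 the passage time to the final species is
  insensitive to the cross-link constant k5 (grouped conditions).
* ``chromatin`` — the reduced two-variable histone-modification circuit;
  raising the asymmetry mu favours the active state.
* ``chromatin_tf`` — the same circuit with a protein-mediated positive
  feedback through a bounded monotone activation g (a Hill function by
  default); raising the protein production constant k5a shortens gene
  reactivation.  Requires a truncation bound for the protein count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .conditions import PropensityPair
from .network import (
    ExpressionRate,
    MassAction,
    Reaction,
    ReactionNetwork,
    StateSpace,
    derive_transition_structure,
    enumerate_states,
)
from .preorder import ComparisonMatrix

__all__ = ["ExampleBundle", "make_example", "random_network", "EXAMPLE_NAMES"]

logger = logging.getLogger(__name__)

EXAMPLE_NAMES = ("ek1", "ek2", "braess", "chromatin", "chromatin_tf")


@dataclass
class ExampleBundle:
    """A base/modified network pair wired for the comparison machinery."""

    name: str
    base: ReactionNetwork
    modified: ReactionNetwork
    A: ComparisonMatrix
    origin: tuple[int, ...]
    theorem: str  # condition set certifying the ordering
    distinguished: str  # the parameter that differs between base and modified
    states: dict[str, tuple[int, ...]] = field(default_factory=dict)
    predicates: dict[str, Callable[[tuple[int, ...]], bool]] = field(
        default_factory=dict
    )
    needs_bound: bool = False

    def space(self, bound: int | None = None) -> StateSpace:
        if self.needs_bound and bound is None:
            raise ValueError(
                f"example {self.name!r} has an infinite state space; a "
                "truncation bound M is required"
            )
        return enumerate_states(self.base, self.origin, bound)

    def pair(self, bound: int | None = None, space: StateSpace | None = None) -> PropensityPair:
        space = space if space is not None else self.space(bound)
        base_ts = derive_transition_structure(self.base, space)
        mod_ts = derive_transition_structure(self.modified, space, base_ts.vectors)
        return PropensityPair(base_ts, mod_ts)

    def target_set(self, name: str, space: StateSpace) -> list[tuple[int, ...]]:
        if name in self.states:
            return [self.states[name]]
        pred = self.predicates[name]
        return [x for x in space.states if pred(x)]


def _ma(reactant, product, ref: str) -> Reaction:
    # placeholder kappa; resolved against parameters at network build
    return Reaction(tuple(reactant), tuple(product), MassAction(1.0, ref))


def _build(species, raw_reactions, params) -> ReactionNetwork:
    reactions = []
    for rx in raw_reactions:
        rate = rx.rate
        if isinstance(rate, MassAction) and rate.kappa_ref is not None:
            rate = MassAction(params[rate.kappa_ref], rate.kappa_ref)
        reactions.append(Reaction(rx.reactant, rx.product, rate))
    return ReactionNetwork(species, reactions, params)


def _ek1(S_tot: int, E_tot: int, params: Mapping[str, float]) -> ExampleBundle:
    defaults = {"kappa1": 1.0, "kappa2": 1.0, "kappa3": 1.0}
    base_params = {**defaults, **params}
    breve = dict(base_params)
    breve["kappa3"] = params.get("kappa3_breve", 2.0 * base_params["kappa3"])
    species = ["S", "P", "E", "SE"]
    reactions = [
        _ma((1, 0, 1, 0), (0, 0, 0, 1), "kappa1"),  # S + E -> SE
        _ma((0, 0, 0, 1), (1, 0, 1, 0), "kappa2"),  # SE -> S + E
        _ma((0, 0, 0, 1), (0, 1, 1, 0), "kappa3"),  # SE -> P + E
    ]
    s = (S_tot, 0, E_tot, 0)
    p = (0, S_tot, E_tot, 0)
    return ExampleBundle(
        name="ek1",
        base=_build(species, reactions, base_params),
        modified=_build(species, reactions, breve),
        A=ComparisonMatrix([[-1, 0, 0, 0], [0, 1, 0, 0]]),
        origin=s,
        theorem="boundary",
        distinguished="kappa3",
        states={"s": s, "p": p},
    )


def _ek2(E_tot: int, params: Mapping[str, float]) -> ExampleBundle:
    defaults = {f"kappa{i}": 1.0 for i in range(1, 7)}
    base_params = {**defaults, **params}
    breve = dict(base_params)
    breve["kappa5"] = params.get("kappa5_breve", 2.0 * base_params["kappa5"])
    species = ["S", "P", "E", "SE"]
    reactions = [
        _ma((1, 0, 1, 0), (0, 0, 0, 1), "kappa1"),  # S + E -> SE
        _ma((0, 0, 0, 1), (1, 0, 1, 0), "kappa2"),  # SE -> S + E
        _ma((0, 0, 0, 1), (0, 1, 1, 0), "kappa3"),  # SE -> P + E
        _ma((0, 1, 1, 0), (0, 0, 0, 1), "kappa4"),  # P + E -> SE
        _ma((0, 0, 0, 0), (1, 0, 0, 0), "kappa5"),  # 0 -> S
        _ma((1, 0, 0, 0), (0, 0, 0, 0), "kappa6"),  # S -> 0
    ]
    return ExampleBundle(
        name="ek2",
        base=_build(species, reactions, base_params),
        modified=_build(species, reactions, breve),
        A=ComparisonMatrix([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, -1, 0]]),
        origin=(0, 0, E_tot, 0),
        theorem="boundary",
        distinguished="kappa5",
        needs_bound=True,
    )


def _braess(S_tot: int, params: Mapping[str, float]) -> ExampleBundle:
    defaults = {f"kappa{i}": 1.0 for i in range(1, 6)}
    base_params = {**defaults, **params}
    breve = dict(base_params)
    breve["kappa5"] = params.get("kappa5_breve", 2.0 * base_params["kappa5"])
    species = ["S1", "S2", "S3", "S4"]
    reactions = [
        _ma((1, 0, 0, 0), (0, 1, 0, 0), "kappa1"),  # S1 -> S2
        _ma((0, 1, 0, 0), (0, 0, 0, 1), "kappa2"),  # S2 -> S4
        _ma((1, 0, 0, 0), (0, 0, 1, 0), "kappa3"),  # S1 -> S3
        _ma((0, 0, 1, 0), (0, 0, 0, 1), "kappa4"),  # S3 -> S4
        _ma((0, 1, 0, 0), (0, 0, 1, 0), "kappa5"),  # S2 -> S3 (cross-link)
    ]
    start = (S_tot, 0, 0, 0)
    target = (0, 0, 0, S_tot)
    return ExampleBundle(
        name="braess",
        base=_build(species, reactions, base_params),
        modified=_build(species, reactions, breve),
        A=ComparisonMatrix([[-1, 0, 0, 0], [0, -1, -1, 0]]),
        origin=start,
        theorem="grouped",
        distinguished="kappa5",
        states={"start": start, "target": target},
    )


_CHROMATIN_DEFAULTS = {
    "k1a": 1.0,
    "k1b": 1.0,
    "k2a": 1.0,
    "k2b": 1.0,
    "k3a": 1.0,
    "k3b": 1.0,
    "c": 1.0,
    "mu": 1.0,
}


def _chromatin(D_tot: int, params: Mapping[str, float]) -> ExampleBundle:
    base_params = {**_CHROMATIN_DEFAULTS, **params, "Dtot": float(D_tot)}
    if base_params["mu"] <= 0 or base_params["c"] <= 0:
        raise ValueError("mu and c must be positive")
    breve = dict(base_params)
    breve["mu"] = params.get("mu_breve", 2.0 * base_params["mu"])
    species = ["DR", "DA"]
    reactions = [
        Reaction((0, 0), (0, 1), ExpressionRate("(Dtot - (x1 + x2)) * (k1a + k1b * x2)")),
        Reaction((0, 0), (1, 0), ExpressionRate("(Dtot - (x1 + x2)) * (k2a + k2b * x1)")),
        Reaction((0, 1), (0, 0), ExpressionRate("x2 * (k3a + x1 * k3b)")),
        Reaction((1, 0), (0, 0), ExpressionRate("x1 * mu * (c * k3a + x2 * k3b)")),
    ]
    r = (D_tot, 0)
    a = (0, D_tot)
    return ExampleBundle(
        name="chromatin",
        base=_build(species, reactions, base_params),
        modified=_build(species, reactions, breve),
        A=ComparisonMatrix([[-1, 0], [0, 1]]),
        origin=r,
        theorem="boundary",
        distinguished="mu",
        states={"r": r, "a": a},
    )


def _chromatin_tf(D_tot: int, params: Mapping[str, float]) -> ExampleBundle:
    defaults = {
        **_CHROMATIN_DEFAULTS,
        "k1a0": 1.0,
        "k1a1": 1.0,
        "k5a": 1.0,
        "k6a": 1.0,
        "K": 10.0,
        "h": 2.0,
    }
    defaults.pop("k1a")
    base_params = {**defaults, **params, "Dtot": float(D_tot)}
    if base_params["mu"] <= 0 or base_params["c"] <= 0:
        raise ValueError("mu and c must be positive")
    breve = dict(base_params)
    breve["k5a"] = params.get("k5a_breve", 2.0 * base_params["k5a"])
    species = ["DR", "DA", "P"]
    reactions = [
        Reaction(
            (0, 0, 0),
            (0, 1, 0),
            ExpressionRate(
                "(Dtot - (x1 + x2)) * (k1a0 + k1a1 * hill(x3, K, h) + k1b * x2)"
            ),
        ),
        Reaction(
            (0, 0, 0), (1, 0, 0), ExpressionRate("(Dtot - (x1 + x2)) * (k2a + k2b * x1)")
        ),
        Reaction((0, 1, 0), (0, 0, 0), ExpressionRate("x2 * (k3a + x1 * k3b)")),
        Reaction((1, 0, 0), (0, 0, 0), ExpressionRate("x1 * mu * (c * k3a + x2 * k3b)")),
        _ma((0, 1, 0), (0, 1, 1), "k5a"),  # DA -> DA + P
        _ma((0, 0, 1), (0, 0, 0), "k6a"),  # P -> 0
    ]
    r = (D_tot, 0, 0)
    return ExampleBundle(
        name="chromatin_tf",
        base=_build(species, reactions, base_params),
        modified=_build(species, reactions, breve),
        A=ComparisonMatrix([[-1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        origin=r,
        theorem="boundary",
        distinguished="k5a",
        states={"r": r},
        predicates={"theta": lambda x, D=D_tot: x[0] == 0 and x[1] == D},
        needs_bound=True,
    )


def make_example(name: str, **params) -> ExampleBundle:
    """Build one of the five benchmark bundles by name.

    Integer size parameters: ``S_tot``/``E_tot``/``D_tot`` as applicable.
    Rate constants default to 1; the distinguished constant of the modified
    network defaults to twice its base value and can be set via
    ``<name>_breve`` (e.g. ``kappa3_breve=4.0``).
    """
    sizes = {}
    for key in ("S_tot", "E_tot", "D_tot"):
        if key in params:
            sizes[key] = int(params.pop(key))
            if sizes[key] < 1:
                raise ValueError(f"{key} must be a positive integer")
    if name == "ek1":
        return _ek1(sizes.get("S_tot", 3), sizes.get("E_tot", 2), params)
    if name == "ek2":
        return _ek2(sizes.get("E_tot", 2), params)
    if name == "braess":
        return _braess(sizes.get("S_tot", 3), params)
    if name == "chromatin":
        return _chromatin(sizes.get("D_tot", 3), params)
    if name == "chromatin_tf":
        return _chromatin_tf(sizes.get("D_tot", 3), params)
    raise ValueError(f"unknown example {name!r}; choose from {EXAMPLE_NAMES}")


def random_network(
    seed: int,
    d_max: int = 3,
    n_max: int = 6,
    state_cap: int = 14,
) -> tuple[PropensityPair, ComparisonMatrix]:
    """Random small mass-action comparison instance for oracle sweeps.

    Draws a mass-action network on at most ``d_max`` species with a bounded
    reachable space of at most ``state_cap`` states, a perturbed copy (each
    rate constant independently kept or scaled up), and a random integer
    comparison matrix with entries in {-1,0,1}, no zero row, and every image
    A v_j in {-1,0,1}^m (enforced by rejection).  Deterministic in ``seed``;
    if the rejection budget is exhausted the seed is incremented (logged).
    """
    base_seed = int(seed)
    for bump in range(50):
        if bump:
            logger.info("random_network: seed %d exhausted, bumping", base_seed + bump - 1)
        rng = np.random.default_rng([base_seed + bump, 0xC0FFEE])
        for _ in range(200):
            d = int(rng.integers(1, d_max + 1))
            n_rx = int(rng.integers(1, n_max + 1))
            reactions = []
            ok = True
            for _ in range(n_rx):
                for _ in range(20):
                    reac = tuple(int(v) for v in rng.integers(0, 2, d))
                    prod = tuple(int(v) for v in rng.integers(0, 2, d))
                    if reac != prod:
                        break
                else:
                    ok = False
                    break
                kappa = float(rng.uniform(0.5, 1.5))
                reactions.append(Reaction(reac, prod, MassAction(kappa)))
            if not ok:
                continue
            touched = [
                any(rx.reactant[i] or rx.product[i] for rx in reactions)
                for i in range(d)
            ]
            if not all(touched):
                continue
            base = ReactionNetwork([f"S{i + 1}" for i in range(d)], reactions)
            origin = tuple(int(v) for v in rng.integers(0, 2, d))
            bound = int(rng.integers(1, 3))
            if max(origin) > bound:
                continue
            try:
                space = enumerate_states(base, origin, bound, cap=4 * state_cap)
            except Exception:
                continue
            if not (2 <= len(space) <= state_cap):
                continue
            if rng.random() < 0.5:
                mod_reactions = reactions  # identical chains: initial-state monotonicity
            else:
                mod_reactions = [
                    Reaction(
                        rx.reactant,
                        rx.product,
                        MassAction(rx.rate.kappa * float(rng.choice([1.0, 1.25]))),
                    )
                    for rx in reactions
                ]
            mod = ReactionNetwork(base.species, mod_reactions)
            base_ts = derive_transition_structure(base, space)
            mod_ts = derive_transition_structure(mod, space, base_ts.vectors)
            pair = PropensityPair(base_ts, mod_ts)
            for _ in range(60):
                m = int(rng.integers(1, 3))
                A = rng.integers(-1, 2, (m, d))
                if np.any(np.all(A == 0, axis=1)):
                    continue
                imgs = A @ np.asarray(pair.vectors).T
                if np.all(np.abs(imgs) <= 1):
                    return pair, ComparisonMatrix(A)
            # A rejection budget exhausted for this network: redraw network
    raise RuntimeError("random_network: generation budget exhausted")
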