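"""Stochastic chemical reaction networks as continuous-time Markov chains.

A network is a finite species set together with reactions, each reaction a
pair of nonnegative integer stoichiometric vectors (reactant, product) and a
rate law.  The associated Markov chain on molecule counts jumps by the
reaction vector ``product - reactant`` at the state-dependent propensity of
the reaction.  This module provides the network container, propensity
evaluation (mass action with exact falling factorials, or a restricted
expression grammar), state-space enumeration by reachability, aggregation of
reactions sharing a jump direction, and sparse generator assembly.
"""

from __future__ import annotations

import ast
import json
import math
import operator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "NetworkSpecError",
    "PropensityError",
    "StateSpaceError",
    "MassAction",
    "ExpressionRate",
    "Reaction",
    "ReactionNetwork",
    "StateSpace",
    "TransitionStructure",
    "GeneratorMatrix",
    "hill",
    "falling_factorial",
    "evaluate_propensity",
    "parse_network",
    "network_to_dict",
    "enumerate_states",
    "derive_transition_structure",
    "build_generator",
]


class NetworkSpecError(ValueError):
    """Raised for an invalid network specification."""


def _load_json(source: str | Path) -> dict:
    """Accept a JSON document as a string or as a path to a file."""
    text = str(source)
    if not text.lstrip().startswith(("{", "[")):
        try:
            if Path(source).exists():
                text = Path(source).read_text()
        except OSError:
            pass
    return json.loads(text)


class PropensityError(ValueError):
    """Raised when a rate law evaluates to a negative or non-finite value."""


class StateSpaceError(RuntimeError):
    """Raised when state-space enumeration cannot complete."""


def hill(x: float, K: float, h: float) -> float:
    """Bounded monotone activation x**h / (K**h + x**h); hill(0, K, h) = 0."""
    if x <= 0:
        return 0.0
    xh = float(x) ** h
    return xh / (K ** h + xh)


def falling_factorial(m: int, ell: int) -> int:
    """(m)_ell = m (m-1) ... (m-ell+1), with (m)_0 = 1, in exact integers."""
    out = 1
    for k in range(ell):
        out *= m - k
        if out == 0:
            return 0
    return out


# --- restricted expression grammar -----------------------------------------

_ALLOWED_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
    ast.Pow: operator.pow,
}
_ALLOWED_UNARY = {ast.USub: operator.neg, ast.UAdd: operator.pos}


def _validate_expr(node: ast.AST, names: set[str]) -> None:
    if isinstance(node, ast.Expression):
        _validate_expr(node.body, names)
    elif isinstance(node, ast.BinOp) and type(node.op) in _ALLOWED_BINOPS:
        if isinstance(node.op, ast.Pow):
            exp = node.right
            if not (isinstance(exp, ast.Constant) and isinstance(exp.value, int)):
                raise NetworkSpecError("only integer literal exponents are allowed")
        _validate_expr(node.left, names)
        _validate_expr(node.right, names)
    elif isinstance(node, ast.UnaryOp) and type(node.op) in _ALLOWED_UNARY:
        _validate_expr(node.operand, names)
    elif isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        pass
    elif isinstance(node, ast.Name):
        if node.id not in names:
            raise NetworkSpecError(f"unknown name {node.id!r} in rate expression")
    elif isinstance(node, ast.Call):
        if not (isinstance(node.func, ast.Name) and node.func.id == "hill"):
            raise NetworkSpecError("only the builtin hill(x, K, h) may be called")
        if len(node.args) != 3 or node.keywords:
            raise NetworkSpecError("hill takes exactly three positional arguments")
        for a in node.args:
            _validate_expr(a, names)
    else:
        raise NetworkSpecError(
            f"disallowed syntax in rate expression: {ast.dump(node)[:60]}"
        )


def compile_expression(
    expr: str, species: Sequence[str], parameters: Mapping[str, float]
) -> Callable[[Sequence[int]], float]:
    """Compile a whitelisted arithmetic expression over state and parameters.

    Permitted: ``+ - * /``, integer powers, numeric literals, the species
    names, positional aliases ``x1 .. xd``, parameter names, and
    ``hill(x, K, h)``.
    """
    d = len(species)
    aliases = {f"x{i + 1}": i for i in range(d)}
    names = set(aliases) | set(species) | set(parameters) | {"hill"}
    tree = ast.parse(expr, mode="eval")
    _validate_expr(tree, names)
    code = compile(tree, "<rate>", "eval")
    species_idx = {name: i for i, name in enumerate(species)}
    const = dict(parameters)
    const["hill"] = hill

    def fn(x: Sequence[int]) -> float:
        env = dict(const)
        for name, i in aliases.items():
            env[name] = x[i]
        for name, i in species_idx.items():
            env[name] = x[i]
        return eval(code, {"__builtins__": {}}, env)  # noqa: S307 - validated AST

    return fn


# --- rate laws and reactions -----------------------------------------------


@dataclass(frozen=True)
class MassAction:
    """Mass-action kinetics: kappa * prod_i (x_i)_(reactant_i)."""

    kappa: float
    kappa_ref: str | None = None  # parameter name, for lossless round-trips

    def __post_init__(self) -> None:
        if not (self.kappa >= 0 and math.isfinite(self.kappa)):
            raise NetworkSpecError(f"rate constant must be >= 0, got {self.kappa}")


@dataclass(frozen=True)
class ExpressionRate:
    """State-dependent kinetics given by a restricted arithmetic expression."""

    expr: str


@dataclass(frozen=True)
class Reaction:
    reactant: tuple[int, ...]
    product: tuple[int, ...]
    rate: MassAction | ExpressionRate

    def __post_init__(self) -> None:
        if len(self.reactant) != len(self.product):
            raise NetworkSpecError("reactant and product vectors differ in length")
        if any(c < 0 for c in self.reactant) or any(c < 0 for c in self.product):
            raise NetworkSpecError("stoichiometric coefficients must be nonnegative")
        if self.reactant == self.product:
            raise NetworkSpecError(
                "reaction with identical reactant and product vectors is not allowed"
            )

    @property
    def vector(self) -> tuple[int, ...]:
        return tuple(p - r for r, p in zip(self.reactant, self.product))


class ReactionNetwork:
    """Species, reactions and parameters of one reaction network.

    Coordinates follow the declared species order; states are molecule-count
    vectors.  Every species must take part in at least one reaction.
    """

    def __init__(
        self,
        species: Sequence[str],
        reactions: Sequence[Reaction],
        parameters: Mapping[str, float] | None = None,
    ) -> None:
        if len(species) < 1:
            raise NetworkSpecError("at least one species is required")
        if len(set(species)) != len(species):
            raise NetworkSpecError("species names must be distinct")
        if not reactions:
            raise NetworkSpecError("at least one reaction is required")
        self.species = tuple(species)
        self.parameters = dict(parameters or {})
        for name, value in self.parameters.items():
            if not (value >= 0 and math.isfinite(value)):
                raise NetworkSpecError(f"parameter {name!r} must be nonnegative")
        self.reactions = tuple(reactions)
        d = len(self.species)
        touched = [False] * d
        for rx in self.reactions:
            if len(rx.reactant) != d:
                raise NetworkSpecError("reaction dimension does not match species")
            for i in range(d):
                if rx.reactant[i] > 0 or rx.product[i] > 0:
                    touched[i] = True
        missing = [self.species[i] for i, t in enumerate(touched) if not t]
        if missing:
            raise NetworkSpecError(
                f"species {missing} appear in no reaction (each species must be a "
                "reactant or a product)"
            )
        self._compiled: list[Callable[[Sequence[int]], float] | None] = []
        for rx in self.reactions:
            if isinstance(rx.rate, ExpressionRate):
                self._compiled.append(
                    compile_expression(rx.rate.expr, self.species, self.parameters)
                )
            else:
                self._compiled.append(None)

    @property
    def d(self) -> int:
        return len(self.species)

    def propensity(self, reaction_index: int, x: Sequence[int]) -> float:
        """Evaluate the propensity of one reaction at state ``x``."""
        rx = self.reactions[reaction_index]
        if isinstance(rx.rate, MassAction):
            acc = 1
            for xi, ri in zip(x, rx.reactant):
                if ri:
                    acc *= falling_factorial(int(xi), ri)
                    if acc == 0:
                        return 0.0
            return rx.rate.kappa * acc
        fn = self._compiled[reaction_index]
        assert fn is not None
        value = fn(x)
        if not (math.isfinite(value) and value >= 0):
            raise PropensityError(
                f"rate expression of reaction {reaction_index} evaluated to "
                f"{value!r} at state {tuple(x)}"
            )
        return float(value)

    def with_parameters(self, **updates: float) -> "ReactionNetwork":
        """Copy of the network with some named parameters replaced."""
        params = dict(self.parameters)
        unknown = set(updates) - set(params)
        if unknown:
            raise NetworkSpecError(f"unknown parameters {sorted(unknown)}")
        params.update(updates)
        reactions = []
        for rx in self.reactions:
            rate = rx.rate
            if isinstance(rate, MassAction) and rate.kappa_ref in updates:
                rate = MassAction(params[rate.kappa_ref], rate.kappa_ref)
            reactions.append(Reaction(rx.reactant, rx.product, rate))
        return ReactionNetwork(self.species, reactions, params)


def evaluate_propensity(
    reaction: Reaction,
    x: Sequence[int],
    species: Sequence[str] | None = None,
    parameters: Mapping[str, float] | None = None,
) -> float:
    """Standalone propensity evaluation for one reaction at state ``x``."""
    if isinstance(reaction.rate, MassAction):
        acc = 1
        for xi, ri in zip(x, reaction.reactant):
            if ri:
                acc *= falling_factorial(int(xi), ri)
        return reaction.rate.kappa * acc
    if species is None:
        species = [f"S{i + 1}" for i in range(len(reaction.reactant))]
    fn = compile_expression(reaction.rate.expr, species, parameters or {})
    value = fn(x)
    if not (math.isfinite(value) and value >= 0):
        raise PropensityError(
            f"rate expression evaluated to {value!r} at state {tuple(x)}"
        )
    return float(value)


# --- JSON dialect -----------------------------------------------------------


def _sparse_to_vector(entry: Mapping[str, int], species: Sequence[str]) -> tuple[int, ...]:
    unknown = set(entry) - set(species)
    if unknown:
        raise NetworkSpecError(f"unknown species {sorted(unknown)} in stoichiometry")
    return tuple(int(entry.get(name, 0)) for name in species)


def parse_network(spec: Mapping | str | Path) -> ReactionNetwork:
    """Build a validated :class:`ReactionNetwork` from the JSON dialect.

    ``spec`` may be a mapping, a JSON string, or a path to a JSON file.  See
    :func:`network_to_dict` for the inverse (the round trip is lossless).
    """
    if isinstance(spec, (str, Path)):
        spec = _load_json(spec)
    species = list(spec["species"])
    parameters = {k: float(v) for k, v in spec.get("parameters", {}).items()}
    reactions = []
    for k, rspec in enumerate(spec["reactions"]):
        reactant = _sparse_to_vector(rspec.get("reactant", {}), species)
        product = _sparse_to_vector(rspec.get("product", {}), species)
        rate_spec = rspec["rate"]
        if rate_spec["type"] == "mass_action":
            kappa = rate_spec["kappa"]
            if isinstance(kappa, str):
                if kappa not in parameters:
                    raise NetworkSpecError(
                        f"reaction {k}: unknown rate-constant parameter {kappa!r}"
                    )
                rate: MassAction | ExpressionRate = MassAction(parameters[kappa], kappa)
            else:
                rate = MassAction(float(kappa))
        elif rate_spec["type"] == "expression":
            rate = ExpressionRate(rate_spec["expr"])
        else:
            raise NetworkSpecError(f"unknown rate law type {rate_spec['type']!r}")
        try:
            reactions.append(Reaction(reactant, product, rate))
        except NetworkSpecError as err:
            raise NetworkSpecError(f"reaction {k}: {err}") from None
    return ReactionNetwork(species, reactions, parameters)


def parse_state_space(
    network: ReactionNetwork, spec: Mapping | str | Path, cap: int = 200_000
) -> StateSpace:
    """Read the optional ``state_space`` section of the JSON dialect.

    ``{"state_space": {"origin": {...sparse map}, "bound": M|null,
    "states": [[...], ...]?}}`` — the explicit ``states`` list overrides
    enumeration (for spaces smaller than a full compatibility class).
    """
    if isinstance(spec, (str, Path)):
        spec = _load_json(spec)
    ss = spec.get("state_space")
    if ss is None:
        raise NetworkSpecError("specification has no state_space section")
    origin = _sparse_to_vector(ss.get("origin", {}), network.species)
    bound = ss.get("bound")
    explicit = ss.get("states")
    return enumerate_states(
        network,
        origin,
        None if bound is None else int(bound),
        cap=cap,
        states=explicit,
    )


def network_to_dict(network: ReactionNetwork) -> dict:
    """Serialize a network to the JSON dialect (inverse of parse_network)."""
    out: dict = {
        "species": list(network.species),
        "parameters": dict(network.parameters),
        "reactions": [],
    }
    for rx in network.reactions:
        rspec: dict = {
            "reactant": {
                s: c for s, c in zip(network.species, rx.reactant) if c
            },
            "product": {s: c for s, c in zip(network.species, rx.product) if c},
        }
        if isinstance(rx.rate, MassAction):
            kappa = rx.rate.kappa_ref if rx.rate.kappa_ref else rx.rate.kappa
            rspec["rate"] = {"type": "mass_action", "kappa": kappa}
        else:
            rspec["rate"] = {"type": "expression", "expr": rx.rate.expr}
        out["reactions"].append(rspec)
    return out


# --- state space ------------------------------------------------------------


@dataclass
class StateSpace:
    """Explicit, lexicographically ordered finite state space.

    ``bound`` is the sup-norm truncation level (None for spaces that are
    finite through conservation laws alone).
    """

    states: list[tuple[int, ...]]
    origin: tuple[int, ...]
    bound: int | None = None
    index: dict[tuple[int, ...], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.states)}
        if len(self.index) != len(self.states):
            raise StateSpaceError("duplicate states in state space")

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, x) -> bool:
        return tuple(x) in self.index

    @property
    def d(self) -> int:
        return len(self.origin)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.states, dtype=np.int64)


def enumerate_states(
    network: ReactionNetwork,
    origin: Sequence[int],
    bound: int | None = None,
    cap: int = 200_000,
    states: Iterable[Sequence[int]] | None = None,
) -> StateSpace:
    """Enumerate the reachable state space from ``origin``.

    The closure follows transitions forward: ``x -> x + v`` is taken whenever
    some reaction with jump vector ``v`` has positive propensity at ``x`` and
    the target is nonnegative with sup-norm at most ``bound``.  This
    reproduces a stoichiometric compatibility class (or a reduced state
    space whose propensities vanish at its edge) without adding
    spurious states where a rate formula is formally positive outside the
    intended domain.

    ``states`` overrides enumeration with an explicit state list.
    """
    origin = tuple(int(c) for c in origin)
    if any(c < 0 for c in origin):
        raise StateSpaceError("origin must be nonnegative")
    if bound is not None and max(origin) > bound:
        raise StateSpaceError("origin violates the sup-norm bound")
    if states is not None:
        listed = sorted({tuple(int(c) for c in s) for s in states})
        if origin not in listed:
            raise StateSpaceError("explicit state list must contain the origin")
        if any(min(s) < 0 for s in listed):
            raise StateSpaceError("explicit states must be nonnegative")
        return StateSpace(listed, origin, bound)

    n_rx = len(network.reactions)
    seen = {origin}
    frontier = [origin]
    while frontier:
        nxt: list[tuple[int, ...]] = []
        for x in frontier:
            for k in range(n_rx):
                if network.propensity(k, x) <= 0.0:
                    continue
                v = network.reactions[k].vector
                y = tuple(a + b for a, b in zip(x, v))
                if min(y) < 0:
                    continue
                if bound is not None and max(y) > bound:
                    continue
                if y not in seen:
                    seen.add(y)
                    nxt.append(y)
            if len(seen) > cap:
                raise StateSpaceError(
                    f"reachable set exceeds {cap} states; supply a sup-norm "
                    "bound (truncation level M) or raise the cap"
                )
        frontier = nxt
    return StateSpace(sorted(seen), origin, bound)


# --- transition structure ---------------------------------------------------


class TransitionStructure:
    """Distinct jump vectors with aggregated propensities over a state space.

    ``rates(x)`` enforces the boundary contract: the aggregated propensity of
    direction j is forced to zero whenever ``x + v_j`` lies outside the state
    space.  ``rates_truncated(x)`` instead implements sup-norm truncation as
    used by the coupled simulator: propensities are zeroed only at states
    *outside* the space, so a chain may exit the truncation by one step (and
    is then frozen).
    """

    def __init__(
        self,
        network: ReactionNetwork,
        space: StateSpace,
        vectors: Sequence[tuple[int, ...]] | None = None,
    ) -> None:
        self.network = network
        self.space = space
        own = []
        for rx in network.reactions:
            v = rx.vector
            if v not in own:
                own.append(v)
        if vectors is None:
            vectors = own
        else:
            vectors = [tuple(int(c) for c in v) for v in vectors]
            stray = [v for v in own if v not in vectors]
            if stray:
                raise NetworkSpecError(
                    f"network has jump vectors {stray} absent from the shared list"
                )
        if any(all(c == 0 for c in v) for v in vectors):
            raise NetworkSpecError("jump vectors must be nonzero")
        if len(set(vectors)) != len(vectors):
            raise NetworkSpecError("jump vectors must be distinct")
        self.vectors: list[tuple[int, ...]] = list(vectors)
        self.source_groups: list[list[int]] = [
            [k for k, rx in enumerate(network.reactions) if rx.vector == v]
            for v in self.vectors
        ]
        self._cache: dict[tuple[int, ...], tuple[float, ...]] = {}
        self._cache_trunc: dict[tuple[int, ...], tuple[float, ...]] = {}

    @property
    def n(self) -> int:
        return len(self.vectors)

    def _raw(self, x: tuple[int, ...]) -> list[float]:
        net = self.network
        return [
            sum(net.propensity(k, x) for k in group) for group in self.source_groups
        ]

    def rates(self, x: Sequence[int]) -> tuple[float, ...]:
        """Aggregated propensities at ``x`` with off-space targets zeroed."""
        x = tuple(x)
        hit = self._cache.get(x)
        if hit is not None:
            return hit
        if x not in self.space:
            out = (0.0,) * self.n
        else:
            raw = self._raw(x)
            idx = self.space.index
            out = tuple(
                r if tuple(a + b for a, b in zip(x, v)) in idx else 0.0
                for r, v in zip(raw, self.vectors)
            )
        self._cache[x] = out
        return out

    def rates_truncated(self, x: Sequence[int]) -> tuple[float, ...]:
        """Aggregated propensities under sup-norm truncation (zero off-space)."""
        x = tuple(x)
        hit = self._cache_trunc.get(x)
        if hit is not None:
            return hit
        if x not in self.space:
            out = (0.0,) * self.n
        else:
            out = tuple(self._raw(x))
        self._cache_trunc[x] = out
        return out

    def propensity(self, j: int, x: Sequence[int]) -> float:
        return self.rates(x)[j]

    def total_rate_sup(self, truncated: bool = False) -> float:
        fn = self.rates_truncated if truncated else self.rates
        return max((sum(fn(x)) for x in self.space.states), default=0.0)


def derive_transition_structure(
    network: ReactionNetwork,
    space: StateSpace,
    vectors: Sequence[tuple[int, ...]] | None = None,
) -> TransitionStructure:
    """Collect distinct jump vectors and aggregate same-direction reactions."""
    return TransitionStructure(network, space, vectors)


# --- generator --------------------------------------------------------------


@dataclass
class GeneratorMatrix:
    """Sparse infinitesimal generator over a state-space ordering."""

    Q: sp.csr_matrix
    space: StateSpace

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.Q.sum(axis=1)).ravel()


def build_generator(ts: TransitionStructure, space: StateSpace) -> GeneratorMatrix:
    """Assemble Q with Q[x, x+v_j] = Upsilon_j(x) and conserving diagonal."""
    n_states = len(space)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i, x in enumerate(space.states):
        rates = ts.rates(x)
        total = 0.0
        for j, r in enumerate(rates):
            if r <= 0.0:
                continue
            y = tuple(a + b for a, b in zip(x, ts.vectors[j]))
            rows.append(i)
            cols.append(space.index[y])
            vals.append(r)
            total += r
        if total > 0.0:
            rows.append(i)
            cols.append(i)
            vals.append(-total)
    Q = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n_states, n_states), dtype=float
    )
    return GeneratorMatrix(Q, space)
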