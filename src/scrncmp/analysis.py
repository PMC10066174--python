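"""Stationary distributions, first-passage analysis and transient probabilities.

These routines exercise the comparison theory's consequences: monotone
dependence of mean first passage times on rate parameters (via the pathwise
ordering and monotone target sets) and monotone shifts of stationary mass on
increasing sets.  Stationary laws are computed by a sparse linear solve of
the global balance equations; first-passage distributions exactly, by making
the target absorbing and evaluating transient probabilities via the
uniformized power series; and mean first passage times by the standard
restricted linear system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .conditions import PropensityPair
from .network import GeneratorMatrix, StateSpace, build_generator
from .preorder import ComparisonMatrix, is_decreasing, is_increasing, leq_A

__all__ = [
    "ReducibleChainError",
    "StationaryDistribution",
    "ProductFormParameters",
    "HittingDominanceReport",
    "stationary",
    "product_form_pi",
    "mfpt",
    "transient_prob",
    "transient_distribution",
    "hitting_dominance",
]


class ReducibleChainError(RuntimeError):
    """The chain is not irreducible on its state space."""


@dataclass
class StationaryDistribution:
    """Probability vector over a state space, with truncation diagnostics."""

    pi: np.ndarray
    space: StateSpace
    boundary_mass: float | None = None
    note: str = ""

    def prob(self, gamma: Iterable[Sequence[int]]) -> float:
        idx = [self.space.index[tuple(s)] for s in gamma]
        return float(self.pi[idx].sum())

    def __getitem__(self, state) -> float:
        return float(self.pi[self.space.index[tuple(state)]])


@dataclass(frozen=True)
class ProductFormParameters:
    """Complex-balanced equilibrium of the open enzyme-kinetics network."""

    c1: float
    c2: float
    c3: float
    c4: float
    E_tot: int

    def __post_init__(self) -> None:
        if not (self.c1 > 0 and self.c2 > 0):
            raise ValueError("c1, c2 must be positive")
        if not (0 < self.c3 < 1 and 0 < self.c4 < 1):
            raise ValueError("c3, c4 must lie in (0, 1)")
        if abs(self.c3 + self.c4 - 1.0) > 1e-12:
            raise ValueError("c3 + c4 must equal 1")


def _positive_adjacency(Q: sp.csr_matrix) -> sp.csr_matrix:
    coo = Q.tocoo()
    keep = (coo.row != coo.col) & (coo.data > 0)
    return sp.csr_matrix(
        (np.ones(keep.sum()), (coo.row[keep], coo.col[keep])), shape=Q.shape
    )


def stationary(gen: GeneratorMatrix) -> StationaryDistribution:
    """Unique stationary distribution of an irreducible finite chain.

    Solves pi Q = 0, sum(pi) = 1 by replacing one balance equation with the
    normalization.  A reducible chain raises :class:`ReducibleChainError`
    listing its closed communicating classes.  On truncated spaces the mass
    sitting on the truncation surface is reported as a diagnostic.
    """
    Q = gen.Q
    n = Q.shape[0]
    adj = _positive_adjacency(Q)
    n_comp, labels = csgraph.connected_components(adj, directed=True, connection="strong")
    if n_comp > 1:
        # a class is closed iff no positive rate leaves it
        closed = []
        for c in range(n_comp):
            members = np.nonzero(labels == c)[0]
            sub = adj[members, :].tocoo()
            if np.all(np.isin(sub.col, members)):
                closed.append([gen.space.states[i] for i in members])
        raise ReducibleChainError(
            f"chain is reducible ({n_comp} communicating classes); closed "
            f"classes: {[sorted(c)[:4] for c in closed]}"
        )
    M = sp.lil_matrix(Q.T)
    M[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    if n <= 1500:
        pi = np.linalg.solve(M.toarray(), b)
    else:
        pi = spla.spsolve(sp.csc_matrix(M), b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    boundary_mass = None
    note = ""
    if gen.space.bound is not None:
        arr = gen.space.as_array()
        on_surface = arr.max(axis=1) >= gen.space.bound
        boundary_mass = float(pi[on_surface].sum())
        note = f"restricted solve on truncation M={gen.space.bound}"
    return StationaryDistribution(pi, gen.space, boundary_mass, note)


def product_form_pi(
    kappas: Sequence[float],
    E_tot: int,
    bound: int | None = None,
    space: StateSpace | None = None,
) -> StationaryDistribution:
    """Closed-form stationary law of the open (complex-balanced) enzyme network.

    The law factorizes as Poisson(c1) x Poisson(c2) on free substrate and
    product counts times a Binomial(E_tot, c4) split of the enzyme between
    free (x3) and bound (x4) form, with

        c1 = k5/k6,  c2 = k1 k3 k5 / (k2 k4 k6),
        c3 = 1/(1 + rho),  c4 = rho/(1 + rho),  rho = k1 k5 / (k2 k6),

    evaluated on the sup-norm truncated space and renormalized.
    """
    k1, k2, k3, k4, k5, k6 = (float(k) for k in kappas)
    if min(k1, k2, k3, k4, k5, k6) <= 0:
        raise ValueError("all six rate constants must be positive")
    rho = k1 * k5 / (k2 * k6)
    params = ProductFormParameters(
        c1=k5 / k6,
        c2=k1 * k3 * k5 / (k2 * k4 * k6),
        c3=1.0 / (1.0 + rho),
        c4=rho / (1.0 + rho),
        E_tot=int(E_tot),
    )
    if space is None:
        if bound is None:
            raise ValueError("either a truncation bound or a state space is required")
        states = sorted(
            (x1, x2, E_tot - x4, x4)
            for x1 in range(bound + 1)
            for x2 in range(bound + 1)
            for x4 in range(E_tot + 1)
        )
        space = StateSpace(states, (0, 0, E_tot, 0), bound)
    log_c = (math.log(params.c1), math.log(params.c2),
             math.log(params.c3), math.log(params.c4))
    logs = np.empty(len(space))
    for i, (x1, x2, x3, x4) in enumerate(space.states):
        logs[i] = (
            x1 * log_c[0] - math.lgamma(x1 + 1)
            + x2 * log_c[1] - math.lgamma(x2 + 1)
            + x3 * log_c[2] - math.lgamma(x3 + 1)
            + x4 * log_c[3] - math.lgamma(x4 + 1)
        )
    logs -= logs.max()
    pi = np.exp(logs)
    pi /= pi.sum()
    out = StationaryDistribution(pi, space, note="product form (renormalized)")
    out.product_form = params  # type: ignore[attr-defined]
    return out


def _reach_sets(adj: sp.csr_matrix, targets: set[int]) -> np.ndarray:
    """Boolean array: states from which some target is reachable (incl. targets)."""
    rev = adj.T.tocsr()
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = list(targets)
    for t in targets:
        seen[t] = True
    while stack:
        i = stack.pop()
        for k in rev.indices[rev.indptr[i]: rev.indptr[i + 1]]:
            if not seen[k]:
                seen[k] = True
                stack.append(int(k))
    return seen


def mfpt(gen: GeneratorMatrix, gamma: Iterable[Sequence[int]]) -> np.ndarray:
    """Mean first passage times to the target set, per start state.

    Solves Q restricted off the target: Q_C h = -1 with h = 0 on the target.
    Starts from which the target is not reached almost surely get +inf
    (never a solver failure).
    """
    space = gen.space
    targets = {space.index[tuple(s)] for s in gamma}
    if not targets:
        raise ValueError("target set must be non-empty")
    n = len(space)
    h = np.zeros(n)
    others = np.array(sorted(set(range(n)) - targets), dtype=int)
    if others.size == 0:
        return h
    adj = _positive_adjacency(gen.Q)
    can_reach = _reach_sets(adj, targets)
    # states that cannot reach the target at all
    dead = set(np.nonzero(~can_reach)[0])
    # states that may wander to a dead state before the target: also infinite
    if dead:
        adj_avoid = adj.tolil(copy=True)
        for t in targets:
            adj_avoid.rows[t] = []
            adj_avoid.data[t] = []
        hits_dead = _reach_sets(adj_avoid.tocsr(), dead)
    else:
        hits_dead = np.zeros(n, dtype=bool)
    infinite = [i for i in others if hits_dead[i]]
    solvable = np.array([i for i in others if not hits_dead[i]], dtype=int)
    h[infinite] = np.inf
    if solvable.size:
        Qc = gen.Q[np.ix_(solvable, solvable)]
        rhs = -np.ones(solvable.size)
        if solvable.size <= 1500:
            sol = np.linalg.solve(Qc.toarray(), rhs)
        else:
            sol = spla.spsolve(sp.csc_matrix(Qc), rhs)
        h[solvable] = sol
    return h


def transient_distribution(
    gen: GeneratorMatrix, x0: Sequence[int], t: float, tail: float = 1e-12
) -> np.ndarray:
    """Distribution of X(t) from a point mass, by the uniformized series.

    p(t) = sum_k e^{-lam t} (lam t)^k / k! * p0 P^k with P = I + Q/lam,
    truncated when the remaining Poisson tail mass drops below ``tail``.
    """
    space = gen.space
    i0 = space.index[tuple(int(c) for c in x0)]
    n = len(space)
    p = np.zeros(n)
    p[i0] = 1.0
    if t == 0.0:
        return p
    lam = float(-gen.Q.diagonal().min())
    if lam <= 0.0:
        return p
    P = sp.eye(n, format="csr") + gen.Q.tocsr() / lam
    mu = lam * t
    log_w = -mu  # log Poisson weight at k = 0
    out = math.exp(log_w) * p
    acc = math.exp(log_w)
    k = 0
    while acc < 1.0 - tail:
        k += 1
        p = p @ P
        log_w += math.log(mu / k)
        w = math.exp(log_w)
        out += w * p
        acc += w
        if k > 10 * mu + 1000:
            break
    return out


def transient_prob(
    gen: GeneratorMatrix, x0: Sequence[int], t: float, gamma: Iterable[Sequence[int]]
) -> float:
    """P(X(t) in gamma | X(0) = x0), to series tail error below 1e-12."""
    dist = transient_distribution(gen, x0, t)
    idx = [gen.space.index[tuple(s)] for s in gamma]
    return float(dist[idx].sum())


def _absorbing(gen: GeneratorMatrix, target_idx: set[int]) -> GeneratorMatrix:
    Q = gen.Q.tolil(copy=True)
    for i in target_idx:
        Q.rows[i] = []
        Q.data[i] = []
    return GeneratorMatrix(Q.tocsr(), gen.space)


@dataclass
class HittingDominanceReport:
    """Survival-function and mean comparison of two first passage times."""

    direction: str  # "increasing" or "decreasing"
    t_grid: list[float]
    survival_base: list[float]
    survival_modified: list[float]
    mean_base: float
    mean_modified: float
    pointwise_ok: bool = field(default=False)
    mean_ok: bool = field(default=False)


def hitting_dominance(
    pair: PropensityPair,
    A,
    gamma: Iterable[Sequence[int]],
    starts: tuple[Sequence[int], Sequence[int]],
    t_grid: Sequence[float],
) -> HittingDominanceReport:
    """Compare the two chains' first-passage-time laws to a monotone target.

    For an increasing target and ordered starts the modified chain hits no
    later in the usual stochastic order (its survival function lies below);
    for a decreasing target the roles swap.  Survival functions are exact:
    the target is made absorbing and occupancy evaluated by the uniformized
    series.  Means come from the restricted linear solve.
    """
    cm = A if isinstance(A, ComparisonMatrix) else ComparisonMatrix(A)
    space = pair.space
    gamma = [tuple(s) for s in gamma]
    x0, x0b = tuple(starts[0]), tuple(starts[1])
    if not leq_A(cm, x0, x0b):
        raise ValueError("starts must satisfy x0 ≼_A x0_breve")
    if is_increasing(cm, space, gamma):
        direction = "increasing"
    elif is_decreasing(cm, space, gamma):
        direction = "decreasing"
    else:
        raise ValueError(
            "target set is neither increasing nor decreasing under ≼_A; "
            "the first-passage comparison does not apply"
        )
    target_idx = {space.index[s] for s in gamma}
    gen_base = _absorbing(build_generator(pair.base, space), target_idx)
    gen_mod = _absorbing(build_generator(pair.modified, space), target_idx)
    surv_base = [
        1.0 - transient_prob(gen_base, x0, t, gamma) for t in t_grid
    ]
    surv_mod = [
        1.0 - transient_prob(gen_mod, x0b, t, gamma) for t in t_grid
    ]
    h_base = mfpt(build_generator(pair.base, space), gamma)
    h_mod = mfpt(build_generator(pair.modified, space), gamma)
    mean_base = float(h_base[space.index[x0]])
    mean_mod = float(h_mod[space.index[x0b]])
    slack = 1e-9
    if direction == "increasing":
        pointwise_ok = all(sm <= sb + slack for sm, sb in zip(surv_mod, surv_base))
        mean_ok = mean_mod <= mean_base + slack
    else:
        pointwise_ok = all(sb <= sm + slack for sm, sb in zip(surv_mod, surv_base))
        mean_ok = mean_base <= mean_mod + slack
    return HittingDominanceReport(
        direction=direction,
        t_grid=list(t_grid),
        survival_base=surv_base,
        survival_modified=surv_mod,
        mean_base=mean_base,
        mean_modified=mean_mod,
        pointwise_ok=pointwise_ok,
        mean_ok=mean_ok,
    )
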