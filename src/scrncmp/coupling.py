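"""Uniformization-based monotone coupling and a plain SSA reference simulator.

Both chains of a comparable pair are driven by one Poisson clock of rate λ
(λ exceeding n times the largest total jump rate of either chain) and one
shared stream of uniform draws.  At each clock tick with draw u, each chain
applies an acceptance map that jumps by v_j exactly when u falls in a
half-open interval of length Υ_j(x)/λ placed inside [(j-1)/n, j/n) (the
ungrouped map), or in stacked sub-intervals within per-group blocks (the
grouped map used with the grouped comparison conditions).  Because the
intervals of matched directions are nested whenever the comparison
conditions hold, ordered states remain ordered at every tick, almost surely.

Sup-norm truncation: propensities are zeroed outside the truncated space, so
a chain may exit by a single step and is then frozen; the exit is recorded.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conditions import GroupStructure, PropensityPair
from .network import TransitionStructure
from .preorder import ComparisonMatrix

__all__ = [
    "OrderViolationError",
    "CoupledTrajectory",
    "Trajectory",
    "uniformization_rate",
    "phi",
    "psi",
    "couple_paths",
    "ssa_path",
]

#: relative margin of λ above the strict uniformization bound
LAMBDA_MARGIN = 1e-3


class OrderViolationError(RuntimeError):
    """A verified coupling emitted an order-violating event (internal bug trap)."""


def uniformization_rate(pair: PropensityPair) -> float:
    """λ = (1 + margin) · n · max over both chains of sup_x Σ_j Υ_j(x).

    Suprema are over the (possibly truncated) finite state space, using the
    truncated propensities, so every Υ_j(x)/λ is strictly below 1/n.
    """
    sup = max(
        pair.base.total_rate_sup(truncated=True),
        pair.modified.total_rate_sup(truncated=True),
    )
    if sup == 0.0:
        return 1.0  # both chains are frozen; any positive rate is valid
    return (1.0 + LAMBDA_MARGIN) * pair.n * sup


def phi(
    ts: TransitionStructure,
    lam: float,
    x: Sequence[int],
    u: float,
    truncated: bool = True,
) -> tuple[int, ...]:
    """Ungrouped acceptance map: x + v_j iff u in I_j(x), else x.

    I_j(x) = [(j-1)/n, (j-1)/n + Υ_j(x)/λ), mutually disjoint by the λ bound.
    The measure-zero draw u = 1 maps to the self-loop.
    """
    x = tuple(x)
    n = ts.n
    j = int(u * n)
    if j >= n:
        j = n - 1
    rates = ts.rates_truncated(x) if truncated else ts.rates(x)
    if u - j / n < rates[j] / lam:
        return tuple(a + b for a, b in zip(x, ts.vectors[j]))
    return x


def psi(
    ts: TransitionStructure,
    lam: float,
    groups: GroupStructure,
    x: Sequence[int],
    u: float,
    truncated: bool = True,
) -> tuple[int, ...]:
    """Grouped acceptance map with stacked sub-intervals per group block.

    Group k (directions sharing A v_j) owns the block [p_{k-1}/n, p_k/n); its
    sub-intervals have lengths Υ_{σ(q)}(x)/λ laid end to end from the block's
    left edge.  With singleton groups this coincides with :func:`phi`.
    """
    x = tuple(x)
    n = ts.n
    un = u * n
    k = bisect_right(groups.p, un) - 1
    if k >= groups.s:
        k = groups.s - 1
    rates = ts.rates_truncated(x) if truncated else ts.rates(x)
    offset = u - groups.p[k] / n
    acc = 0.0
    for q in range(groups.p[k], groups.p[k + 1]):
        acc += rates[groups.sigma[q]] / lam
        if offset < acc:
            v = ts.vectors[groups.sigma[q]]
            return tuple(a + b for a, b in zip(x, v))
    return x


@dataclass
class Trajectory:
    """One piecewise-constant right-continuous sample path."""

    times: list[float]
    states: list[tuple[int, ...]]

    def state_at(self, t: float) -> tuple[int, ...]:
        i = bisect_right(self.times, t) - 1
        return self.states[max(i, 0)]


@dataclass
class CoupledTrajectory:
    """A coupled pair of sample paths on one Poisson clock.

    ``times``/``states_*`` record the accepted jump epochs (plus time 0);
    thinned clock ticks are only counted.  ``ordered`` reports whether
    A(X̆ - X) >= 0 held at every event epoch.
    """

    times: list[float]
    states_base: list[tuple[int, ...]]
    states_modified: list[tuple[int, ...]]
    ordered: bool
    violation_times: list[float] = field(default_factory=list)
    n_events: int = 0
    n_thinned: int = 0
    lam: float = 0.0
    exited_base: bool = False
    exited_modified: bool = False
    exit_time: float | None = None
    seed: int | None = None

    @property
    def exited(self) -> bool:
        return self.exited_base or self.exited_modified


def couple_paths(
    pair: PropensityPair,
    A,
    x0: Sequence[int],
    x0_breve: Sequence[int],
    t_max: float,
    seed,
    scheme: str = "ungrouped",
    require_ordered: bool = True,
) -> CoupledTrajectory:
    """Co-simulate the base and modified chains with shared randomness.

    One Poisson(λ) clock and one uniform draw per tick drive both acceptance
    maps.  When the relevant comparison conditions have been verified by the
    caller, the cone ordering of the two states is a.s. preserved at every
    tick; ``require_ordered=True`` turns any violation into
    :class:`OrderViolationError` (bug trap).  For negative tests pass
    ``require_ordered=False`` and inspect ``ordered``.

    Truncated spaces use the zeroed-outside propensities: a chain exiting
    the truncation freezes and the exit is flagged.
    """
    if scheme not in ("ungrouped", "grouped"):
        raise ValueError("scheme must be 'ungrouped' or 'grouped'")
    cm = A if isinstance(A, ComparisonMatrix) else ComparisonMatrix(A)
    x = tuple(int(c) for c in x0)
    y = tuple(int(c) for c in x0_breve)
    Amat = np.asarray(cm.A, dtype=float)
    tol = cm.tol

    def ordered_pair(a: tuple[int, ...], b: tuple[int, ...]) -> bool:
        diff = np.subtract(b, a)
        return bool(np.all(Amat @ diff >= -tol))

    if not ordered_pair(x, y):
        raise ValueError("initial states must satisfy x0 ≼_A x0_breve")

    lam = uniformization_rate(pair)
    n = pair.n
    base, mod = pair.base, pair.modified
    vectors = pair.vectors
    space_index = pair.space.index
    groups = GroupStructure.from_vectors(cm, vectors) if scheme == "grouped" else None

    rng = np.random.default_rng(seed)
    n_ticks = int(rng.poisson(lam * t_max))
    times = np.sort(rng.random(n_ticks)) * t_max
    draws = rng.random(n_ticks)

    out_t = [0.0]
    out_x = [x]
    out_y = [y]
    violations: list[float] = []
    n_thinned = 0
    exited_base = exited_mod = False
    exit_time: float | None = None

    for t, u in zip(times, draws):
        if groups is None:
            new_x = phi(base, lam, x, u)
            new_y = phi(mod, lam, y, u)
        else:
            new_x = psi(base, lam, groups, x, u)
            new_y = psi(mod, lam, groups, y, u)
        if new_x == x and new_y == y:
            n_thinned += 1
            continue
        x, y = new_x, new_y
        out_t.append(float(t))
        out_x.append(x)
        out_y.append(y)
        if x not in space_index and not exited_base:
            exited_base = True
            exit_time = exit_time if exit_time is not None else float(t)
        if y not in space_index and not exited_mod:
            exited_mod = True
            exit_time = exit_time if exit_time is not None else float(t)
        if not ordered_pair(x, y):
            violations.append(float(t))
            if require_ordered:
                raise OrderViolationError(
                    f"coupled states lost the cone ordering at t={t:.6g}: "
                    f"X={x}, X_breve={y}"
                )

    return CoupledTrajectory(
        times=out_t,
        states_base=out_x,
        states_modified=out_y,
        ordered=not violations,
        violation_times=violations,
        n_events=n_ticks,
        n_thinned=n_thinned,
        lam=lam,
        exited_base=exited_base,
        exited_modified=exited_mod,
        exit_time=exit_time,
        seed=seed if isinstance(seed, int) else None,
    )


def ssa_path(
    ts: TransitionStructure,
    x0: Sequence[int],
    t_max: float,
    seed,
) -> Trajectory:
    """Plain direct-method (Gillespie) simulation of one chain.

    Exponential holding time at the total rate, jump direction drawn with
    probability Υ_j(x) / ΣΥ(x); a state with zero total rate absorbs.
    """
    rng = np.random.default_rng(seed)
    x = tuple(int(c) for c in x0)
    t = 0.0
    times = [0.0]
    states = [x]
    while True:
        rates = ts.rates_truncated(x)
        total = sum(rates)
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        r = rng.random() * total
        acc = 0.0
        j = ts.n - 1
        for k, rate in enumerate(rates):
            acc += rate
            if r < acc:
                j = k
                break
        x = tuple(a + b for a, b in zip(x, ts.vectors[j]))
        times.append(t)
        states.append(x)
    return Trajectory(times, states)
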