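"""Matrix-defined cone preorders on lattice state spaces.

A comparison matrix A (m rows, d columns, no zero row) induces the preorder
x ≼_A y  iff  A(y - x) >= 0 componentwise, i.e. y - x lies in the polyhedral
cone K_A = {z | Az >= 0}.  The relation is reflexive and transitive; it is a
partial order only when A has full column rank.  This module provides the
relation, the facet (boundary-slice) membership test used by the
boundary-form comparison conditions, monotone (increasing / decreasing) set
machinery, and exhaustive up-set enumeration for small spaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import StateSpace

__all__ = [
    "ComparisonMatrix",
    "leq_A",
    "boundary_indices",
    "is_increasing",
    "is_decreasing",
    "maximal_states",
    "minimal_states",
    "enumerate_increasing_sets",
]

#: absolute tolerance for real-valued A; integer data is compared exactly
REAL_TOL = 1e-9


@dataclass(frozen=True)
class ComparisonMatrix:
    """An m x d comparison matrix defining the cone preorder ≼_A."""

    A: np.ndarray

    def __init__(self, A) -> None:
        arr = np.atleast_2d(np.asarray(A))
        if arr.ndim != 2:
            raise ValueError("A must be a matrix")
        if np.any(np.all(arr == 0, axis=1)):
            raise ValueError("A must have no identically-zero row")
        if np.all(arr == np.round(arr)):
            arr = arr.astype(np.int64)
        else:
            arr = arr.astype(float)
        arr.setflags(write=False)
        object.__setattr__(self, "A", arr)

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def d(self) -> int:
        return self.A.shape[1]

    @property
    def is_integer(self) -> bool:
        return np.issubdtype(self.A.dtype, np.integer)

    @property
    def tol(self) -> float:
        return 0.0 if self.is_integer else REAL_TOL

    def negated(self) -> "ComparisonMatrix":
        return ComparisonMatrix(-np.asarray(self.A))

    @classmethod
    def from_json(cls, source: Mapping | str | Path) -> "ComparisonMatrix":
        if isinstance(source, (str, Path)):
            from .network import _load_json

            source = _load_json(source)
        return cls(np.asarray(source["A"]))

    def to_dict(self) -> dict:
        return {"A": self.A.tolist()}


def _as_cm(A) -> ComparisonMatrix:
    return A if isinstance(A, ComparisonMatrix) else ComparisonMatrix(A)


def leq_A(A, x: Sequence[int], y: Sequence[int]) -> bool:
    """True iff x ≼_A y, i.e. every coordinate of A(y-x) is >= 0."""
    cm = _as_cm(A)
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != (cm.d,) or y.shape != (cm.d,):
        raise ValueError(f"states must be length-{cm.d} vectors")
    return bool(np.all(cm.A @ (y - x) >= -cm.tol))


def boundary_indices(A, x: Sequence[int], y: Sequence[int]) -> frozenset[int]:
    """Rows i (0-based) with <A_i, y-x> = 0, i.e. the slices ∂_i(K_A+x) ∋ y.

    Requires x ≼_A y; an interior point returns the empty set and y = x
    returns all rows.
    """
    cm = _as_cm(A)
    g = cm.A @ (np.asarray(y) - np.asarray(x))
    if np.any(g < -cm.tol):
        raise ValueError("boundary_indices requires x ≼_A y")
    return frozenset(int(i) for i in np.nonzero(np.abs(g) <= cm.tol)[0])


def _check_subset(space: StateSpace, gamma: Iterable[Sequence[int]]) -> set:
    out = {tuple(s) for s in gamma}
    stray = out - set(space.index)
    if stray:
        raise ValueError(f"states {sorted(stray)[:3]} not in the state space")
    return out


def is_increasing(A, space: StateSpace, gamma: Iterable[Sequence[int]]) -> bool:
    """True iff gamma is upward closed in (space, ≼_A)."""
    cm = _as_cm(A)
    members = _check_subset(space, gamma)
    for x in members:
        for y in space.states:
            if y not in members and leq_A(cm, x, y):
                return False
    return True


def is_decreasing(A, space: StateSpace, gamma: Iterable[Sequence[int]]) -> bool:
    """True iff gamma is downward closed in (space, ≼_A)."""
    cm = _as_cm(A)
    members = _check_subset(space, gamma)
    for x in members:
        for y in space.states:
            if y not in members and leq_A(cm, y, x):
                return False
    return True


def maximal_states(A, space: StateSpace) -> list[tuple[int, ...]]:
    """States x with x ≼_A y (y in the space) only for y = x."""
    cm = _as_cm(A)
    out = []
    for x in space.states:
        if all(y == x or not leq_A(cm, x, y) for y in space.states):
            out.append(x)
    return out


def minimal_states(A, space: StateSpace) -> list[tuple[int, ...]]:
    """States x with y ≼_A x (y in the space) only for y = x."""
    cm = _as_cm(A)
    out = []
    for x in space.states:
        if all(y == x or not leq_A(cm, y, x) for y in space.states):
            out.append(x)
    return out


def successor_masks(A, space: StateSpace) -> list[int]:
    """Bitmask, per state, of the states weakly above it under ≼_A."""
    cm = _as_cm(A)
    n = len(space)
    masks = [0] * n
    for i, x in enumerate(space.states):
        m = 0
        for k, y in enumerate(space.states):
            if leq_A(cm, x, y):
                m |= 1 << k
        masks[i] = m
    return masks


def enumerate_increasing_sets(
    A, space: StateSpace, cap: int = 14
) -> list[frozenset[tuple[int, ...]]]:
    """All upward-closed subsets of (space, ≼_A), including ∅ and the space.

    Exhaustive 2^|space| filter with memoized successor bitmasks; refuses
    spaces larger than ``cap`` states.  Deterministic order (by bitmask).
    """
    n = len(space)
    if n > cap:
        raise ValueError(f"state space has {n} > {cap} states; raise cap explicitly")
    succ = successor_masks(A, space)
    states = space.states
    out: list[frozenset[tuple[int, ...]]] = []
    for mask in range(1 << n):
        ok = True
        rem = mask
        while rem:
            low = rem & -rem
            i = low.bit_length() - 1
            if succ[i] & ~mask:
                ok = False
                break
            rem ^= low
        if ok:
            out.append(frozenset(states[i] for i in range(n) if mask >> i & 1))
    return out
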