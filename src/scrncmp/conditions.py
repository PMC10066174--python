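"""Machine-checkable sufficient conditions for stochastic ordering of CTMCs.

Given two chains on one state space that jump along a shared list of vectors
v_1..v_n with propensities Υ (base) and Ῠ (modified), and a comparison matrix
A, three condition sets guarantee a monotone coupling with
X(t) ≼_A X̆(t) for all t almost surely:

* the general pairwise conditions (checked for every ordered state pair);
* the boundary form, valid when every A v_j has entries in {-1, 0, 1}, where
  per-direction rate inequalities need only hold on the facet slices
  ∂_i(K_A + x) of translated cones;
* the grouped boundary form, which weakens the per-direction inequalities to
  sums over groups of directions sharing a common image A v_j.

A brute-force generator-inequality oracle (after Massey's comparison
criterion, which is necessary for the ordering) is included for validating
the implications on small chains.  All exhaustive scans are vectorized over
the state list; they remain O(|X|^2 · m · n) and are meant for desk-scale
spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import GeneratorMatrix, StateSpace, TransitionStructure
from .preorder import ComparisonMatrix, enumerate_increasing_sets, leq_A

__all__ = [
    "PropensityPair",
    "GroupStructure",
    "Witness",
    "ConditionReport",
    "check_general",
    "check_boundary",
    "check_grouped",
    "massey_oracle",
]

#: relative tolerance for rate inequalities (propensities are floats; the
#: inequalities are exact in rational arithmetic)
INEQ_RTOL = 1e-9


def _viol_mask(lhs: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Elementwise: required inequality lhs <= rhs fails beyond tolerance."""
    scale = np.maximum(1.0, np.maximum(np.abs(lhs), np.abs(rhs)))
    return lhs > rhs + INEQ_RTOL * scale


@dataclass
class PropensityPair:
    """A base / modified propensity pair over a shared space and vector list."""

    base: TransitionStructure
    modified: TransitionStructure

    def __post_init__(self) -> None:
        if self.base.vectors != self.modified.vectors:
            raise ValueError("the two structures must share one jump-vector list")
        if self.base.space.states != self.modified.space.states:
            raise ValueError("the two structures must share one state space")

    @property
    def space(self) -> StateSpace:
        return self.base.space

    @property
    def vectors(self) -> list[tuple[int, ...]]:
        return self.base.vectors

    @property
    def n(self) -> int:
        return self.base.n

    def swapped(self) -> "PropensityPair":
        return PropensityPair(self.modified, self.base)

    def rate_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(N x n) aggregated propensities of both chains over the state list."""
        states = self.space.states
        U = np.array([self.base.rates(x) for x in states])
        Ub = np.array([self.modified.rates(x) for x in states])
        return U, Ub


@dataclass(frozen=True)
class GroupStructure:
    """Partition of direction indices by the distinct images eta^k = A v_j.

    ``sigma`` lists the direction indices group by group (a permutation of
    0..n-1); ``p`` holds the cumulative group sizes p_0 = 0 < ... < p_s = n.
    Image order is by first occurrence along j = 0..n-1, so the structure is
    deterministic for a given vector list.
    """

    images: tuple[tuple[int, ...], ...]
    groups: tuple[tuple[int, ...], ...]
    sigma: tuple[int, ...]
    p: tuple[int, ...]

    @classmethod
    def from_vectors(
        cls, A: ComparisonMatrix, vectors: Sequence[tuple[int, ...]]
    ) -> "GroupStructure":
        Av = [tuple(int(c) for c in np.asarray(A.A) @ np.asarray(v)) for v in vectors]
        images: list[tuple[int, ...]] = []
        for img in Av:
            if img not in images:
                images.append(img)
        groups = tuple(
            tuple(j for j, img in enumerate(Av) if img == eta) for eta in images
        )
        sigma = tuple(j for g in groups for j in g)
        p = [0]
        for g in groups:
            p.append(p[-1] + len(g))
        return cls(tuple(images), groups, sigma, tuple(p))

    @property
    def s(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class Witness:
    """One violated inequality: states, row/group context, and both sides."""

    x: tuple[int, ...]
    y: tuple[int, ...]
    row: int | None
    index: int  # direction j (per-direction checks) or group k (grouped)
    relation: str  # "breve<=base" or "breve>=base"
    lhs: float
    rhs: float


@dataclass
class ConditionReport:
    verdict: bool
    theorem: str
    witnesses: list[Witness] = field(default_factory=list)
    note: str = ""

    def __bool__(self) -> bool:
        return self.verdict


def _as_cm(A) -> ComparisonMatrix:
    return A if isinstance(A, ComparisonMatrix) else ComparisonMatrix(A)


def _geometry(A: ComparisonMatrix, space: StateSpace):
    """G = A S^T (m x N) over the state list, plus the comparison tolerance."""
    if len(space) > 20_000:
        import warnings

        warnings.warn(
            f"exhaustive pairwise scan over {len(space)} states is quadratic; "
            "expect long runtimes",
            stacklevel=3,
        )
    S = space.as_array()
    G = np.asarray(A.A) @ S.T
    return G.astype(float), A.tol


def _shift_index(space: StateSpace, vectors: Sequence[tuple[int, ...]]) -> np.ndarray:
    """shift[j, i] = index of state_i + v_j in the space, or -1 if outside."""
    idx = space.index
    out = np.full((len(vectors), len(space)), -1, dtype=np.int64)
    for j, v in enumerate(vectors):
        for i, x in enumerate(space.states):
            y = tuple(a + b for a, b in zip(x, v))
            out[j, i] = idx.get(y, -1)
    return out


def _trunc_note(space: StateSpace) -> str:
    return f"verified on truncation M={space.bound}" if space.bound is not None else ""


def check_general(pair: PropensityPair, A) -> ConditionReport:
    """Check the general pairwise comparison conditions on the full space.

    For every x ≼_A y and direction j: if y + v_j lies in the space but
    outside K_A + x, require Ῠ_j(y) <= Υ_j(x); if x + v_j lies in the space
    and y ∉ K_A + x + v_j, require Ῠ_j(y) >= Υ_j(x).
    """
    cm = _as_cm(A)
    space = pair.space
    G, tol = _geometry(cm, space)
    shift = _shift_index(space, pair.vectors)
    U, Ub = pair.rate_tables()
    N = len(space)
    states = space.states
    witnesses: list[Witness] = []
    for ix in range(N):
        ordered = np.all(G >= G[:, ix: ix + 1] - tol, axis=0)  # x ≼_A y
        if not ordered.any():
            continue
        for j in range(pair.n):
            tgt = shift[j]  # index of y + v_j per y
            valid = tgt >= 0
            in_cone = np.zeros(N, dtype=bool)
            vi = np.nonzero(valid)[0]
            if vi.size:
                in_cone[vi] = np.all(
                    G[:, tgt[vi]] >= G[:, ix: ix + 1] - tol, axis=0
                )
            need_le = ordered & valid & ~in_cone  # y+v_j exits K_A + x
            if need_le.any():
                bad = need_le & _viol_mask(Ub[:, j], np.full(N, U[ix, j]))
                for iy in np.nonzero(bad)[0]:
                    witnesses.append(
                        Witness(states[ix], states[iy], None, j,
                                "breve<=base", Ub[iy, j], U[ix, j])
                    )
            ixv = shift[j, ix]  # index of x + v_j
            if ixv >= 0:
                above = np.all(G >= G[:, ixv: ixv + 1] - tol, axis=0)
                need_ge = ordered & ~above  # y not in K_A + x + v_j
                if need_ge.any():
                    bad = need_ge & _viol_mask(np.full(N, U[ix, j]), Ub[:, j])
                    for iy in np.nonzero(bad)[0]:
                        witnesses.append(
                            Witness(states[ix], states[iy], None, j,
                                    "breve>=base", Ub[iy, j], U[ix, j])
                        )
    return ConditionReport(not witnesses, "general", witnesses, _trunc_note(space))


def _require_integer(A: ComparisonMatrix) -> None:
    if not A.is_integer:
        raise ValueError("the boundary-form conditions require an integer matrix A")


def _image_condition(
    A: ComparisonMatrix, vectors: Sequence[tuple[int, ...]]
) -> list[Witness]:
    """Condition (i): every A v_j has entries in {-1, 0, 1}."""
    bad = []
    for j, v in enumerate(vectors):
        img = np.asarray(A.A) @ np.asarray(v)
        if np.any(np.abs(img) > 1):
            row = int(np.argmax(np.abs(img)))
            bad.append(
                Witness(
                    tuple(v), tuple(v), row, j, "|<A_i,v_j>|<=1", float(img[row]), 1.0
                )
            )
    return bad


def _boundary_scan(
    pair: PropensityPair,
    cm: ComparisonMatrix,
    base_table: np.ndarray,
    mod_table: np.ndarray,
    signs: np.ndarray,
    grouped: bool,
) -> list[Witness]:
    """Shared facet scan for the per-direction and grouped boundary checks.

    ``signs[i, c]`` is the sign constraint of column c (direction j or group
    k) on row i; ``*_table`` are (N x columns) rate or grouped-sum tables.
    """
    space = pair.space
    G, tol = _geometry(cm, space)
    N = len(space)
    states = space.states
    witnesses: list[Witness] = []
    for ix in range(N):
        diff = G - G[:, ix: ix + 1]
        ordered = np.all(diff >= -tol, axis=0)
        if not ordered.any():
            continue
        on_facet = np.abs(diff) <= tol  # (m, N): y in ∂_i(K_A + x)
        for i in range(cm.m):
            ys = ordered & on_facet[i]
            if not ys.any():
                continue
            for c in range(signs.shape[1]):
                sign = signs[i, c]
                if sign == 0:
                    continue
                if sign < 0:
                    bad = ys & _viol_mask(
                        mod_table[:, c], np.full(N, base_table[ix, c])
                    )
                    rel = "breve<=base"
                else:
                    bad = ys & _viol_mask(
                        np.full(N, base_table[ix, c]), mod_table[:, c]
                    )
                    rel = "breve>=base"
                for iy in np.nonzero(bad)[0]:
                    witnesses.append(
                        Witness(states[ix], states[iy], i, c, rel,
                                mod_table[iy, c], base_table[ix, c])
                    )
    return witnesses


def check_boundary(pair: PropensityPair, A) -> ConditionReport:
    """Check the boundary-form conditions (per-direction, on facet slices).

    Requires integer A with every A v_j in {-1,0,1}^m.  For each x, row i and
    y in ∂_i(K_A+x) ∩ space: <A_i, v_j> < 0 forces Ῠ_j(y) <= Υ_j(x) and
    <A_i, v_j> > 0 forces Ῠ_j(y) >= Υ_j(x).  A state pair on two facets with
    opposite signs for some j therefore forces equality (reported as two
    witnesses when violated).
    """
    cm = _as_cm(A)
    _require_integer(cm)
    bad_images = _image_condition(cm, pair.vectors)
    if bad_images:
        return ConditionReport(
            False, "boundary", bad_images,
            "condition (i) fails: A v_j not in {-1,0,1}^m",
        )
    signs = np.asarray(cm.A) @ np.asarray(pair.vectors).T  # (m, n)
    U, Ub = pair.rate_tables()
    witnesses = _boundary_scan(pair, cm, U, Ub, signs, grouped=False)
    return ConditionReport(not witnesses, "boundary", witnesses, _trunc_note(pair.space))


def check_grouped(pair: PropensityPair, A) -> ConditionReport:
    """Check the grouped boundary conditions (sums over equal-image groups).

    Same facet geometry as :func:`check_boundary`, but the inequality for a
    group G^k with image eta^k compares the *sums* of rates over the group's
    directions, in the direction of the sign of eta^k_i.  With all groups
    singletons this coincides with the per-direction check.
    """
    cm = _as_cm(A)
    _require_integer(cm)
    bad_images = _image_condition(cm, pair.vectors)
    if bad_images:
        return ConditionReport(
            False, "grouped", bad_images,
            "condition (i) fails: A v_j not in {-1,0,1}^m",
        )
    gs = GroupStructure.from_vectors(cm, pair.vectors)
    U, Ub = pair.rate_tables()
    Ug = np.column_stack([U[:, list(g)].sum(axis=1) for g in gs.groups])
    Ubg = np.column_stack([Ub[:, list(g)].sum(axis=1) for g in gs.groups])
    signs = np.array(gs.images).T  # (m, s): eta^k_i
    witnesses = _boundary_scan(pair, cm, Ug, Ubg, signs, grouped=True)
    return ConditionReport(not witnesses, "grouped", witnesses, _trunc_note(pair.space))


def massey_oracle(
    Q: GeneratorMatrix,
    Q_breve: GeneratorMatrix,
    A,
    space: StateSpace | None = None,
    cap: int = 14,
) -> ConditionReport:
    """Brute-force generator-inequality check over all increasing sets.

    For every ordered pair x ≼_A y and every increasing Γ with x ∈ Γ or
    y ∉ Γ, requires sum_{w in Γ} Q[x, w] <= sum_{w in Γ} Q̆[y, w].  The sums
    include diagonal entries.  This criterion is necessary for the pathwise
    ordering, so it is implied by any of the three sufficient condition sets.
    """
    cm = _as_cm(A)
    space = space or Q.space
    if Q.space.states != space.states or Q_breve.space.states != space.states:
        raise ValueError("generators must share the given state space")
    upsets = enumerate_increasing_sets(cm, space, cap=cap)
    masks = [sum(1 << space.index[s] for s in gamma) for gamma in upsets]
    Qd = Q.Q.toarray()
    Qbd = Q_breve.Q.toarray()
    n = len(space)
    ind = np.zeros((len(upsets), n))
    for g, mask in enumerate(masks):
        for i in range(n):
            if mask >> i & 1:
                ind[g, i] = 1.0
    sums = Qd @ ind.T  # (state, upset): sum over gamma of Q[x, .]
    sums_b = Qbd @ ind.T
    witnesses: list[Witness] = []
    for ix, x in enumerate(space.states):
        for iy, y in enumerate(space.states):
            if not leq_A(cm, x, y):
                continue
            for g, mask in enumerate(masks):
                in_x = bool(mask >> ix & 1)
                in_y = bool(mask >> iy & 1)
                if not (in_x or not in_y):
                    continue
                lhs, rhs = sums[ix, g], sums_b[iy, g]
                if _viol_mask(np.array(lhs), np.array(rhs)):
                    witnesses.append(
                        Witness(x, y, None, g, "Q_sum<=Qbreve_sum",
                                float(lhs), float(rhs))
                    )
    return ConditionReport(not witnesses, "massey", witnesses)
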