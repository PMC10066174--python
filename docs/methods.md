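# Methods

This note records the model, the algorithmic and numerical choices behind
`scrncmp`, and what the tests do and do not establish.

## Model and scope

A network is a species list (d ≥ 1), reactions (v⁻, v⁺) with v⁻ ≠ v⁺, and a
rate law per reaction.  The associated Markov chain lives on a finite (or
sup-norm-truncated) subset 𝒳 ⊆ ℤ₊^d and jumps by the *distinct* reaction
vectors v₁..vₙ; reactions sharing one vector are aggregated into a single
direction propensity Υ_j(x) = Σ Λ(x) over that group.  The standing boundary
contract is Υ_j(x) = 0 whenever x + v_j ∉ 𝒳; the generator is
Q[x, x+v_j] = Υ_j(x) with conserving diagonal.

Rate laws are either mass action — κ · Π_i (x_i)_{(v⁻)_i} with the falling
factorial computed in exact integer arithmetic before the single float
multiply — or a whitelisted arithmetic expression over state coordinates
(x1..xd or species names), named parameters, `+ − × ÷`, integer-literal
powers, and one built-in bounded monotone function
`hill(x, K, h) = x^h/(K^h + x^h)`.  The expression is compiled from a
validated AST; no other calls or names evaluate.  A rate expression that
returns a negative or non-finite value at a visited state raises an error
naming the reaction and the state.  κ = 0 is permitted (it yields a null
propensity); this is needed to represent "reaction absent" cleanly, as in
the Braess cross-link study.

Out of scope: SBML, time-varying or stochastic rate constants, deterministic
concentration models, tau-leaping or diffusion approximations, coupling of
more than two chains, and any formal non-explosion verification (simulation
always runs on a finite or truncated space).

## State-space enumeration

`enumerate_states` closes the origin under *forward* moves: x → x + v_j is
taken whenever some reaction in direction j has positive propensity at x and
the target is nonnegative (and within the sup-norm bound M, when given).
The alternative — closing under ±v_j blindly — is simpler but wrong for
reduced models whose state space is cut out by propensities vanishing at its
edge rather than by stoichiometry: in the chromatin circuit the erasure rate
x₂(κ₃ₐ + x₁κ₃ᵦ) is formally positive at states with x₁ + x₂ > D_tot, so a
backward step would manufacture states outside the intended triangle.
Forward closure from the canonical origin reproduces the intended spaces for
all five benchmarks (9 states for the closed enzyme class at S_tot=3,
E_tot=2; 10 for the Braess class at S_tot=2; the triangle x₁+x₂ ≤ D_tot for
chromatin).  The cost is origin-dependence: enumerate from a state that
reaches the whole class (the bundles' canonical origins do), or pass an
explicit state list via the JSON dialect.  Enumeration is deterministic
(lexicographic order) and capped at 200 000 states with an explicit error
advising a bound.

## Two truncation semantics

Countably infinite chains are handled on 𝒳_M = {x : ‖x‖∞ ≤ M}, in two
deliberately different ways:

* **Simulation** uses propensities zeroed *outside* 𝒳_M
  (`rates_truncated`): a chain at the surface may exit by one step, after
  which all its rates vanish and it freezes; the exit is flagged with its
  time.  This matches the limiting construction that justifies the coupling
  on unbounded spaces, and exits are reported rather than hidden (ensemble
  drivers exclude exited pairs from ordered-fraction counts).
* **Stationary analysis** uses restriction: rates pointing out of 𝒳_M are
  zeroed (`rates`, the boundary contract), because a frozen chain has no
  stationary law.  The solver reports the stationary mass on the truncation
  surface as a diagnostic; for the open enzyme network at M = 40 this mass
  is ~1e−48 and the solve agrees with the closed-form law to ~1e−15 in
  sup norm.

## Condition checking

All three checks scan ordered state pairs with vectorized cone geometry
(G = A·states^T; a pair is ordered iff the column difference is ≥ 0, on a
facet i iff coordinate i is 0) and are O(|𝒳|²·m·n) — desk scale; the open
enzyme truncation at M = 30 (2 883 states) checks in about one second.
Rate inequalities use relative tolerance 1e−9 scaled by max(1, |lhs|, |rhs|):
the model-level inequalities are exact in rational arithmetic, and the tolerance only
absorbs float evaluation noise.  Cone membership is exact for integer A and
integer states; real A uses absolute tolerance 1e−9 (the facet test
⟨A_i, y−x⟩ = 0 must not be corrupted by rounding).

Violations are returned as witnesses (x, y, facet row, direction or group,
required relation, both sides); a report's verdict is pass iff the witness
list is empty, and witnesses re-evaluate to the reported numbers.

The grouped conditions are *weaker* per direction than the general ones, so
grouped-pass does not imply general-pass (the Braess relay passes grouped
and fails general); the sound implication chain, asserted by property tests,
is: boundary ⇒ grouped, boundary ⇒ general, and each ⇒ the brute-force
generator inequalities over all increasing sets (which are necessary for the
ordering).  Up-sets are enumerated by filtering all 2^|𝒳| subsets with
memoized successor bitmasks, capped at 14 states by default.

No automated search for a comparison matrix is attempted.  The manual
recipe that produced the shipped matrices: decide, per direction v_j,
whether the monotonicity of interest should let a transition lead inside
(b = 1), outside (b = −1), or parallel (b = 0) to each facet, and solve
⟨A_i, v_j⟩ = b_{ij} row by row for small integer entries.

## Coupling and simulation

λ = (1 + 1e−3) · n · max of the two total-rate suprema over the (truncated)
space.  The margin keeps the inequality strict while staying close to the
efficiency optimum (acceptance probability per tick scales like ΣΥ/λ).  A
pair with all rates zero gets λ = 1 so the clock is well defined.

The ungrouped acceptance map places I_j(x) = [(j−1)/n, (j−1)/n + Υ_j(x)/λ)
— the λ bound makes these proper subsets of their blocks, hence disjoint;
the grouped map stacks sub-intervals of lengths Υ_{σ(q)}(x)/λ end-to-end
inside each group block [p_{k−1}/n, p_k/n), with group order fixed by first
occurrence of the image Av_j (deterministic σ).  The measure-zero draw u = 1
maps to the self-loop.  One Poisson clock and one uniform stream drive both
chains; arrival times are drawn as order statistics of uniforms on
[0, t_max].  Only accepted jumps are stored (thinned ticks are counted);
identical seeds give bit-identical trajectories, and ensemble drivers key
each pair's generator by (master seed, tag, pair index) so ensembles are
reproducible and order-independent.

When the caller has verified the relevant conditions, an order-violating
event is impossible; `couple_paths` still checks every accepted event and
raises (bug trap) unless `require_ordered=False`, which is how the negative
controls measure violation rates.  The ungrouped map is used with the
general/boundary conditions, the grouped map with the grouped conditions.

A plain direct-method SSA is provided as the independent marginal reference;
distributional agreement of the coupled marginals with SSA and with the
uniformized transient law is part of the acceptance suite.

## Analysis

* Stationary law: strong connectivity of the positive-rate digraph is
  required (closed communicating classes are listed on failure); one balance
  equation is replaced by normalization; dense solve below 1 500 states,
  sparse LU above.
* Transient probabilities: uniformized power series at λ = max |Q_xx|,
  truncated when the accumulated Poisson weight exceeds 1 − 1e−12.
* Mean first passage times: sparse solve of Q_C h = −1 off the target.
  Starts that can reach (avoiding the target) a state from which the target
  is unreachable get +∞ explicitly, never a singular-solver error.
* First-passage distributions: exact, by absorbing the target and evaluating
  transient occupancy — no simulation in the dominance reports; means come
  from the linear solve and are cross-checked against quadrature of the
  survival function in tests.

## Synthetic random instances

`random_network` draws ≤ 3 species, ≤ 6 reactions with 0/1 stoichiometries,
rate constants uniform on [0.5, 1.5], a bounded space of ≤ 14 states, and a
random integer comparison matrix with entries in {−1,0,1}, no zero row and
all images Av_j in {−1,0,1}^m (rejection sampled).  Half the instances
compare a chain with itself (initial-condition monotonicity), the other half
scale each rate constant by 1 or 1.25 independently.  These sizes make the
brute-force oracle (up-set enumeration, matrix exponentials) exact and fast;
about a third of instances pass the general conditions, so the oracle sweep
is far from vacuous.  What a green sweep establishes: on small, mass-action,
bounded instances the sufficient conditions never contradict the necessary
generator inequalities or transient dominance.  What it does not: coverage
of non-mass-action kinetics at scale, large state spaces, or near-degenerate
rate ties beyond the 1e−9 tolerance.

## Known limitations

* All exhaustive checks are quadratic in |𝒳|; beyond ~20 000 states they
  are the wrong tool (a warning threshold, then the cap, applies).
* Truncation exits are handled by flag-and-freeze; automatic bound doubling
  is left to the caller (rebuild the pair at 2M), since silently changing
  the state space mid-ensemble would break seed reproducibility.
* Forward-closure enumeration can under-enumerate from a non-generic origin
  (e.g. an absorbing state); the JSON dialect's explicit state list is the
  escape hatch.
* The stationary solver's restriction semantics is an approximation for
  truncated infinite chains, self-diagnosed by the boundary-mass report.
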