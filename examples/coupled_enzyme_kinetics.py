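"""Monotone co-simulation of two enzyme-kinetics chains.

Builds the closed Michaelis-Menten network (S_tot=3, E_tot=2) twice — once
with catalytic constant k3=1 and once with k3=2 — verifies the boundary
comparison conditions under the matrix preorder, and co-simulates 200
coupled trajectory pairs on one Poisson clock.  The printed fraction is the
share of pairs for which the faster chain stayed weakly ahead (fewer
substrate, no fewer product molecules) at *every* jump epoch; the theory
says this must be every pair.
"""

from scrncmp import check_boundary, couple_paths, make_example, uniformization_rate

bundle = make_example("ek1")  # k3 = 1 vs k3_breve = 2
pair = bundle.pair()
report = check_boundary(pair, bundle.A)
print(f"boundary comparison conditions: {'PASS' if report.verdict else 'FAIL'}")
print(f"uniformization rate lambda = {uniformization_rate(pair):.3f}")

s = bundle.states["s"]  # all substrate, free enzyme
n_pairs, ordered, accepted = 200, 0, 0
for k in range(n_pairs):
    tr = couple_paths(pair, bundle.A, s, s, t_max=10.0, seed=[7, k])
    ordered += tr.ordered
    accepted += len(tr.times) - 1
print(f"ordered pairs: {ordered}/{n_pairs} "
      f"(mean accepted jumps per pair: {accepted / n_pairs:.1f})")
print("every coupled pair preserves the cone ordering, as the comparison "
      "theory guarantees almost surely")
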