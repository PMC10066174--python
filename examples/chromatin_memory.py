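"""Epigenetic memory of a histone-modification circuit versus its asymmetry.

In the reduced chromatin circuit (x1 repressive, x2 activating marks on
D_tot nucleosomes) the parameter mu scales the erasure pressure on the
repressive mark.  The fully active state a = (0, D_tot) is maximal and the
fully repressed state r = (D_tot, 0) minimal under the comparison preorder,
so the theory predicts that raising mu raises the stationary weight of a,
lowers that of r, prolongs the active state's memory (E_a[T_r] up) and
shortens reactivation (E_r[T_a] down).  Exact values below.
"""

from scrncmp import build_generator, derive_transition_structure, make_example, mfpt, stationary

print("  mu     pi_a     pi_r   E_r[T_a]   E_a[T_r]")
for mu in (0.5, 1.0, 2.0):
    b = make_example("chromatin", mu=mu)  # D_tot = 3, other constants 1
    space = b.space()
    gen = build_generator(derive_transition_structure(b.base, space), space)
    pi = stationary(gen)
    a, r = b.states["a"], b.states["r"]
    to_a = mfpt(gen, [a])[space.index[r]]
    to_r = mfpt(gen, [r])[space.index[a]]
    print(f"{mu:4.1f}  {pi[a]:.5f}  {pi[r]:.5f}  {to_a:9.4f}  {to_r:9.4f}")
print("stationary mass and memory-loss times shift monotonically with mu")
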