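"""Defining a comparison problem entirely from JSON documents.

A network, its state space and a comparison matrix can be supplied as plain
JSON, so problems can be prepared outside Python.  Here a birth-death module
(constant production, linear degradation) is compared against a copy with a
higher production rate; the boundary conditions certify that the copy
stochastically dominates the original for all time.
"""

import json

from scrncmp import (
    ComparisonMatrix,
    PropensityPair,
    check_boundary,
    derive_transition_structure,
    parse_network,
    parse_state_space,
)

doc = {
    "species": ["X"],
    "parameters": {"k_prod": 1.0, "k_deg": 0.5},
    "reactions": [
        {"reactant": {}, "product": {"X": 1},
         "rate": {"type": "mass_action", "kappa": "k_prod"}},
        {"reactant": {"X": 1}, "product": {},
         "rate": {"type": "mass_action", "kappa": "k_deg"}},
    ],
    "state_space": {"origin": {}, "bound": 25},
}
matrix_doc = {"A": [[1]]}

net = parse_network(json.dumps(doc))
space = parse_state_space(net, doc)
faster = net.with_parameters(k_prod=2.0)
A = ComparisonMatrix.from_json(matrix_doc)

base = derive_transition_structure(net, space)
mod = derive_transition_structure(faster, space, base.vectors)
report = check_boundary(PropensityPair(base, mod), A)
print(f"state space: {len(space)} states; comparison matrix A = {A.A.tolist()}")
print("doubling the production rate dominates the base chain:",
      "PASS" if report.verdict else "FAIL")
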