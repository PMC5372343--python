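"""Exact inversion distances and an optimal scenario for the four canonical
rearrangement patterns on five blocks.

A transposition or block interchange costs 3 inversions; their inverted
variants cost 2 — this is why an inversion-only distance overcounts such
events, and why the pipeline eliminates their 'independent' forms first.
"""

from panscaf import (
    SignedPermutation,
    identity,
    inversion_distance,
    optimal_scenario,
    bfs_oracle,
)

patterns = {
    "transposition          +1+2+4+3+5": (1, 2, 4, 3, 5),
    "inverted transposition +1+2-4+3+5": (1, 2, -4, 3, 5),
    "block interchange      +1+4+3+2+5": (1, 4, 3, 2, 5),
    "inverted interchange   +1-4+3-2+5": (1, -4, 3, -2, 5),
}

for name, elems in patterns.items():
    p = SignedPermutation(elems)
    d = inversion_distance(p)
    print(f"{name}: distance {d.distance} "
          f"(cycles {d.cycles}, hurdles {d.hurdles}; BFS oracle {bfs_oracle(p)})")

scen = optimal_scenario(SignedPermutation((1, 2, 4, 3, 5)), identity(5))
print("\none optimal scenario for the transposition pattern "
      f"(position ranges per step): {list(scen.steps)}")
print("each step is an inversion (i, j) on the evolving source; the three "
      "steps replace what was really a single transposition event.")
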