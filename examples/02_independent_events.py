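"""Common-adjacency merging and independent-event elimination.

The scaffold +1+2+6+7+3+4+5+8 differs from the identity by a single
transposition of the regions (6,7) and (3,4,5).  After merging block runs
that are adjacent in both scaffolds, the regions become single blocks and
the swap is detected as one independent transposition — so the residual
inversion distance is 0, not 3.
"""

from panscaf import SignedPermutation, identity, collapse_common_adjacencies
from panscaf.distance import pairwise_distance
from panscaf.events import eliminate_independent_events

source = SignedPermutation((1, 2, 6, 7, 3, 4, 5, 8))
target = identity(8)

a, b, grouping = collapse_common_adjacencies(target, source)
print(f"after merging: target {a}, source {b}")
print(f"merged runs: {dict(enumerate(grouping.runs, start=1))}")

naive = pairwise_distance(source, target).distance
res = eliminate_independent_events(source, target)
print(f"\ninversion distance without elimination: {naive}")
print(f"eliminated events: {res.counts}")
for ev in res.events:
    print(f"  {ev.kind}: regions {ev.blocks[0]} and {ev.blocks[1]} swap")
print(f"residual inversion distance: "
      f"{pairwise_distance(res.source, res.target).distance} "
      f"(R_d = {res.r_d})")
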