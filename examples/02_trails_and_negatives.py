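"""Generate trails of ideas and negative samples on planted-lineage data.

Simulates a small temporal hypergraph whose hyperedges evolve along
lineages, then shows: a backward concept-overlap random walk (the trail of
ideas behind a target), a hard negative (20% of the target's concepts
replaced), and a global negative (an unrelated hyperedge).  The overlap
numbers illustrate why hard negatives are deceptively similar.
"""

import numpy as np

from hypertrail import SamplerConfig, SyntheticConfig, simulate
from hypertrail.sampling import (global_negative, hard_negative,
                                 replacement_candidates, trail)

th, lineages = simulate(SyntheticConfig(n_concepts=200, n_lineages=10, T=6,
                                        seed=42))
print(f"simulated {th.num_hyperedges} hyperedges over {th.num_steps} years")

target = th.snapshots[5][0]
rng = np.random.default_rng(0)
tr = trail(th, target, SamplerConfig(), rng)
print(f"\ntarget hyperedge {target.id} at t={target.timestamp}, "
      f"size {target.size}")
for e in tr.predecessors:
    ov = len(e.members & target.members)
    print(f"  trail step t={e.timestamp}: hyperedge {e.id} "
          f"(overlap with target: {ov} concepts)")

pool = replacement_candidates(th, target)
hard = hard_negative(target, r=0.2, candidate_vocab=pool, rng=rng)
shared = len(hard.members & target.members)
print(f"\nhard negative (r=0.2): shares {shared}/{target.size} concepts "
      f"with the target - deceptively similar")

gns = global_negative(th, target.id, rng)
print(f"global negative: hyperedge {gns.id} from t={gns.timestamp}, "
      f"shares {len(gns.members & target.members)}/{target.size} concepts "
      f"- an unrelated hypothesis")
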