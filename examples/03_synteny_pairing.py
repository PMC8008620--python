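"""Pair one-telomere arm scaffolds into chromosomes using a reference map.

Arm scaffolds (in arbitrary orientation) are aligned to a reference whose
linkage groups are known; alignment blocks are aggregated into a
row-stochastic proportion matrix, each arm is assigned to the linkage
group holding a clear majority of its aligned bp, the two arms per group
are paired with telomeres facing outward, and the plan is materialised
with a 500-bp N gap standing in for the centromere.  With 10% of blocks
re-targeted to wrong linkage groups, the true chromosomes are still
recovered exactly.
"""

import chromarm as ca
from chromarm.synteny import (
    assign_arm, build_chromosomes, pair_arms, synteny_matrix)
from chromarm.telomeres import classify_scaffold, scan_telomere_arrays

specs = [ca.ChromosomeSpec(f"chr{i}", 20_000 + 4_000 * i, 40_000 + 4_000 * i)
         for i in (1, 2, 3)]
records, truth = ca.simulate_genome(specs, seed=3)
arms, flips = ca.arm_records(records, truth, flip_prob=0.5, seed=3)
_, placements = ca.simulate_reference(records, truth, divergence=0.0, seed=3)
blocks, _ = ca.simulate_alignment_blocks(
    placements, block_len=500, n_blocks_per_arm=50, jitter=100,
    noise_fraction=0.10, seed=3, query_flips=flips)

matrix = synteny_matrix(blocks)
print("proportion of each arm's aligned bp per linkage group:")
print(matrix.proportion.round(2))

assignments = [assign_arm(a, matrix) for a in matrix.proportion.index]
statuses = {r.id: classify_scaffold(r, scan_telomere_arrays(r)) for r in arms}
plans = pair_arms(assignments, statuses, {r.id: len(r.sequence) for r in arms})
for p in plans:
    print(p.name, "=", " + gap +".join(f" {a}({o})" for a, o in p.parts))

built = build_chromosomes(plans, arms)
ok = sorted(b.sequence for b in built) == sorted(r.sequence for r in records)
print("rebuilt chromosomes identical to the simulated truth:", ok)
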