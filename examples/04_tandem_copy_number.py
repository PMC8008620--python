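"""Estimate the true copy number of a collapsed tandem array from coverage.

Assemblers limited by read length collapse long tandem arrays (such as
rDNA) onto a few assembled units; reads from all true copies pile onto
those units, inflating depth.  The estimator rescales the assembled copy
count by the ratio of locus depth to genome-wide reference depth.
"""

import numpy as np

import chromarm as ca

for multiplier in (5.0, 25.0):
    locus = ca.TandemLocusSpec(arm="short", offset=20_000, unit_len=2_000,
                               assembled_copies=4, depth_multiplier=multiplier)
    spec = ca.ChromosomeSpec("chr1", 200_000, 300_000, tandem_locus=locus)
    records, truth = ca.simulate_genome([spec], seed=4)
    track = ca.simulate_depth(records, truth, mean_depth=50, seed=4)["chr1"]

    iv = truth.tandem_loci[0]["interval"]
    r = track.resolution
    locus_depth = track.values[iv.start // r:iv.end // r].mean()
    genome_depth = np.median(track.values[track.values > 0])
    est = ca.estimate_tandem_copies(4, locus_depth, genome_depth)
    print(f"depth x{multiplier:4.0f}: locus={locus_depth:6.1f} "
          f"genome={genome_depth:5.1f} -> {est:6.1f} copies "
          f"(truth {truth.tandem_loci[0]['true_copies']:.0f})")

# 4 assembled copies at 5x and 25x excess coverage give ~20 and ~100 true
# copies: the ends of the plausible range for a collapsed rDNA array.
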