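# chromarm

Post-assembly chromosome-arm analytics for small genomes assembled to (or
near) telomere-to-telomere contiguity.

After long-read contigs have been scaffolded with Hi-C, a recurring set of
questions remains before an assembly can be called chromosome-level:

* Which scaffolds carry telomeres, at one end or both? A scaffold with
  terminal TTAGGG arrays at both ends is a complete chromosome; a scaffold
  with one is a chromosome arm awaiting a partner.
* How do sequence features — GC content, repeat density, sequencing depth,
  restriction-site density, gene density — vary along chromosomes, and do
  the short and long arms of a chromosome differ systematically?
* Which arm scaffolds belong together? With a reference karyotype or
  physical map, pairwise whole-genome alignment assigns each arm to a
  linkage group, and two arms per group are joined across an arbitrary
  centromeric gap.
* How many copies of a collapsed tandem array (such as rDNA) does the
  genome really carry, given the assembly keeps only a few?
* Do Hi-C contacts confirm that chromosome arms behave as separate
  contact domains?

`chromarm` implements this whole post-assembly layer as a typed Python
library with a thin CLI, plus a synthetic-genome generator with exact
ground truth, so every stage is testable end-to-end without real data.

## Methods at a glance

**Telomere arrays.** Exact, case-insensitive matches of the chordate
telomere motif TTAGGG (strand +) and its reverse complement CCCTAA
(strand −) are chained when consecutive match starts are ≤ motif length +
`max_unit_gap` apart; chains with ≥ `min_units` matches are arrays, with
purity = matched bp / span. Arrays within `end_window` of a scaffold end
are terminal, giving the scaffold status `both_ends` / `one_end` /
`interstitial_only` / `none`.

**Arm landscape.** Windows of 50 kbp tile each chromosome. Per window:
GC = (G+C)/(A+C+G+T) with N excluded from the denominator; repeat
fraction = soft-masked bp / span; mean depth; GATC (DpnII) count on the
forward strand only (the motif is palindromic); genes counted by start
position. The chromosome splits at its single central N gap into short and
long arms, and each feature is compared between arms with Welch's
unequal-variance t test, t = (x̄₁−x̄₂)/√(s₁²/n₁+s₂²/n₂) with
Welch–Satterthwaite df, **and** the Mann-Whitney U test (midranks; exact
enumeration for n+m ≤ 16 without ties, tie- and continuity-corrected
normal approximation otherwise). A difference is significant only when
both two-sided p < 0.05; no multiple-testing correction is applied.

**Tandem copy number.** For a tandem locus with `a` assembled copies,
estimated true copies = a · (locus mean depth / genome reference depth).

**Synteny and arm pairing.** One-to-one alignment blocks are collated
twice: colinear same-strand chains with gaps ≤ 200 kbp on both genomes
(match regions), then same-landmark groupings within 500 kbp on the target
regardless of strand (syntenic regions, which may overlap across
landmarks). Union target footprints per (scaffold, linkage group) give a
row-stochastic proportion matrix; an arm is assigned to a linkage group
when it holds ≥ 50% of the arm's aligned bp with a ≥ 10-point lead. The
two arms per group are joined shorter-arm-first, each oriented so its
telomere faces outward, across a 500-bp N gap.

**Hi-C arm summary.** Every eligible bin pair falls in exactly one
category — intra-arm, inter-arm same chromosome, inter-chromosome — and
category means and their ratios quantify arm-level contact structure; an
end-clustering score compares inter-chromosomal contact among
telomeric/pericentromeric bins to background.

## Worked example

```python
import chromarm as ca
from chromarm.landscape import compare_arms, compute_windows, split_at_gap

specs = [ca.ChromosomeSpec("chr1", 1_000_000, 1_500_000)]
records, truth = ca.simulate_genome(specs, seed=2)
rec = records[0]
partition = split_at_gap(rec, truth.gaps)
depth = ca.simulate_depth(records, truth, mean_depth=50, seed=2)[rec.id]
windows = compute_windows(rec, depth=depth, genes=truth.genes,
                          window=50_000, partition=partition)
for c in compare_arms(windows, partition):
    print(c.feature, round(c.mean_short, 3), round(c.mean_long, 3),
          f"{c.welch_p:.2e}", f"{c.mw_p:.2e}", c.significant)
```

prints

```
gc_fraction 0.38 0.419 2.81e-44 3.88e-09 True
repeat_fraction 0.3 0.15 5.83e-16 3.82e-09 True
depth_mean 49.97 50.056 3.42e-01 2.42e-01 False
dpnii_count 168.75 182.793 1.80e-04 4.63e-04 True
gene_count 5.0 4.931 8.88e-01 9.34e-01 False
```

The generator planted a GC contrast of 0.38 vs 0.42 and repeat densities
of 0.30 vs 0.15, and the dual rule recovers both. DpnII density was never
planted, yet is significant too: GATC frequency follows base composition,
so the GC contrast drags restriction-site density along — whereas depth
and gene rate, simulated arm-neutrally, stay non-significant.

The `examples/` directory has one short script per capability: telomere
annotation, the arm landscape above, synteny-guided arm pairing (which
rebuilds simulated chromosomes byte-identically from shuffled, flipped arm
scaffolds through 10%-noise alignments), tandem copy-number estimation,
and Hi-C arm summaries. The same stages are exposed as a CLI:
`chromarm simulate | telomeres | windows | arms | synteny | contacts`.

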