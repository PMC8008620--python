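# Methods

This note documents the models and procedures behind `chromarm`, the
parameters that matter, the choices made where the design was genuinely
open, and the limits of what the synthetic tests demonstrate.

## Coordinate and sequence conventions

All coordinates are 0-based half-open on the forward strand, everywhere in
memory. The only 1-based format handled (GFF3) is converted at the file
boundary: a gene printed as `start=1 end=10` becomes the interval
`[0, 10)`. Soft-masking (repeat annotation) travels as lowercase inside the
sequence string, as RepeatMasker emits it; reverse complementation
preserves case. Sequences admit exactly `{A,C,G,T,N}` in either case; U
and IUPAC ambiguity codes are rejected at read time rather than converted,
so malformed genomes fail fast with the offending position named. Tabular
writers emit a `# chromarm v…` header comment; FASTA writers do not,
because a comment line inside FASTA is not valid FASTA.

## Telomere array detection

Arrays are found by exact, case-insensitive matching of the motif
(default TTAGGG) and its reverse complement, chaining same-strand matches
whose starts are within `len(motif) + max_unit_gap` (default 6) bp, and
keeping chains with at least `min_units` (default 3) matches. Placement is
terminal when the array starts within `end_window` (default 1000) bp of
the 5′ end or ends within it of the 3′ end. Purity is matched bp over
array span, so a pure array has purity 1 and interruptions dilute it.

Design choices:

* **Exact matching only.** Divergent telomere-like repeats are the
  province of dedicated repeat annotators; exactness makes the scanner
  verifiable by a brute-force oracle and keeps purity interpretable.
* **min_units = 3** cannot fire on random sequence at desk scale: a chain
  of three motif hits within the allowed gaps has probability on the order
  of 10⁻¹⁰ per position at uniform base composition.
* Arrays are always reported in forward-strand coordinates, so BED output
  is directly comparable to truth annotations regardless of strand.

Scaffold status derives purely from terminal placements: `both_ends`
(telomere-to-telomere), `one_end` (an arm), `interstitial_only`, `none`.

## Windowed landscape and the arm contrast

Windows of `window` bp (default 50 000) tile each sequence from zero; the
final short window is computed but flagged `partial` and excluded from arm
statistics by default, since unequal support would bias the tests
(`keep_partial` overrides). Per window:

* **GC** uses an N-free denominator; an all-N window is missing (NaN).
* **Repeat fraction** is lowercase bp over the full window span.
* **DpnII count** scans GATC case-insensitively on the forward strand
  only — the motif is its own reverse complement, so scanning both strands
  would exactly double every count. A site is assigned to the window
  containing its first base.
* **Gene count** counts genes whose start lies in the window, so window
  counts sum exactly to the per-sequence total (overlap counting would
  not).
* **Depth mean** averages the depth-track steps overlapping the window.
  The depth abstraction accepts either mean per-base coverage or read-start
  counts and records which in its `kind` field; the analyses treat both
  identically.

A chromosome is split into arms at its single central N gap (gaps
labelled `gap`/`centromere`, or unlabeled, count); the shorter flank is
the short arm, with an exact tie labelling the left flank short.
Scaffolds with zero or multiple central gaps — e.g. sex-specific
regions — are legitimately unpartitionable and raise an error rather than
being guessed at.

The arm contrast runs two tests per feature and requires **both**
two-sided p-values below α = 0.05:

* Welch's unequal-variance t with Welch–Satterthwaite degrees of freedom;
  degenerate input (both variances zero, or n < 2) raises rather than
  returning a fabricated p.
* Mann-Whitney U with midranks. The p-value is exact by full enumeration
  of all C(n+m, n) labelings when n+m ≤ 16 and no ties are present
  (two-sided p = twice the smaller tail, capped at 1); otherwise the
  normal approximation with tie correction and a 0.5 continuity
  correction. The midrank + continuity choices are declared because
  common implementations differ in their exactness heuristics.

No multiple-testing correction is applied across the five features or
across chromosomes; raw p-values are reported so users can correct
downstream as they see fit. The dual rule is conservative by
construction: its null false-positive rate is bounded by the more
stringent of the two tests, and simulation (500 null replicates in the
acceptance suite) keeps it at or below the nominal 5%.

## Tandem copy number

For a tandem locus the assembler collapsed to `a` copies, the true copy
number is estimated as `a × locus_depth / reference_depth`: reads from
all true copies map onto the few assembled units, inflating their depth
proportionally. The estimator is a pure ratio — it deliberately carries no
mapping-bias or GC correction, and its two inputs (locus mean depth and a
genome-wide reference depth, typically the median) are the caller's
choice.

## Alignment collation and arm pairing

Input alignments are one-to-one blocks in an 8-column TSV (query, target,
0-based half-open spans on the forward strand of each genome, relative
orientation, score). MAF ingestion is out of scope by design; converting
aligner output into this dialect is a one-line upstream step.

**Match regions** chain blocks within a (query, target, strand) group,
sorted by target start, while (i) the target-side gap ≤ `join_distance`
(default 200 000 bp), (ii) the query-side gap ≤ the same bound, and (iii)
query coordinates move monotonically with the strand (increasing for `+`,
decreasing for `−`; overlapping blocks count as gap ≤ 0). The precise
rule is declared here and oracle-tested against an exhaustive split-point
search, since "join within a distance" admits several readings.

**Syntenic regions** group match regions of one (target, query) pair,
sorted by target start, while the target-side gap to the previous member
is strictly under `max_distance` (default 500 000 bp) — regardless of
strand or colinearity, so syntenic regions of different query landmarks
can overlap on the target. The distance is measured on the target genome
and grouping is per query landmark; the converse reading would be
equally implementable, and this choice is recorded as open.

**The proportion matrix** counts, per (assembly scaffold, linkage group),
the union of target-side block footprints — duplicates covering the same
footprint count once — and normalises each row by its total aligned bp,
not by sequence length: unaligned sequence (repeats, sex-specific
regions) would otherwise distort rows. Rows with no alignment are
missing, not zero.

**Assignment and pairing.** An arm goes to the linkage group holding at
least `min_fraction` (default 0.5) of its aligned bp with a lead of at
least `min_margin` (default 0.1) over the runner-up; anything else is
ambiguous with diagnostics, never silently forced. Each pairable group
must hold exactly two assigned arms. The shorter arm is placed first, and
each arm is oriented so its terminal telomere faces outward (left part:
`+` if the telomere is 5′, `−` if 3′; right part mirrored). An arm with
no terminal telomere keeps `+` and the plan records a warning. Built
chromosomes join the oriented parts with `gap_len` N characters (default
500 — the conventional arbitrary stand-in for an unassembled centromere),
reverse-complementing `−` parts with case preserved.

## Hi-C arm summary

Bins are labelled with their (chromosome, arm) when ≥ 50% of the bin lies
in the arm; bins straddling the gap 50/50, overlapping it more, or on
unpartitioned sequences are excluded. Every unordered pair of labelled
bins — minus same-sequence pairs within `exclude_diag_bins` (default 1) of
the diagonal, which carry self/adjacent-ligation signal — contributes to
exactly one category: intra-arm, inter-arm same chromosome,
inter-chromosome. The summary reports category means, pair counts and the
two ratios. The end-clustering score is the mean inter-chromosomal
contact between end-region bins over the same mean between background
bins, and is scale-invariant.

Deliberate simplifications, recorded as limitations:

* Counts are used as given — raw or pre-balanced. Matrix balancing
  (ICE/KR) has many dialects and is out of scope; a balanced matrix can
  be passed directly.
* Genomic-distance dependence is **not** modelled, so category means
  conflate distance with category on real data. The synthetic generator
  has no distance decay, which makes the recovery tests unbiased but also
  means they do not exercise this confounder.

## The synthetic generator

Each simulated chromosome is
`[5′ telomere][short arm][N gap][long arm][3′ telomere]` with:

* i.i.d. per-arm base composition at the arm's GC — no dinucleotide
  structure. This suffices for every statistic computed here and keeps
  oracles closed-form (window GC is binomial; the 5-Mbp arm test bound of
  ±0.005 is > 5σ).
* Soft-mask intervals of fixed 500 bp placed uniformly without overlap
  (via the gap-insertion construction) until the arm's target density is
  met; density, not length distribution, is what the landscape contrasts.
* Genes of fixed length placed uniformly without overlap at `gene_rate`
  per bp (default 10⁻⁴, a gene-dense small-genome figure).
* Defaults GC 0.38/0.42 and repeat density 0.30/0.15 (short/long),
  telomeres of 50 units, a 500-bp gap: a two-arm contrast of the size and
  direction the landscape module is meant to detect.
* An optional tandem locus: a unit repeated `assembled_copies` times in
  the sequence, with depth inflated by `depth_multiplier`, so the true
  copy number `assembled × multiplier` is known.

The reference genome concatenates each chromosome's arms (gap removed)
into one linkage group, independently reverse-complementing each arm with
probability 0.5 and applying i.i.d. point substitutions at the chosen
divergence. Arm scaffolds can additionally be reverse-complemented with a
recorded flip map (`arm_records(..., flip_prob)`), making plan
orientations a real recovery target rather than a constant. Alignment
blocks tile each arm with jitter and map through the placement map; noise
blocks keep their query span and get a uniform wrong-linkage-group target
of the same length — the simplest adversary for majority voting. Depth is
negative binomial (Poisson in the `dispersion=None` limit) per
`resolution`-bp step (default 100 bp, so interior steps of a 500-bp gap
exist and are zeroed). Contacts are independent Poisson draws per bin
pair at the category mean, symmetric with a zero diagonal; the default
means (10, 1, 1) are a property-testing structure, not an estimate of any
real contact map.

Determinism: one master seed is split into named child streams
(genome, reference, blocks, depth, contacts), so identical inputs give
byte-identical outputs and stages can be regenerated independently.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level error and mappability, indels and
rearrangements between assembly and reference, heterozygosity,
dinucleotide/codon structure, distance-dependent contact decay, and
telomere-length variation. The end-to-end recovery results certify the
logic of the pipeline, not the hardness of real genomes.

## Problem sizes

The test suite and the acceptance script run on desk-scale genomes —
arms of 5 kbp to 5 Mbp, 50-replicate recovery experiments on ~120-kbp
chromosomes, 500/200-replicate calibration/power runs at 100 windows per
arm — chosen so the full suite completes in seconds while every Monte
Carlo bound retains a ≥ 3σ margin.
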