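"""Synthetic genomes with the structure the arm analyses assume.

Each simulated chromosome is laid out as

    [5' telomere array][short arm][central N gap][long arm][3' telomere array]

with per-arm base composition drawn i.i.d. at the arm's GC fraction,
soft-masked (lowercase) repeat intervals placed uniformly without overlap
to a target density, genes placed uniformly without overlap at a configurable
rate, and an optional tandem locus whose read depth is inflated by a known
multiplier (emulating a collapsed rDNA array).  A companion reference
genome concatenates the two arms of each chromosome into one "linkage
group" (gap removed, arms optionally reverse-complemented, point-substituted
at a chosen divergence), and alignment blocks, depth tracks and
block-structured contact matrices are generated against the recorded truth.

Everything is deterministic given (specs, seed): one master seed is split
deterministically per sub-generator so stages can be regenerated
independently.  Base composition is i.i.d. per arm — no dinucleotide
structure — which keeps every downstream statistic's expectation available
in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .io import (
    AlignmentBlock,
    DepthTrack,
    GenomicInterval,
    SequenceRecord,
    revcomp,
)
from .telomeres import TELOMERE_MOTIF

_MASK_LEN = 500  # fixed repeat-interval length; density, not length, is contrasted
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TandemLocusSpec:
    """A tandem array collapsed in the assembly but present at higher depth."""

    arm: str  # "short" | "long"
    offset: int  # bp from arm start
    unit_len: int = 2000
    assembled_copies: int = 4
    depth_multiplier: float = 5.0


@dataclass
class ChromosomeSpec:
    """Layout and composition of one simulated two-armed chromosome."""

    name: str
    short_arm_len: int
    long_arm_len: int
    gc_short: float = 0.38
    gc_long: float = 0.42
    repeat_density_short: float = 0.30
    repeat_density_long: float = 0.15
    telomere_units_5p: int = 50
    telomere_units_3p: int = 50
    gap_len: int = 500
    gene_rate: float = 1e-4  # genes per bp of arm
    gene_len: int = 1000
    tandem_locus: TandemLocusSpec | None = None

    def __post_init__(self) -> None:
        if self.short_arm_len > self.long_arm_len:
            raise ParameterError(f"{self.name}: short arm longer than long arm")
        for frac in (self.gc_short, self.gc_long,
                     self.repeat_density_short, self.repeat_density_long):
            if not 0.0 <= frac <= 1.0:
                raise ParameterError(f"{self.name}: fraction {frac} outside [0,1]")
        if self.telomere_units_5p < 0 or self.telomere_units_3p < 0:
            raise ParameterError(f"{self.name}: telomere unit counts must be >= 0")
        if self.gap_len <= 0:
            raise ParameterError(f"{self.name}: gap_len must be positive")


@dataclass
class ArmPlacement:
    """Where one arm lives on its reference linkage group."""

    arm_id: str
    chrom: str
    side: str  # short | long
    lg: str
    lg_start: int
    lg_end: int
    orientation: str  # + if the arm is forward on the LG
    arm_len: int


@dataclass
class GenomeTruth:
    """Ground-truth annotations for a simulated genome."""

    telomeres: list[GenomicInterval] = field(default_factory=list)
    gaps: list[GenomicInterval] = field(default_factory=list)
    masks: list[GenomicInterval] = field(default_factory=list)
    genes: list[GenomicInterval] = field(default_factory=list)
    arm_map: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    tandem_loci: list[dict] = field(default_factory=list)

    def gap_of(self, seq_id: str) -> GenomicInterval:
        for g in self.gaps:
            if g.seq_id == seq_id:
                return g
        raise KeyError(seq_id)


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    # stable named streams off one master seed
    name_key = sum(ord(c) * (i + 1) for i, c in enumerate(stream))
    return np.random.default_rng(np.random.SeedSequence([seed, name_key]))


def _random_arm(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _place_nonoverlapping(
    rng: np.random.Generator, region_len: int, n: int, item_len: int
) -> list[int]:
    """Uniform non-overlapping starts via the gap-insertion construction."""
    slack = region_len - n * item_len
    if slack < 0:
        raise ParameterError(
            f"cannot place {n} items of {item_len} bp in {region_len} bp"
        )
    if n == 0:
        return []
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    return [int(cuts[i] + i * item_len) for i in range(n)]


def simulate_genome(
    specs: list[ChromosomeSpec], seed: int
) -> tuple[list[SequenceRecord], GenomeTruth]:
    """Generate a genome and its ground truth from chromosome specs.

    Deterministic given (specs, seed).  Soft-masked intervals of fixed
    500-bp length are placed uniformly without overlap inside each arm until
    the arm's repeat density is reached (rounded to whole intervals); genes
    are placed uniformly without overlap at ``gene_rate`` per arm bp.
    Telomere units are exact TTAGGG (5', strand +) and CCCTAA (3',
    strand -) repeats recorded in the truth.
    """
    records: list[SequenceRecord] = []
    truth = GenomeTruth()
    for ci, spec in enumerate(specs):
        rng = _child_rng(seed, f"genome:{spec.name}")
        lg = f"LG{ci + 1}"
        tel5 = TELOMERE_MOTIF * spec.telomere_units_5p
        tel3 = revcomp(TELOMERE_MOTIF) * spec.telomere_units_3p

        arms: dict[str, np.ndarray] = {}
        for side, length, gc in (
            ("short", spec.short_arm_len, spec.gc_short),
            ("long", spec.long_arm_len, spec.gc_long),
        ):
            arms[side] = _random_arm(rng, length, gc)

        # tandem locus: overwrite part of an arm with a repeated unit
        if spec.tandem_locus is not None:
            tl = spec.tandem_locus
            arm = arms[tl.arm]
            span = tl.unit_len * tl.assembled_copies
            if tl.offset < 0 or tl.offset + span > len(arm):
                raise ParameterError(f"{spec.name}: tandem locus outside its arm")
            unit = arm[tl.offset:tl.offset + tl.unit_len].copy()
            arm[tl.offset:tl.offset + span] = np.tile(unit, tl.assembled_copies)

        # repeat masks: lowercase fixed-length intervals at the target density
        mask_local: dict[str, list[tuple[int, int]]] = {"short": [], "long": []}
        for side, density in (
            ("short", spec.repeat_density_short),
            ("long", spec.repeat_density_long),
        ):
            arm = arms[side]
            n_masks = int(round(density * len(arm) / _MASK_LEN))
            if n_masks * _MASK_LEN > len(arm):
                raise ParameterError(
                    f"{spec.name}: repeat density {density} infeasible on {side} arm"
                )
            for s in _place_nonoverlapping(rng, len(arm), n_masks, _MASK_LEN):
                arm[s:s + _MASK_LEN] |= 0x20  # lowercase
                mask_local[side].append((s, s + _MASK_LEN))

        # genes: uniform non-overlapping, counted per arm
        gene_local: dict[str, list[tuple[int, int]]] = {"short": [], "long": []}
        for side in ("short", "long"):
            arm_len = len(arms[side])
            n_genes = int(round(spec.gene_rate * arm_len))
            for s in _place_nonoverlapping(rng, arm_len, n_genes, spec.gene_len):
                gene_local[side].append((s, s + spec.gene_len))

        short_seq = arms["short"].tobytes().decode("ascii")
        long_seq = arms["long"].tobytes().decode("ascii")
        seq = tel5 + short_seq + "N" * spec.gap_len + long_seq + tel3
        records.append(SequenceRecord(spec.name, seq))

        # assemble truth in chromosome coordinates
        off_short = len(tel5)
        gap_start = off_short + len(short_seq)
        off_long = gap_start + spec.gap_len
        end_long = off_long + len(long_seq)
        if spec.telomere_units_5p:
            truth.telomeres.append(
                GenomicInterval(spec.name, 0, len(tel5), strand="+", label="telomere")
            )
        if spec.telomere_units_3p:
            truth.telomeres.append(
                GenomicInterval(spec.name, end_long, end_long + len(tel3),
                                strand="-", label="telomere")
            )
        truth.gaps.append(
            GenomicInterval(spec.name, gap_start, off_long, label="gap")
        )
        offsets = {"short": off_short, "long": off_long}
        for side in ("short", "long"):
            off = offsets[side]
            for s, e in mask_local[side]:
                truth.masks.append(
                    GenomicInterval(spec.name, off + s, off + e, label="repeat")
                )
            for gi, (s, e) in enumerate(gene_local[side]):
                truth.genes.append(
                    GenomicInterval(spec.name, off + s, off + e, strand="+",
                                    label=f"{spec.name}_{side}_g{gi + 1}")
                )
            truth.arm_map[f"{spec.name}_{side}"] = (spec.name, side, lg)
        if spec.tandem_locus is not None:
            tl = spec.tandem_locus
            off = offsets[tl.arm]
            span = tl.unit_len * tl.assembled_copies
            truth.tandem_loci.append(
                {
                    "interval": GenomicInterval(
                        spec.name, off + tl.offset, off + tl.offset + span,
                        label="tandem"),
                    "assembled_copies": tl.assembled_copies,
                    "depth_multiplier": tl.depth_multiplier,
                    "true_copies": tl.assembled_copies * tl.depth_multiplier,
                }
            )
    return records, truth


def arm_records(
    records: list[SequenceRecord],
    truth: GenomeTruth,
    flip_prob: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, bool]]:
    """Cut each chromosome at its gap into two arm scaffolds.

    The short-arm scaffold keeps its 5' telomere, the long-arm scaffold its
    3' telomere — each is a one-telomere scaffold as left by Hi-C
    scaffolding before arm pairing.  With ``flip_prob`` each scaffold is
    independently reverse-complemented (assembly orientation is arbitrary);
    the returned map records which were flipped.
    """
    rng = _child_rng(seed, "armflip")
    out: list[SequenceRecord] = []
    flips: dict[str, bool] = {}
    for rec in records:
        gap = truth.gap_of(rec.id)
        for side, seq in (
            ("short", rec.sequence[:gap.start]),
            ("long", rec.sequence[gap.end:]),
        ):
            arm_id = f"{rec.id}_{side}"
            flip = bool(rng.random() < flip_prob)
            flips[arm_id] = flip
            out.append(SequenceRecord(arm_id, revcomp(seq) if flip else seq))
    return out, flips


def simulate_reference(
    records: list[SequenceRecord],
    truth: GenomeTruth,
    divergence: float,
    seed: int,
) -> tuple[list[SequenceRecord], list[ArmPlacement]]:
    """Build a diverged reference whose linkage groups concatenate true arms.

    Each linkage group is the short arm followed by the long arm of one
    chromosome (gap removed, telomeres included); each arm is independently
    reverse-complemented with probability 0.5 (recorded in the placement
    map) and point-substituted at the given rate.
    """
    if not 0.0 <= divergence <= 0.2:
        raise ParameterError("divergence must be in [0, 0.2]")
    rng = _child_rng(seed, "reference")
    refs: list[SequenceRecord] = []
    placements: list[ArmPlacement] = []
    by_id = {r.id: r for r in records}
    lgs: dict[str, list[tuple[str, str, str]]] = {}
    for arm_id, (chrom, side, lg) in truth.arm_map.items():
        lgs.setdefault(lg, []).append((arm_id, chrom, side))

    for lg in sorted(lgs):
        parts = sorted(lgs[lg], key=lambda t: 0 if t[2] == "short" else 1)
        seq_parts: list[str] = []
        pos = 0
        for arm_id, chrom, side in parts:
            rec = by_id[chrom]
            gap = truth.gap_of(chrom)
            arm_seq = rec.sequence[:gap.start] if side == "short" else rec.sequence[gap.end:]
            flip = bool(rng.random() < 0.5)
            placed = revcomp(arm_seq) if flip else arm_seq
            placed = _substitute(rng, placed, divergence)
            placements.append(
                ArmPlacement(
                    arm_id=arm_id, chrom=chrom, side=side, lg=lg,
                    lg_start=pos, lg_end=pos + len(placed),
                    orientation="-" if flip else "+",
                    arm_len=len(arm_seq),
                )
            )
            seq_parts.append(placed)
            pos += len(placed)
        refs.append(SequenceRecord(lg, "".join(seq_parts)))
    return refs, placements


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lower = arr >= 97
    upper = np.where(lower, arr - 32, arr)
    is_base = upper != ord("N")
    hit = (rng.random(len(arr)) < rate) & is_base
    idx = np.nonzero(hit)[0]
    if idx.size:
        # replace with one of the three other bases, preserving case
        cur = upper[idx]
        choice = rng.integers(0, 3, size=idx.size)
        for bi, base in enumerate(_BASES):
            sel = cur == base
            alts = np.delete(_BASES, bi)
            upper[idx[sel]] = alts[choice[sel] % 3]
        new = np.where(lower, upper + 32, upper)
        arr[idx] = new[idx]
    return arr.tobytes().decode("ascii")


def simulate_alignment_blocks(
    arm_map: list[ArmPlacement],
    block_len: int = 1000,
    n_blocks_per_arm: int = 50,
    jitter: int = 0,
    noise_fraction: float = 0.0,
    seed: int = 0,
    query_flips: dict[str, bool] | None = None,
) -> tuple[list[AlignmentBlock], list[bool]]:
    """Arm-structured one-to-one alignment blocks against the reference.

    For each arm, ``n_blocks_per_arm`` blocks tile the arm with uniformly
    jittered positions and map to the corresponding linkage-group location
    and orientation.  A fraction ``noise_fraction`` of blocks is re-targeted
    to a uniformly chosen wrong linkage group at a uniform position (same
    length, random strand) — the simplest adversary for majority-vote arm
    assignment.  ``query_flips`` mirrors query coordinates of scaffolds
    that were reverse-complemented by :func:`arm_records`.  Returns the
    blocks and a parallel is-noise truth vector.
    """
    if not 0.0 <= noise_fraction <= 0.5:
        raise ParameterError("noise_fraction must be in [0, 0.5]")
    rng = _child_rng(seed, "blocks")
    lg_len = {}
    for p in arm_map:
        lg_len[p.lg] = max(lg_len.get(p.lg, 0), p.lg_end)
    lg_ids = sorted(lg_len)
    blocks: list[AlignmentBlock] = []
    is_noise: list[bool] = []
    for p in sorted(arm_map, key=lambda p: p.arm_id):
        if block_len > p.arm_len:
            raise ParameterError(
                f"{p.arm_id}: block_len {block_len} exceeds arm length {p.arm_len}"
            )
        if n_blocks_per_arm == 0:
            continue
        spacing = p.arm_len / n_blocks_per_arm
        flipped_q = bool(query_flips.get(p.arm_id, False)) if query_flips else False
        for i in range(n_blocks_per_arm):
            q0 = int(round(i * spacing))
            if jitter:
                q0 += int(rng.integers(-jitter, jitter + 1))
            q0 = max(0, min(q0, p.arm_len - block_len))
            q1 = q0 + block_len
            noise = bool(rng.random() < noise_fraction)
            if noise and len(lg_ids) > 1:
                wrong = [l for l in lg_ids if l != p.lg]
                tgt = wrong[int(rng.integers(0, len(wrong)))]
                t0 = int(rng.integers(0, lg_len[tgt] - block_len + 1))
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                noise = False
                tgt = p.lg
                if p.orientation == "+":
                    t0 = p.lg_start + q0
                    strand = "+"
                else:
                    t0 = p.lg_start + (p.arm_len - q1)
                    strand = "-"
            qa, qb = (p.arm_len - q1, p.arm_len - q0) if flipped_q else (q0, q1)
            strand_out = strand
            if flipped_q:
                strand_out = "-" if strand == "+" else "+"
            blocks.append(
                AlignmentBlock(p.arm_id, qa, qb, tgt, t0, t0 + block_len,
                               strand_out, score=block_len)
            )
            is_noise.append(noise)
    return blocks, is_noise


def simulate_depth(
    records: list[SequenceRecord],
    truth: GenomeTruth,
    mean_depth: float = 50.0,
    dispersion: float | None = None,
    seed: int = 0,
    resolution: int = 100,
) -> dict[str, DepthTrack]:
    """Negative-binomial per-step depth with tandem-locus inflation.

    ``dispersion`` is the negative-binomial size parameter k (variance
    m + m^2/k); None means the Poisson limit.  Steps fully inside an N gap
    get depth exactly 0; steps fully inside a tandem locus have their mean
    multiplied by the locus's depth multiplier.
    """
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    if dispersion is not None and dispersion <= 0:
        raise ParameterError("dispersion must be positive (or None for Poisson)")
    rng = _child_rng(seed, "depth")
    tracks: dict[str, DepthTrack] = {}
    loci = [(t["interval"], t["depth_multiplier"]) for t in truth.tandem_loci]
    for rec in records:
        n_steps = math.ceil(len(rec.sequence) / resolution)
        means = np.full(n_steps, float(mean_depth))
        starts = np.arange(n_steps) * resolution
        ends = np.minimum(starts + resolution, len(rec.sequence))
        for iv, mult in loci:
            if iv.seq_id != rec.id:
                continue
            inside = (starts >= iv.start) & (ends <= iv.end)
            means[inside] *= mult
        if dispersion is None:
            vals = rng.poisson(means).astype(float)
        else:
            p = dispersion / (dispersion + means)
            vals = rng.negative_binomial(dispersion, p).astype(float)
        for g in truth.gaps:
            if g.seq_id == rec.id:
                gap_steps = (starts >= g.start) & (ends <= g.end)
                vals[gap_steps] = 0.0
        tracks[rec.id] = DepthTrack(rec.id, resolution, vals)
    return tracks


DEFAULT_CONTACT_MEANS = {"intra_arm": 10.0, "inter_arm_same_chrom": 1.0,
                         "inter_chrom": 1.0}


def simulate_contacts(
    bins: list[GenomicInterval],
    arm_of_bin: list,
    means: dict[str, float] = DEFAULT_CONTACT_MEANS,
    seed: int = 0,
):
    """Block-structured Poisson contact matrix over annotated bins.

    Entry (i, j) is Poisson with the mean of its category — same arm label,
    different arms of one sequence, or different sequences; the diagonal is
    zero and the matrix is symmetric.  Bins labeled ``excluded`` draw from
    the inter-chromosome mean.
    """
    from .contacts import ContactMatrix, EXCLUDED  # local import avoids a cycle

    for k in ("intra_arm", "inter_arm_same_chrom", "inter_chrom"):
        if means.get(k, -1) < 0:
            raise ParameterError(f"contact mean {k!r} must be >= 0")
    rng = _child_rng(seed, "contacts")
    n = len(bins)
    if len(arm_of_bin) != n:
        raise ParameterError("one arm label per bin required")
    counts = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            li, lj = arm_of_bin[i], arm_of_bin[j]
            if li == EXCLUDED or lj == EXCLUDED:
                mu = means["inter_chrom"]
            elif li == lj:
                mu = means["intra_arm"]
            elif bins[i].seq_id == bins[j].seq_id:
                mu = means["inter_arm_same_chrom"]
            else:
                mu = means["inter_chrom"]
            c = float(rng.poisson(mu))
            counts[i, j] = counts[j, i] = c
    return ContactMatrix(list(bins), counts)


# ---------------------------------------------------------------------------
# Config-driven bundle (backs `chromarm simulate`)
# ---------------------------------------------------------------------------


def specs_from_config(path: str | Path) -> list[ChromosomeSpec]:
    """Load chromosome specs from a YAML/JSON config mirroring ChromosomeSpec."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    chroms = cfg["chromosomes"] if isinstance(cfg, dict) else cfg
    specs = []
    for c in chroms:
        c = dict(c)
        if c.get("tandem_locus"):
            c["tandem_locus"] = TandemLocusSpec(**c["tandem_locus"])
        specs.append(ChromosomeSpec(**c))
    return specs


def simulate_bundle(
    specs: list[ChromosomeSpec],
    seed: int,
    outdir: str | Path,
    divergence: float = 0.02,
    block_len: int = 1000,
    n_blocks_per_arm: int = 50,
    noise_fraction: float = 0.05,
    mean_depth: float = 50.0,
    contact_bin_size: int = 10_000,
) -> None:
    """Write a complete synthetic data set plus truth files to ``outdir``."""
    from . import io as cio
    from .contacts import assign_bins_to_arms, make_bins
    from .landscape import split_at_gap

    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    records, truth = simulate_genome(specs, seed)
    arms, _flips = arm_records(records, truth, flip_prob=0.0, seed=seed)
    refs, placements = simulate_reference(records, truth, divergence, seed)
    blocks, _ = simulate_alignment_blocks(
        placements, block_len=block_len, n_blocks_per_arm=n_blocks_per_arm,
        jitter=block_len // 4, noise_fraction=noise_fraction, seed=seed,
    )
    depth = simulate_depth(records, truth, mean_depth=mean_depth, seed=seed)
    partitions = [split_at_gap(r, truth.gaps) for r in records]
    bins = make_bins({r.id: len(r.sequence) for r in records}, contact_bin_size)
    labels = assign_bins_to_arms(bins, partitions)
    cmat = simulate_contacts(bins, labels, seed=seed)

    cio.write_fasta(records, outdir / "genome.fa")
    cio.write_fasta(arms, outdir / "arms.fa")
    cio.write_fasta(refs, outdir / "reference.fa")
    cio.write_bed(truth.telomeres, outdir / "truth" / "telomeres.bed")
    cio.write_bed(truth.gaps, outdir / "truth" / "gaps.bed")
    cio.write_bed(truth.masks, outdir / "truth" / "masks.bed")
    cio.write_gff3_genes(truth.genes, outdir / "truth" / "genes.gff3")
    cio.write_depth(depth.values(), outdir / "depth.tsv")
    cio.write_alignment_blocks(blocks, outdir / "blocks.tsv")
    cio.write_bed(bins, outdir / "bins.bed")
    cio.write_contacts_triplet(cmat.counts, outdir / "contacts.tsv")
    with open(outdir / "truth" / "arm_map.tsv", "w") as fh:
        fh.write("# arm_id\tchrom\tside\tlg\n")
        for arm_id, (chrom, side, lg) in sorted(truth.arm_map.items()):
            fh.write(f"{arm_id}\t{chrom}\t{side}\t{lg}\n")
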