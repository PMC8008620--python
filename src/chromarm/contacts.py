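"""Arm-level summaries of binned Hi-C contact matrices.

Two questions about chromosome-scale contact maps are quantified here:

* how strongly do loci interact within an arm compared with the other arm
  of the same chromosome, and compared with other chromosomes — the
  "arms behave as separate contact domains" observation; and
* are chromosome ends (telomeric/pericentromeric bins) enriched for
  inter-chromosomal contacts relative to background — the off-diagonal
  clustering signal.

Counts are taken as given (raw or pre-balanced): the summaries concern
relative category intensity, and matrix balancing has many dialects best
left to dedicated tools.  Genomic-distance dependence within categories is
deliberately not modelled; see the package methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError
from .io import GenomicInterval
from .landscape import ArmPartition

EXCLUDED = "excluded"

CATEGORIES = ("intra_arm", "inter_arm_same_chrom", "inter_chrom")


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts over ordered, uniform genome bins."""

    bins: list[GenomicInterval]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise InputError(
                f"counts shape {self.counts.shape} does not match {n} bins"
            )
        if np.any(self.counts < 0):
            raise InputError("contact counts must be nonnegative")
        if not np.allclose(self.counts, self.counts.T):
            raise InputError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass
class ArmContactSummary:
    mean_intra_arm: float
    mean_inter_arm_same_chrom: float
    mean_inter_chrom: float
    ratio_intra_vs_inter_arm: float
    ratio_inter_arm_vs_inter_chrom: float
    n_pairs: dict[str, int]


def make_bins(seq_lengths: dict[str, int], bin_size: int) -> list[GenomicInterval]:
    """Uniform tiling bins per sequence, in sequence order (last bin short)."""
    if bin_size <= 0:
        raise ParameterError("bin_size must be positive")
    bins = []
    for sid, n in seq_lengths.items():
        for s in range(0, n, bin_size):
            bins.append(GenomicInterval(sid, s, min(s + bin_size, n), label="bin"))
    return bins


def assign_bins_to_arms(
    bins: list[GenomicInterval], partitions: list[ArmPartition]
) -> list[tuple[str, str] | str]:
    """Label each bin with its (chromosome, arm-side) or ``excluded``.

    A bin gets an arm label when at least half of its span lies inside that
    arm; bins straddling the gap 50/50, overlapping it, or sitting on an
    unpartitioned sequence are excluded.
    """
    by_seq = {p.seq_id: p for p in partitions}
    labels: list[tuple[str, str] | str] = []
    for b in bins:
        part = by_seq.get(b.seq_id)
        if part is None:
            labels.append(EXCLUDED)
            continue
        half = len(b) / 2.0
        assigned: tuple[str, str] | str = EXCLUDED
        for side, arm in (("short", part.short_arm), ("long", part.long_arm)):
            overlap = min(b.end, arm.end) - max(b.start, arm.start)
            if overlap > half or (overlap == half and overlap == len(b)):
                assigned = (b.seq_id, side)
                break
        labels.append(assigned)
    return labels


def _category_masks(
    labels: list[tuple[str, str] | str],
    bins: list[GenomicInterval],
    exclude_diag_bins: int,
) -> dict[str, np.ndarray]:
    n = len(labels)
    # integer arm ids make same-arm a plain equality on arrays
    arm_ids: dict = {}
    ids = np.array([
        -1 if l == EXCLUDED else arm_ids.setdefault(l, len(arm_ids))
        for l in labels
    ])
    seqs = np.array([b.seq_id for b in bins])
    idx = np.arange(n)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    upper = ii < jj
    labeled = ids >= 0
    eligible = upper & labeled[ii] & labeled[jj]
    same_seq = seqs[ii] == seqs[jj]
    near_diag = same_seq & (np.abs(ii - jj) <= exclude_diag_bins)
    eligible &= ~near_diag

    same_arm = (ids[ii] == ids[jj]) & labeled[ii]
    masks = {
        "intra_arm": eligible & same_arm,
        "inter_arm_same_chrom": eligible & same_seq & ~same_arm,
        "inter_chrom": eligible & ~same_seq,
    }
    return masks


def arm_contact_summary(
    matrix: ContactMatrix,
    labels: list[tuple[str, str] | str],
    exclude_diag_bins: int = 1,
) -> ArmContactSummary:
    """Mean contact per bin pair in the three arm categories.

    Every unordered pair of labeled bins — excluding same-sequence pairs
    within ``exclude_diag_bins`` of the diagonal, which carry self/adjacent
    ligation signal — contributes to exactly one of: intra-arm, inter-arm
    same chromosome, inter-chromosome.  Ratios are NaN when a denominator
    category is empty or zero.
    """
    if len(labels) != matrix.n_bins:
        raise InputError("one label per bin required")
    arm_ids = {l for l in labels if l != EXCLUDED}
    if len(arm_ids) < 2:
        raise InputError("need at least two labeled arms")
    masks = _category_masks(labels, matrix.bins, exclude_diag_bins)
    means: dict[str, float] = {}
    n_pairs: dict[str, int] = {}
    for cat, mask in masks.items():
        n_pairs[cat] = int(mask.sum())
        means[cat] = float(matrix.counts[mask].mean()) if n_pairs[cat] else float("nan")

    def ratio(a: float, b: float) -> float:
        return a / b if b and not np.isnan(b) and b > 0 else float("nan")

    return ArmContactSummary(
        mean_intra_arm=means["intra_arm"],
        mean_inter_arm_same_chrom=means["inter_arm_same_chrom"],
        mean_inter_chrom=means["inter_chrom"],
        ratio_intra_vs_inter_arm=ratio(means["intra_arm"], means["inter_arm_same_chrom"]),
        ratio_inter_arm_vs_inter_chrom=ratio(
            means["inter_arm_same_chrom"], means["inter_chrom"]
        ),
        n_pairs=n_pairs,
    )


def end_clustering_score(
    matrix: ContactMatrix,
    end_regions: list[GenomicInterval],
    labels: list[tuple[str, str] | str] | None = None,
) -> float:
    """Enrichment of inter-chromosomal contact among chromosome-end bins.

    Bins overlapping any end region (telomeric or pericentromeric interval)
    form the end set; the remaining (labeled, when labels are given) bins
    are background.  The score is the ratio of mean inter-chromosomal
    contact between end bins to mean inter-chromosomal contact between
    background bins.  Scale-invariant by construction.
    """
    if not end_regions:
        raise InputError("empty end-region set")
    n = matrix.n_bins
    is_end = np.zeros(n, dtype=bool)
    for i, b in enumerate(matrix.bins):
        for r in end_regions:
            if r.seq_id == b.seq_id and min(b.end, r.end) > max(b.start, r.start):
                is_end[i] = True
                break
    if not is_end.any():
        raise InputError("no bin overlaps the end regions")
    usable = np.ones(n, dtype=bool)
    if labels is not None:
        usable = np.array([l != EXCLUDED for l in labels])
    seqs = np.array([b.seq_id for b in matrix.bins])
    idx = np.arange(n)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    inter = (ii < jj) & (seqs[ii] != seqs[jj]) & usable[ii] & usable[jj]
    end_mask = inter & is_end[ii] & is_end[jj]
    bg_mask = inter & ~is_end[ii] & ~is_end[jj]
    if not end_mask.any() or not bg_mask.any():
        raise InputError("no inter-chromosomal pairs in end or background set")
    end_mean = float(matrix.counts[end_mask].mean())
    bg_mean = float(matrix.counts[bg_mask].mean())
    if bg_mean == 0:
        return float("nan")
    return end_mean / bg_mean
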