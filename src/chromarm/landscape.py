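"""Windowed chromosome-arm feature landscapes and the dual-test arm contrast.

Each chromosome-scale scaffold is tiled with fixed windows (50 kbp by
default) and per-window GC content, soft-masked repeat fraction, mean
sequencing depth, DpnII (GATC) restriction-site count and gene count are
computed.  Chromosomes are split into a short and a long arm at their
central centromeric N-gap, and each feature is contrasted between arms with
both Welch's unequal-variance t test and the Mann-Whitney rank test; a
difference is called significant only when BOTH two-sided p-values fall
below 0.05.  No multiple-testing correction is applied across features;
raw p-values are reported so users can correct downstream.

The module also carries the coverage-ratio estimator for the true copy
number of a collapsed tandem locus (e.g. an rDNA array): assembled copies
scaled by the ratio of locus read depth to the genome-wide reference depth.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ParameterError, PartitionError
from .io import DepthTrack, GenomicInterval, SequenceRecord

WINDOW_COLUMNS = [
    "seq_id", "window_index", "start", "end", "gc_fraction", "repeat_fraction",
    "depth_mean", "dpnii_count", "gene_count", "arm", "partial",
]

ARM_FEATURES = ["gc_fraction", "repeat_fraction", "depth_mean", "dpnii_count", "gene_count"]

GAP_LABELS = frozenset({"gap", "centromere", "centromeric_gap"})


@dataclass(frozen=True)
class ArmPartition:
    """A chromosome split at its central gap into short and long arms."""

    seq_id: str
    gap: GenomicInterval
    short_arm: GenomicInterval
    long_arm: GenomicInterval

    @property
    def short_side(self) -> str:
        """'left' when the short arm precedes the gap."""
        return "left" if self.short_arm.start < self.gap.start else "right"


@dataclass(frozen=True)
class ArmComparison:
    feature: str
    n_short: int
    n_long: int
    mean_short: float
    mean_long: float
    welch_t: float
    welch_df: float
    welch_p: float
    mw_u: float
    mw_p: float
    significant: bool


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def _find_motif_starts(seq_upper: str, motif: str) -> np.ndarray:
    starts = []
    i = seq_upper.find(motif)
    while i != -1:
        starts.append(i)
        i = seq_upper.find(motif, i + 1)  # overlapping occurrences count
    return np.array(starts, dtype=int)


def compute_windows(
    record: SequenceRecord,
    depth: DepthTrack | None = None,
    genes: list[GenomicInterval] | None = None,
    window: int = 50_000,
    dpnii_motif: str = "GATC",
    partition: ArmPartition | None = None,
) -> pd.DataFrame:
    """Tile one sequence with fixed windows and compute per-window features.

    Windows are [0,w), [w,2w), ... with a final short window flagged
    ``partial``.  GC uses an N-free denominator (an all-N window yields
    NaN); repeat fraction is soft-masked (lowercase) bp over the full window
    span; restriction sites are counted case-insensitively on the forward
    strand only (GATC is its own reverse complement, so scanning both
    strands would exactly double every count) and assigned to the window
    containing the site's first base; genes are counted by start position so
    window counts sum to the per-sequence total.  When a partition is given,
    windows fully inside an arm are labelled short/long, windows touching
    the gap are labelled gap, and anything else is unassigned.
    """
    if window <= 0:
        raise ParameterError("window must be positive")
    dpnii_motif = dpnii_motif.upper()
    if window < len(dpnii_motif):
        raise ParameterError("window shorter than restriction motif")

    n = len(record.sequence)
    b = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    lower = (b >= 97)
    upper = np.where(lower, b - 32, b)
    is_n = upper == ord("N")
    is_gc = (upper == ord("G")) | (upper == ord("C"))

    n_windows = max(1, math.ceil(n / window)) if n else 0
    edges = np.arange(0, n_windows * window + 1, window)
    edges[-1] = n
    starts, ends = edges[:-1], edges[1:]

    if n:
        cut = starts  # reduceat over window starts
        gc_sum = np.add.reduceat(is_gc.astype(np.int64), cut)
        n_sum = np.add.reduceat(is_n.astype(np.int64), cut)
        rep_sum = np.add.reduceat(lower.astype(np.int64), cut)
    else:
        gc_sum = n_sum = rep_sum = np.array([], dtype=np.int64)

    spans = ends - starts
    informative = spans - n_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(informative > 0, gc_sum / np.maximum(informative, 1), np.nan)
    rep = rep_sum / spans

    site_starts = _find_motif_starts(record.sequence.upper(), dpnii_motif)
    dpnii = np.bincount(site_starts // window, minlength=n_windows)[:n_windows] if site_starts.size else np.zeros(n_windows, dtype=int)

    gene_counts = np.zeros(n_windows, dtype=int)
    if genes:
        g_starts = np.array([g.start for g in genes if g.seq_id == record.id], dtype=int)
        if g_starts.size:
            gene_counts = np.bincount(g_starts // window, minlength=n_windows)[:n_windows]

    depth_mean = np.full(n_windows, np.nan)
    if depth is not None:
        if depth.seq_id != record.id:
            raise ParameterError(
                f"depth track is for {depth.seq_id!r}, not {record.id!r}"
            )
        r = depth.resolution
        for i in range(n_windows):
            lo = starts[i] // r
            hi = math.ceil(ends[i] / r)
            vals = depth.values[lo:hi]
            if vals.size:
                depth_mean[i] = float(np.mean(vals))

    arm = np.full(n_windows, "unassigned", dtype=object)
    if partition is not None and partition.seq_id == record.id:
        for i in range(n_windows):
            s, e = starts[i], ends[i]
            if e > partition.gap.start and s < partition.gap.end:
                arm[i] = "gap"
            elif partition.short_arm.start <= s and e <= partition.short_arm.end:
                arm[i] = "short"
            elif partition.long_arm.start <= s and e <= partition.long_arm.end:
                arm[i] = "long"

    return pd.DataFrame(
        {
            "seq_id": record.id,
            "window_index": np.arange(n_windows),
            "start": starts,
            "end": ends,
            "gc_fraction": gc,
            "repeat_fraction": rep,
            "depth_mean": depth_mean,
            "dpnii_count": dpnii,
            "gene_count": gene_counts,
            "arm": arm,
            "partial": spans != window,
        }
    )


# ---------------------------------------------------------------------------
# Arm partition
# ---------------------------------------------------------------------------


def split_at_gap(record: SequenceRecord, gaps: list[GenomicInterval]) -> ArmPartition:
    """Split a chromosome at its single central gap into short and long arms.

    Only gaps labelled as centromeric (``gap``/``centromere``, or unlabeled)
    on this sequence count.  Exactly one is required: scaffolds without a
    central gap (e.g. sex-specific regions) are legitimately unpartitioned
    and raise :class:`PartitionError`.  The shorter flank is the short arm;
    an exact tie labels the left flank short.
    """
    mine = [
        g for g in gaps
        if g.seq_id == record.id and (not g.label or g.label.lower() in GAP_LABELS)
    ]
    if len(mine) != 1:
        raise PartitionError(
            f"{record.id!r}: need exactly one centromeric gap, found {len(mine)}"
        )
    gap = mine[0]
    n = len(record.sequence)
    if not (0 < gap.start and gap.end < n):
        raise PartitionError(f"{record.id!r}: gap {gap.start}-{gap.end} is terminal")
    left = GenomicInterval(record.id, 0, gap.start, label="arm")
    right = GenomicInterval(record.id, gap.end, n, label="arm")
    if len(left) <= len(right):
        short, long_ = left, right
    else:
        short, long_ = right, left
    return ArmPartition(record.id, gap, short, long_)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t test (two-sided).

    Returns (t, Welch-Satterthwaite df, p).  Requires n >= 2 per sample and
    nonzero variance in at least one sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateInputError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateInputError("both samples have zero variance")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


_EXACT_N_MAX = 16


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided), U reported for the first sample.

    Midranks resolve ties.  The p-value is exact (full enumeration of rank
    assignments) when n_x + n_y <= 16 and there are no ties; otherwise the
    normal approximation with tie correction and a 0.5 continuity correction
    is used.  Two-sided exact p is twice the smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise DegenerateInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < nx + ny

    if nx + ny <= _EXACT_N_MAX and not has_ties:
        p = _exact_mw_p(u_x, nx, ny)
    else:
        mu = nx * ny / 2.0
        counts = np.unique(pooled, return_counts=True)[1]
        tie_term = float(np.sum(counts**3 - counts))
        n = nx + ny
        var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            return u_x, 1.0
        z = max(0.0, abs(u_x - mu) - 0.5) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(z)
    return u_x, float(min(p, 1.0))


def _exact_mw_p(u_obs: float, nx: int, ny: int) -> float:
    """Two-sided exact p by enumerating all C(nx+ny, nx) rank labelings."""
    n = nx + ny
    offset = nx * (nx - 1) // 2  # positions are 0-based ranks
    us = [
        sum(comb) - offset
        for comb in itertools.combinations(range(n), nx)
    ]
    total = len(us)
    lo = sum(u <= u_obs for u in us) / total
    hi = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(lo, hi))


def dual_arm_test(short_vals, long_vals, feature: str = "", alpha: float = 0.05) -> ArmComparison:
    """Run the Welch + Mann-Whitney pair on one feature's window values.

    ``significant`` is True only when both two-sided p-values are below
    ``alpha`` — the conservative dual rule used for the arm contrast.
    """
    x = np.asarray(short_vals, dtype=float)
    y = np.asarray(long_vals, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise DegenerateInputError(
            f"feature {feature!r}: need >= 2 usable windows per arm "
            f"(got {len(x)}, {len(y)})"
        )
    t, df, p_w = welch_t_test(x, y)
    u, p_mw = mann_whitney_u(x, y)
    return ArmComparison(
        feature=feature,
        n_short=len(x), n_long=len(y),
        mean_short=float(x.mean()), mean_long=float(y.mean()),
        welch_t=t, welch_df=df, welch_p=p_w,
        mw_u=u, mw_p=p_mw,
        significant=bool(p_w < alpha and p_mw < alpha),
    )


def compare_arms(
    windows: pd.DataFrame,
    partition: ArmPartition | None = None,
    features: list[str] = ARM_FEATURES,
    alpha: float = 0.05,
    keep_partial: bool = False,
) -> list[ArmComparison]:
    """Contrast short-arm vs long-arm windows for each feature.

    Gap windows are always excluded; the final partial window is excluded
    unless ``keep_partial`` (unequal support would bias the tests).  Windows
    with a missing value are dropped per feature.  No multiple-testing
    correction is applied across features.
    """
    w = windows if keep_partial else windows[~windows["partial"]]
    short = w[w["arm"] == "short"]
    long_ = w[w["arm"] == "long"]
    out = []
    for feat in features:
        out.append(dual_arm_test(short[feat].to_numpy(), long_[feat].to_numpy(),
                                 feature=feat, alpha=alpha))
    return out


def comparisons_to_frame(comparisons: list[ArmComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


# ---------------------------------------------------------------------------
# Tandem copy number
# ---------------------------------------------------------------------------


def estimate_tandem_copies(
    assembled_copies: float,
    locus_mean_depth: float,
    genome_reference_depth: float,
) -> float:
    """Coverage-ratio estimate of the true copy number of a collapsed tandem.

    An assembler limited by read length collapses a long tandem array onto a
    few assembled units; reads from all true copies then pile onto those
    units, so true copies ≈ assembled copies × (locus depth / genome depth).
    """
    if assembled_copies <= 0 or locus_mean_depth <= 0 or genome_reference_depth <= 0:
        raise ParameterError("all inputs must be positive")
    return assembled_copies * locus_mean_depth / genome_reference_depth
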