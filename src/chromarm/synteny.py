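"""Two-level alignment collation, the chromosome/linkage-group proportion
matrix, and synteny-guided pairing of arm scaffolds into gapped chromosomes.

The collation hierarchy mirrors how one-to-one whole-genome alignments are
condensed for synteny work:

* **match regions** — colinear same-strand chains of alignment blocks,
  joined while the gap on *both* genomes stays within ``join_distance``
  (200 kbp by default) and query order is consistent with the strand;
* **syntenic regions** — same-landmark groupings of match regions on the
  target genome within ``max_distance`` (500 kbp by default), regardless of
  strand or colinearity, so regions of different query landmarks may
  overlap.

Aggregating aligned bp per (assembly scaffold, reference linkage group)
gives a row-stochastic proportion matrix; each arm scaffold is assigned to
the linkage group holding a clear majority of its aligned bp, two arms per
group are paired with their telomeric ends facing outward, and the plan is
materialised with a fixed-length N gap standing in for the centromere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BuildError, PairingError, ParameterError
from .io import AlignmentBlock, SequenceRecord, revcomp
from .telomeres import ScaffoldTelomereStatus, terminal_side


@dataclass(frozen=True)
class MatchRegion:
    """A colinear same-strand chain of alignment blocks."""

    query_id: str
    target_id: str
    strand: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    n_blocks: int
    aligned_bp: int  # sum of target-side block lengths


@dataclass(frozen=True)
class SyntenicRegion:
    """A same-landmark grouping of match regions on the target genome."""

    target_id: str
    query_id: str
    t_start: int
    t_end: int
    n_matches: int
    aligned_bp: int


@dataclass
class SyntenyMatrix:
    """Aligned-bp and per-row proportion matrices (rows: assembly, cols: LGs)."""

    aligned_bp: pd.DataFrame
    proportion: pd.DataFrame  # rows with zero alignment are NaN


@dataclass(frozen=True)
class ArmAssignment:
    arm_id: str
    lg: str | None  # None = ambiguous
    fraction: float
    margin: float
    aligned_bp: int


@dataclass
class ChromosomePlan:
    name: str
    parts: list[tuple[str, str]]  # (arm seq_id, orientation + / -)
    gap_len: int = 500
    lg: str = ""
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Collation
# ---------------------------------------------------------------------------


def _joinable(prev: AlignmentBlock, nxt: AlignmentBlock, join_distance: int) -> bool:
    """Can ``nxt`` (following ``prev`` in t_start order) extend the chain?

    Requires the target-side gap and the query-side gap both <= the join
    distance (overlaps count as gap <= 0) and query coordinates colinear
    with the strand: increasing for '+', decreasing for '-'.
    """
    if nxt.t_start - prev.t_end > join_distance:
        return False
    if prev.strand == "+":
        if nxt.q_start < prev.q_start or nxt.q_end < prev.q_end:
            return False
        return nxt.q_start - prev.q_end <= join_distance
    else:
        if nxt.q_start > prev.q_start or nxt.q_end > prev.q_end:
            return False
        return prev.q_start - nxt.q_end <= join_distance


def collate_match_parts(
    blocks: list[AlignmentBlock], join_distance: int = 200_000
) -> list[MatchRegion]:
    """Chain colinear alignment blocks into match regions.

    Blocks are grouped by (query, target, strand) and sorted by target
    start; consecutive blocks are chained while joinable (see module
    docstring), and every chain break starts a new region.
    """
    if join_distance < 0:
        raise ParameterError("join_distance must be >= 0")
    groups: dict[tuple[str, str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        groups.setdefault((b.query_id, b.target_id, b.strand), []).append(b)

    regions: list[MatchRegion] = []
    for (q, t, strand), members in sorted(groups.items()):
        members = sorted(members, key=lambda b: (b.t_start, b.t_end))
        chain: list[AlignmentBlock] = []
        for b in members:
            if chain and not _joinable(chain[-1], b, join_distance):
                regions.append(_finish_region(chain))
                chain = []
            chain.append(b)
        if chain:
            regions.append(_finish_region(chain))
    return regions


def _finish_region(chain: list[AlignmentBlock]) -> MatchRegion:
    b0 = chain[0]
    return MatchRegion(
        query_id=b0.query_id,
        target_id=b0.target_id,
        strand=b0.strand,
        q_start=min(b.q_start for b in chain),
        q_end=max(b.q_end for b in chain),
        t_start=min(b.t_start for b in chain),
        t_end=max(b.t_end for b in chain),
        n_blocks=len(chain),
        aligned_bp=sum(b.t_len for b in chain),
    )


def collate_syntenic_regions(
    matches: list[MatchRegion], max_distance: int = 500_000
) -> list[SyntenicRegion]:
    """Group match regions mapping to the same query landmark.

    Within each (target, query) pair, regions sorted by target start are
    grouped while the target-side gap to the previous member is strictly
    below ``max_distance``, regardless of strand or colinearity.  Syntenic
    regions of different query landmarks may therefore overlap on the
    target.
    """
    groups: dict[tuple[str, str], list[MatchRegion]] = {}
    for m in matches:
        groups.setdefault((m.target_id, m.query_id), []).append(m)

    out: list[SyntenicRegion] = []
    for (t, q), members in sorted(groups.items()):
        members = sorted(members, key=lambda m: (m.t_start, m.t_end))
        group: list[MatchRegion] = []
        for m in members:
            if group and m.t_start - group[-1].t_end >= max_distance:
                out.append(_finish_syntenic(group))
                group = []
            group.append(m)
        if group:
            out.append(_finish_syntenic(group))
    return out


def _finish_syntenic(group: list[MatchRegion]) -> SyntenicRegion:
    return SyntenicRegion(
        target_id=group[0].target_id,
        query_id=group[0].query_id,
        t_start=min(m.t_start for m in group),
        t_end=max(m.t_end for m in group),
        n_matches=len(group),
        aligned_bp=sum(m.aligned_bp for m in group),
    )


# ---------------------------------------------------------------------------
# Proportion matrix and arm assignment
# ---------------------------------------------------------------------------


def _union_length(spans: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(spans):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def synteny_matrix(
    blocks: list[AlignmentBlock],
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
) -> SyntenyMatrix:
    """Aligned-bp matrix of assembly scaffolds (query) vs reference LGs (target).

    The target-side footprints of all blocks pairing a row with a column are
    merged to a union before counting, so duplicated blocks over the same
    footprint are counted once.  Proportions are normalised per row by the
    row's total aligned bp (not by sequence length); a row with no aligned
    bp gets NaN proportions.
    """
    spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for b in blocks:
        spans.setdefault((b.query_id, b.target_id), []).append((b.t_start, b.t_end))
    rows = row_ids if row_ids is not None else sorted({b.query_id for b in blocks})
    cols = col_ids if col_ids is not None else sorted({b.target_id for b in blocks})

    bp = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (q, t), sp in spans.items():
        if q in bp.index and t in bp.columns:
            bp.loc[q, t] = _union_length(sp)
    totals = bp.sum(axis=1)
    prop = bp.div(totals.where(totals > 0), axis=0)
    return SyntenyMatrix(aligned_bp=bp, proportion=prop)


def assign_arm(
    arm_id: str,
    matrix: SyntenyMatrix,
    min_fraction: float = 0.5,
    min_margin: float = 0.1,
) -> ArmAssignment:
    """Majority-vote assignment of one arm scaffold to a linkage group.

    The winning column must hold at least ``min_fraction`` of the arm's
    aligned bp and lead the runner-up by at least ``min_margin``; otherwise
    the arm is reported ambiguous (lg=None) with its diagnostics.
    """
    if arm_id not in matrix.proportion.index:
        raise ParameterError(f"{arm_id!r} is not a matrix row")
    props = matrix.proportion.loc[arm_id]
    total_bp = int(matrix.aligned_bp.loc[arm_id].sum())
    if props.isna().all() or total_bp == 0:
        return ArmAssignment(arm_id, None, 0.0, 0.0, 0)
    order = props.sort_values(ascending=False)
    best, second = float(order.iloc[0]), float(order.iloc[1]) if len(order) > 1 else 0.0
    margin = best - second
    winner = str(order.index[0])
    bp_win = int(matrix.aligned_bp.loc[arm_id, winner])
    if best >= min_fraction and margin >= min_margin:
        return ArmAssignment(arm_id, winner, best, margin, bp_win)
    return ArmAssignment(arm_id, None, best, margin, bp_win)


# ---------------------------------------------------------------------------
# Pairing and building
# ---------------------------------------------------------------------------


def pair_arms(
    assignments: list[ArmAssignment],
    telomere_status: dict[str, ScaffoldTelomereStatus],
    arm_lengths: dict[str, int],
    gap_len: int = 500,
) -> list[ChromosomePlan]:
    """Pair the two arm scaffolds assigned to each linkage group.

    The shorter arm is placed first (left).  Each arm is oriented so its
    terminal telomere faces outward: the left part keeps '+' when its
    telomere is 5' and flips to '-' when 3'; the right part is the mirror
    rule.  An arm lacking any terminal telomere keeps '+' (a warning is
    recorded in the plan's provenance).  A linkage group with a number of
    assigned arms other than two raises :class:`PairingError` naming the
    offenders.
    """
    if gap_len <= 0:
        raise ParameterError("gap_len must be positive")
    by_lg: dict[str, list[ArmAssignment]] = {}
    for a in assignments:
        if a.lg is not None:
            by_lg.setdefault(a.lg, []).append(a)

    bad = {lg: [a.arm_id for a in arms] for lg, arms in by_lg.items() if len(arms) != 2}
    if bad:
        raise PairingError(f"linkage groups without exactly two assigned arms: {bad}")

    plans: list[ChromosomePlan] = []
    for lg in sorted(by_lg):
        a1, a2 = sorted(by_lg[lg], key=lambda a: (arm_lengths[a.arm_id], a.arm_id))
        left, right = a1.arm_id, a2.arm_id
        warnings = []

        def orient(arm_id: str, position: str) -> str:
            side = terminal_side(telomere_status[arm_id])
            if side is None:
                warnings.append(f"{arm_id}: no terminal telomere; kept '+'")
                return "+"
            if position == "left":
                return "+" if side == "5p" else "-"
            return "+" if side == "3p" else "-"

        plans.append(
            ChromosomePlan(
                name=f"chr_{lg}",
                parts=[(left, orient(left, "left")), (right, orient(right, "right"))],
                gap_len=gap_len,
                lg=lg,
                provenance={
                    "aligned_bp": {a.arm_id: a.aligned_bp for a in (a1, a2)},
                    "margin": {a.arm_id: a.margin for a in (a1, a2)},
                    "warnings": warnings,
                },
            )
        )
    return plans


def build_chromosomes(
    plans: list[ChromosomePlan], records: list[SequenceRecord]
) -> list[SequenceRecord]:
    """Materialise chromosome plans: oriented parts joined by N gaps.

    '-' parts are reverse-complemented with soft-mask case preserved; the
    output length is the sum of part lengths plus gap_len per junction.
    """
    by_id = {r.id: r for r in records}
    out: list[SequenceRecord] = []
    for plan in plans:
        segs = []
        for part_id, orientation in plan.parts:
            if part_id not in by_id:
                raise BuildError(f"plan {plan.name!r}: missing part {part_id!r}")
            seq = by_id[part_id].sequence
            segs.append(revcomp(seq) if orientation == "-" else seq)
        out.append(SequenceRecord(plan.name, ("N" * plan.gap_len).join(segs)))
    return out


# ---------------------------------------------------------------------------
# Tabular round-trips for the CLI
# ---------------------------------------------------------------------------


def plans_to_frame(plans: list[ChromosomePlan]) -> pd.DataFrame:
    rows = []
    for p in plans:
        for rank, (part, orientation) in enumerate(p.parts):
            rows.append(
                {
                    "name": p.name, "part_rank": rank, "seq_id": part,
                    "orientation": orientation, "gap_len": p.gap_len, "lg": p.lg,
                    "aligned_bp": p.provenance.get("aligned_bp", {}).get(part, 0),
                    "margin": p.provenance.get("margin", {}).get(part, float("nan")),
                }
            )
    return pd.DataFrame(rows)


def plans_from_frame(df: pd.DataFrame) -> list[ChromosomePlan]:
    plans = []
    for name, grp in df.groupby("name", sort=True):
        grp = grp.sort_values("part_rank")
        plans.append(
            ChromosomePlan(
                name=str(name),
                parts=[(r.seq_id, r.orientation) for r in grp.itertuples()],
                gap_len=int(grp["gap_len"].iloc[0]),
                lg=str(grp["lg"].iloc[0]),
            )
        )
    return plans
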