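"""Collation vs brute force, proportion matrix, assignment, pairing, build."""

import numpy as np
import pytest

import chromarm as ca
from chromarm.errors import BuildError, PairingError
from chromarm.synteny import (
    _joinable,
    assign_arm,
    build_chromosomes,
    collate_match_parts,
    collate_syntenic_regions,
    pair_arms,
    plans_from_frame,
    plans_to_frame,
    synteny_matrix,
)
from chromarm.telomeres import classify_scaffold, scan_telomere_arrays


def B(q, qs, qe, t, ts, te, strand="+", score=1):
    return ca.AlignmentBlock(q, qs, qe, t, ts, te, strand, score)


# ---------------------------------------------------------------------------
# Match-region collation
# ---------------------------------------------------------------------------


def brute_force_collate(blocks, join_distance):
    """Independent oracle: group, sort, and split at every non-joinable gap."""
    groups = {}
    for b in blocks:
        groups.setdefault((b.query_id, b.target_id, b.strand), []).append(b)
    regions = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda b: (b.t_start, b.t_end))
        start = 0
        for i in range(1, len(members) + 1):
            if i == len(members) or not _oracle_joinable(
                members[i - 1], members[i], join_distance
            ):
                chain = members[start:i]
                regions.append(
                    (key, min(b.t_start for b in chain), max(b.t_end for b in chain),
                     len(chain), sum(b.t_end - b.t_start for b in chain))
                )
                start = i
    return sorted(regions)


def _oracle_joinable(a, b, j):
    if b.t_start - a.t_end > j:
        return False
    if a.strand == "+":
        return (b.q_start >= a.q_start and b.q_end >= a.q_end
                and b.q_start - a.q_end <= j)
    return (b.q_start <= a.q_start and b.q_end <= a.q_end
            and a.q_start - b.q_end <= j)


def _as_tuples(regions):
    return sorted(
        ((r.query_id, r.target_id, r.strand), r.t_start, r.t_end, r.n_blocks,
         r.aligned_bp)
        for r in regions
    )


def test_two_close_colinear_blocks_chain():
    blocks = [B("q", 0, 100, "t", 0, 100), B("q", 200, 300, "t", 200, 300)]
    (r,) = collate_match_parts(blocks, join_distance=200_000)
    assert (r.n_blocks, r.q_start, r.q_end, r.t_start, r.t_end) == (2, 0, 300, 0, 300)
    assert r.aligned_bp == 200


def test_target_gap_beyond_join_distance_splits():
    blocks = [B("q", 0, 100, "t", 0, 100), B("q", 200, 300, "t", 400_100, 400_200)]
    assert len(collate_match_parts(blocks, join_distance=200_000)) == 2


def test_anticolinear_query_order_splits():
    blocks = [B("q", 500, 600, "t", 0, 100), B("q", 0, 100, "t", 200, 300)]
    assert len(collate_match_parts(blocks, join_distance=200_000)) == 2


def test_minus_strand_decreasing_query_chains():
    blocks = [B("q", 500, 600, "t", 0, 100, "-"), B("q", 0, 100, "t", 200, 300, "-")]
    (r,) = collate_match_parts(blocks)
    assert r.n_blocks == 2 and r.q_start == 0 and r.q_end == 600


def _random_blocks(rng, n):
    out = []
    for _ in range(n):
        q = f"q{rng.integers(1, 3)}"
        t = f"t{rng.integers(1, 3)}"
        strand = "+" if rng.random() < 0.5 else "-"
        qs = int(rng.integers(0, 5_000))
        ts = int(rng.integers(0, 5_000))
        out.append(B(q, qs, qs + int(rng.integers(1, 500)),
                     t, ts, ts + int(rng.integers(1, 500)), strand))
    return out


def test_collation_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(31)
    for _ in range(200):
        blocks = _random_blocks(rng, int(rng.integers(0, 50)))
        j = int(rng.integers(0, 2_000))
        assert _as_tuples(collate_match_parts(blocks, j)) == \
            brute_force_collate(blocks, j)


def test_collation_idempotent_and_monotone():
    rng = np.random.default_rng(37)
    for _ in range(50):
        blocks = _random_blocks(rng, 30)
        j = int(rng.integers(0, 2_000))
        r1 = collate_match_parts(blocks, j)
        # re-collating the regions (as one block each) changes nothing
        as_blocks = [
            B(r.query_id, r.q_start, r.q_end, r.target_id, r.t_start, r.t_end,
              r.strand) for r in r1
        ]
        assert len(collate_match_parts(as_blocks, 0)) == len(r1)
        assert len(collate_match_parts(blocks, 2 * j + 1)) <= len(r1)


# ---------------------------------------------------------------------------
# Syntenic regions
# ---------------------------------------------------------------------------


def _match(q, t, ts, te, strand="+"):
    return ca.MatchRegion(q, t, strand, 0, te - ts, ts, te, 1, te - ts)


def test_same_landmark_matches_group_within_distance():
    ms = [_match("q1", "t", 0, 10_000), _match("q1", "t", 110_000, 120_000, "-"),
          _match("q1", "t", 220_000, 230_000)]
    (r,) = collate_syntenic_regions(ms, max_distance=500_000)
    assert (r.n_matches, r.t_start, r.t_end) == (3, 0, 230_000)


def test_different_landmarks_stay_separate_and_may_overlap():
    ms = [_match("q1", "t", 0, 10_000), _match("q2", "t", 5_000, 15_000)]
    rs = collate_syntenic_regions(ms)
    assert len(rs) == 2
    spans = sorted((r.t_start, r.t_end) for r in rs)
    assert spans[0][1] > spans[1][0]  # overlapping on the target


def test_distance_at_or_beyond_threshold_splits():
    ms = [_match("q1", "t", 0, 10_000), _match("q1", "t", 610_000, 620_000)]
    assert len(collate_syntenic_regions(ms, max_distance=600_000)) == 2
    assert len(collate_syntenic_regions(ms, max_distance=600_001)) == 1


def test_syntenic_monotone_in_max_distance():
    rng = np.random.default_rng(41)
    ms = [_match("q1", "t", int(s), int(s) + 1_000)
          for s in rng.integers(0, 10_000_000, size=40)]
    counts = [len(collate_syntenic_regions(ms, max_distance=d))
              for d in (1_000, 100_000, 1_000_000, 10_000_000)]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# Matrix and assignment
# ---------------------------------------------------------------------------


def test_matrix_proportions_union_and_row_stochastic():
    blocks = [
        B("chrA", 0, 10, "LG1", 0, 3_000_000),
        B("chrA", 0, 10, "LG1", 1_000_000, 2_000_000),  # inside the union
        B("chrA", 20, 30, "LG2", 0, 1_000_000),
    ]
    m = synteny_matrix(blocks)
    assert m.aligned_bp.loc["chrA", "LG1"] == 3_000_000
    assert m.proportion.loc["chrA", "LG1"] == pytest.approx(0.75)
    assert m.proportion.loc["chrA", "LG2"] == pytest.approx(0.25)
    assert m.proportion.sum(axis=1).loc["chrA"] == pytest.approx(1.0, abs=1e-9)


def test_matrix_empty_rows_are_missing():
    m = synteny_matrix([], row_ids=["a"], col_ids=["LG1"])
    assert m.aligned_bp.loc["a", "LG1"] == 0
    assert m.proportion.isna().all().all()


def test_assignment_thresholds():
    blocks = [B("arm", 0, 10, "LG1", 0, 90), B("arm", 0, 10, "LG2", 0, 7),
              B("arm", 0, 10, "LG3", 0, 3)]
    m = synteny_matrix(blocks)
    a = assign_arm("arm", m)
    assert a.lg == "LG1" and a.margin == pytest.approx(0.83)
    blocks2 = [B("arm", 0, 10, "LG1", 0, 45), B("arm", 0, 10, "LG2", 0, 44),
               B("arm", 0, 10, "LG3", 0, 11)]
    assert assign_arm("arm", synteny_matrix(blocks2)).lg is None


# ---------------------------------------------------------------------------
# Pairing and building
# ---------------------------------------------------------------------------


def _status(seq_id, side, n=500):
    rng = np.random.default_rng(43)
    body = "".join(rng.choice(list("AC"), size=n))
    seq = ("TTAGGG" * 5 + body) if side == "5p" else (body + "CCCTAA" * 5)
    rec = ca.SequenceRecord(seq_id, seq)
    return rec, classify_scaffold(rec, scan_telomere_arrays(rec, end_window=100))


def test_pairing_orients_telomeres_outward():
    rec_a, st_a = _status("A", "5p", n=400)
    rec_b, st_b = _status("B", "5p", n=900)
    assignments = [ca.ArmAssignment("A", "LG1", 0.9, 0.8, 1000),
                   ca.ArmAssignment("B", "LG1", 0.9, 0.8, 1000)]
    plans = pair_arms(assignments, {"A": st_a, "B": st_b},
                      {"A": len(rec_a.sequence), "B": len(rec_b.sequence)})
    (p,) = plans
    # both telomeres 5': left arm forward, right arm flipped
    assert p.parts == [("A", "+"), ("B", "-")]
    built = build_chromosomes(plans, [rec_a, rec_b])[0]
    assert len(built.sequence) == len(rec_a.sequence) + len(rec_b.sequence) + 500
    assert built.sequence.startswith("TTAGGG")
    assert built.sequence.endswith("CCCTAA")


def test_pairing_errors_and_warnings():
    _, st = _status("A", "5p")
    assignments = [ca.ArmAssignment(x, "LG1", 0.9, 0.8, 1) for x in "ABC"]
    with pytest.raises(PairingError, match="LG1"):
        pair_arms(assignments, {x: st for x in "ABC"}, {x: 10 for x in "ABC"})
    # arm without terminal telomere: '+' with a provenance warning
    bare = ca.SequenceRecord("B", "AC" * 300)
    st_b = classify_scaffold(bare, [])
    plans = pair_arms(
        [ca.ArmAssignment("A", "LG1", 0.9, 0.8, 1),
         ca.ArmAssignment("B", "LG1", 0.9, 0.8, 1)],
        {"A": st, "B": st_b}, {"A": 100, "B": 600},
    )
    assert plans[0].parts[1] == ("B", "+")
    assert plans[0].provenance["warnings"]


def test_build_reverse_complement_preserves_case_and_single_part():
    rec = ca.SequenceRecord("A", "ACgtN")
    plan = ca.ChromosomePlan("chr", [("A", "-")], gap_len=500)
    (built,) = build_chromosomes([plan], [rec])
    assert built.sequence == "NacGT"
    with pytest.raises(BuildError):
        build_chromosomes([ca.ChromosomePlan("c", [("missing", "+")])], [rec])


def test_plan_frame_round_trip():
    plan = ca.ChromosomePlan("chr_LG1", [("a", "+"), ("b", "-")], 500, "LG1",
                             {"aligned_bp": {"a": 10, "b": 20},
                              "margin": {"a": 0.5, "b": 0.6}})
    df = plans_to_frame([plan])
    (back,) = plans_from_frame(df)
    assert back.name == plan.name and back.parts == plan.parts
    assert back.gap_len == 500 and back.lg == "LG1"


def test_end_to_end_recovery_single_replicate(small_genome):
    records, truth = small_genome
    arms, flips = ca.arm_records(records, truth, flip_prob=0.5, seed=19)
    _, placements = ca.simulate_reference(records, truth, divergence=0.0, seed=19)
    blocks, _ = ca.simulate_alignment_blocks(
        placements, block_len=500, n_blocks_per_arm=50, jitter=100,
        noise_fraction=0.0, seed=19, query_flips=flips)
    m = synteny_matrix(blocks)
    assignments = [assign_arm(a, m) for a in m.proportion.index]
    lg_truth = {arm: lg for arm, (_, _, lg) in truth.arm_map.items()}
    assert {a.arm_id: a.lg for a in assignments} == lg_truth
    statuses = {r.id: classify_scaffold(r, scan_telomere_arrays(r)) for r in arms}
    plans = pair_arms(assignments, statuses, {r.id: len(r.sequence) for r in arms})
    built = build_chromosomes(plans, arms)
    originals = {r.id: r.sequence for r in records}
    rebuilt = sorted(b.sequence for b in built)
    assert rebuilt == sorted(originals.values())
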