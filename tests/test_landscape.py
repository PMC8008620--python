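"""Window features, arm partition, dual tests, and the copy-number formula."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

import chromarm as ca
from chromarm.errors import (
    DegenerateInputError,
    ParameterError,
    PartitionError,
)
from chromarm.landscape import (
    compare_arms,
    compute_windows,
    dual_arm_test,
    estimate_tandem_copies,
    mann_whitney_u,
    split_at_gap,
    welch_t_test,
)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def test_uniform_g_sequence_windows():
    rec = ca.SequenceRecord("s", "G" * 100_000)
    w = compute_windows(rec, window=50_000)
    assert len(w) == 2
    assert (w["gc_fraction"] == 1.0).all()
    assert (w["repeat_fraction"] == 0.0).all()
    assert (w["dpnii_count"] == 0).all()
    assert not w["partial"].any()


def test_dpnii_density_of_pure_gatc_window():
    rec = ca.SequenceRecord("s", "GATC" * 12_500)
    w = compute_windows(rec, window=50_000)
    assert len(w) == 1
    # GATC cannot overlap itself: sliding oracle gives exactly 12,500 sites
    assert w["dpnii_count"].iloc[0] == 12_500


def test_all_n_window_is_missing_and_n_free_denominator():
    rec = ca.SequenceRecord("s", "GG" + "N" * 48)
    w = compute_windows(rec, window=50)
    assert w["gc_fraction"].iloc[0] == 1.0  # 2 informative bp, both G
    rec2 = ca.SequenceRecord("s", "N" * 50)
    assert math.isnan(compute_windows(rec2, window=50)["gc_fraction"].iloc[0])


def test_window_features_match_bruteforce_counting():
    rng = np.random.default_rng(17)
    seq = "".join(rng.choice(list("ACGTacgtNn"), size=2_317))
    rec = ca.SequenceRecord("s", seq)
    w = compute_windows(rec, window=500)
    assert list(w["start"]) == [0, 500, 1000, 1500, 2000]
    assert w["partial"].iloc[-1]
    for _, row in w.iterrows():
        chunk = seq[row.start:row.end]
        inf = [c for c in chunk.upper() if c != "N"]
        gc = sum(c in "GC" for c in inf) / len(inf) if inf else float("nan")
        if math.isnan(gc):
            assert math.isnan(row.gc_fraction)
        else:
            assert row.gc_fraction == pytest.approx(gc)
        assert row.repeat_fraction == pytest.approx(
            sum(c.islower() for c in chunk) / len(chunk))
        sites = sum(
            seq.upper()[i:i + 4] == "GATC"
            for i in range(row.start, min(row.end, len(seq) - 3))
        )
        assert row.dpnii_count == sites


def test_gene_counts_sum_to_total_and_assign_by_start():
    rec = ca.SequenceRecord("s", "A" * 1_000)
    genes = [ca.GenomicInterval("s", 95, 205, label="g1"),   # starts in w0
             ca.GenomicInterval("s", 100, 180, label="g2"),  # starts in w1
             ca.GenomicInterval("s", 990, 1000, label="g3"),
             ca.GenomicInterval("other", 0, 10, label="g4")]
    w = compute_windows(rec, genes=genes, window=100)
    assert w["gene_count"].sum() == 3
    assert w["gene_count"].iloc[0] == 1 and w["gene_count"].iloc[1] == 1


def test_depth_means_follow_track_resolution():
    rec = ca.SequenceRecord("s", "A" * 250)
    track = ca.DepthTrack("s", 100, np.array([10.0, 20.0, 40.0]))
    w = compute_windows(rec, depth=track, window=100)
    assert list(w["depth_mean"]) == [10.0, 20.0, 40.0]
    w2 = compute_windows(rec, depth=track, window=200)
    assert w2["depth_mean"].iloc[0] == 15.0


def test_window_parameter_validation():
    rec = ca.SequenceRecord("s", "ACGT")
    with pytest.raises(ParameterError):
        compute_windows(rec, window=0)


# ---------------------------------------------------------------------------
# Arm partition
# ---------------------------------------------------------------------------


def test_split_matches_published_chr1_style_coordinates():
    rec = ca.SequenceRecord("chr1", "A" * 14_533_022)
    gap = ca.GenomicInterval("chr1", 5_191_657, 5_192_155, label="gap")
    part = split_at_gap(rec, [gap])
    assert (part.short_arm.start, part.short_arm.end) == (0, 5_191_657)
    assert (part.long_arm.start, part.long_arm.end) == (5_192_155, 14_533_022)


def test_split_tie_labels_left_short_and_errors():
    rec = ca.SequenceRecord("s", "A" * 210)
    gap = ca.GenomicInterval("s", 100, 110, label="gap")
    part = split_at_gap(rec, [gap])
    assert part.short_arm.start == 0 and part.short_side == "left"
    with pytest.raises(PartitionError):
        split_at_gap(rec, [])
    with pytest.raises(PartitionError):
        split_at_gap(rec, [gap, ca.GenomicInterval("s", 150, 160, label="gap")])
    # gaps on other sequences or with non-centromeric labels are ignored
    part2 = split_at_gap(rec, [gap, ca.GenomicInterval("t", 5, 9, label="gap"),
                               ca.GenomicInterval("s", 10, 20, label="repeat")])
    assert part2.gap == gap


def test_window_arm_labels(small_genome):
    records, truth = small_genome
    rec = records[0]
    part = split_at_gap(rec, truth.gaps)
    w = compute_windows(rec, window=5_000, partition=part)
    full = w[~w["partial"]]
    assert set(full["arm"]) <= {"short", "long", "gap"}
    assert (full[full["arm"] == "short"]["end"] <= part.gap.start + 5_000).all()
    gap_rows = w[w["arm"] == "gap"]
    assert len(gap_rows) >= 1
    # arm window counts are within one window of the arm spans
    n_short = (len(part.short_arm)) // 5_000
    assert abs(len(w[w["arm"] == "short"]) - n_short) <= 1


# ---------------------------------------------------------------------------
# Welch t / Mann-Whitney vs independent oracles
# ---------------------------------------------------------------------------


def _welch_p_oracle(t, df):
    """Two-sided p by numerical integration of the t density."""
    dens = lambda u: sps.t.pdf(u, df)
    tail, _ = integrate.quad(dens, abs(t), np.inf)
    return 2 * tail


def test_welch_identical_samples_and_degenerate():
    t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
    assert t == 0 and p == pytest.approx(1.0)
    with pytest.raises(DegenerateInputError):
        welch_t_test([0, 0, 0], [1, 1, 1])
    with pytest.raises(DegenerateInputError):
        welch_t_test([1], [1, 2])


def test_welch_matches_numerical_oracle_and_scipy():
    x, y = [1, 2, 3, 4], [2, 4, 6, 8]
    t, df, p = welch_t_test(x, y)
    assert p == pytest.approx(_welch_p_oracle(t, df), abs=1e-9)
    t_sp, p_sp = sps.ttest_ind(x, y, equal_var=False)
    assert t == pytest.approx(float(t_sp), abs=1e-12)
    assert p == pytest.approx(float(p_sp), abs=1e-12)
    rng = np.random.default_rng(23)
    for _ in range(20):
        a = rng.normal(size=rng.integers(3, 12))
        b = rng.normal(1.0, 2.0, size=rng.integers(3, 12))
        t, df, p = welch_t_test(a, b)
        assert p == pytest.approx(_welch_p_oracle(t, df), abs=1e-6)


def _mw_exact_oracle(x, y):
    """Independent enumeration over all labelings (no ties assumed)."""
    import itertools
    pooled = sorted(x + y)
    nx = len(x)
    obs = sum(sum(xx > v for v in y) for xx in x)
    us = []
    for comb in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(sum(sum(xx > v for v in ys) for xx in xs))
    lo = sum(u <= obs for u in us) / len(us)
    hi = sum(u >= obs for u in us) / len(us)
    return obs, min(1.0, 2 * min(lo, hi))


def test_mann_whitney_exact_small_sample():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0 and p == pytest.approx(1 / 3)


def test_mann_whitney_matches_enumeration_oracle():
    rng = np.random.default_rng(29)
    for _ in range(50):
        nx = int(rng.integers(1, 6))
        ny = int(rng.integers(1, 6))
        x = list(rng.normal(size=nx))
        y = list(rng.normal(size=ny))
        u, p = mann_whitney_u(x, y)
        u_o, p_o = _mw_exact_oracle(x, y)
        assert u == u_o
        assert p == pytest.approx(p_o, abs=1e-12)


def test_mann_whitney_ties_and_identical_samples():
    u, p = mann_whitney_u([1.0, 1.0, 2.0], [1.0, 2.0, 2.0])
    assert 0 < p <= 1.0
    _, p_same = mann_whitney_u([1, 1, 2, 2], [1, 1, 2, 2])
    assert p_same == pytest.approx(1.0)
    big_x = list(np.arange(100.0))
    big_y = list(np.arange(100.0) + 50.0)
    _, p_shift = mann_whitney_u(big_x, big_y)
    assert p_shift < 1e-10


# ---------------------------------------------------------------------------
# Dual rule and compare_arms
# ---------------------------------------------------------------------------


def test_compare_arms_on_contrasted_genome(small_genome):
    records, truth = small_genome
    rec = records[0]
    part = split_at_gap(rec, truth.gaps)
    depth = ca.simulate_depth(records, truth, mean_depth=50, seed=13)[rec.id]
    w = compute_windows(rec, depth=depth, genes=truth.genes, window=5_000,
                        partition=part)
    cmps = {c.feature: c for c in compare_arms(w, part)}
    # generator defaults: GC 0.38 vs 0.42, repeat 0.30 vs 0.15
    assert cmps["gc_fraction"].significant
    assert cmps["repeat_fraction"].significant
    assert cmps["gc_fraction"].mean_short < cmps["gc_fraction"].mean_long
    assert cmps["repeat_fraction"].mean_short > cmps["repeat_fraction"].mean_long


def test_compare_arms_excludes_gap_and_partial_windows(small_genome):
    records, truth = small_genome
    rec = records[0]
    part = split_at_gap(rec, truth.gaps)
    w = compute_windows(rec, window=5_000, partition=part)
    c = compare_arms(w, part, features=["gc_fraction"])[0]
    full = w[~w["partial"]]
    assert c.n_short == (full["arm"] == "short").sum()
    assert c.n_long == (full["arm"] == "long").sum()


def test_dual_rule_constant_windows_degenerate():
    with pytest.raises(DegenerateInputError):
        dual_arm_test([1.0] * 10, [1.0] * 10, feature="gc_fraction")
    with pytest.raises(DegenerateInputError):
        dual_arm_test([1.0], [1.0, 2.0], feature="gc_fraction")


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "assembled,locus,ref,expected",
    [(7, 30, 30, 7), (4, 5, 1, 20), (4, 25, 1, 100), (4, 250, 50, 20)],
)
def test_copy_number_formula(assembled, locus, ref, expected):
    assert estimate_tandem_copies(assembled, locus, ref) == pytest.approx(expected)


def test_copy_number_rejects_nonpositive():
    with pytest.raises(ParameterError):
        estimate_tandem_copies(0, 5, 1)
    with pytest.raises(ParameterError):
        estimate_tandem_copies(4, 5, 0)
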