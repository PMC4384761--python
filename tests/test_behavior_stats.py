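"""Behavioral statistics against independent oracles: exhaustive binomial
enumeration, printed accuracy-table reproduction, exact rank-permutation
distributions, and brute-force label-permutation enumeration for the
double-dissociation bootstrap."""
import math
from itertools import permutations, product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as spstats

from thetaloop.behavior_sim import BehaviorParams, simulate_cohort
from thetaloop.behavior_stats import (DIAGONALS, binomial_direction,
                                      binomial_pdf_pvalue, binomial_pvalue,
                                      classify_trial_types,
                                      double_dissociation_bootstrap,
                                      friedman_pvalue, friedman_test,
                                      occupancy_test, summarize_accuracy,
                                      table1_cohort, table1_frame,
                                      table1_group_means, table1_improvements,
                                      _quadrant_class, _diagonal_hits,
                                      _vector_pvalues)


# ---------------------------------------------------------------------------
# binomial rules

def _enumerated_tail(k, n, p0):
    """Oracle: accumulate the exact tail by enumerating all 2^n outcomes."""
    pmf = np.zeros(n + 1)
    for outcome in product((0, 1), repeat=n):
        ones = sum(outcome)
        pmf[ones] += p0 ** ones * (1 - p0) ** (n - ones)
    if k / n >= p0:
        return pmf[k:].sum()
    return pmf[: k + 1].sum()


@pytest.mark.parametrize("p0", [0.3, 0.5, 0.72])
def test_binomial_tail_equals_enumeration(p0):
    for n in range(1, 10):
        for k in range(n + 1):
            assert binomial_pvalue(k, n, p0) == pytest.approx(
                min(1.0, _enumerated_tail(k, n, p0)), abs=1e-12)


def test_binomial_boundary_and_worked_example():
    assert binomial_pvalue(10, 10, 1.0) == 1.0
    assert binomial_pvalue(0, 10, 0.0) == 1.0
    # upper tail of 7/10 vs 0.5: (120+45+10+1)/1024
    assert binomial_pvalue(7, 10, 0.5) == pytest.approx(0.171875, abs=1e-12)


def test_pdf_rule_flags_mouse4_retrieval_trough():
    """41/50 correct vs a 0.72 baseline: the pmf rule reproduces the
    printed P=0.04 and calls the enhancement significant, while the exact
    tail (0.074) would not."""
    assert binomial_pdf_pvalue(41, 50, 0.72) == pytest.approx(0.0375, abs=5e-4)
    assert binomial_direction(41, 50, 0.72, method="pdf") == "up"
    assert binomial_pvalue(41, 50, 0.72) == pytest.approx(0.0740, abs=5e-4)
    assert binomial_direction(41, 50, 0.72, method="tail") == "null"


def test_pdf_rule_reproduces_printed_per_mouse_pvalues():
    """At 50 trials per label the pmf at the printed accuracy reproduces the
    printed p-values to rounding for the cells with clean rounding."""
    cells = [  # (mouse, condition, stim, printed p)
        ("mouse4", "encoding", "peak", 0.0001),
        ("mouse4", "retrieval", "trough", 0.04),
        ("mouse4", "retrieval", "peak", 0.12),
        ("mouse4", "encoding", "trough", 0.08),
        ("mouse3", "encoding", "trough", 0.11),
        ("mouse2", "encoding", "peak", 0.01),
    ]
    tab = table1_frame().set_index(["mouse_id", "condition", "stim"])["accuracy"]
    for mouse, cond, stim, printed in cells:
        p0 = tab[(mouse, cond, "baseline")]
        k = round(tab[(mouse, cond, stim)] * 50)
        assert binomial_pdf_pvalue(k, 50, p0) == pytest.approx(printed, abs=0.006)


@given(st.integers(1, 40), st.integers(0, 40),
       st.sampled_from([0.2, 0.5, 0.72, 0.9]))
def test_vectorized_pvalues_match_scalar(n, k, p0):
    k = min(k, n)
    kv, pv = np.asarray([k]), np.asarray([p0])
    assert _vector_pvalues(kv, n, pv, "tail")[0] == pytest.approx(
        binomial_pvalue(k, n, p0), abs=1e-10)
    assert _vector_pvalues(kv, n, pv, "pdf")[0] == pytest.approx(
        binomial_pdf_pvalue(k, n, p0), abs=1e-10)


def test_binomial_invalid_inputs():
    with pytest.raises(ValueError):
        binomial_pvalue(5, 3, 0.5)
    with pytest.raises(ValueError):
        binomial_pvalue(1, 2, 1.5)


# ---------------------------------------------------------------------------
# printed-table summaries

def test_table1_group_means_match_reported():
    gm = table1_group_means()
    assert gm[("retrieval", "baseline")] == pytest.approx(57.3, abs=0.3)
    assert gm[("retrieval", "trough")] == pytest.approx(71.0, abs=0.3)
    assert gm[("encoding", "trough")] == pytest.approx(58.7, abs=0.3)
    assert gm[("encoding", "peak")] == pytest.approx(69.6, abs=0.3)


def test_table1_improvement_magnitudes():
    imp = table1_improvements()
    assert imp["retrieval_trough"] == pytest.approx(13.75, abs=1e-9)
    assert imp["encoding_peak"] == pytest.approx(10.5, abs=1e-9)


def test_summarize_accuracy_trivial_and_truncation():
    rows = []
    for i in range(160):  # 10 extra trials must be ignored
        rows.append({"mouse_id": "m1", "condition": "retrieval",
                     "stim": ["baseline", "peak", "trough"][i % 3],
                     "correct": True})
    summary = summarize_accuracy(pd.DataFrame(rows))
    tab = summary.table
    assert tab["n"].sum() == 150
    assert np.all(tab["phat"] == 1.0)
    # p0 = 1 for stimulated groups: pmf at k=n equals 1
    assert np.all(tab.loc[tab["stim"] != "baseline", "p_binom"] == 1.0)


def test_summarize_accuracy_conserves_counts_and_group_mean():
    cohort = table1_cohort()
    summary = summarize_accuracy(cohort)
    total_correct = cohort.groupby(["mouse_id", "condition"])["correct"].sum()
    by_group = summary.table.groupby(["mouse_id", "condition"])["k"].sum()
    assert (total_correct == by_group).all()
    # n=50 per label cannot represent odd-hundredth accuracies exactly
    # (0.71 -> 35.5 correct trials), so allow the rounding quantisation
    assert summary.group_means()[("retrieval", "trough")] == pytest.approx(
        71.0, abs=0.75)


def test_summarize_accuracy_requires_baseline():
    frame = pd.DataFrame({"mouse_id": ["m1"] * 4, "condition": ["retrieval"] * 4,
                          "stim": ["peak"] * 4, "correct": [True] * 4})
    with pytest.raises(ValueError, match="baseline"):
        summarize_accuracy(frame)


def test_classify_trial_types_partition_and_deltas():
    frame = pd.DataFrame({
        "mouse_id": "m1", "condition": "retrieval",
        "stim": ["baseline", "baseline", "peak", "peak"],
        "correct": [True, False, True, True],
        "trial_type": ["correct/switch"] * 4,
    })
    out = classify_trial_types(frame)
    assert set(out.table["trial_type"]) == {"correct/switch"}
    delta = out.deltas.loc[out.deltas["stim"] == "peak", "delta"].iloc[0]
    assert delta == pytest.approx(1.0 - 0.5)


def test_injected_effect_concentrates_on_one_type():
    base = BehaviorParams(n_trials=600)
    effect = {"retrieval": {"baseline": 0.0, "peak": 0.0, "trough": 0.15},
              "encoding": {"baseline": 0.0, "peak": 0.0, "trough": 0.0}}
    cohort = simulate_cohort(base.with_(stim_effect=effect), seed=5)
    out = classify_trial_types(cohort, max_trials=600)
    d = out.deltas
    ret_trough = d[(d.condition == "retrieval") & (d.stim == "trough")]["delta"].mean()
    enc_trough = d[(d.condition == "encoding") & (d.stim == "trough")]["delta"].mean()
    assert ret_trough > enc_trough + 0.05


# ---------------------------------------------------------------------------
# rank statistics

def test_friedman_tail_mapping_matches_reported():
    assert round(friedman_pvalue(8.4, 3), 3) == 0.038
    assert round(friedman_pvalue(8.1, 3), 3) == 0.044


def test_friedman_degenerate_and_perfect_ordering():
    chi2, df, p = friedman_test(np.ones((4, 4)))
    assert chi2 == 0.0 and p == 1.0
    # identical columns up to a constant shift per subject
    m = np.tile([1.0, 1.0, 1.0, 1.0], (4, 1))
    assert friedman_test(m)[2] == 1.0
    # perfect common ordering of 4 conditions: rank sums (4, 8, 12, 16)
    m = np.tile([0.1, 0.2, 0.3, 0.4], (4, 1)) + np.arange(4)[:, None]
    chi2, df, _ = friedman_test(m)
    assert chi2 == pytest.approx(12.0) and df == 3


def test_friedman_matches_scipy_with_and_without_ties():
    rng = np.random.default_rng(0)
    for _ in range(3):
        m = rng.random((5, 4))
        ours = friedman_test(m)
        ref = spstats.friedmanchisquare(*m.T)
        assert ours[0] == pytest.approx(ref.statistic)
        assert ours[2] == pytest.approx(ref.pvalue)
    m = rng.integers(0, 3, size=(6, 4)).astype(float)  # heavy ties
    ours = friedman_test(m)
    ref = spstats.friedmanchisquare(*m.T)
    assert ours[0] == pytest.approx(ref.statistic)


def test_friedman_close_to_exact_permutation_distribution():
    """For 4 subjects x 4 conditions the chi-square tail approximates the
    exact within-subject rank-permutation null."""
    m = np.array([[1.0, 2.0, 4.0, 3.0],
                  [2.0, 1.0, 4.0, 3.0],
                  [1.0, 3.0, 4.0, 2.0],
                  [2.0, 1.0, 3.0, 4.0]])
    chi2, df, p = friedman_test(m)
    perms = np.array(list(permutations([1.0, 2.0, 3.0, 4.0])))  # (24, 4)
    sums = (perms[:, None, None, None, :] + perms[None, :, None, None, :]
            + perms[None, None, :, None, :] + perms[None, None, None, :, :])
    sums = sums.reshape(-1, 4)
    stats_all = 12.0 / (4 * 4 * 5) * ((sums - 10.0) ** 2).sum(axis=1)
    p_exact = np.mean(stats_all >= chi2 - 1e-9)
    assert p == pytest.approx(p_exact, abs=0.04)


def test_ranksum_exact_and_bonferroni():
    p_raw, p_adj = occupancy_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert p_raw == pytest.approx(0.1, abs=1e-12)
    p_raw, p_adj = occupancy_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0], n_tests=2)
    assert p_adj == pytest.approx(0.2, abs=1e-12)
    rng = np.random.default_rng(0)
    same = rng.standard_normal(30)
    p_raw, _ = occupancy_test(same, same)
    assert p_raw == 1.0
    with pytest.raises(ValueError):
        occupancy_test([], [1.0])


# ---------------------------------------------------------------------------
# double dissociation

def _tiny_cohort():
    rows = []
    for m, outs in (("mouse1", [True, False, True, False]),
                    ("mouse2", [True, True, False, True])):
        for c in ("retrieval", "encoding"):
            for s, o in zip(["baseline", "baseline", "peak", "trough"], outs):
                rows.append(dict(mouse_id=m, condition=c, stim=s, correct=o))
    return pd.DataFrame(rows)


def _oracle_enumeration(tiny, alpha, consistency):
    """Brute force: iterate every distinct label ordering in every group."""
    groups = {}
    for (m, c), grp in tiny.groupby(["mouse_id", "condition"]):
        outs = grp["correct"].tolist()
        labels = tuple(grp["stim"].tolist())
        groups[(m, c)] = (outs, sorted(set(permutations(labels))))
    keys = list(groups)
    mice = sorted({m for m, _ in keys})
    n_any = n_both = n_tot = 0
    for combo in product(*(groups[k][1] for k in keys)):
        dirs = {}
        for key, labs in zip(keys, combo):
            outs, _ = groups[key]
            kb = sum(o for o, l in zip(outs, labs) if l == "baseline")
            nb = labs.count("baseline")
            for stim in ("peak", "trough"):
                k_ = sum(o for o, l in zip(outs, labs) if l == stim)
                n_ = labs.count(stim)
                p = binomial_pdf_pvalue(k_, n_, kb / nb)
                if p >= alpha or k_ / n_ == kb / nb:
                    dirs[key + (stim,)] = 0
                else:
                    dirs[key + (stim,)] = 1 if k_ / n_ > kb / nb else -1
        classes = {}
        for c in ("retrieval", "encoding"):
            for s in ("peak", "trough"):
                v = np.array([[dirs[(m, c, s)] for m in mice]], dtype=np.int8)
                classes[(c, s)] = int(_quadrant_class(v, consistency)[0])
        hits = _diagonal_hits(classes, True, False)
        n_tot += 1
        n_any += bool(hits["A"] or hits["B"])
        n_both += bool(hits["A"] and hits["B"])
    return n_any / n_tot, n_both / n_tot


def test_exhaustive_bootstrap_equals_enumeration_oracle():
    tiny = _tiny_cohort()
    dd = double_dissociation_bootstrap(tiny, exhaustive=True,
                                       alpha=0.5, consistency=2)
    p_any, p_both = _oracle_enumeration(tiny, alpha=0.5, consistency=2)
    assert dd.p_any_diagonal == pytest.approx(p_any, abs=1e-12)
    assert dd.p_both_diagonals == pytest.approx(p_both, abs=1e-12)


def test_sampled_bootstrap_converges_to_exhaustive():
    tiny = _tiny_cohort()
    exact = double_dissociation_bootstrap(tiny, exhaustive=True,
                                          alpha=0.5, consistency=2)
    sampled = double_dissociation_bootstrap(tiny, n_boot=4000, seed=0,
                                            alpha=0.5, consistency=2)
    assert sampled.p_any_diagonal == pytest.approx(exact.p_any_diagonal, abs=0.02)


def test_null_cohort_shows_no_observed_dissociation():
    rows = []
    for m in ("mouse1", "mouse2", "mouse3", "mouse4"):
        for c in ("retrieval", "encoding"):
            for s in ("baseline", "peak", "trough"):
                for i in range(50):
                    rows.append(dict(mouse_id=m, condition=c, stim=s,
                                     correct=i < 25))  # phat = p0 = 0.5 exactly
    dd = double_dissociation_bootstrap(pd.DataFrame(rows), n_boot=500, seed=1)
    assert all(q["class"] == "null" for q in dd.quadrants.values())
    assert not dd.observed_hits["A"] and not dd.observed_hits["B"]
    assert dd.p_any_diagonal <= 0.05  # consistent spurious effects are rare


def test_table1_cohort_shows_double_dissociation():
    """The trial table reconstructed from the printed accuracies shows the
    published pattern: retrieval-trough and encoding-peak consistently
    enhanced, both off-diagonal quadrants consistently unchanged, and a
    shuffled-label probability far below alpha."""
    dd = double_dissociation_bootstrap(table1_cohort(), n_boot=2000, seed=2)
    assert dd.quadrants[("retrieval", "trough")]["class"] == "up"
    assert dd.quadrants[("encoding", "peak")]["class"] == "up"
    assert dd.quadrants[("retrieval", "peak")]["class"] == "null"
    assert dd.quadrants[("encoding", "trough")]["class"] == "null"
    assert dd.observed_hits["A"] and dd.observed_hits["B"]
    assert dd.p_both_diagonals < 0.01
    assert dd.p_any_diagonal >= dd.p_both_diagonals


def test_hit_rule_flags():
    cohort = table1_cohort()
    strict = double_dissociation_bootstrap(cohort, n_boot=10, seed=0,
                                           count_no_change=False)
    assert strict.observed_hits["A"] and not strict.observed_hits["B"]
    offnull = double_dissociation_bootstrap(cohort, n_boot=10, seed=0,
                                            require_off_diagonal_null=True)
    assert offnull.observed_hits["A"]  # diagonal B is consistently null


def test_bootstrap_input_validation():
    cohort = table1_cohort()
    with pytest.raises(ValueError):
        double_dissociation_bootstrap(cohort, n_boot=0)
    with pytest.raises(ValueError):
        double_dissociation_bootstrap(cohort, alpha=1.5)
    with pytest.raises(ValueError, match="stim"):
        double_dissociation_bootstrap(
            cohort.drop(columns=["stim"]), n_boot=10)
    one_mouse = cohort[cohort["mouse_id"] == "mouse1"]
    with pytest.raises(ValueError):
        double_dissociation_bootstrap(one_mouse, n_boot=10)
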