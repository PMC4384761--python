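"""Behavioral statistics: per-mouse binomial tests, trial-type breakdown,
Friedman and rank-sum tests, and the label-shuffling bootstrap for the
2×2 (task segment × trigger phase) double dissociation.

Two binomial significance rules are provided.  ``binomial_pvalue`` is the
adaptive one-sided exact tail probability.  ``binomial_pdf_pvalue`` is the
binomial probability mass at the observed count — the "p.d.f. of the
binomial distribution" rule used to score individual mice against their
own baseline accuracy; it reproduces the published per-mouse p-values from
the printed accuracy table at 50 trials per label.  The dissociation
classifier defaults to the pdf rule.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .behavior_sim import CONDITIONS, STIM_LABELS, trials_to_frame

__all__ = [
    "TABLE1_ACCURACY", "table1_frame", "table1_group_means", "table1_improvements",
    "table1_cohort", "binomial_pvalue", "binomial_pdf_pvalue", "binomial_direction",
    "AccuracySummary", "summarize_accuracy", "TrialTypeBreakdown",
    "classify_trial_types", "friedman_test", "friedman_pvalue", "occupancy_test",
    "DDResult", "double_dissociation_bootstrap", "DIAGONALS",
]

MAX_TRIALS_PER_CONDITION = 150

# Published per-mouse accuracies: probability of a correct response for four
# mice under six conditions (segment × stimulation label).  These printed
# values are inputs to the group-level summaries and to the reconstruction
# of a reference cohort.
TABLE1_ACCURACY = {
    ("mouse1", "retrieval"): {"baseline": 0.55, "peak": 0.49, "trough": 0.71},
    ("mouse1", "encoding"): {"baseline": 0.58, "peak": 0.48, "trough": 0.43},
    ("mouse2", "retrieval"): {"baseline": 0.52, "peak": 0.57, "trough": 0.64},
    ("mouse2", "encoding"): {"baseline": 0.60, "peak": 0.75, "trough": 0.66},
    ("mouse3", "retrieval"): {"baseline": 0.50, "peak": 0.53, "trough": 0.67},
    ("mouse3", "encoding"): {"baseline": 0.62, "peak": 0.73, "trough": 0.64},
    ("mouse4", "retrieval"): {"baseline": 0.72, "peak": 0.73, "trough": 0.82},
    ("mouse4", "encoding"): {"baseline": 0.56, "peak": 0.82, "trough": 0.62},
}

# The two diagonals of the 2x2 (condition × stimulated phase) design.  A is
# the matched pairing (trough acts on retrieval, peak on encoding).
DIAGONALS = {
    "A": (("retrieval", "trough"), ("encoding", "peak")),
    "B": (("retrieval", "peak"), ("encoding", "trough")),
}


def table1_frame() -> pd.DataFrame:
    """The printed per-mouse accuracy table in long form."""
    rows = [
        {"mouse_id": m, "condition": c, "stim": s, "accuracy": v}
        for (m, c), d in TABLE1_ACCURACY.items() for s, v in d.items()
    ]
    return pd.DataFrame(rows)


def table1_group_means() -> dict:
    """Across-mouse mean accuracy (percent) per (condition, stim)."""
    frame = table1_frame()
    out = {}
    for (c, s), grp in frame.groupby(["condition", "stim"]):
        out[(c, s)] = float(grp["accuracy"].mean() * 100.0)
    return out


def table1_improvements() -> dict:
    """Mean stimulation-minus-baseline accuracy change (percentage points)."""
    deltas = {"retrieval_trough": [], "encoding_peak": [],
              "retrieval_peak": [], "encoding_trough": []}
    for (mouse, cond), d in TABLE1_ACCURACY.items():
        for stim in ("peak", "trough"):
            deltas[f"{cond}_{stim}"].append(d[stim] - d["baseline"])
    return {k: float(np.mean(v) * 100.0) for k, v in deltas.items()}


def table1_cohort(n_per_type: int = 50) -> pd.DataFrame:
    """Trial table reconstructed from the printed accuracies.

    Per-label trial counts are not published; labels were interleaved with
    equal probability over 150 analysed trials per condition, so
    ``n_per_type`` defaults to 50.  Each group gets round(accuracy·n)
    correct trials.  Labels are interleaved round-robin so truncation to
    the first 150 trials keeps all of them.
    """
    rows = []
    for (mouse, cond), d in TABLE1_ACCURACY.items():
        per_label = {}
        for stim, acc in d.items():
            k = int(round(acc * n_per_type))
            outcomes = [True] * k + [False] * (n_per_type - k)
            per_label[stim] = outcomes
        for i in range(n_per_type):
            for stim in STIM_LABELS:
                rows.append({"mouse_id": mouse, "condition": cond,
                             "stim": stim, "correct": per_label[stim][i]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binomial significance rules

def _check_kn(k: int, n: int, p0: float) -> None:
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")


def binomial_pvalue(k: int, n: int, p0: float) -> float:
    """One-sided exact binomial tail in the observed direction.

    Upper tail sum_{j>=k} C(n,j) p0^j (1-p0)^(n-j) when k/n >= p0, lower
    tail otherwise, by direct summation.
    """
    _check_kn(k, n, p0)
    if k / n >= p0:
        js = range(k, n + 1)
    else:
        js = range(0, k + 1)
    return float(min(1.0, sum(
        math.comb(n, j) * p0 ** j * (1.0 - p0) ** (n - j) for j in js)))


def binomial_pdf_pvalue(k: int, n: int, p0: float) -> float:
    """Binomial probability mass at the observed count.

    The published per-mouse significance rule: the pmf value C(n,k) p0^k
    (1-p0)^(n-k) itself is compared to alpha.  Unusual as a p-value, but it
    reproduces the printed per-mouse numbers (e.g. pmf(41; 50, 0.56) =
    0.0001) and is retained as the classification rule for the
    double-dissociation analysis.
    """
    _check_kn(k, n, p0)
    return float(math.comb(n, k) * p0 ** k * (1.0 - p0) ** (n - k))


def binomial_direction(k: int, n: int, p0: float, alpha: float = 0.05,
                       method: str = "pdf") -> str:
    """'up', 'down' or 'null': significant enhancement/impairment vs p0."""
    p = binomial_pdf_pvalue(k, n, p0) if method == "pdf" else binomial_pvalue(k, n, p0)
    if p >= alpha or k / n == p0:
        return "null"
    return "up" if k / n > p0 else "down"


# ---------------------------------------------------------------------------
# accuracy summaries

@dataclass
class AccuracySummary:
    """Per (mouse, condition, stim) accuracy with binomial tests vs baseline.

    ``table`` columns: mouse_id, condition, stim, k, n, phat, p0, p_binom,
    direction.  Baseline rows carry p_binom = NaN (they define p0).
    """

    table: pd.DataFrame
    alpha: float
    method: str

    def group_means(self) -> dict:
        out = {}
        for (c, s), grp in self.table.groupby(["condition", "stim"]):
            out[(c, s)] = float(grp["phat"].mean() * 100.0)
        return out


def _truncated(frame: pd.DataFrame, max_trials: int) -> pd.DataFrame:
    return (frame.groupby(["mouse_id", "condition"], sort=False, group_keys=False)
            .head(max_trials))


def summarize_accuracy(trials, max_trials: int = MAX_TRIALS_PER_CONDITION,
                       alpha: float = 0.05, method: str = "pdf") -> AccuracySummary:
    """Group trials by stimulation label and test each against baseline.

    Only the first ``max_trials`` trials per (mouse, condition) enter the
    analysis.  The baseline accuracy of the same mouse and condition is the
    chance level p0 for its peak and trough groups.
    """
    frame = _truncated(trials_to_frame(trials), max_trials)
    rows = []
    for (mouse, cond), grp in frame.groupby(["mouse_id", "condition"], sort=False):
        base = grp[grp["stim"] == "baseline"]
        if base.empty:
            raise ValueError(f"no baseline trials for {mouse}/{cond}")
        p0 = float(base["correct"].mean())
        for stim in STIM_LABELS:
            sub = grp[grp["stim"] == stim]
            if sub.empty:
                continue
            k, n = int(sub["correct"].sum()), len(sub)
            if stim == "baseline":
                p, direction = float("nan"), "baseline"
            else:
                p = (binomial_pdf_pvalue(k, n, p0) if method == "pdf"
                     else binomial_pvalue(k, n, p0))
                direction = binomial_direction(k, n, p0, alpha, method)
            rows.append({"mouse_id": mouse, "condition": cond, "stim": stim,
                         "k": k, "n": n, "phat": k / n, "p0": p0,
                         "p_binom": p, "direction": direction})
    return AccuracySummary(table=pd.DataFrame(rows), alpha=alpha, method=method)


@dataclass
class TrialTypeBreakdown:
    """Accuracy per trial type × stimulation label, with stimulation deltas.

    ``table`` columns: condition, trial_type, stim, k, n, phat.
    ``deltas`` columns: condition, trial_type, stim, delta (phat − baseline
    phat of the same condition and type).
    """

    table: pd.DataFrame
    deltas: pd.DataFrame


def classify_trial_types(trials,
                         max_trials: int = MAX_TRIALS_PER_CONDITION) -> TrialTypeBreakdown:
    """Partition trials into the four outcome-history types.

    Each session's first trial (no previous outcome) is excluded.  Types
    cross the previous trial's outcome with the cue relation (whether the
    rewarded arm repeats or switches).
    """
    frame = _truncated(trials_to_frame(trials), max_trials)
    frame = frame[frame["trial_type"].notna()]
    rows = []
    for (cond, ttype, stim), grp in frame.groupby(
            ["condition", "trial_type", "stim"], sort=False):
        rows.append({"condition": cond, "trial_type": ttype, "stim": stim,
                     "k": int(grp["correct"].sum()), "n": len(grp),
                     "phat": float(grp["correct"].mean())})
    table = pd.DataFrame(rows)
    deltas = []
    for (cond, ttype), grp in table.groupby(["condition", "trial_type"]):
        base = grp[grp["stim"] == "baseline"]
        if base.empty:
            continue
        b = float(base["phat"].iloc[0])
        for _, row in grp[grp["stim"] != "baseline"].iterrows():
            deltas.append({"condition": cond, "trial_type": ttype,
                           "stim": row["stim"], "delta": row["phat"] - b})
    return TrialTypeBreakdown(table=table, deltas=pd.DataFrame(deltas))


# ---------------------------------------------------------------------------
# nonparametric tests

def friedman_pvalue(chi2: float, df: int) -> float:
    """Upper chi-square tail for a Friedman statistic."""
    return float(spstats.chi2.sf(chi2, df))


def friedman_test(matrix) -> tuple[float, int, float]:
    """Friedman rank test (nonparametric repeated-measures ANOVA).

    Rows are subjects, columns conditions.  Ranks are taken within subject
    with average ranks on ties; the statistic is tie-corrected.  A matrix
    whose rows are all constant has no rank information: chi2 = 0, p = 1.
    """
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    n, k = x.shape
    ranks = np.apply_along_axis(spstats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(
        (col_sums - n * (k + 1) / 2.0) ** 2)
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts ** 3 - counts)
    correction = 1.0 - ties / (n * (k ** 3 - k))
    if correction <= 0:
        return 0.0, k - 1, 1.0
    chi2 = stat / correction
    return float(chi2), k - 1, friedman_pvalue(chi2, k - 1)


def occupancy_test(times_a, times_b, n_tests: int = 1) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum with Bonferroni correction.

    Exact enumeration when both samples have at most 10 observations and
    no ties; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(times_a, dtype=np.float64)
    b = np.asarray(times_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) else "asymptotic"
    res = spstats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                               use_continuity=False)
    p_raw = min(1.0, float(res.pvalue))
    return p_raw, min(1.0, p_raw * n_tests)


# ---------------------------------------------------------------------------
# double-dissociation bootstrap

@dataclass
class DDResult:
    """Outcome of the 2×2 label-shuffling analysis.

    ``quadrants[(condition, stim)]`` holds per-mouse directions and the
    quadrant class ('up'/'down'/'null' when >= `consistency` mice agree,
    else 'inconsistent').  ``observed_hits[d]`` says whether diagonal d of
    the observed data shows the dissociation under the chosen rule.
    ``p_any_diagonal`` / ``p_both_diagonals`` are the shuffled-label
    probabilities of at least one / both diagonals hitting.
    """

    quadrants: dict
    observed_hits: dict
    p_any_diagonal: float
    p_both_diagonals: float
    n_boot: int | None
    alpha: float
    consistency: int
    method: str
    count_no_change: bool
    require_off_diagonal_null: bool


_UP, _DOWN, _NULL = 1, -1, 0


def _vector_pvalues(k: np.ndarray, n: int, p0: np.ndarray, method: str) -> np.ndarray:
    if method == "pdf":
        return spstats.binom.pmf(k, n, p0)
    phat = k / n
    upper = spstats.binom.sf(k - 1, n, p0)
    lower = spstats.binom.cdf(k, n, p0)
    return np.where(phat >= p0, upper, lower)


def _directions(k: np.ndarray, n: int, p0: np.ndarray, alpha: float,
                method: str) -> np.ndarray:
    p = _vector_pvalues(k, n, p0, method)
    phat = k / n
    out = np.zeros(np.broadcast(k, p0).shape, dtype=np.int8)
    sig = (p < alpha) & (phat != p0)
    out[sig & (phat > p0)] = _UP
    out[sig & (phat < p0)] = _DOWN
    return out


def _quadrant_class(dirs: np.ndarray, consistency: int) -> np.ndarray:
    """Class code per repetition from (reps, mice) direction codes.

    1 = consistent up, -1 = consistent down, 0 = consistent null,
    9 = inconsistent.
    """
    ups = (dirs == _UP).sum(axis=-1)
    downs = (dirs == _DOWN).sum(axis=-1)
    nulls = (dirs == _NULL).sum(axis=-1)
    cls = np.full(ups.shape, 9, dtype=np.int8)
    cls[nulls >= consistency] = 0
    cls[downs >= consistency] = -1
    cls[ups >= consistency] = 1
    return cls


def _diagonal_hits(classes: dict, count_no_change: bool,
                   require_off_diagonal_null: bool) -> dict:
    """Per-diagonal hit flags from quadrant class codes (arrays or scalars)."""
    pair = {d: tuple(classes[q] for q in quads) for d, quads in DIAGONALS.items()}
    same_nonnull = {}
    null_pair = {}
    for d, (c1, c2) in pair.items():
        same_nonnull[d] = (c1 == c2) & np.isin(c1, (1, -1))
        null_pair[d] = (c1 == 0) & (c2 == 0)
    if require_off_diagonal_null:
        same_nonnull = {
            "A": same_nonnull["A"] & null_pair["B"],
            "B": same_nonnull["B"] & null_pair["A"],
        }
    hits = {}
    for d, other in (("A", "B"), ("B", "A")):
        h = same_nonnull[d]
        if count_no_change:
            h = h | (null_pair[d] & same_nonnull[other])
        hits[d] = h
    return hits


def _dd_groups(frame: pd.DataFrame, max_trials: int):
    """Per-(mouse, condition) outcome vectors and label counts."""
    frame = _truncated(frame, max_trials)
    mice = sorted(frame["mouse_id"].unique())
    both = [m for m in mice
            if set(frame.loc[frame["mouse_id"] == m, "condition"]) >= set(CONDITIONS)]
    if len(both) < 2:
        raise ValueError("need >= 2 mice with both conditions present")
    groups = {}
    for mouse in both:
        for cond in CONDITIONS:
            grp = frame[(frame["mouse_id"] == mouse) & (frame["condition"] == cond)]
            counts = tuple(int((grp["stim"] == s).sum()) for s in STIM_LABELS)
            if min(counts) == 0:
                raise ValueError(f"missing a stimulation label for {mouse}/{cond}")
            groups[(mouse, cond)] = (
                grp["correct"].to_numpy(dtype=bool), counts)
    return both, groups


def double_dissociation_bootstrap(trials, n_boot: int = 10000,
                                  alpha: float = 0.05, consistency: int = 3,
                                  seed: int | None = None, method: str = "pdf",
                                  count_no_change: bool = True,
                                  require_off_diagonal_null: bool = False,
                                  exhaustive: bool = False,
                                  max_trials: int = MAX_TRIALS_PER_CONDITION) -> DDResult:
    """Label-shuffling significance of the 2×2 double dissociation.

    Within each (mouse, condition) the stimulation labels are permuted
    across trials, preserving per-label trial counts; each repetition
    recomputes every mouse's peak and trough accuracy and its binomial
    significance against the shuffled baseline accuracy, classifies the
    four quadrants by cross-mouse consistency, and asks whether either
    diagonal of the design shows the dissociation.  ``p_any_diagonal`` and
    ``p_both_diagonals`` are the fractions of repetitions with at least one
    or both diagonals hitting.

    With ``exhaustive=True`` the permutation distribution is enumerated
    exactly (multivariate hypergeometric weights over per-label correct
    counts) instead of sampled; feasible only for small cohorts.
    """
    if not exhaustive and n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    frame = trials_to_frame(trials)
    required = {"mouse_id", "condition", "stim", "correct"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    mice, _ = _dd_groups(frame, max_trials)
    frame = _truncated(frame, max_trials)
    frame = frame[frame["mouse_id"].isin(mice)]

    # observed quadrant classification -------------------------------------
    obs_dirs = {}   # (cond, stim) -> per-mouse direction codes
    group_stats = {}  # (mouse, cond) -> dict stim -> (k, n); plus totals
    for mouse in mice:
        for cond in CONDITIONS:
            grp = frame[(frame["mouse_id"] == mouse) & (frame["condition"] == cond)]
            stats = {}
            for stim in STIM_LABELS:
                sub = grp[grp["stim"] == stim]
                stats[stim] = (int(sub["correct"].sum()), len(sub))
            group_stats[(mouse, cond)] = {
                "per_label": stats,
                "K": int(grp["correct"].sum()),
                "n": len(grp),
            }
    quadrants = {}
    for cond in CONDITIONS:
        for stim in ("peak", "trough"):
            dirs = []
            for mouse in mice:
                st = group_stats[(mouse, cond)]["per_label"]
                kb, nb = st["baseline"]
                k, n = st[stim]
                p0 = kb / nb
                d = binomial_direction(k, n, p0, alpha, method)
                dirs.append({"up": _UP, "down": _DOWN, "null": _NULL}[d])
            dirs = np.asarray(dirs, dtype=np.int8)
            cls = int(_quadrant_class(dirs[None, :], consistency)[0])
            quadrants[(cond, stim)] = {
                "per_mouse": {m: {1: "up", -1: "down", 0: "null"}[int(v)]
                              for m, v in zip(mice, dirs)},
                "class": {1: "up", -1: "down", 0: "null", 9: "inconsistent"}[cls],
                "_code": cls,
            }
    obs_classes = {q: quadrants[q]["_code"] for q in quadrants}
    observed_hits = {d: bool(h) for d, h in _diagonal_hits(
        obs_classes, count_no_change, require_off_diagonal_null).items()}

    # shuffled-label null ----------------------------------------------------
    if exhaustive:
        p_any, p_both, n_reps = _exhaustive_null(
            mice, group_stats, alpha, consistency, method,
            count_no_change, require_off_diagonal_null)
        n_out = None
    else:
        rng = np.random.default_rng(seed)
        class_arrays = {}
        for cond in CONDITIONS:
            dir_arrays = {"peak": [], "trough": []}
            for mouse in mice:
                gs = group_stats[(mouse, cond)]
                nb, np_, nt = (gs["per_label"][s][1] for s in STIM_LABELS)
                outcomes = np.zeros(gs["n"], dtype=bool)
                outcomes[: gs["K"]] = True
                tiled = np.tile(outcomes, (n_boot, 1))
                perm = rng.permuted(tiled, axis=1)
                kb = perm[:, :nb].sum(axis=1)
                kp = perm[:, nb:nb + np_].sum(axis=1)
                kt = perm[:, nb + np_:].sum(axis=1)
                p0 = kb / nb
                dir_arrays["peak"].append(_directions(kp, np_, p0, alpha, method))
                dir_arrays["trough"].append(_directions(kt, nt, p0, alpha, method))
            for stim in ("peak", "trough"):
                dirs = np.stack(dir_arrays[stim], axis=1)  # (reps, mice)
                class_arrays[(cond, stim)] = _quadrant_class(dirs, consistency)
        hits = _diagonal_hits(class_arrays, count_no_change,
                              require_off_diagonal_null)
        p_any = float(np.mean(hits["A"] | hits["B"]))
        p_both = float(np.mean(hits["A"] & hits["B"]))
        n_out = n_boot

    for q in quadrants:
        quadrants[q].pop("_code", None)
    return DDResult(quadrants=quadrants, observed_hits=observed_hits,
                    p_any_diagonal=p_any, p_both_diagonals=p_both,
                    n_boot=n_out, alpha=alpha, consistency=consistency,
                    method=method, count_no_change=count_no_change,
                    require_off_diagonal_null=require_off_diagonal_null)


def _group_count_distribution(K: int, n: int, counts) -> list:
    """Exact P(k_baseline, k_peak, k_trough) under uniform label permutation.

    Permuting labels across trials makes the per-label correct counts
    multivariate hypergeometric: the number of assignments placing k_s of
    the K correct trials under label s is a product of multinomials.
    Returns [(kb, kp, kt, prob), ...] over feasible triples.
    """
    nb, np_, nt = counts
    total = math.comb(n, nb) * math.comb(n - nb, np_)
    out = []
    for kb in range(max(0, K - np_ - nt), min(nb, K) + 1):
        for kp in range(max(0, K - kb - nt), min(np_, K - kb) + 1):
            kt = K - kb - kp
            ways = (math.comb(K, kb) * math.comb(K - kb, kp)
                    * math.comb(n - K, nb - kb)
                    * math.comb(n - K - (nb - kb), np_ - kp))
            out.append((kb, kp, kt, ways / total))
    return out


def _exhaustive_null(mice, group_stats, alpha, consistency, method,
                     count_no_change, require_off_diagonal_null):
    """Enumerate the label-permutation null exactly (small cohorts only)."""
    dists = {}
    total_states = 1
    for key, gs in group_stats.items():
        counts = tuple(gs["per_label"][s][1] for s in STIM_LABELS)
        dists[key] = _group_count_distribution(gs["K"], gs["n"], counts)
        total_states *= len(dists[key])
        if total_states > 2_000_000:
            raise ValueError("cohort too large for exhaustive enumeration")
    keys = list(dists)
    p_any = 0.0
    p_both = 0.0
    for combo in product(*(dists[k] for k in keys)):
        prob = 1.0
        dirs = {}
        for (mouse, cond), (kb, kp, kt, pr) in zip(keys, combo):
            prob *= pr
            counts = tuple(group_stats[(mouse, cond)]["per_label"][s][1]
                           for s in STIM_LABELS)
            p0 = kb / counts[0]
            dirs[(mouse, cond, "peak")] = int(
                _directions(np.asarray([kp]), counts[1],
                            np.asarray([p0]), alpha, method)[0])
            dirs[(mouse, cond, "trough")] = int(
                _directions(np.asarray([kt]), counts[2],
                            np.asarray([p0]), alpha, method)[0])
        classes = {}
        for cond in CONDITIONS:
            for stim in ("peak", "trough"):
                v = np.asarray([[dirs[(m, cond, stim)] for m in mice]],
                               dtype=np.int8)
                classes[(cond, stim)] = int(_quadrant_class(v, consistency)[0])
        hits = _diagonal_hits(classes, count_no_change, require_off_diagonal_null)
        if hits["A"] or hits["B"]:
            p_any += prob
        if hits["A"] and hits["B"]:
            p_both += prob
    return p_any, p_both, total_states
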