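import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from sinuscore.cohort_stats import (
    AgreementReport,
    PairedCohort,
    bland_altman,
    bonferroni,
    cohort_table,
    friedman_test,
    percent_change,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# percent change


def test_percent_change_published_examples():
    assert percent_change(21, 24) == pytest.approx(14.2857, abs=1e-4)
    assert round(percent_change(21, 24), 2) == 14.29
    assert percent_change(4.14, 0.75) == pytest.approx(-81.8841, abs=1e-4)
    assert round(percent_change(4.14, 0.75)) == -82


def test_percent_change_identity_and_zero_baseline():
    assert percent_change(3.7, 3.7) == 0.0
    with pytest.raises(ValueError, match="zero baseline"):
        percent_change(0.0, 1.0)


# ---------------------------------------------------------------------------
# Friedman


def test_friedman_identical_columns_degenerate():
    col = [1.0, 2.0, 3.0, 4.0]
    stat, p = friedman_test([col, col, col])
    assert stat == 0.0 and p == 1.0


def test_friedman_perfect_ordering_matches_closed_form():
    # strictly ordered columns for every subject: chi2 = 12n/(k(k+1)) * sum(Rj - (k+1)/2)^2
    n, k = 10, 3
    base = np.arange(n, dtype=float)
    stat, p = friedman_test([base, base + 10, base + 20])
    assert stat == pytest.approx(20.0)
    assert p < 0.001


def test_friedman_invariant_to_subject_permutation():
    rng = np.random.default_rng(1)
    data = rng.normal(size=(3, 12))
    stat1, _ = friedman_test(data)
    perm = rng.permutation(12)
    stat2, _ = friedman_test(data[:, perm])
    assert stat1 == pytest.approx(stat2)


def test_friedman_invariant_to_joint_monotone_transform():
    rng = np.random.default_rng(2)
    data = rng.uniform(0.1, 5.0, size=(4, 9))
    stat1, p1 = friedman_test(data)
    stat2, p2 = friedman_test(np.exp(data))
    assert stat1 == pytest.approx(stat2) and p1 == pytest.approx(p2)


def test_friedman_matches_scipy_on_random_data():
    rng = np.random.default_rng(7)
    for _ in range(25):
        data = rng.normal(size=(3, 15))
        stat, p = friedman_test(data)
        ref = sps.friedmanchisquare(*data)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


def test_friedman_rejects_missing_cells():
    with pytest.raises(ValueError, match="missing"):
        friedman_test([[1.0, np.nan], [2.0, 3.0]])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _enumeration_p(diffs):
    """Brute-force two-sided p: all 2^n sign assignments of the rank vector."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = n * (n + 1) / 2
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws, float)
    lower = np.mean(ws <= w_obs)
    upper = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(lower, upper))


def test_wilcoxon_all_positive_n6_exact_tail():
    pre = np.zeros(6)
    post = np.arange(1.0, 7.0)
    res = wilcoxon_signed_rank(pre, post)
    assert res.method == "exact"
    assert res.pvalue == pytest.approx(2 / 64)


def test_wilcoxon_all_zero_differences_degenerate():
    with pytest.warns(UserWarning, match="degenerate"):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.pvalue == 1.0 and res.n_effective == 0


@given(st.integers(0, 2**32 - 1))
@settings(deadline=None, derandomize=True, max_examples=40)
def test_wilcoxon_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 11))
    pre = rng.normal(size=n)
    post = pre + rng.normal(size=n)  # continuous, ties have measure zero
    res = wilcoxon_signed_rank(pre, post)
    assert res.method == "exact"
    assert res.pvalue == pytest.approx(_enumeration_p(post - pre))


def test_wilcoxon_sign_flip_symmetry():
    rng = np.random.default_rng(9)
    pre = rng.normal(size=8)
    post = pre + rng.normal(size=8)
    p1 = wilcoxon_signed_rank(pre, post).pvalue
    p2 = wilcoxon_signed_rank(post, pre).pvalue
    assert p1 == pytest.approx(p2)


def test_wilcoxon_normal_path_close_to_scipy():
    rng = np.random.default_rng(4)
    pre = rng.normal(size=30)
    post = pre + rng.normal(0.4, 1.0, size=30)
    res = wilcoxon_signed_rank(pre, post)
    assert res.method == "normal"
    ref = sps.wilcoxon(post, pre, zero_method="wilcox", correction=True,
                       method="approx", alternative="two-sided")
    assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


def test_wilcoxon_ties_force_normal_path():
    pre = np.zeros(6)
    post = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
    res = wilcoxon_signed_rank(pre, post)
    assert res.method == "normal"


# ---------------------------------------------------------------------------
# Bonferroni


def test_bonferroni_examples_and_monotonicity():
    assert bonferroni([0.01], m=3)[0] == pytest.approx(0.03)
    assert bonferroni([0.5], m=3)[0] == 1.0
    raw = np.array([0.001, 0.2, 0.9])
    adj = bonferroni(raw)
    assert np.all(adj >= raw)
    with pytest.raises(ValueError):
        bonferroni([1.5])


# ---------------------------------------------------------------------------
# Bland-Altman


def test_bland_altman_identical_methods():
    rep = bland_altman([1, 2, 3], [1, 2, 3])
    assert rep.bias == 0.0 and rep.loa_low == rep.loa_high == 0.0


def test_bland_altman_constant_offset():
    a = np.array([1.0, 2.0, 3.0])
    rep = bland_altman(a, a - 0.4)
    assert rep.bias == pytest.approx(0.4)
    assert rep.sd_diff == pytest.approx(0.0)


def test_bland_altman_hand_computed_oracle():
    rep = bland_altman([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0])
    assert rep.bias == pytest.approx(2.5)
    assert rep.sd_diff == pytest.approx(1.2910, abs=1e-4)
    assert rep.loa_low == pytest.approx(-0.0304, abs=1e-3)
    assert rep.loa_high == pytest.approx(5.0304, abs=1e-3)


def test_bland_altman_interval_symmetric_about_bias():
    rng = np.random.default_rng(6)
    rep = bland_altman(rng.normal(size=15), rng.normal(size=15))
    assert rep.loa_low <= rep.bias <= rep.loa_high
    assert (rep.loa_high + rep.loa_low) / 2 == pytest.approx(rep.bias)


def test_reported_agreement_numbers_are_self_consistent():
    # published comparison of the ratio score against the classical staging:
    # bias +0.17 with limits (-0.007, +0.34) must correspond to one SD
    bias, lo, hi = 0.17, -0.007, 0.34
    sd = (hi - lo) / (2 * 1.96)
    assert (lo + hi) / 2 == pytest.approx(bias, abs=0.01)
    assert bias - 1.96 * sd == pytest.approx(lo, abs=0.01)
    assert bias + 1.96 * sd == pytest.approx(hi, abs=0.01)


def test_bland_altman_length_mismatch_rejected():
    with pytest.raises(ValueError):
        bland_altman([1, 2, 3], [1, 2])


# ---------------------------------------------------------------------------
# cohort container and tables


def _cohort_frame():
    rows = []
    lms_pre = [8, 9, 10, 7, 9]
    lms_post = [6, 7, 7, 5, 6]
    for i, (a, b) in enumerate(zip(lms_pre, lms_post)):
        rows.append({"subject_id": i, "timepoint": "pre", "lms": a, "snot22": 40 + i})
        rows.append({"subject_id": i, "timepoint": "post", "lms": b, "snot22": 15 + i})
    return pd.DataFrame(rows)


def test_cohort_table_deltas_and_descriptives():
    cohort = PairedCohort(_cohort_frame())
    table = cohort_table(cohort)
    assert table.loc["lms", "delta_mean"] == pytest.approx(
        np.mean([6, 7, 7, 5, 6]) - np.mean([8, 9, 10, 7, 9])
    )
    assert table.loc["snot22", "median_pre"] == 42.0
    assert table.loc["lms", "min_post"] == 5.0


def test_cohort_table_single_subject_sd_absent():
    df = pd.DataFrame(
        [
            {"subject_id": 0, "timepoint": "pre", "score": 0.5},
            {"subject_id": 0, "timepoint": "post", "score": 0.4},
        ]
    )
    table = cohort_table(PairedCohort(df))
    assert table.loc["score", "sd_pre"] is None


def test_cohort_table_constant_column():
    df = pd.DataFrame(
        [
            {"subject_id": i, "timepoint": tp, "score": 2.0}
            for i in range(4)
            for tp in ("pre", "post")
        ]
    )
    table = cohort_table(PairedCohort(df))
    assert table.loc["score", "sd_pre"] == 0.0
    assert table.loc["score", "min_pre"] == table.loc["score", "max_pre"] == 2.0


def test_cohort_missing_timepoint_rejected():
    df = _cohort_frame().iloc[:-1]  # drop one post row
    cohort = PairedCohort(df)
    with pytest.raises(ValueError, match="missing a timepoint"):
        cohort.paired("lms")


def test_cohort_csv_round_trip(tmp_path):
    df = _cohort_frame()
    p = tmp_path / "cohort.csv"
    df.to_csv(p, index=False)
    cohort = PairedCohort.from_csv(p)
    pre, post = cohort.paired("lms")
    assert pre.tolist() == [8, 9, 10, 7, 9]
    assert cohort.n_subjects() == 5
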