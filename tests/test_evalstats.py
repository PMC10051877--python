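"""Study scoring against hand-computed cases and the statistical tests
against brute-force / enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import synthmri as s
from synthmri import evalstats


def _truth(n_conv, n_syn):
    truth = {f"c{i}": "conventional" for i in range(n_conv)}
    truth.update({f"s{i}": "synthetic" for i in range(n_syn)})
    return truth


def _table(answers_by_rater, truth, group="g"):
    rows = []
    for rid, answers in answers_by_rater.items():
        for img, ans in answers.items():
            rows.append((rid, group, img, truth[img], ans))
    return pd.DataFrame(rows, columns=["rater_id", "experience_group",
                                       "image_id", "true_class", "answer"])


def test_always_conventional_strategy_on_25_35_design():
    """A rater answering 'conventional' everywhere scores 100% FN, 0%
    FP and 25/60 ~ 42% correct."""
    truth = _truth(25, 35)
    table = _table({"r0": {k: "conventional" for k in truth}}, truth)
    summary = evalstats.score_study(table)["g"]
    assert summary.pct_fn == 100
    assert summary.pct_fp == 0
    assert summary.pct_correct == 42       # round(100*25/60)


def test_missing_answers_are_reported():
    truth = _truth(2, 2)
    answers = {k: "conventional" for k in truth}
    table = _table({"r0": answers,
                    "r1": {k: v for k, v in answers.items() if k != "s0"}},
                   truth)
    with pytest.raises(ValueError, match="r1"):
        evalstats.score_study(table)


def test_concordance_extremes_and_errors():
    truth = _truth(3, 3)
    same = {k: "synthetic" for k in truth}
    opposite = {k: "conventional" for k in truth}
    t_same = _table({"a": same, "b": dict(same)}, truth)
    assert evalstats.concordance(t_same, "g") == 100
    t_opp = _table({"a": same, "b": opposite}, truth)
    assert evalstats.concordance(t_opp, "g") == 0
    t_single = _table({"a": same}, truth)
    with pytest.raises(ValueError):
        evalstats.concordance(t_single, "g")


def test_chance_level_concordance_of_independent_raters():
    """Four raters at chance agree on ~50% of images pairwise."""
    vals = []
    for rep in range(400):
        table = s.simulate_raters(_truth(30, 30), [0.5] * 4, seed=rep,
                                  groups=["g"] * 4)
        vals.append(evalstats.concordance(table, "g"))
    assert abs(np.mean(vals) - 50) < 3


def test_group_accuracy_recovery_at_067():
    """Simulated raters at accuracy 0.67 on a 26/34 design score a mean
    %correct within one point of 67 over many replicates."""
    truth = _truth(26, 34)
    vals = []
    for rep in range(500):
        table = s.simulate_raters(truth, [0.67, 0.67], seed=rep,
                                  groups=["expert", "expert"])
        vals.append(evalstats.score_study(table)["expert"].pct_correct)
    assert abs(np.mean(vals) - 67) < 1


# ---------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------

def test_chi_square_zero_for_identical_rows():
    stat, df, p = evalstats.chi_square_independence([[10, 10], [10, 10]])
    assert stat == 0.0 and df == 1 and p == 1.0
    stat, _, p = evalstats.chi_square_independence([[20, 40], [10, 20]])
    assert stat == pytest.approx(0.0, abs=1e-12)


def test_chi_square_matches_direct_formula_on_random_tables():
    rng = np.random.default_rng(3)
    for _ in range(50):
        obs = rng.integers(1, 60, size=(3, 2)).astype(float)
        stat, df, p = evalstats.chi_square_independence(obs)
        total = obs.sum()
        expected = np.outer(obs.sum(1), obs.sum(0)) / total
        brute = ((obs - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(brute, abs=1e-10)
        assert df == 2
        assert p == pytest.approx(sps.chi2.sf(brute, 2), abs=1e-12)


def test_chi_square_rejects_zero_marginals():
    with pytest.raises(ValueError):
        evalstats.chi_square_independence([[0, 0], [5, 5]])


# ---------------------------------------------------------------------
# wilcoxon signed-rank
# ---------------------------------------------------------------------

def test_wilcoxon_exact_p_matches_sign_enumeration():
    """Exact two-sided p for n=8 equals the enumeration over all 2^8
    sign assignments of the rank sum."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        d = rng.normal(0.4, 1.0, 8)
        while len(np.unique(np.abs(d))) < 8 or (d == 0).any():
            d = rng.normal(0.4, 1.0, 8)
        stat, p = evalstats.wilcoxon_signed_rank(d, np.zeros(8))
        ranks = sps.rankdata(np.abs(d))
        t_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        ts = np.array([ranks[list(signs)].sum() for signs in
                       (np.array(sgn, bool) for sgn in
                        itertools.product([0, 1], repeat=8))])
        t_min = np.minimum(ts, ranks.sum() - ts)
        assert stat == t_obs
        assert p == pytest.approx((t_min <= t_obs).mean(), abs=1e-12)


def test_wilcoxon_symmetric_differences_give_p_one():
    a = np.array([1.0, -1.0, 2.5, -2.5, 0.75, -0.75])
    stat, p = evalstats.wilcoxon_signed_rank(a, np.zeros_like(a))
    assert p == pytest.approx(1.0)


def test_wilcoxon_single_nonzero_difference():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([1.0, 2.0, 3.0, 1.5])
    stat, _ = evalstats.wilcoxon_signed_rank(a, b)
    assert stat in (0.0, 1.0)   # the lone rank lands on one side
    with pytest.raises(ValueError):
        evalstats.wilcoxon_signed_rank(a, a)


# ---------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------

def test_t_identical_samples_give_zero_statistic():
    a = [1.0, 2.0, 3.0, 4.0]
    stat, df, p = evalstats.two_sample_t(a, a)
    assert stat == 0.0 and df == 6 and p == 1.0


def test_t_large_separation_is_significant():
    a = np.array([1.0, 2.0, 3.0])
    stat, _, p = evalstats.two_sample_t(a, a + 50.0)
    assert p < 0.01


def test_t_matches_textbook_formula_on_random_samples():
    rng = np.random.default_rng(11)
    for _ in range(30):
        a = rng.normal(0, 1, rng.integers(4, 12))
        b = rng.normal(0.5, 1.5, rng.integers(4, 12))
        stat, df, p = evalstats.two_sample_t(a, b, "student")
        n1, n2 = len(a), len(b)
        sp2 = (((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
               / (n1 + n2 - 2))
        brute = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert stat == pytest.approx(brute, abs=1e-10)
        assert df == n1 + n2 - 2
        assert p == pytest.approx(2 * sps.t.sf(abs(brute), df), abs=1e-12)


def test_t_welch_variant_and_degenerate_variance():
    a = np.array([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        evalstats.two_sample_t(a, a, "welch")
    stat, df, p = evalstats.two_sample_t([1.0, 2.0, 3.0],
                                         [2.0, 4.0, 6.0, 8.0], "welch")
    assert df < 5  # welch df below the pooled 5


# ---------------------------------------------------------------------
# design
# ---------------------------------------------------------------------

def test_design_study_draws_without_replacement_and_reproducibly():
    pool = {"conventional": [f"c{i}" for i in range(100)],
            "synthetic": [f"s{i}" for i in range(253)]}
    design, sel = evalstats.design_study(pool, 26, 34, seed=5)
    assert design.total == 60
    assert (sel["true_class"] == "conventional").sum() == 26
    assert (sel["true_class"] == "synthetic").sum() == 34
    assert sel["image_id"].is_unique
    _, sel2 = evalstats.design_study(pool, 26, 34, seed=5)
    assert sel.equals(sel2)


def test_design_study_whole_pool_and_overdraw():
    pool = {"conventional": ["c0", "c1"], "synthetic": ["s0"]}
    _, sel = evalstats.design_study(pool, 2, 1, seed=0)
    assert set(sel["image_id"]) == {"c0", "c1", "s0"}
    with pytest.raises(ValueError):
        evalstats.design_study(pool, 3, 1, seed=0)
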