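"""Scoring of blinded conventional-vs-synthetic rater studies and the
accompanying statistical tests.

Definitions follow the study-table conventions: a false positive is a
conventional image labeled synthetic, a false negative is a synthetic
image labeled conventional, and concordance within an experience group
is the proportion of identical answers (mean pairwise agreement for
more than two raters).  Percentages are reported as integers
(round half up).

The hypothesis tests (Pearson chi-square without continuity
correction, Wilcoxon signed-rank, two-sample t) delegate to
scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyDesign", "ConfusionSummary", "score_study", "concordance",
    "chi_square_independence", "wilcoxon_signed_rank", "two_sample_t",
    "design_study",
]


@dataclass(frozen=True)
class StudyDesign:
    """Composition of one blinded rating round."""

    n_conventional: int
    n_synthetic: int
    exposure_seconds: float = 5.0
    selection: str = "random_without_replacement"
    seed: int = 0

    def __post_init__(self):
        if self.n_conventional < 1 or self.n_synthetic < 1:
            raise ValueError("image counts must be >= 1")

    @property
    def total(self) -> int:
        return self.n_conventional + self.n_synthetic


@dataclass(frozen=True)
class ConfusionSummary:
    """Per-group percentages, rounded to integers."""

    pct_correct: int
    pct_fp: int
    pct_fn: int
    pct_concordance: int | None      # None for single-rater groups


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


_COLS = ["rater_id", "experience_group", "image_id", "true_class", "answer"]


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLS if c not in table.columns]
    if missing:
        raise ValueError(f"study table missing columns: {missing}")
    gaps = []
    images = set(table["image_id"].unique())
    for rid, sub in table.groupby("rater_id"):
        counts = sub["image_id"].value_counts()
        if (counts != 1).any() or set(counts.index) != images:
            gaps.append(rid)
    if gaps:
        raise ValueError(f"raters with missing/duplicate answers: {gaps}")
    return table


def score_study(table: pd.DataFrame) -> dict[str, ConfusionSummary]:
    """Score a study table per experience group.

    %correct is over all answers of the group; %FP over the group's
    answers to conventional images; %FN over its answers to synthetic
    images.
    """
    table = _validate_table(table)
    out: dict[str, ConfusionSummary] = {}
    for grp, sub in table.groupby("experience_group"):
        correct = (sub["answer"] == sub["true_class"]).mean() * 100.0
        conv = sub[sub["true_class"] == "conventional"]
        syn = sub[sub["true_class"] == "synthetic"]
        fp = (conv["answer"] == "synthetic").mean() * 100.0 if len(conv) else 0.0
        fn = (syn["answer"] == "conventional").mean() * 100.0 if len(syn) else 0.0
        n_raters = sub["rater_id"].nunique()
        conc = concordance(table, grp) if n_raters >= 2 else None
        out[grp] = ConfusionSummary(_round_half_up(correct),
                                    _round_half_up(fp), _round_half_up(fn),
                                    conc)
    return out


def concordance(table: pd.DataFrame, group: str) -> int:
    """Mean pairwise agreement among the group's raters, in percent.

    For two raters this is exactly the proportion of images on which
    they gave the same answer.
    """
    sub = table[table["experience_group"] == group]
    pivot = sub.pivot(index="image_id", columns="rater_id", values="answer")
    if pivot.shape[1] < 2:
        raise ValueError(f"group {group!r} has fewer than 2 raters")
    agree = [ (pivot[a] == pivot[b]).mean()
              for a, b in combinations(pivot.columns, 2) ]
    return _round_half_up(100.0 * float(np.mean(agree)))


# ---------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------

def chi_square_independence(contingency) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity
    correction.  Returns (statistic, df, p)."""
    obs = np.asarray(contingency, dtype=np.float64)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(obs, correction=False)
    if (res.expected_freq <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped and tied ranks averaged; the exact
    null distribution is used for n <= 25 untied differences, the
    normal approximation beyond.  Returns (statistic, p).
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero: statistic undefined")
    ranks = np.abs(d)
    has_ties = len(np.unique(ranks)) < len(ranks)
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=False,
                         alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(a, b, variant: str = "student") -> tuple[float, float, float]:
    """Two-sided two-sample t-test.  ``student`` pools variances,
    ``welch`` does not.  Returns (statistic, df, p)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    equal_var = variant == "student"
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("degenerate (zero) variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


# ---------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------

def design_study(pool: dict, n_conventional: int, n_synthetic: int,
                 seed: int = 0) -> tuple[StudyDesign, pd.DataFrame]:
    """Draw a blinded study from a QC-passed image pool.

    ``pool`` maps class name ('conventional'/'synthetic') to a list of
    image ids; images are drawn uniformly without replacement per
    class, reproducibly by seed.  Returns the design and the selected
    image table (image_id, true_class).
    """
    want = {"conventional": n_conventional, "synthetic": n_synthetic}
    rng = np.random.default_rng(seed)
    rows = []
    for cls, n in want.items():
        items = list(pool.get(cls, []))
        if len(items) < n:
            raise ValueError(
                f"pool has {len(items)} {cls} images, need {n}")
        chosen = rng.choice(len(items), size=n, replace=False)
        rows += [(items[i], cls) for i in sorted(chosen)]
    design = StudyDesign(n_conventional, n_synthetic, seed=seed)
    return design, pd.DataFrame(rows, columns=["image_id", "true_class"])
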