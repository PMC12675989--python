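"""Group-comparison statistical layer.

Implements the decision rule used throughout the cohort reports: check
normality per group (Shapiro-Wilk), log(x+1)-transform when rejected,
fall back to the Wilcoxon rank-sum test when the transform does not
restore normality; two groups are compared with Welch's t, three or more
with a one-way ANOVA followed by pairwise Welch tests summarised as
compact significance letters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientDataError

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Result of comparing one trait between vigour classes."""

    trait: str
    groups: dict            # class label -> {"mean", "se", "n"}
    test_used: str          # "welch_t" | "wilcoxon" | "anova" | "degenerate"
    statistic: float
    p: float
    letters: dict           # class label -> significance letter(s)
    transform: str = "none"  # "none" | "log1p"
    log: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return bool(self.p < ALPHA)


def welch_t(x, y):
    """Welch's unequal-variance t test.

    Returns (t, df, p). Identical constant groups are reported as
    t=0, p=1 rather than NaN; constant groups with different means as
    p=0 (an infinite t in the limit).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("welch_t needs >= 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return math.inf, float(len(x) + len(y) - 2), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    num = (vx / len(x) + vy / len(y)) ** 2
    den = (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    return float(t), float(num / den), float(p)


def wilcoxon_rank_sum(x, y):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test; returns (W, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("wilcoxon needs non-empty groups")
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical samples carry no evidence either way
        u = len(x) * len(y) / 2.0
        return float(u), 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def anova_oneway(groups):
    """One-way ANOVA F and p over a list of arrays."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise InsufficientDataError("anova needs >= 2 groups")
    if all(a.var(ddof=1) == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        if len(set(means)) == 1:
            return 0.0, 1.0
        return math.inf, 0.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def _is_normal(x, alpha=ALPHA):
    x = np.asarray(x, float)
    if len(x) < 3 or x.var(ddof=1) == 0:
        return True  # Shapiro undefined; treat as unobjectionable
    return sps.shapiro(x).pvalue >= alpha


def significance_letters(labels, pairwise_p, alpha=ALPHA):
    """Compact letter display from a pairwise p-value matrix.

    Insert-and-absorb algorithm: groups sharing a letter are pairwise
    non-significant; groups with disjoint letters differ at ``alpha``.
    ``pairwise_p`` maps frozenset({a, b}) -> p.
    """
    letter_sets = [set(labels)]  # start with everybody together
    for a in labels:
        for b in labels:
            if a >= b:
                continue
            p = pairwise_p.get(frozenset((a, b)), 1.0)
            if p < alpha:
                new_sets = []
                for s in letter_sets:
                    if a in s and b in s:
                        new_sets.append(s - {a})
                        new_sets.append(s - {b})
                    else:
                        new_sets.append(s)
                # absorb subsets
                letter_sets = [
                    s for s in new_sets
                    if not any(s < t for t in new_sets)
                ]
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for i, s in enumerate(letter_sets):
        for lab in sorted(s):
            out[lab] += alphabet[i]
    return out


def compare_groups(values_by_class, trait="trait", method="auto", alpha=ALPHA):
    """Compare a trait between vigour classes.

    ``method='auto'`` follows the normality-driven decision rule in the
    module docstring; explicit methods bypass it.
    """
    labels = list(values_by_class)
    arrays = {k: np.asarray(v, float) for k, v in values_by_class.items()}
    for k, a in arrays.items():
        if len(a) < 2:
            raise InsufficientDataError(f"group {k!r} has fewer than 2 values")
    log = []
    transform = "none"

    groups_summary = {
        k: {"mean": float(a.mean()),
            "se": float(a.std(ddof=1) / math.sqrt(len(a))) if len(a) > 1 else float("nan"),
            "n": int(len(a))}
        for k, a in arrays.items()
    }

    work = arrays
    if method == "auto":
        normal = all(_is_normal(a, alpha) for a in arrays.values())
        if not normal:
            log.append("shapiro rejected; applying log(x+1)")
            if all((a > -1).all() for a in arrays.values()):
                trans = {k: np.log1p(a) for k, a in arrays.items()}
                if all(_is_normal(a, alpha) for a in trans.values()):
                    work, transform = trans, "log1p"
                    method = "welch_t" if len(labels) == 2 else "anova"
                    log.append("log(x+1) restored normality")
                else:
                    method = "wilcoxon" if len(labels) == 2 else "anova"
                    log.append("still non-normal after log(x+1)")
            else:
                method = "wilcoxon" if len(labels) == 2 else "anova"
                log.append("log(x+1) inapplicable (values <= -1)")
        else:
            method = "welch_t" if len(labels) == 2 else "anova"
        log.append(f"method resolved to {method}")

    if all(a.var(ddof=1) == 0 for a in work.values()) and \
            len({a.mean() for a in work.values()}) == 1:
        letters = {k: "a" for k in labels}
        return GroupComparison(trait, groups_summary, "degenerate", 0.0, 1.0,
                               letters, transform, log + ["constant trait in all groups"])

    if method == "welch_t":
        if len(labels) != 2:
            raise InsufficientDataError("welch_t requires exactly 2 groups")
        stat, _, p = welch_t(work[labels[0]], work[labels[1]])
        pair_p = {frozenset(labels): p}
    elif method == "wilcoxon":
        if len(labels) != 2:
            raise InsufficientDataError("wilcoxon requires exactly 2 groups")
        stat, p = wilcoxon_rank_sum(work[labels[0]], work[labels[1]])
        pair_p = {frozenset(labels): p}
    elif method == "anova":
        stat, p = anova_oneway(list(work.values()))
        pair_p = {}
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                tw, _, pw = welch_t(work[a], work[b])
                pair_p[frozenset((a, b))] = pw
    else:
        raise ValueError(f"unknown method {method!r}")

    letters = significance_letters(labels, pair_p, alpha)
    return GroupComparison(trait, groups_summary, method, stat, p,
                           letters, transform, log)
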