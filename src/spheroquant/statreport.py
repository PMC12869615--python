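"""Group-comparison decision tree with compact-letter-display reporting.

The decision tree:

* Shapiro-Wilk on every group decides normality (all p > alpha => normal);
  Levene's test (Brown-Forsythe, median-centered) decides variance
  homogeneity.
* 2 groups: Student's t (normal, equal var), Welch's t (normal, unequal
  var), Wilcoxon rank-sum / Mann-Whitney U (nonparametric).
* 3+ groups: ANOVA -> Tukey HSD; Welch's ANOVA -> Games-Howell;
  Kruskal-Wallis -> Dunn.

Post-hoc pairwise p-values feed a compact letter display: groups that do not
share a letter are significantly different at alpha.  Dunn p-values are
reported as produced by the procedure, with no additional multiplicity
correction layered on; endpoints are not corrected across each other.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupData",
    "TestPlan",
    "TestReport",
    "choose_test",
    "run_plan",
    "analyze",
    "compact_letter_display",
    "dunn_test",
]


@dataclass(frozen=True)
class GroupData:
    """Labeled numeric samples; every group needs n >= 3 (Shapiro-Wilk)."""

    groups: dict[str, np.ndarray]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        clean = {}
        for name, values in self.groups.items():
            v = np.asarray(values, dtype=np.float64)
            if len(v) < 3:
                raise ValueError(
                    f"group {name!r} has {len(v)} observations; "
                    "Shapiro-Wilk needs at least 3"
                )
            clean[name] = v
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, value: str = "value", group: str = "group",
        alpha: float = 0.05,
    ) -> "GroupData":
        return cls(
            {str(g): sub[value].to_numpy() for g, sub in df.groupby(group)},
            alpha=alpha,
        )

    @property
    def names(self) -> list[str]:
        return list(self.groups)


@dataclass(frozen=True)
class TestPlan:
    normality_p: dict[str, float]
    levene_p: float
    chosen_test: str  # student_t | welch_t | wilcoxon | anova | welch_anova | kruskal_wallis
    posthoc: str  # none | tukey | games_howell | dunn


@dataclass(frozen=True)
class TestReport:
    plan: TestPlan
    omnibus_p: float
    statistic: float
    pairwise_p: pd.DataFrame | None = None
    letters: dict[str, str] | None = None


def choose_test(data: GroupData) -> TestPlan:
    """Apply the decision tree to pick the omnibus test and post-hoc."""
    alpha = data.alpha
    norm_p = {n: float(stats.shapiro(v).pvalue) for n, v in data.groups.items()}
    all_normal = all(p > alpha for p in norm_p.values())
    lev_p = float(
        stats.levene(*data.groups.values(), center="median").pvalue
    )
    equal_var = lev_p > alpha
    two = len(data.groups) == 2
    if all_normal and equal_var:
        test, posthoc = ("student_t", "none") if two else ("anova", "tukey")
    elif all_normal:
        test, posthoc = ("welch_t", "none") if two else ("welch_anova", "games_howell")
    else:
        test, posthoc = ("wilcoxon", "none") if two else ("kruskal_wallis", "dunn")
    return TestPlan(
        normality_p=norm_p, levene_p=lev_p, chosen_test=test, posthoc=posthoc
    )


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled ranks (tie-corrected), two-sided.

    Returns a symmetric DataFrame of uncorrected pairwise p-values.
    """
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for n in names:
        k = len(groups[n])
        mean_ranks[n] = ranks[start : start + k].mean()
        sizes[n] = k
        start += k
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        pv = 2.0 * stats.norm.sf(abs(z))
        p.loc[a, b] = p.loc[b, a] = pv
    return p


def _games_howell(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    import pingouin as pg

    df = pd.concat(
        [pd.DataFrame({"value": v, "group": n}) for n, v in groups.items()],
        ignore_index=True,
    )
    gh = pg.pairwise_gameshowell(data=df, dv="value", between="group")
    names = list(groups)
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for _, row in gh.iterrows():
        p.loc[str(row["A"]), str(row["B"])] = row["pval"]
        p.loc[str(row["B"]), str(row["A"])] = row["pval"]
    return p


def _tukey(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[n] * len(v) for n, v in groups.items()])
    res = pairwise_tukeyhsd(values, labels)
    names = list(groups)
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), pv in zip(
        itertools.combinations(res.groupsunique, 2), res.pvalues
    ):
        p.loc[str(a), str(b)] = p.loc[str(b), str(a)] = pv
    return p


def run_plan(data: GroupData, plan: TestPlan) -> TestReport:
    """Execute the chosen omnibus test and (for 3+ groups) the post-hoc."""
    groups = data.groups
    vals = list(groups.values())
    test = plan.chosen_test
    if test == "student_t":
        st = stats.ttest_ind(vals[0], vals[1], equal_var=True)
        stat, p = st.statistic, st.pvalue
    elif test == "welch_t":
        st = stats.ttest_ind(vals[0], vals[1], equal_var=False)
        stat, p = st.statistic, st.pvalue
    elif test == "wilcoxon":
        # Mann-Whitney U with normal approximation + continuity and tie
        # correction (the rank-sum test on independent samples)
        st = stats.mannwhitneyu(vals[0], vals[1], method="asymptotic")
        stat, p = st.statistic, st.pvalue
    elif test == "anova":
        st = stats.f_oneway(*vals)
        stat, p = st.statistic, st.pvalue
    elif test == "welch_anova":
        import pingouin as pg

        df = pd.concat(
            [pd.DataFrame({"value": v, "group": n}) for n, v in groups.items()],
            ignore_index=True,
        )
        res = pg.welch_anova(data=df, dv="value", between="group")
        stat, p = float(res["F"].iloc[0]), float(res["p_unc"].iloc[0])
    elif test == "kruskal_wallis":
        st = stats.kruskal(*vals)
        stat, p = st.statistic, st.pvalue
    else:
        raise ValueError(f"unknown test {test!r}")

    pairwise = None
    letters = None
    if plan.posthoc == "tukey":
        pairwise = _tukey(groups)
    elif plan.posthoc == "games_howell":
        pairwise = _games_howell(groups)
    elif plan.posthoc == "dunn":
        pairwise = dunn_test(groups)
    if pairwise is not None:
        letters = compact_letter_display(pairwise, data.alpha)
    return TestReport(
        plan=plan,
        omnibus_p=float(p),
        statistic=float(stat),
        pairwise_p=pairwise,
        letters=letters,
    )


def analyze(data: GroupData) -> TestReport:
    """choose_test followed by run_plan."""
    return run_plan(data, choose_test(data))


def compact_letter_display(
    pairwise_p: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Insert-and-absorb letter assignment over the non-significance graph.

    Guarantee (checked by construction): two groups share a letter iff their
    pairwise comparison is non-significant at alpha.  Letter count is not
    guaranteed minimal.
    """
    names = list(pairwise_p.index)
    nonsig = {
        (a, b): bool(pairwise_p.loc[a, b] > alpha)
        for a in names
        for b in names
        if a != b
    }
    # start from one column holding every group; each significant pair
    # splits any column containing both into C\{a} and C\{b}; subset columns
    # are absorbed.  Non-significant pairs are never separated (a split on
    # (x, y) keeps every other pair together in both copies), and final
    # columns contain no significant pair.
    letter_sets: list[set[str]] = [set(names)]
    for a, b in itertools.combinations(names, 2):
        if nonsig[(a, b)]:
            continue
        new_sets: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend((s - {a}, s - {b}))
            else:
                new_sets.append(s)
        # absorb: drop duplicates and strict subsets
        letter_sets = [
            s
            for i, s in enumerate(new_sets)
            if s
            and s not in new_sets[:i]
            and not any(s < t for t in new_sets)
        ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for i, s in enumerate(letter_sets):
        ch = alphabet[i % len(alphabet)] * (i // len(alphabet) + 1)
        for g in sorted(s, key=names.index):
            letters[g] += ch
    # any group with no letter (significantly different from everything)
    next_i = len(letter_sets)
    for g in names:
        if not letters[g]:
            letters[g] = alphabet[next_i % len(alphabet)] * (next_i // len(alphabet) + 1)
            next_i += 1
    _check_letters(letters, nonsig, names)
    return letters


def _check_letters(letters, nonsig, names) -> None:
    for a, b in itertools.combinations(names, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        if share != nonsig[(a, b)]:
            raise AssertionError(
                f"letter display invariant violated for ({a}, {b}): "
                f"share={share}, nonsignificant={nonsig[(a, b)]}"
            )
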