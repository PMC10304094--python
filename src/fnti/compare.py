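"""FNTi comparison across FCI grade groups.

Workflow mirrored here: per-group normality screening (Shapiro–Wilk),
variance-homogeneity screening (Levene), a Welch heteroscedastic one-way
ANOVA, the Games–Howell post hoc procedure for all pairwise contrasts under
unequal variances and sizes, and a compact letter display so a descriptive
table can carry superscripts where groups sharing a letter are not
significantly different.

Groups are mappings ``label -> 1-D array of FNTi values``.  Each hip joint
is treated as an independent observation (no dog-level clustering
correction), a documented limitation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class GroupDataError(ValueError):
    """Invalid group structure for comparison."""


def _validate_groups(groups: Mapping[str, np.ndarray], min_n: int = 3) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise GroupDataError("need at least 2 groups")
    out: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.ndim != 1 or len(arr) < min_n:
            raise GroupDataError(f"group {name!r}: need a 1-D sample with n >= {min_n}")
        if not np.all(np.isfinite(arr)):
            raise GroupDataError(f"group {name!r}: non-finite values")
        out[str(name)] = arr
    return out


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test (Royston algorithm), 3 <= n <= 5000."""
    arr = np.asarray(values, dtype=float)
    if not 3 <= len(arr) <= 5000:
        raise GroupDataError(f"Shapiro–Wilk defined for 3 <= n <= 5000, got {len(arr)}")
    if np.ptp(arr) == 0.0:
        raise GroupDataError("Shapiro–Wilk undefined for a constant sample")
    res = stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


@dataclass
class LeveneResult:
    statistic: float
    df1: int
    df2: int
    p_value: float


def levene(groups: Mapping[str, np.ndarray], center: str = "mean") -> LeveneResult:
    """Levene's variance-homogeneity test.

    ``center="mean"`` is the classic Levene test (one-way ANOVA on absolute
    deviations from group means); ``center="median"`` gives the
    Brown–Forsythe variant.
    """
    g = _validate_groups(groups)
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    arrays = list(g.values())
    stat, p = stats.levene(*arrays, center=center)
    k = len(arrays)
    big_n = sum(len(a) for a in arrays)
    return LeveneResult(float(stat), k - 1, big_n - k, float(p))


@dataclass
class WelchAnovaResult:
    f_stat: float
    df1: float
    df2: float
    p_value: float


def welch_anova(groups: Mapping[str, np.ndarray]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    With group weights w_i = n_i / s_i^2 and weighted grand mean
    x̄* = Σ w_i x̄_i / Σ w_i,

        F = [Σ w_i (x̄_i − x̄*)² / (k−1)] / [1 + 2(k−2)Λ / (k²−1)],
        Λ = Σ (1 − w_i/W)² / (n_i − 1),  df1 = k−1,  df2 = (k²−1)/(3Λ).
    """
    g = _validate_groups(groups)
    k = len(g)
    n = np.array([len(v) for v in g.values()], dtype=float)
    m = np.array([v.mean() for v in g.values()])
    s2 = np.array([v.var(ddof=1) for v in g.values()])
    for name, var in zip(g, s2):
        if var == 0.0:
            raise GroupDataError(f"group {name!r} has zero within-group variance")
    w = n / s2
    W = w.sum()
    grand = (w * m).sum() / W
    lam = ((1.0 - w / W) ** 2 / (n - 1.0)).sum()
    num = (w * (m - grand) ** 2).sum() / (k - 1)
    f = num / (1.0 + 2.0 * (k - 2) * lam / (k**2 - 1.0))
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = stats.f.sf(f, k - 1, df2)
    return WelchAnovaResult(float(f), float(k - 1), float(df2), float(p))


def games_howell(groups: Mapping[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Games–Howell pairwise comparisons for unequal variances and sizes.

    For each pair: SE = √(s_i²/n_i + s_j²/n_j), t = (x̄_i − x̄_j)/SE, df by
    Welch–Satterthwaite, and the adjusted p-value is the survival function
    of the studentized range distribution at |t|·√2 with k groups and that
    df (evaluated with scipy's studentized_range).  Two-sided throughout.
    """
    g = _validate_groups(groups)
    k = len(g)
    names = list(g)
    stats_by = {
        name: (len(v), v.mean(), v.var(ddof=1)) for name, v in g.items()
    }
    for name, (_, _, var) in stats_by.items():
        if var == 0.0:
            raise GroupDataError(f"group {name!r} has zero within-group variance")
    rows = []
    for gi, gj in itertools.combinations(names, 2):
        ni, mi, vi = stats_by[gi]
        nj, mj, vj = stats_by[gj]
        se = math.sqrt(vi / ni + vj / nj)
        t = (mi - mj) / se
        df = (vi / ni + vj / nj) ** 2 / (
            (vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1)
        )
        p_adj = float(stats.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))
        p_adj = min(1.0, max(0.0, p_adj))
        rows.append(
            {
                "group_i": gi,
                "group_j": gj,
                "mean_diff": mi - mj,
                "se": se,
                "t": t,
                "df": df,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def compact_letters(
    means: Mapping[str, float],
    significant_pairs: set[frozenset] | Sequence[tuple[str, str]],
) -> dict[str, str]:
    """Compact letter display via the insertion–absorption algorithm.

    Groups are processed in ascending-mean order; letters are assigned so
    that two groups share at least one letter **iff** their pair is not in
    ``significant_pairs``.  Output is deterministic: letters a, b, c, … are
    numbered along the mean order.
    """
    sig = {frozenset(p) for p in significant_pairs}
    order = sorted(means, key=lambda g: (means[g], str(g)))
    rank = {g: i for i, g in enumerate(order)}
    for pair in sig:
        if len(pair) != 2 or any(g not in rank for g in pair):
            raise GroupDataError(f"significant pair {set(pair)} does not match the groups")
    # process pairs in mean order for deterministic letter labels
    sorted_pairs = sorted((sorted(p, key=rank.get) for p in sig), key=lambda ab: (rank[ab[0]], rank[ab[1]]))
    # each "letter" is the set of groups sharing it; start with everyone
    letters: list[set[str]] = [set(order)]
    for a, b in sorted_pairs:
        for col in [c for c in letters if a in c and b in c]:
            letters.remove(col)
            letters.append(col - {a})
            letters.append(col - {b})
        # absorb: drop empty sets, duplicates, and sets contained in another
        uniq: list[set[str]] = []
        for c in letters:
            if c and c not in uniq:
                uniq.append(c)
        letters = [c for c in uniq if not any(c < other for other in uniq)]
    # deterministic letter order: by first (lowest-mean) member, then size
    letters.sort(key=lambda c: (min(rank[g] for g in c), -len(c), sorted(rank[g] for g in c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment: dict[str, list[str]] = {g: [] for g in order}
    for idx, col in enumerate(letters):
        ch = alphabet[idx] if idx < 26 else f"l{idx}"
        for gname in col:
            assignment[gname].append(ch)
    return {g: "".join(sorted(assignment[g])) for g in order}


def describe_groups(groups: Mapping[str, np.ndarray], conf: float = 0.95) -> pd.DataFrame:
    """Per-group descriptives: n, mean, SD, t-based CI of the mean, min, max."""
    g = _validate_groups(groups, min_n=2)
    rows = []
    for name, vals in g.items():
        n = len(vals)
        mean = vals.mean()
        sd = vals.std(ddof=1)
        half = stats.t.ppf((1 + conf) / 2, n - 1) * sd / math.sqrt(n)
        rows.append(
            {
                "group": name,
                "n": n,
                "mean": mean,
                "sd": sd,
                "ci_lower": mean - half,
                "ci_upper": mean + half,
                "min": vals.min(),
                "max": vals.max(),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def boxplot_data(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Quartiles, Tukey whiskers and outliers per group, for box plots."""
    g = _validate_groups(groups, min_n=2)
    rows = []
    for name, vals in g.items():
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inliers = vals[(vals >= lo_f) & (vals <= hi_f)]
        outliers = vals[(vals < lo_f) | (vals > hi_f)]
        rows.append(
            {
                "group": name,
                "whisker_low": inliers.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "whisker_high": inliers.max(),
                "outliers": ";".join(f"{v:.6g}" for v in sorted(outliers)),
            }
        )
    return pd.DataFrame(rows).set_index("group")


@dataclass
class GroupComparisonReport:
    """Bundle mirroring a grade-comparison results table."""

    descriptives: pd.DataFrame  # indexed by group, incl. a 'letters' column
    welch: WelchAnovaResult
    pairwise: pd.DataFrame
    alpha: float

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "welch": {
                "F": self.welch.f_stat,
                "df1": self.welch.df1,
                "df2": self.welch.df2,
                "p": self.welch.p_value,
            },
            "groups": self.descriptives.reset_index().to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def compare_groups(groups: Mapping[str, np.ndarray], alpha: float = 0.05) -> GroupComparisonReport:
    """Descriptives + Welch ANOVA + Games–Howell + compact letters."""
    g = _validate_groups(groups)
    desc = describe_groups(g)
    welch = welch_anova(g)
    pairwise = games_howell(g, alpha=alpha)
    sig = {
        frozenset((r.group_i, r.group_j))
        for r in pairwise.itertuples()
        if r.significant
    }
    letters = compact_letters({name: v.mean() for name, v in g.items()}, sig)
    desc = desc.assign(letters=[letters[name] for name in desc.index])
    return GroupComparisonReport(desc, welch, pairwise, alpha)
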