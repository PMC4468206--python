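"""The statistical battery: between-, mixed- and within-subject ANOVAs,
Tukey and Bonferroni follow-ups, simple-effects analysis and the unpaired
t-test, implemented from first-principles sums of squares.

Conventions: unbalanced between-subject designs use Type-III sums of
squares (sum-to-zero coding, each effect tested after all others), which is
the convention matching "main effect" language under imbalance.  Mixed
designs test the between factor against the subjects-within-groups mean
square and the within factor and interaction against the within-subject
residual.  Sphericity corrections are omitted; for the two-level within
factors used here they are moot (with more levels they would matter).
Significance is conventionally assessed at alpha = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

ALPHA = 0.05


@dataclass
class StatResult:
    """One tested effect: statistic, degrees of freedom, p, follow-ups.

    ``F`` holds the test statistic named by ``stat_label`` (an F ratio for
    ANOVAs, Student's t for the t-test).
    """

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    followup: list = field(default_factory=list)
    stat_label: str = "F"

    def __post_init__(self) -> None:
        if self.stat_label == "F" and self.F < -1e-12:
            raise ValueError("F statistic cannot be negative")
        if not 0 <= self.p <= 1 + 1e-12:
            raise ValueError("p must lie in [0, 1]")


def _check_columns(table: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")


def _sum_code(labels: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    levels = sorted(pd.unique(labels))
    k = len(levels)
    if k < 2:
        raise ValueError("factor needs at least 2 levels")
    X = np.zeros((len(labels), k - 1))
    for j, level in enumerate(levels[:-1]):
        X[:, j] = np.where(labels == level, 1.0, np.where(labels == levels[-1], -1.0, 0.0))
    return X, levels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def anova_two_way_between(
    table: pd.DataFrame,
    factor_a: str = "A",
    factor_b: str = "B",
    value: str = "value",
) -> list[StatResult]:
    """Two-way between-subjects ANOVA with Type-III sums of squares.

    Returns the two main effects and the interaction.  Unbalanced cell
    sizes are handled by the sum-coded regression route; empty cells are
    rejected by name.
    """
    _check_columns(table, [factor_a, factor_b, value])
    cells = table.groupby([factor_a, factor_b])[value].count()
    levels_a = sorted(table[factor_a].unique())
    levels_b = sorted(table[factor_b].unique())
    for la, lb in itertools.product(levels_a, levels_b):
        if (la, lb) not in cells.index or cells[(la, lb)] == 0:
            raise ValueError(f"empty cell: {factor_a}={la!r}, {factor_b}={lb!r}")
    y = table[value].to_numpy(dtype=float)
    Xa, _ = _sum_code(table[factor_a])
    Xb, _ = _sum_code(table[factor_b])
    Xab = np.einsum("ij,ik->ijk", Xa, Xb).reshape(len(y), -1)
    ones = np.ones((len(y), 1))
    blocks = {"intercept": ones, factor_a: Xa, factor_b: Xb,
              f"{factor_a} x {factor_b}": Xab}
    X_full = np.hstack(list(blocks.values()))
    rss_full = _rss(X_full, y)
    df_err = len(y) - X_full.shape[1]
    if df_err <= 0:
        raise ValueError("no error degrees of freedom (need >= 2 subjects per cell)")
    mse = rss_full / df_err
    results = []
    for name in (factor_a, factor_b, f"{factor_a} x {factor_b}"):
        X_red = np.hstack([v for k, v in blocks.items() if k != name])
        ss = max(_rss(X_red, y) - rss_full, 0.0)
        df = blocks[name].shape[1]
        F = (ss / df) / mse if mse > 0 else 0.0
        p = float(sst.f.sf(F, df, df_err)) if mse > 0 else 1.0
        results.append(StatResult(effect=name, F=F, df_num=df, df_den=df_err, p=p))
    return results


def anova_mixed(
    table: pd.DataFrame,
    between: str = "between",
    within: str = "within",
    subject: str = "subject",
    value: str = "value",
) -> list[StatResult]:
    """Mixed (split-plot) two-way ANOVA.

    The between factor is tested against subjects-within-groups; the within
    factor and the interaction against the within-subject residual.  Every
    subject must be observed at every within level.
    """
    _check_columns(table, [between, within, subject, value])
    w_levels = sorted(table[within].unique())
    q = len(w_levels)
    if q < 2:
        raise ValueError("within factor needs at least 2 levels")
    for subj, grp in table.groupby(subject):
        seen = sorted(grp[within].unique())
        if seen != w_levels or len(grp) != q:
            raise ValueError(
                f"subject {subj!r} lacks a complete set of within-factor levels"
            )
    groups_of = table.groupby(subject)[between].nunique()
    if (groups_of > 1).any():
        bad = groups_of[groups_of > 1].index[0]
        raise ValueError(f"subject {bad!r} appears in more than one group")

    y = table[value].to_numpy(dtype=float)
    N = len(y)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_mean = table.groupby(subject)[value].mean()
    subj_group = table.groupby(subject)[between].first()
    g_levels = sorted(subj_group.unique())
    n_subj = len(subj_mean)
    n_g = subj_group.value_counts()

    ss_between_subjects = q * float(((subj_mean - grand) ** 2).sum())
    group_mean = subj_mean.groupby(subj_group).mean()
    ss_A = q * float(sum(n_g[g] * (group_mean[g] - grand) ** 2 for g in g_levels))
    ss_subj = ss_between_subjects - ss_A
    df_A, df_subj = len(g_levels) - 1, n_subj - len(g_levels)

    w_mean = table.groupby(within)[value].mean()
    ss_B = n_subj * float(((w_mean - grand) ** 2).sum())
    cell = table.groupby([between, within])[value].mean()
    ss_cells = float(
        sum(n_g[g] * (cell[(g, w)] - grand) ** 2 for g in g_levels for w in w_levels)
    )
    ss_AB = ss_cells - ss_A - ss_B
    ss_err = ss_total - ss_between_subjects - ss_B - ss_AB
    df_B = q - 1
    df_AB = df_A * df_B
    df_err = df_subj * df_B
    if df_subj <= 0 or df_err <= 0:
        raise ValueError("not enough subjects for the mixed design")

    ms_subj = ss_subj / df_subj
    ms_err = ss_err / df_err
    out = []
    for name, ss, dfn, dfd, ms_e in (
        (between, ss_A, df_A, df_subj, ms_subj),
        (within, ss_B, df_B, df_err, ms_err),
        (f"{between} x {within}", ss_AB, df_AB, df_err, ms_err),
    ):
        F = (ss / dfn) / ms_e if ms_e > 0 else 0.0
        F = max(F, 0.0)
        out.append(StatResult(effect=name, F=F, df_num=dfn, df_den=dfd,
                              p=float(sst.f.sf(F, dfn, dfd))))
    return out


def anova_one_way_within(
    table: pd.DataFrame,
    subject: str = "subject",
    level: str = "level",
    value: str = "value",
) -> StatResult:
    """One-way repeated-measures ANOVA with subject blocking."""
    _check_columns(table, [subject, level, value])
    levels = sorted(table[level].unique())
    q = len(levels)
    if q < 2:
        raise ValueError("need at least 2 within-factor levels")
    for subj, grp in table.groupby(subject):
        if sorted(grp[level].unique()) != levels or len(grp) != q:
            raise ValueError(f"incomplete block for subject {subj!r}")
    y = table[value].to_numpy(dtype=float)
    grand = y.mean()
    n = table[subject].nunique()
    ss_total = float(((y - grand) ** 2).sum())
    ss_treat = n * float(((table.groupby(level)[value].mean() - grand) ** 2).sum())
    ss_subj = q * float(((table.groupby(subject)[value].mean() - grand) ** 2).sum())
    ss_err = max(ss_total - ss_treat - ss_subj, 0.0)
    df_t, df_e = q - 1, (q - 1) * (n - 1)
    if df_e <= 0:
        raise ValueError("need at least 2 subjects")
    ms_e = ss_err / df_e
    F = (ss_treat / df_t) / ms_e if ms_e > 0 else (0.0 if ss_treat == 0 else np.inf)
    return StatResult(effect=level, F=float(F), df_num=df_t, df_den=df_e,
                      p=float(sst.f.sf(F, df_t, df_e)))


def tukey_hsd(
    means: dict[str, float],
    ns: dict[str, int],
    mse: float,
    df_error: int,
) -> list[tuple[tuple[str, str], float, float]]:
    """Tukey(-Kramer) studentized-range test for all pairs of group means.

    Returns ``((group_i, group_j), q, adjusted_p)`` per pair, using the
    pooled error mean square and its degrees of freedom from the omnibus
    ANOVA.
    """
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    if len(means) < 2:
        raise ValueError("need at least two groups")
    k = len(means)
    out = []
    for gi, gj in itertools.combinations(sorted(means), 2):
        se = np.sqrt(mse / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
        q = abs(means[gi] - means[gj]) / se if se > 0 else 0.0
        p = float(sst.studentized_range.sf(q, k, df_error)) if q > 0 else 1.0
        out.append(((gi, gj), float(q), min(p, 1.0)))
    return out


def bonferroni_adjust(p_values: list[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p * m); m defaults to the family size."""
    ps = list(p_values)
    if any(not 0 <= p <= 1 for p in ps):
        raise ValueError("p values must lie in [0, 1]")
    m = len(ps) if m is None else m
    return [min(1.0, p * m) for p in ps]


def simple_effects(
    table: pd.DataFrame,
    factor: str,
    across: str,
    value: str = "value",
    error_ms: float | None = None,
    error_df: int | None = None,
) -> list[StatResult]:
    """Effect of ``factor`` at each level of ``across``.

    Each slice is tested against the omnibus error term (supplied, or
    recomputed from the full two-way between-subjects model).  Intended as
    the follow-up to a significant interaction; the caller decides whether
    the interaction warranted it.
    """
    _check_columns(table, [factor, across, value])
    if table[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    if error_ms is None or error_df is None:
        omnibus = anova_two_way_between(table, factor, across, value)
        error_df = omnibus[0].df_den
        # full-model residual mean square
        cell_means = table.groupby([factor, across])[value].transform("mean")
        rss = float(((table[value] - cell_means) ** 2).sum())
        error_ms = rss / error_df
    out = []
    for lvl, grp in table.groupby(across):
        counts = grp.groupby(factor)[value].count()
        means = grp.groupby(factor)[value].mean()
        slice_mean = grp[value].mean()
        ss = float(sum(counts[a] * (means[a] - slice_mean) ** 2 for a in means.index))
        dfn = len(means) - 1
        if dfn < 1:
            raise ValueError(f"{factor!r} has a single level at {across}={lvl!r}")
        F = (ss / dfn) / error_ms if error_ms > 0 else 0.0
        out.append(
            StatResult(effect=f"{factor} at {across}={lvl}", F=F, df_num=dfn,
                       df_den=int(error_df), p=float(sst.f.sf(F, dfn, error_df)))
        )
    return out


def t_unpaired(x, y, two_tailed: bool = True) -> StatResult:
    """Pooled-variance unpaired Student's t-test.

    When both samples have zero variance and equal means the comparison is
    vacuous and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    df = x.size + y.size - 2
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return StatResult(effect="t", F=0.0, df_num=1, df_den=df, p=1.0,
                              stat_label="t")
        return StatResult(effect="t", F=np.inf, df_num=1, df_den=df, p=0.0,
                          stat_label="t")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / x.size + 1.0 / y.size))
    p = float(sst.t.sf(abs(t), df)) * (2 if two_tailed else 1)
    return StatResult(effect="t", F=float(t), df_num=1, df_den=df, p=min(p, 1.0),
                      stat_label="t")
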