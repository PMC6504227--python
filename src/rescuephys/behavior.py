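"""Behavioral endpoints and the cohort statistical battery.

Implements the activity suppression ratio, two-factor between-subjects
ANOVA (type-III sums of squares), mixed repeated-measures ANOVA, MANOVA
(Pillai's trace), t tests, Wilcoxon rank sum, Cohen's d, and Bonferroni
pairwise comparisons, returning uniform :class:`StatResult` records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from rescuephys.core import ContractError

VALUE_COL = "value"
ENDPOINT_COL = "endpoint"
ANIMAL_COL = "animal_id"


@dataclass
class StatResult:
    """One test outcome formatted like a figure-legend statistic."""

    test: str
    statistic: float
    df: Optional[tuple] = None
    p: Optional[float] = None
    effect_size: Optional[float] = None
    comparison: Optional[str] = None
    note: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df) if self.df is not None else None,
            "p": self.p,
            "effect_size": self.effect_size,
            "comparison": self.comparison,
            "note": self.note,
        }


def activity_suppression_ratio(
    train_activity_cm: float, test_activity_cm: float
) -> float:
    """test / (train + test) over matched 0-2 min windows.

    0.5 means no suppression; lower values mean stronger contextual memory.
    """
    if train_activity_cm < 0 or test_activity_cm < 0:
        raise ContractError("activities must be >= 0")
    total = train_activity_cm + test_activity_cm
    if total == 0:
        raise ContractError("both activities are 0; ratio undefined")
    return test_activity_cm / total


def _endpoint_frame(table: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    if ENDPOINT_COL in table.columns:
        sub = table[table[ENDPOINT_COL] == endpoint]
        if sub.empty:
            raise ContractError(f"endpoint {endpoint!r} absent from table")
        return sub.copy()
    return table.copy()


def two_factor_anova(
    table: pd.DataFrame,
    endpoint: str,
    factors: tuple[str, str] = ("cre", "genotype"),
) -> list[StatResult]:
    """Between-subjects two-factor ANOVA with type-III sums of squares.

    Returns main effects for both factors plus the interaction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = _endpoint_frame(table, endpoint)
    f1, f2 = factors
    levels1 = sub[f1].unique()
    levels2 = sub[f2].unique()
    if min(len(levels1), len(levels2)) < 2:
        # degenerate design: only one level of a factor observed; report the
        # main effect of the other factor alone
        lone = f2 if len(levels1) < 2 else f1
        data = sub.rename(columns={lone: "_f1", VALUE_COL: "_y"})
        model = smf.ols("_y ~ C(_f1, Sum)", data=data).fit()
        tab = sm.stats.anova_lm(model, typ=3)
        return [
            _anova_row(
                tab,
                "C(_f1, Sum)",
                f"{endpoint}: {lone}",
                note="degenerate design: single-level factor dropped",
            )
        ]
    counts = sub.groupby([f1, f2], observed=True)[VALUE_COL].count()
    for a in levels1:
        for b in levels2:
            if counts.get((a, b), 0) < 2:
                raise ContractError(
                    f"cell ({f1}={a}, {f2}={b}) has <2 observations"
                )
    if np.ptp(sub[VALUE_COL].to_numpy()) == 0:
        # identically constant response: every F is 0 by convention
        return [
            StatResult(
                test="two_factor_anova",
                statistic=0.0,
                df=(1, int(len(sub) - len(levels1) * len(levels2))),
                p=1.0,
                comparison=f"{endpoint}: {label}",
                note="constant response",
            )
            for label in (f1, f2, "interaction")
        ]
    data = sub.rename(columns={f1: "_f1", f2: "_f2", VALUE_COL: "_y"})
    model = smf.ols("_y ~ C(_f1, Sum) * C(_f2, Sum)", data=data).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    return [
        _anova_row(tab, term, f"{endpoint}: {label}")
        for label, term in [
            (f1, "C(_f1, Sum)"),
            (f2, "C(_f2, Sum)"),
            ("interaction", "C(_f1, Sum):C(_f2, Sum)"),
        ]
    ]


def _anova_row(tab, term: str, comparison: str, note: Optional[str] = None) -> StatResult:
    df_resid = int(tab.loc["Residual", "df"])
    f = float(tab.loc[term, "F"])
    p = float(tab.loc[term, "PR(>F)"])
    if not math.isfinite(f) and float(tab.loc[term, "sum_sq"]) < 1e-12:
        # no between-cell variance at all: define F = 0, p = 1
        f, p = 0.0, 1.0
    return StatResult(
        test="two_factor_anova",
        statistic=f,
        df=(int(tab.loc[term, "df"]), df_resid),
        p=p,
        comparison=comparison,
        note=note,
    )


def mixed_rm_anova(
    table: pd.DataFrame,
    endpoint: str,
    between: str = "genotype",
    within: str = "tmx",
    subject: str = ANIMAL_COL,
) -> list[StatResult]:
    """Mixed (split-plot) ANOVA: one between factor, one within factor.

    Animals missing a within level are excluded with a warning; the subject
    stratum supplies the between-effect error term.
    """
    import pingouin as pg

    sub = _endpoint_frame(table, endpoint)
    n_levels = sub[within].nunique()
    complete = sub.groupby(subject)[within].nunique() == n_levels
    incomplete = complete[~complete].index.tolist()
    if incomplete:
        warnings.warn(
            f"excluding animals missing a within level: {incomplete}",
            stacklevel=2,
        )
        sub = sub[~sub[subject].isin(incomplete)]
    for level, grp in sub.groupby(between, observed=True):
        if grp[subject].nunique() < 2:
            raise ContractError(f"between level {level!r} has <2 animals")
    aov = pg.mixed_anova(
        data=sub, dv=VALUE_COL, within=within, between=between, subject=subject
    )
    aov = aov.set_index("Source")
    out = []
    for source, label in [
        (between, between),
        (within, within),
        ("Interaction", "interaction"),
    ]:
        row = aov.loc[source]
        f = float(row["F"])
        p = float(row["p_unc"])
        if not math.isfinite(f) and float(row["SS"]) < 1e-12:
            f, p = 0.0, 1.0  # no effect variance at all
        out.append(
            StatResult(
                test="mixed_rm_anova",
                statistic=f,
                df=(int(row["DF1"]), int(row["DF2"])),
                p=p,
                comparison=f"{endpoint}: {label}",
            )
        )
    return out


def manova(
    table: pd.DataFrame,
    endpoints: Sequence[str],
    factors: tuple[str, str] = ("cre", "genotype"),
) -> list[StatResult]:
    """MANOVA across correlated endpoints; Pillai's trace per term."""
    from statsmodels.multivariate.manova import MANOVA

    wide = (
        _endpoint_frame_multi(table, endpoints)
        .pivot_table(
            index=[ANIMAL_COL, *factors],
            columns=ENDPOINT_COL,
            values=VALUE_COL,
            observed=True,
        )
        .reset_index()
    )
    missing = wide[list(endpoints)].isna().any(axis=1)
    if missing.any():
        raise ContractError(
            f"{int(missing.sum())} animals lack one or more endpoints"
        )
    f1, f2 = factors
    # drop endpoints that exactly duplicate an earlier one (rank-degenerate
    # response matrix would make the within-covariance singular)
    kept: list[str] = []
    dropped: list[str] = []
    for e in endpoints:
        if any(np.allclose(wide[e], wide[k]) for k in kept):
            dropped.append(e)
        else:
            kept.append(e)
    note = f"duplicate endpoints dropped: {dropped}" if dropped else None
    if len(kept) == 1:
        # fully degenerate response: equivalent to the univariate ANOVA
        long = wide.melt(
            id_vars=[ANIMAL_COL, f1, f2],
            value_vars=kept,
            var_name=ENDPOINT_COL,
            value_name=VALUE_COL,
        )
        out = []
        for r in two_factor_anova(long, kept[0], factors=factors):
            df1, df2 = r.df
            pillai = (df1 * r.statistic) / (df1 * r.statistic + df2)
            out.append(
                StatResult(
                    test="manova_pillai",
                    statistic=pillai,
                    df=(float(df1), float(df2)),
                    p=r.p,
                    comparison=r.comparison.split(": ", 1)[-1],
                    note="; ".join(
                        x
                        for x in (f"approx F={r.statistic:.4g}", note)
                        if x
                    ),
                )
            )
        return out
    cols = {e: f"_e{i}" for i, e in enumerate(kept)}
    data = wide.rename(columns={**cols, f1: "_f1", f2: "_f2"})
    dv = " + ".join(cols.values())
    try:
        mv = MANOVA.from_formula(
            f"{dv} ~ C(_f1, Sum) * C(_f2, Sum)", data=data
        )
        res = mv.mv_test()
    except Exception as exc:  # singular within-covariance and kin
        raise ContractError(
            "MANOVA failed (possibly singular within-group covariance); "
            f"consider dropping an endpoint: {exc}"
        ) from exc
    out = []
    for term, label in [
        ("C(_f1, Sum)", f1),
        ("C(_f2, Sum)", f2),
        ("C(_f1, Sum):C(_f2, Sum)", "interaction"),
    ]:
        stat = res.results[term]["stat"]
        row = stat.loc["Pillai's trace"]
        out.append(
            StatResult(
                test="manova_pillai",
                statistic=float(row["Value"]),
                df=(float(row["Num DF"]), float(row["Den DF"])),
                p=float(row["Pr > F"]),
                comparison=label,
                note="; ".join(
                    x
                    for x in (f"approx F={float(row['F Value']):.4g}", note)
                    if x
                ),
            )
        )
    return out


def _endpoint_frame_multi(
    table: pd.DataFrame, endpoints: Sequence[str]
) -> pd.DataFrame:
    sub = table[table[ENDPOINT_COL].isin(endpoints)]
    have = set(sub[ENDPOINT_COL].unique())
    lacking = set(endpoints) - have
    if lacking:
        raise ContractError(f"endpoints absent from table: {sorted(lacking)}")
    return sub.copy()


def group_compare(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "unpaired_t",
    w_convention: str = "mannwhitney_first",
) -> StatResult:
    """Two-group comparison: unpaired t, paired t, or Wilcoxon rank sum.

    For the rank-sum test the reported statistic follows ``w_convention``:
    'mannwhitney_first' (default) is the Mann-Whitney U of the first group;
    'ranksum' is the raw rank sum of the first group. p is exact for small
    samples without ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ContractError("each group needs >= 2 values")
    if test == "unpaired_t":
        r = sps.ttest_ind(a, b)
        return StatResult(
            test=test,
            statistic=float(r.statistic),
            df=(int(len(a) + len(b) - 2),),
            p=float(r.pvalue),
        )
    if test == "paired_t":
        if len(a) != len(b):
            raise ContractError("paired test needs equal-length groups")
        r = sps.ttest_rel(a, b)
        return StatResult(
            test=test,
            statistic=float(r.statistic),
            df=(int(len(a) - 1),),
            p=float(r.pvalue),
        )
    if test == "wilcoxon":
        method = "exact" if (len(a) <= 25 and len(b) <= 25) else "asymptotic"
        r = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        u_first = float(r.statistic)
        if w_convention == "mannwhitney_first":
            stat = u_first
        elif w_convention == "ranksum":
            stat = u_first + len(a) * (len(a) + 1) / 2.0
        else:
            raise ContractError(f"unknown w_convention {w_convention!r}")
        return StatResult(test=test, statistic=stat, p=float(r.pvalue))
    raise ContractError(f"unknown test {test!r}")


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """|mean difference| / pooled SD (n-1 weighted pooling)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ContractError("each group needs >= 2 values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (
        na + nb - 2
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ContractError("zero pooled SD with unequal means; d undefined")
    return abs(a.mean() - b.mean()) / math.sqrt(pooled_var)


def bonferroni_pairwise(
    table: pd.DataFrame,
    endpoint: str,
    group_col: str = "group",
    groups: Optional[Sequence] = None,
) -> list[StatResult]:
    """All pairwise unpaired t tests with Bonferroni-adjusted p values."""
    sub = _endpoint_frame(table, endpoint)
    if groups is None:
        groups = list(sub[group_col].unique())
    if len(groups) < 2:
        raise ContractError("need >= 2 groups")
    pairs = [
        (groups[i], groups[j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    ]
    m = len(pairs)
    out = []
    for ga, gb in pairs:
        a = sub.loc[sub[group_col] == ga, VALUE_COL].to_numpy()
        b = sub.loc[sub[group_col] == gb, VALUE_COL].to_numpy()
        r = group_compare(a, b, test="unpaired_t")
        out.append(
            StatResult(
                test="bonferroni_t",
                statistic=r.statistic,
                df=r.df,
                p=min(1.0, r.p * m),
                effect_size=cohens_d(a, b),
                comparison=f"{ga} vs {gb}",
                note=f"raw p={r.p:.4g}, m={m}",
            )
        )
    return out
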