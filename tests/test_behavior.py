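import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rescuephys.behavior import (
    activity_suppression_ratio,
    bonferroni_pairwise,
    cohens_d,
    group_compare,
    manova,
    mixed_rm_anova,
    two_factor_anova,
)
from rescuephys.core import ContractError


def _table(rows):
    return pd.DataFrame(
        rows, columns=["animal_id", "genotype", "cre", "tmx", "endpoint", "value"]
    )


def _four_group_table(rng, means, sd=1.0, n=6, endpoint="asr"):
    rows = []
    i = 0
    for (g, c), m in means.items():
        for _ in range(n):
            i += 1
            rows.append((f"a{i}", g, c, "-", endpoint, rng.normal(m, sd)))
    return _table(rows)


# --- ASR --------------------------------------------------------------------


def test_asr_arithmetic():
    assert activity_suppression_ratio(90, 30) == pytest.approx(0.25)


def test_asr_symmetry():
    assert activity_suppression_ratio(42.0, 42.0) == pytest.approx(0.5)


def test_asr_full_suppression():
    assert activity_suppression_ratio(50.0, 0.0) == 0.0


def test_asr_undefined():
    with pytest.raises(ContractError):
        activity_suppression_ratio(0.0, 0.0)


@settings(max_examples=50, deadline=None)
@given(
    train=st.floats(0.1, 1e4),
    test=st.floats(0.0, 1e4),
    scale=st.floats(0.01, 100),
)
def test_asr_bounds_and_rescaling(train, test, scale):
    r = activity_suppression_ratio(train, test)
    assert 0.0 <= r <= 1.0
    assert activity_suppression_ratio(scale * train, scale * test) == pytest.approx(
        r, rel=1e-9
    )


# --- two-factor ANOVA -------------------------------------------------------


def test_two_factor_anova_detects_genotype():
    rng = np.random.default_rng(42)
    means = {("+/+", "-"): 0.2, ("+/+", "+"): 0.2, ("+/ls", "-"): 0.5, ("+/ls", "+"): 0.5}
    tab = _four_group_table(rng, means, sd=0.05, n=8)
    res = {r.comparison: r for r in two_factor_anova(tab, "asr")}
    assert res["asr: genotype"].p < 1e-6
    assert res["asr: cre"].p > 0.01
    assert res["asr: genotype"].df == (1, 28)


def test_two_factor_anova_constant_cells():
    rows = [
        (f"a{i}{g}{c}", g, c, "-", "asr", 0.4)
        for g in ("+/+", "+/ls")
        for c in "-+"
        for i in range(3)
    ]
    res = two_factor_anova(_table(rows), "asr")
    assert all(r.statistic == 0.0 and r.p == 1.0 for r in res)


def test_two_factor_anova_empty_cell_named():
    rows = [
        ("a1", "+/+", "-", "-", "asr", 0.1),
        ("a2", "+/+", "-", "-", "asr", 0.2),
        ("a3", "+/+", "+", "-", "asr", 0.1),
        ("a4", "+/+", "+", "-", "asr", 0.3),
        ("a5", "+/ls", "-", "-", "asr", 0.4),
        ("a6", "+/ls", "-", "-", "asr", 0.5),
        ("a7", "+/ls", "+", "-", "asr", 0.4),
    ]
    with pytest.raises(ContractError, match="cell"):
        two_factor_anova(_table(rows), "asr")


def test_two_factor_anova_single_level_degrades(rng):
    rows = []
    for i in range(12):
        rows.append((f"a{i}", "+/+", "-+"[i % 2], "-", "asr", rng.normal(0.3, 0.1)))
    res = two_factor_anova(_table(rows), "asr")
    assert len(res) == 1
    assert "degenerate" in res[0].note


def _typ1_oracle(tab, endpoint):
    """Type-I ANOVA on a balanced design (independent route)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = tab[tab.endpoint == endpoint].rename(columns={"value": "_y"})
    model = smf.ols("_y ~ C(cre) * C(genotype)", data=data).fit()
    return sm.stats.anova_lm(model, typ=1)


def test_type_iii_equals_type_i_when_balanced(rng):
    means = {("+/+", "-"): 1.0, ("+/+", "+"): 1.2, ("+/ls", "-"): 2.0, ("+/ls", "+"): 1.4}
    tab = _four_group_table(rng, means, sd=0.3, n=5)
    res = {r.comparison: r for r in two_factor_anova(tab, "asr")}
    oracle = _typ1_oracle(tab, "asr")
    assert res["asr: cre"].statistic == pytest.approx(oracle.loc["C(cre)", "F"])
    assert res["asr: genotype"].statistic == pytest.approx(
        oracle.loc["C(genotype)", "F"]
    )
    assert res["asr: interaction"].statistic == pytest.approx(
        oracle.loc["C(cre):C(genotype)", "F"]
    )


# --- mixed RM ANOVA ---------------------------------------------------------


def _mixed_table(rng, n_wt=6, n_het=7, geno_shift=0.0, tmx_shift=0.0,
                 inter_shift=0.0, sd=1.0):
    rows = []
    for i in range(n_wt + n_het):
        g = "+/+" if i < n_wt else "+/ls"
        base = rng.normal(5.0 + (geno_shift if g == "+/ls" else 0.0), sd)
        for t in "-+":
            v = base + rng.normal(0, sd)
            if t == "+":
                v += tmx_shift + (inter_shift if g == "+/ls" else 0.0)
            rows.append((f"a{i}", g, "+", t, "wake_rate", v))
    return _table(rows)


def test_mixed_anova_df_structure(rng):
    tab = _mixed_table(rng)
    res = {r.comparison: r for r in mixed_rm_anova(tab, "wake_rate")}
    assert res["wake_rate: genotype"].df == (1, 11)
    assert res["wake_rate: tmx"].df == (1, 11)
    assert res["wake_rate: interaction"].df == (1, 11)


def test_mixed_anova_within_identical_is_zero(rng):
    rows = []
    for i in range(8):
        g = "+/+" if i < 4 else "+/ls"
        base = rng.normal(5, 1)
        for t in "-+":
            rows.append((f"a{i}", g, "+", t, "wake_rate", base))
    res = {r.comparison: r for r in mixed_rm_anova(_table(rows), "wake_rate")}
    assert res["wake_rate: tmx"].statistic == 0.0


def test_mixed_anova_missing_level_excluded(rng):
    tab = _mixed_table(rng)
    tab = tab.drop(tab[(tab.animal_id == "a0") & (tab.tmx == "+")].index)
    with pytest.warns(UserWarning, match="missing a within level"):
        res = {r.comparison: r for r in mixed_rm_anova(tab, "wake_rate")}
    assert res["wake_rate: genotype"].df == (1, 10)


def _split_plot_oracle(tab):
    """Independent split-plot computation for a 2-level within design.

    Between F comes from a one-way ANOVA on subject means; within and
    interaction come from a two-factor ANOVA on subject-mean-centered data
    with the residual error stratum.
    """
    from scipy import stats as sps

    wide = tab.pivot_table(index=["animal_id", "genotype"], columns="tmx",
                           values="value").reset_index()
    wide["mean"] = (wide["-"] + wide["+"]) / 2
    groups = [g["mean"].to_numpy() for _, g in wide.groupby("genotype")]
    f_between = sps.f_oneway(*groups).statistic

    # within-subject effects live entirely in the half-differences d_i
    wide["d"] = (wide["+"] - wide["-"]) / 2
    n_subj = wide.shape[0]
    d_bar = wide["d"].mean()
    g_means = wide.groupby("genotype")["d"].mean()
    counts = wide.groupby("genotype").size()
    n_groups = len(counts)
    ss_tmx = 2 * n_subj * d_bar**2
    ss_inter = 2 * float((counts * (g_means - d_bar) ** 2).sum())
    d_centered = wide["d"] - wide["genotype"].map(g_means)
    ss_resid = 2 * float((d_centered**2).sum())
    df_resid = n_subj - n_groups
    f_tmx = ss_tmx / (ss_resid / df_resid)
    f_inter = (ss_inter / (n_groups - 1)) / (ss_resid / df_resid)
    return f_between, f_tmx, f_inter


def test_mixed_anova_against_split_plot_oracle(rng):
    tab = _mixed_table(rng, n_wt=5, n_het=5, geno_shift=1.0, tmx_shift=0.5,
                       inter_shift=0.8)
    res = {r.comparison: r for r in mixed_rm_anova(tab, "wake_rate")}
    f_between, f_tmx, f_inter = _split_plot_oracle(
        tab.rename(columns={})
    )
    assert res["wake_rate: genotype"].statistic == pytest.approx(f_between)
    assert res["wake_rate: tmx"].statistic == pytest.approx(f_tmx)
    assert res["wake_rate: interaction"].statistic == pytest.approx(f_inter)


# --- MANOVA -----------------------------------------------------------------


def _seizure_table(rng, wt_mean=300.0, het_mean=150.0, sd=30.0, n=6,
                   correlated=True):
    rows = []
    i = 0
    for g, m in [("+/+", wt_mean), ("+/ls", het_mean)]:
        for c in "-+":
            for _ in range(n):
                i += 1
                base = rng.normal(m, sd)
                e1 = base
                e2 = base + rng.normal(120, 10 if correlated else sd)
                e3 = e2 + abs(rng.normal(140, 10 if correlated else sd))
                for e, v in zip(("1st clonus", "T/C", "THE"), (e1, e2, e3)):
                    rows.append((f"a{i}", g, c, "-", e, v))
    return _table(rows)


def test_manova_detects_genotype(rng):
    tab = _seizure_table(rng)
    res = {r.comparison: r for r in manova(tab, ("1st clonus", "T/C", "THE"))}
    assert res["genotype"].p < 1e-4
    assert res["cre"].p > 0.01
    assert 0 <= res["genotype"].statistic <= 1


def test_manova_identical_endpoints_match_univariate(rng):
    tab = _seizure_table(rng)
    one = tab[tab.endpoint == "1st clonus"]
    dup = pd.concat(
        [one, one.assign(endpoint="T/C"), one.assign(endpoint="THE")],
        ignore_index=True,
    )
    res = {r.comparison: r for r in manova(dup, ("1st clonus", "T/C", "THE"))}
    uni = {r.comparison: r for r in two_factor_anova(dup, "1st clonus")}
    for term in ("cre", "genotype", "interaction"):
        assert res[term].p == pytest.approx(uni[f"1st clonus: {term}"].p)
        assert "dropped" in res[term].note


def test_manova_missing_endpoint_contract(rng):
    tab = _seizure_table(rng)
    tab = tab.drop(tab[(tab.animal_id == "a1") & (tab.endpoint == "THE")].index)
    with pytest.raises(ContractError):
        manova(tab, ("1st clonus", "T/C", "THE"))


# --- group_compare / cohens_d -----------------------------------------------


def test_identical_groups_null():
    a = [1.0, 2.0, 3.0, 4.0]
    r = group_compare(a, list(a))
    assert r.statistic == pytest.approx(0.0)
    assert r.p == pytest.approx(1.0)


def test_unpaired_t_df():
    rng = np.random.default_rng(0)
    r = group_compare(rng.normal(size=11), rng.normal(size=10))
    assert r.df == (19,)


def test_paired_t_requires_equal_length():
    with pytest.raises(ContractError):
        group_compare([1, 2, 3], [1, 2], test="paired_t")


def test_wilcoxon_enumeration_oracle():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    r = group_compare(a, b, test="wilcoxon")
    # independent enumeration over all C(6,3)=20 assignments
    pooled = np.array(a + b)
    obs_u = sum(x < y for x in a for y in b)  # U counts b-wins; here a < b always
    obs_u1 = sum(x > y for x in a for y in b)
    assert r.statistic == obs_u1  # Mann-Whitney U of the first group = 0
    us = []
    for idx in itertools.combinations(range(6), 3):
        ga = pooled[list(idx)]
        gb = pooled[[i for i in range(6) if i not in idx]]
        us.append(sum(x > y for x in ga for y in gb))
    mean_u = np.mean(us)
    extreme = sum(abs(u - mean_u) >= abs(obs_u1 - mean_u) for u in us)
    assert r.p == pytest.approx(extreme / len(us))


def test_wilcoxon_exact_matches_enumeration_random(rng):
    a = rng.normal(size=6).round(3)
    b = (rng.normal(size=5) + 0.5).round(3)
    r = group_compare(a, b, test="wilcoxon")
    pooled = np.concatenate([a, b])
    n = len(a)
    obs = sum(x > y for x in a for y in b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        ga = pooled[list(idx)]
        gb = pooled[[i for i in range(len(pooled)) if i not in idx]]
        us.append(sum(x > y for x in ga for y in gb))
    mean_u = np.mean(us)
    p_enum = np.mean([abs(u - mean_u) >= abs(obs - mean_u) - 1e-12 for u in us])
    assert r.p == pytest.approx(p_enum, abs=1e-12)


def test_wilcoxon_ranksum_convention():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    r = group_compare(a, b, test="wilcoxon", w_convention="ranksum")
    assert r.statistic == 6.0  # ranks 1+2+3


def test_cohens_d_unit_case(rng):
    a = rng.normal(0, 1, size=100_000)
    b = rng.normal(1, 1, size=100_000)
    assert cohens_d(a, b) == pytest.approx(1.0, abs=0.02)


def test_cohens_d_identity():
    assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0


@settings(max_examples=30, deadline=None)
@given(
    shift=st.floats(-50, 50),
    scale=st.floats(0.01, 100),
    seed=st.integers(0, 1000),
)
def test_cohens_d_affine_invariance(shift, scale, seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=10)
    b = rng.normal(1, 2, size=12)
    d0 = cohens_d(a, b)
    d1 = cohens_d(scale * a + shift, scale * b + shift)
    assert d1 == pytest.approx(d0, rel=1e-9)


def test_exact_known_d():
    # means 0 vs 1, equal within-group SDs -> d = 1/sd
    a = np.array([-1.0, 0.0, 1.0])
    b = np.array([0.0, 1.0, 2.0])
    assert cohens_d(a, b) == pytest.approx(1.0)


# --- bonferroni -------------------------------------------------------------


def test_bonferroni_two_groups_unadjusted(rng):
    rows = [("a%d" % i, "+/+", "-", "-", "asr", v) for i, v in
            enumerate(rng.normal(0.3, 0.1, 6))]
    rows += [("b%d" % i, "+/ls", "-", "-", "asr", v) for i, v in
             enumerate(rng.normal(0.5, 0.1, 6))]
    tab = _table(rows)
    tab["group"] = tab["genotype"]
    res = bonferroni_pairwise(tab, "asr")
    raw = group_compare(
        tab[tab.group == "+/+"].value.to_numpy(),
        tab[tab.group == "+/ls"].value.to_numpy(),
    )
    assert len(res) == 1
    assert res[0].p == pytest.approx(raw.p)


def test_bonferroni_four_identical_groups(rng):
    rows = []
    for gi, grp in enumerate(["w-", "w+", "h-", "h+"]):
        for i in range(5):
            rows.append((f"{grp}{i}", "+/+", "-", "-", "asr", 0.4))
    tab = _table(rows)
    tab["group"] = [r[0][:2] for r in rows]
    res = bonferroni_pairwise(tab, "asr")
    assert len(res) == 6
    assert all(r.p == 1.0 for r in res)


def test_bonferroni_multiplier(rng):
    rows = []
    for gi, (grp, m) in enumerate(
        [("g1", 0.1), ("g2", 0.3), ("g3", 0.5), ("g4", 0.7)]
    ):
        for i in range(5):
            rows.append((f"{grp}{i}", "+/+", "-", "-", "asr", rng.normal(m, 0.1)))
    tab = _table(rows)
    tab["group"] = [r[0][:2] for r in rows]
    res = bonferroni_pairwise(tab, "asr")
    for r in res:
        ga, gb = r.comparison.split(" vs ")
        raw = group_compare(
            tab[tab.group == ga].value.to_numpy(),
            tab[tab.group == gb].value.to_numpy(),
        )
        assert r.p == pytest.approx(min(1.0, 6 * raw.p))
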