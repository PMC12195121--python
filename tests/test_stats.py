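"""Statistical battery: frozen hand-computed oracles, library cross-checks,
identities and degenerate-input handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from conftest import make_records_frame

from acl_impinge.errors import StatsError
from acl_impinge.stats import (
    anova_oneway,
    anova_twoway,
    format_report,
    stat_battery,
    ttest_diameter,
    ttest_flexion_paired,
)


def diameter_frame(vals7, vals9):
    n7, n9 = len(vals7), len(vals9)
    return make_records_frame(
        list(vals7) + list(vals9),
        fem="AM",
        tib="AM",
        knee=[f"k{i}" for i in range(n7)] + [f"k{i}" for i in range(n9)],
        diameter=[7.0] * n7 + [9.0] * n9,
    )


# ---------------------------------------------------------------------------
# t-tests


def test_identical_groups_give_t0_p1():
    res = ttest_diameter(diameter_frame([1, 2, 3], [1, 2, 3]))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_ttest_matches_manual_pooled_formula():
    a = np.array([3.1, 4.2, 2.8, 5.0, 3.6])
    b = np.array([4.9, 6.1, 5.4, 7.0])
    res = ttest_diameter(diameter_frame(a, b))
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_manual = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    assert res.statistic == pytest.approx(t_manual, rel=1e-12)
    assert res.df == na + nb - 2
    assert res.p_value == pytest.approx(
        2 * sps.t.sf(abs(t_manual), na + nb - 2), rel=1e-12
    )


def test_ttest_requires_two_diameters():
    df = make_records_frame([1.0, 2.0], fem="AM", tib="AM", diameter=9.0)
    with pytest.raises(StatsError):
        ttest_diameter(df)


def paired_frame(v0, v45):
    import pandas as pd

    a = make_records_frame(v0, fem="AM", tib="AM", angle=0.0)
    b = make_records_frame(v45, fem="AM", tib="AM", angle=45.0)
    return pd.concat([a, b], ignore_index=True)


def test_paired_identical_vectors():
    res = ttest_flexion_paired(paired_frame([1, 2, 3], [1, 2, 3]), 0.0, 45.0)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_paired_constant_nonzero_difference_is_degenerate():
    res = ttest_flexion_paired(paired_frame([5, 6, 7], [3, 4, 5]), 0.0, 45.0)
    assert np.isinf(res.statistic) and res.p_value == 0.0
    assert "degenerate" in res.note


def test_paired_matches_scipy():
    v0 = [10.0, 12.5, 9.1, 14.0, 11.2]
    v45 = [8.0, 11.0, 9.5, 10.0, 10.1]
    res = ttest_flexion_paired(paired_frame(v0, v45), 0.0, 45.0)
    ref = sps.ttest_rel(v0, v45)
    assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)


def test_paired_unmatched_keys_listed():
    df = paired_frame([1, 2, 3], [1, 2, 3]).iloc[:-1]
    with pytest.raises(StatsError, match="unmatched"):
        ttest_flexion_paired(df, 0.0, 45.0)


# ---------------------------------------------------------------------------
# one-way ANOVA


def oneway_frame(groups):
    vals = [v for g in groups for v in g]
    fem = [lab for lab, g in zip(("AM", "central", "PL"), groups) for _ in g]
    return make_records_frame(vals, fem=fem, tib="AM")


def test_oneway_identical_groups():
    res = anova_oneway(oneway_frame([[1, 2, 3]] * 3), "femoral")
    assert res.statistic == 0.0
    assert res.effect_size == 0.0


def test_oneway_hand_computed_toy():
    # groups {1,2,3},{2,3,4},{4,5,6}: SSB=14, SSW=6 -> F=7, eta^2=0.7
    res = anova_oneway(oneway_frame([[1, 2, 3], [2, 3, 4], [4, 5, 6]]), "femoral")
    assert res.statistic == pytest.approx(7.0, abs=1e-12)
    assert res.effect_size == pytest.approx(0.7, abs=1e-12)
    assert res.df == (2.0, 6.0)
    ref = sps.f_oneway([1, 2, 3], [2, 3, 4], [4, 5, 6])
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)


def test_oneway_effect_size_saturates():
    res = anova_oneway(
        oneway_frame([[0.0, 0.01], [100.0, 100.01], [200.0, 200.01]]), "femoral"
    )
    assert res.effect_size > 0.999


def test_oneway_eta_equals_model_r_squared():
    import statsmodels.formula.api as smf

    df = oneway_frame([[1.0, 3.0, 2.2], [4.1, 5.0, 3.9], [2.0, 2.5, 1.0]])
    res = anova_oneway(df, "femoral")
    model = smf.ols("volume ~ C(femoral_position)", data=df).fit()
    assert res.effect_size == pytest.approx(model.rsquared, rel=1e-12)


def test_oneway_preconditions():
    with pytest.raises(StatsError):
        anova_oneway(oneway_frame([[1, 2, 3]]), "femoral")
    with pytest.raises(StatsError):
        anova_oneway(oneway_frame([[1, 2], [3]]), "femoral")
    with pytest.raises(StatsError):
        anova_oneway(oneway_frame([[1, 2]] * 3), "bogus_factor")


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.lists(st.floats(-50, 50), min_size=3, max_size=12),
       st.lists(st.floats(-50, 50), min_size=3, max_size=12))
def test_two_level_anova_equals_squared_t(g1, g2):
    """F = t^2 for a 2-level one-way ANOVA on the same data."""
    if np.var(g1 + g2) == 0:
        return
    df = make_records_frame(
        g1 + g2, fem=["AM"] * len(g1) + ["PL"] * len(g2), tib="AM"
    )
    f_res = anova_oneway(df, "femoral")
    t = sps.ttest_ind(g1, g2, equal_var=True).statistic
    assert f_res.statistic == pytest.approx(t**2, rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# two-way ANOVA


def twoway_frame(cells, n_rep=None):
    """cells: {(fem, tib): [values]}"""
    vals, fem, tib = [], [], []
    for (fa, tb), v in cells.items():
        vals += list(v)
        fem += [fa] * len(v)
        tib += [tb] * len(v)
    return make_records_frame(vals, fem=fem, tib=tib)


TOY_2X2 = {
    ("AM", "AM"): [1, 2],
    ("AM", "PL"): [3, 4],
    ("PL", "AM"): [5, 6],
    ("PL", "PL"): [9, 10],
}


def test_twoway_hand_computed_toy():
    # SS_A=50, SS_B=18, SS_AB=2, SS_E=2 (df 1,1,1,4)
    res = anova_twoway(twoway_frame(TOY_2X2))
    assert res["femoral_position"].statistic == pytest.approx(100.0, abs=1e-9)
    assert res["tibial_position"].statistic == pytest.approx(36.0, abs=1e-9)
    assert res["interaction"].statistic == pytest.approx(4.0, abs=1e-9)
    assert res["femoral_position"].effect_size == pytest.approx(50 / 52, abs=1e-12)
    assert res["tibial_position"].effect_size == pytest.approx(18 / 20, abs=1e-12)
    assert res["interaction"].effect_size == pytest.approx(2 / 4, abs=1e-12)


def test_twoway_matches_statsmodels():
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rng = np.random.default_rng(8)
    cells = {
        (fa, tb): rng.normal(size=4)
        for fa in ("AM", "central", "PL")
        for tb in ("AM", "central", "PL")
    }
    df = twoway_frame(cells)
    res = anova_twoway(df)
    model = smf.ols(
        "volume ~ C(femoral_position) * C(tibial_position)", data=df
    ).fit()
    table = anova_lm(model, typ=2)
    assert res["femoral_position"].statistic == pytest.approx(
        table.loc["C(femoral_position)", "F"], rel=1e-9
    )
    assert res["tibial_position"].statistic == pytest.approx(
        table.loc["C(tibial_position)", "F"], rel=1e-9
    )
    assert res["interaction"].statistic == pytest.approx(
        table.loc["C(femoral_position):C(tibial_position)", "F"], rel=1e-9
    )


def test_twoway_identical_cells_all_zero_f():
    cells = {
        (fa, tb): [5.0, 5.0]
        for fa in ("AM", "PL")
        for tb in ("AM", "PL")
    }
    res = anova_twoway(twoway_frame(cells))
    assert all(r.statistic == 0.0 and r.p_value == 1.0 for r in res.values())


def test_twoway_empty_cell_raises():
    cells = dict(TOY_2X2)
    del cells[("PL", "PL")]
    with pytest.raises(StatsError, match="empty cells"):
        anova_twoway(twoway_frame(cells))


def test_twoway_unbalanced_warns_and_matches_typeii():
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    cells = dict(TOY_2X2)
    cells[("AM", "AM")] = [1, 2, 2.5]
    df = twoway_frame(cells)
    with pytest.warns(UserWarning, match="type-II"):
        res = anova_twoway(df)
    model = smf.ols(
        "volume ~ C(femoral_position) * C(tibial_position)", data=df
    ).fit()
    table = anova_lm(model, typ=2)
    assert res["femoral_position"].statistic == pytest.approx(
        table.loc["C(femoral_position)", "F"], rel=1e-9
    )


# ---------------------------------------------------------------------------
# battery


def test_stat_battery_reports_all_strata(one_knee_run):
    records, _ = one_knee_run
    import dataclasses

    import pandas as pd

    from acl_impinge.experiment import records_to_dataframe

    # two jittered copies of the knee so every test has replication
    rng = np.random.default_rng(0)
    frames = []
    for i in range(3):
        twin = [
            dataclasses.replace(
                r,
                knee_id=f"knee_{i:03d}",
                volume=max(0.0, r.volume * float(rng.uniform(0.9, 1.1))),
            )
            for r in records
        ]
        frames.append(records_to_dataframe(twin))
    df = pd.concat(frames, ignore_index=True)
    report = stat_battery(df)
    assert "diameter" in report
    assert "flexion 0 vs 45" in report
    assert "one-way tibial (9 mm @ 0°)" in report
    assert "two-way interaction (9 mm @ 0°)" in report
    text = format_report(report)
    assert "partial_eta_sq" in text
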