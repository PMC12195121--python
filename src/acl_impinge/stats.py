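"""Statistical battery over impingement records.

Mirrors the study's analysis plan: an independent t-test for graft
diameter, paired t-tests across flexion angles, one-way ANOVA over
footprint position (three levels: AM, central, PL) and two-way ANOVA for
the femoral x tibial interaction, with partial eta squared
(SS_effect / (SS_effect + SS_error)) as the effect size.

Defaults are two-sided pooled-variance tests with no multiplicity
correction; Welch and per-configuration alternatives are switchable.  The
unit of analysis is the knee-level record within the chosen stratum
(typically full extension at a fixed diameter); pooling across strata is
the caller's decision.

ANOVA sums of squares are computed in closed form for balanced layouts
(where type I/II/III coincide); unbalanced input falls back to a type-II
OLS decomposition with an explicit warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

ALPHA = 0.05  # study-wide significance level


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    df: float | tuple
    p_value: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    group_n: dict = field(default_factory=dict)
    note: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)

    def __str__(self) -> str:
        df = (
            f"{self.df:g}"
            if np.isscalar(self.df)
            else ", ".join(f"{d:g}" for d in self.df)
        )
        s = f"{self.test_name}: stat={self.statistic:.4g} (df={df}), p={self.p_value:.4g}"
        if self.effect_size is not None:
            s += f", {self.effect_size_name}={self.effect_size:.3f}"
        if self.note:
            s += f" [{self.note}]"
        return s


def _as_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .experiment import records_to_dataframe

    return records_to_dataframe(records)


# ---------------------------------------------------------------------------
# t-tests


def ttest_diameter(records, welch: bool = False, per_knee: bool = True) -> TestResult:
    """Independent two-sample t-test of overlap volume between the two graft
    diameters (two-sided; pooled variance unless ``welch``).

    With ``per_knee`` (default) volumes are first averaged within each knee
    so the knee is the unit of analysis.
    """
    df = _as_dataframe(records)
    diameters = sorted(df["diameter"].unique())
    if len(diameters) != 2:
        raise StatsError(
            f"diameter t-test needs exactly 2 diameters, found {diameters}"
        )
    groups = []
    for d in diameters:
        sub = df[df["diameter"] == d]
        vals = (
            sub.groupby("knee_id")["volume"].mean().to_numpy()
            if per_knee
            else sub["volume"].to_numpy()
        )
        if len(vals) < 2:
            raise StatsError(f"diameter group {d} has n < 2")
        groups.append(vals)
    res = sps.ttest_ind(groups[1], groups[0], equal_var=not welch)
    n0, n1 = len(groups[0]), len(groups[1])
    return TestResult(
        test_name="independent t-test (diameter)"
        + (" [Welch]" if welch else ""),
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        effect_size=_cohens_d(groups[1], groups[0]),
        effect_size_name="cohens_d",
        group_n={f"{diameters[0]:g} mm": n0, f"{diameters[1]:g} mm": n1},
    )


def _cohens_d(a, b) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
        / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / pooled)


def ttest_flexion_paired(records, angle_a: float, angle_b: float) -> TestResult:
    """Paired two-sided t-test of volumes between two flexion angles.

    Records are matched on (knee, femoral position, tibial position,
    diameter); any key present at only one angle raises with the missing
    keys listed.  A zero-variance nonzero mean difference is degenerate
    (infinite t); it is reported as p = 0 with a note.
    """
    df = _as_dataframe(records)
    key = ["knee_id", "femoral_position", "tibial_position", "diameter"]
    a = df[df["flexion_angle"] == angle_a].set_index(key)["volume"]
    b = df[df["flexion_angle"] == angle_b].set_index(key)["volume"]
    if a.empty or b.empty:
        raise StatsError(
            f"no records at flexion angle {angle_a if a.empty else angle_b}"
        )
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        missing = list(only_a[:5]) + list(only_b[:5])
        raise StatsError(
            f"unmatched pairs between {angle_a} and {angle_b} deg: {missing}"
        )
    a, b = a.sort_index(), b.sort_index()
    diffs = a.to_numpy() - b.to_numpy()
    n = len(diffs)
    if n < 2:
        raise StatsError("paired t-test needs at least 2 matched pairs")
    name = f"paired t-test ({angle_a:g}° vs {angle_b:g}°)"
    if np.std(diffs, ddof=1) == 0:
        if np.mean(diffs) == 0:
            return TestResult(name, 0.0, float(n - 1), 1.0,
                              group_n={"pairs": n}, note="identical pairs")
        return TestResult(
            name, float(np.inf) * np.sign(np.mean(diffs)), float(n - 1), 0.0,
            group_n={"pairs": n},
            note="degenerate: zero variance of differences, nonzero mean",
        )
    res = sps.ttest_rel(a.to_numpy(), b.to_numpy())
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        group_n={"pairs": n},
    )


# ---------------------------------------------------------------------------
# ANOVA


_FACTOR_ALIASES = {
    "femoral": "femoral_position",
    "tibial": "tibial_position",
    "femoral_position": "femoral_position",
    "tibial_position": "tibial_position",
}


def anova_oneway(records, factor: str) -> TestResult:
    """One-way between-groups ANOVA of volume over a footprint factor.

    Partial eta squared equals SS_between / (SS_between + SS_within),
    i.e. the R^2 of the one-factor model.
    """
    df = _as_dataframe(records)
    col = _FACTOR_ALIASES.get(factor)
    if col is None:
        raise StatsError(f"unknown factor {factor!r}")
    groups = [g.to_numpy() for _, g in df.groupby(col, observed=True)["volume"]]
    labels = [str(k) for k, _ in df.groupby(col, observed=True)]
    if len(groups) < 2:
        raise StatsError(f"one-way ANOVA needs >= 2 levels of {col}")
    if any(len(g) < 2 for g in groups):
        raise StatsError(f"every level of {col} needs n >= 2")
    y = np.concatenate(groups)
    grand = y.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(y) - len(groups)
    if ss_within == 0 and ss_between == 0:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))
    eta = ss_between / (ss_between + ss_within) if (ss_between + ss_within) else 0.0
    return TestResult(
        test_name=f"one-way ANOVA ({col})",
        statistic=float(f_stat),
        df=(float(df_b), float(df_w)),
        p_value=p,
        effect_size=float(eta),
        effect_size_name="partial_eta_sq",
        group_n={lab: len(g) for lab, g in zip(labels, groups)},
    )


def anova_twoway(records, factor_a: str = "femoral", factor_b: str = "tibial") -> dict:
    """Two-way ANOVA with interaction over the footprint factors.

    Returns {'femoral_position': TestResult, 'tibial_position': TestResult,
    'interaction': TestResult}.  Balanced layouts use the closed-form
    decomposition (type I/II/III coincide); unbalanced input warns and uses
    a type-II OLS decomposition.  An empty cell raises.
    """
    df = _as_dataframe(records)
    ca = _FACTOR_ALIASES.get(factor_a)
    cb = _FACTOR_ALIASES.get(factor_b)
    if ca is None or cb is None:
        raise StatsError(f"unknown factor in ({factor_a!r}, {factor_b!r})")
    levels_a = sorted(df[ca].unique())
    levels_b = sorted(df[cb].unique())
    counts = df.groupby([ca, cb], observed=True)["volume"].count()
    if len(counts) < len(levels_a) * len(levels_b):
        present = set(counts.index)
        empty = [
            c for c in itertools.product(levels_a, levels_b) if c not in present
        ]
        raise StatsError(f"two-way ANOVA requires a full crossing; empty cells: {empty}")
    if counts.min() < 2:
        raise StatsError("two-way ANOVA with interaction needs n >= 2 per cell")
    balanced = counts.nunique() == 1
    if not balanced:
        warnings.warn(
            "unbalanced two-way layout: using type-II sums of squares",
            stacklevel=2,
        )
        ss = _typeii_ss(df, ca, cb)
    else:
        ss = _balanced_ss(df, ca, cb)
    n = len(df)
    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b
    df_e = n - len(levels_a) * len(levels_b)
    out = {}
    for name, ss_eff, dfe in (
        (ca, ss["a"], df_a),
        (cb, ss["b"], df_b),
        ("interaction", ss["ab"], df_ab),
    ):
        if ss["e"] == 0:
            f_stat = 0.0 if ss_eff == 0 else np.inf
            p = 1.0 if ss_eff == 0 else 0.0
        else:
            f_stat = (ss_eff / dfe) / (ss["e"] / df_e)
            p = float(sps.f.sf(f_stat, dfe, df_e))
        eta = ss_eff / (ss_eff + ss["e"]) if (ss_eff + ss["e"]) else 0.0
        out[name] = TestResult(
            test_name=f"two-way ANOVA: {name}"
            + ("" if balanced else " [type II]"),
            statistic=float(f_stat),
            df=(float(dfe), float(df_e)),
            p_value=p,
            effect_size=float(eta),
            effect_size_name="partial_eta_sq",
            group_n={"cells": len(counts), "per_cell_min": int(counts.min())},
        )
    return out


def _balanced_ss(df, ca, cb) -> dict:
    y = df["volume"].to_numpy()
    grand = y.mean()
    cell = df.groupby([ca, cb], observed=True)["volume"].mean()
    mean_a = df.groupby(ca, observed=True)["volume"].mean()
    mean_b = df.groupby(cb, observed=True)["volume"].mean()
    n_per_cell = len(df) / len(cell)
    n_a = len(df) / len(mean_a)
    n_b = len(df) / len(mean_b)
    ss_a = float(n_a * ((mean_a - grand) ** 2).sum())
    ss_b = float(n_b * ((mean_b - grand) ** 2).sum())
    inter = cell.copy()
    for (la, lb) in inter.index:
        inter.loc[(la, lb)] = (
            cell.loc[(la, lb)] - mean_a.loc[la] - mean_b.loc[lb] + grand
        )
    ss_ab = float(n_per_cell * (inter**2).sum())
    resid = df["volume"] - df.set_index([ca, cb]).index.map(cell).to_numpy()
    ss_e = float((resid**2).sum())
    return {"a": ss_a, "b": ss_b, "ab": ss_ab, "e": ss_e}


def _typeii_ss(df, ca, cb) -> dict:
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = df.rename(columns={ca: "A", cb: "B"})
    model = smf.ols("volume ~ C(A) * C(B)", data=data).fit()
    table = anova_lm(model, typ=2)
    return {
        "a": float(table.loc["C(A)", "sum_sq"]),
        "b": float(table.loc["C(B)", "sum_sq"]),
        "ab": float(table.loc["C(A):C(B)", "sum_sq"]),
        "e": float(table.loc["Residual", "sum_sq"]),
    }


# ---------------------------------------------------------------------------
# full report


def stat_battery(records, extension_angle: float = 0.0) -> dict:
    """The full analysis battery, stratified the way the headline table is:
    footprint ANOVAs within (extension angle, diameter) strata, the
    diameter t-test over all cells, and paired t-tests for every flexion
    pair."""
    df = _as_dataframe(records)
    report: dict = {"diameter": ttest_diameter(df)}
    angles = sorted(df["flexion_angle"].unique())
    for a, b in itertools.combinations(angles, 2):
        report[f"flexion {a:g} vs {b:g}"] = ttest_flexion_paired(df, a, b)
    for d in sorted(df["diameter"].unique()):
        stratum = df[(df["flexion_angle"] == extension_angle) & (df["diameter"] == d)]
        if stratum.empty:
            continue
        label = f"{d:g} mm @ {extension_angle:g}°"
        report[f"one-way femoral ({label})"] = anova_oneway(stratum, "femoral")
        report[f"one-way tibial ({label})"] = anova_oneway(stratum, "tibial")
        two = anova_twoway(stratum)
        report[f"two-way femoral ({label})"] = two["femoral_position"]
        report[f"two-way tibial ({label})"] = two["tibial_position"]
        report[f"two-way interaction ({label})"] = two["interaction"]
    return report


def format_report(report: dict) -> str:
    return "\n".join(f"{name}\n  {result}" for name, result in report.items())


__all__ = [
    "ALPHA",
    "TestResult",
    "ttest_diameter",
    "ttest_flexion_paired",
    "anova_oneway",
    "anova_twoway",
    "stat_battery",
    "format_report",
]
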