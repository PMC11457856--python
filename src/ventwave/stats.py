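"""Cohort comparison statistics: Welch t tests, one-way ANOVA with Tukey HSD,
and balanced two-way repeated-measures (split-plot) ANOVA.

The repeated-measures model decomposes variance into group (between-
subject), time (within-subject), group x time, with subjects-within-group as
the error stratum for the group effect — the closed-form balanced analogue of
the mixed-effects analysis used for group x time designs. Unbalanced tables
are rejected with guidance rather than approximated. Alpha is fixed at 0.05
by convention throughout the reporting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "welch_t", "oneway_anova_tukey",
           "rm_group_time", "summarize_cohort"]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    df: tuple
    p: float
    effect: float | None = None  # point estimate (e.g. mean difference)
    ci: tuple[float, float] | None = None  # 95% CI for the effect
    pairwise: pd.DataFrame | None = None  # Tukey-adjusted comparisons
    terms: pd.DataFrame | None = None  # per-term ANOVA table (RM designs)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.ci is not None and self.effect is not None:
            if not (self.ci[0] - 1e-12 <= self.effect <= self.ci[1] + 1e-12):
                raise ValueError("CI must contain the point estimate")


def welch_t(a, b) -> ComparisonResult:
    """Two-sided Welch t test with Satterthwaite df and a 95% CI for the
    mean difference. Two identical zero-variance samples return statistic 0,
    p = 1 (the degenerate case scipy leaves as NaN)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(a.size + b.size - 2)
        if diff == 0:
            return ComparisonResult("welch_t", 0.0, (df,), 1.0, effect=0.0,
                                    ci=(0.0, 0.0))
        return ComparisonResult("welch_t", np.inf * np.sign(diff), (df,), 0.0,
                                effect=diff, ci=(diff, diff))
    import warnings
    with warnings.catch_warnings():
        # near-identical samples trip scipy's precision-loss warning; the
        # exact zero-variance case is already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(confidence_level=0.95)
    return ComparisonResult("welch_t", float(res.statistic), (float(res.df),),
                            float(res.pvalue), effect=diff,
                            ci=(float(ci.low), float(ci.high)))


def oneway_anova_tukey(groups, pairwise: bool = True) -> ComparisonResult:
    """One-way ANOVA F test with all pairwise Tukey HSD comparisons.

    ``groups`` is a mapping name -> values or a sequence of arrays. The
    Tukey adjustment uses the studentized-range distribution (scipy);
    ``pairwise=False`` skips it (the studentized-range integral is costly)
    when only the omnibus F is needed, e.g. in calibration loops.
    """
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    # F from sums of squares directly so that equal group means give F = 0
    grand = np.concatenate(arrays)
    ss_between = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b = len(arrays) - 1
    df_w = grand.size - len(arrays)
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    pw_table = None
    if pairwise and ss_within == 0:
        # degenerate within-group stratum: differences are exact
        rows = [{"group_a": names[i], "group_b": names[j],
                 "diff": float(arrays[i].mean() - arrays[j].mean()),
                 "p_adj": 1.0 if arrays[i].mean() == arrays[j].mean() else 0.0,
                 "ci_low": float(arrays[i].mean() - arrays[j].mean()),
                 "ci_high": float(arrays[i].mean() - arrays[j].mean())}
                for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
        pw_table = pd.DataFrame(rows)
    elif pairwise:
        tk = sps.tukey_hsd(*arrays)
        ci = tk.confidence_interval(0.95)
        rows = []
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                rows.append({
                    "group_a": names[i], "group_b": names[j],
                    "diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(tk.pvalue[i, j]),
                    "ci_low": float(ci.low[i, j]), "ci_high": float(ci.high[i, j]),
                })
        pw_table = pd.DataFrame(rows)
    means = [g.mean() for g in arrays]
    i_max, i_min = int(np.argmax(means)), int(np.argmin(means))
    return ComparisonResult("oneway_anova_tukey", float(f),
                            (float(df_b), float(df_w)), float(p),
                            effect=float(means[i_max] - means[i_min]),
                            pairwise=pw_table)


def _f_and_p(ss_num: float, df_num: int, ss_den: float, df_den: int):
    """F ratio with explicit zero handling: a zero-SS term is F = 0, p = 1
    even over a zero error stratum."""
    if ss_num <= 1e-300:
        return 0.0, 1.0
    if ss_den <= 1e-300:
        return np.inf, 0.0
    f = (ss_num / df_num) / (ss_den / df_den)
    return float(f), float(sps.f.sf(f, df_num, df_den))


def rm_group_time(table: pd.DataFrame, metric: str,
                  subject_col: str = "subject_id", group_col: str = "group",
                  time_col: str = "time_s", value_col: str = "value",
                  pairwise: bool = True) -> ComparisonResult:
    """Balanced two-way repeated-measures (split-plot) ANOVA.

    Decomposes group (tested against subjects-within-group), time, and
    group x time (both tested against the within-subject residual). Requires
    a complete balanced table: every subject observed at every timepoint and
    equal group sizes; anything else raises with guidance. Pairwise group
    comparisons use the Tukey studentized-range adjustment on subject means
    with the subjects-within-group error stratum.
    """
    df = table
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    wide = df.pivot_table(index=[group_col, subject_col], columns=time_col,
                          values=value_col, aggfunc="first")
    if wide.isna().any().any():
        raise ValueError(
            "unbalanced table: every subject needs a value at every "
            "timepoint (complete balanced design required; fill or drop "
            "incomplete subjects before calling rm_group_time)")
    sizes = wide.groupby(level=0).size()
    if sizes.nunique() != 1:
        raise ValueError(
            "unbalanced table: groups must have equal subject counts "
            f"(got {dict(sizes)})")
    groups = list(sizes.index)
    a, n, b = len(groups), int(sizes.iloc[0]), wide.shape[1]
    if a < 2 or n < 2 or b < 1:
        raise ValueError("need >= 2 groups and >= 2 subjects per group")

    y = wide.to_numpy().reshape(a, n, b)
    grand = y.mean()
    m_g = y.mean(axis=(1, 2))
    m_gs = y.mean(axis=2)
    m_t = y.mean(axis=(0, 1))
    m_gt = y.mean(axis=1)

    ss_group = n * b * np.sum((m_g - grand) ** 2)
    ss_subj = b * np.sum((m_gs - m_g[:, None]) ** 2)
    ss_time = a * n * np.sum((m_t - grand) ** 2)
    ss_gt = n * np.sum((m_gt - m_g[:, None] - m_t[None, :] + grand) ** 2)
    resid = y - m_gs[:, :, None] - m_gt[:, None, :] + m_g[:, None, None]
    ss_err = np.sum(resid ** 2)

    df_g, df_s = a - 1, a * (n - 1)
    df_t, df_i = b - 1, (a - 1) * (b - 1)
    df_e = a * (n - 1) * (b - 1)

    f_g, p_g = _f_and_p(ss_group, df_g, ss_subj, df_s)
    f_t, p_t = _f_and_p(ss_time, df_t, ss_err, df_e)
    f_i, p_i = _f_and_p(ss_gt, df_i, ss_err, df_e)
    terms = pd.DataFrame([
        {"term": "group", "SS": ss_group, "df": df_g, "F": f_g, "p": p_g,
         "error_SS": ss_subj, "error_df": df_s},
        {"term": "time", "SS": ss_time, "df": df_t, "F": f_t, "p": p_t,
         "error_SS": ss_err, "error_df": df_e},
        {"term": "group_x_time", "SS": ss_gt, "df": df_i, "F": f_i, "p": p_i,
         "error_SS": ss_err, "error_df": df_e},
    ])

    pw_table = None
    if pairwise:
        ms_subj = ss_subj / df_s if df_s else np.nan
        rows = []
        for i in range(a):
            for j in range(i + 1, a):
                d = float(m_g[i] - m_g[j])
                if ms_subj > 0:
                    q = abs(d) / np.sqrt(ms_subj / (n * b))
                    p_adj = float(sps.studentized_range.sf(q, a, df_s))
                else:
                    p_adj = 1.0 if d == 0 else 0.0
                rows.append({"group_a": groups[i], "group_b": groups[j],
                             "diff": d, "p_adj": p_adj})
        pw_table = pd.DataFrame(rows)
    return ComparisonResult("rm_group_time", f_i, (float(df_i), float(df_e)),
                            p_i, pairwise=pw_table, terms=terms)


def summarize_cohort(table: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Figure-style cohort summary: per-group mean +/- SD per metric and the
    convention-matched test battery (Welch t for 2 groups, one-way ANOVA with
    Tukey HSD for 3 or more). Values are averaged per subject first when
    multiple timepoints are present.

    ``table`` columns: subject_id, group, metric, value (time_s optional).
    Returns ``{"summary": DataFrame, "comparisons": {metric: ComparisonResult}}``.
    """
    required = {"subject_id", "group", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    per_subject = (table.groupby(["metric", "group", "subject_id"],
                                 sort=True)["value"].mean().reset_index())
    summary = (per_subject.groupby(["metric", "group"], sort=True)["value"]
               .agg(mean="mean", sd="std", n="count").reset_index())
    comparisons: dict[str, ComparisonResult] = {}
    for metric, sub in per_subject.groupby("metric", sort=True):
        groups = {g: gsub["value"].to_numpy()
                  for g, gsub in sub.groupby("group", sort=True)}
        if len(groups) < 2 or min(len(v) for v in groups.values()) < 2:
            continue
        if len(groups) == 2:
            va, vb = list(groups.values())
            comparisons[metric] = welch_t(va, vb)
        else:
            comparisons[metric] = oneway_anova_tukey(groups)
    return {"summary": summary, "comparisons": comparisons, "alpha": alpha}
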