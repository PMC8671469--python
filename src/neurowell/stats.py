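"""One-way ANOVA with normality check, Tukey HSD, and dose–response summaries.

The comparison layer mirrors the conventional analysis of plate-based
assays: a fixed-effects one-way ANOVA across condition groups, a
Shapiro–Wilk test on the pooled residuals as the normality check, and
Tukey's studentized-range procedure (Tukey–Kramer for unbalanced
groups) for all pairwise post-hoc comparisons.  Significance stars
follow the usual convention: * p<0.05, ** p<0.01, *** p<0.001,
**** p<0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ComparisonResult",
    "one_way_anova",
    "tukey_hsd",
    "compare_groups",
    "dose_response_summary",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Map an (adjusted) p-value to the star convention."""
    if np.isnan(p):
        return ""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < threshold:
            return stars
    return "ns"


@dataclass
class ComparisonResult:
    """ANOVA + residual-normality + pairwise Tukey results.

    When every group is internally constant but group means differ,
    the within-group variance is zero and ``f_statistic`` is reported
    as ``inf`` with ``p_value = 0.0`` (the limit of the F test as the
    error variance vanishes).  ``pairwise`` has C(k, 2) rows with
    columns ``group_a, group_b, mean_diff, p_adj, stars``.
    """

    f_statistic: float
    p_value: float
    shapiro_w: float
    shapiro_p: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    group_means: dict[str, float] = field(default_factory=dict)


def _validate_groups(df: pd.DataFrame, value_col: str, group_col: str) -> dict[str, np.ndarray]:
    if value_col not in df.columns or group_col not in df.columns:
        raise ValueError(f"table needs columns {value_col!r} and {group_col!r}")
    clean = df.dropna(subset=[value_col])
    groups = {str(g): sub[value_col].to_numpy(dtype=float)
              for g, sub in clean.groupby(group_col, sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least two groups for a comparison")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than two observations")
    return groups


def one_way_anova(df: pd.DataFrame, value_col: str = "value",
                  group_col: str = "condition") -> ComparisonResult:
    """Classical fixed-effects one-way ANOVA with a residual normality check.

    Residuals (observation minus group mean) are tested with
    Shapiro–Wilk; a constant residual vector (degenerate) yields NaN
    normality statistics.
    """
    groups = _validate_groups(df, value_col, group_col)
    arrays = list(groups.values())
    residuals = np.concatenate([a - a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = float((residuals**2).sum())
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))
    if np.ptp(residuals) == 0.0:
        w, sp = float("nan"), float("nan")
    else:
        w, sp = sps.shapiro(residuals)
    return ComparisonResult(
        f_statistic=float(f_stat), p_value=float(p),
        shapiro_w=float(w), shapiro_p=float(sp),
        group_means={name: float(a.mean()) for name, a in groups.items()},
    )


def tukey_hsd(df: pd.DataFrame, value_col: str = "value",
              group_col: str = "condition", alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Tukey HSD comparisons (Tukey–Kramer when unbalanced).

    Returns one row per unordered pair with the mean difference
    (B − A), the studentized-range adjusted p-value and its stars.
    """
    groups = _validate_groups(df, value_col, group_col)
    clean = df.dropna(subset=[value_col])
    values = clean[value_col].to_numpy(dtype=float)
    labels = clean[group_col].astype(str).to_numpy()
    if np.ptp(values - pd.Series(values).groupby(labels).transform("mean").to_numpy()) == 0.0:
        # zero within-group variance: build the degenerate table directly
        names = sorted(groups)
        rows = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                diff = groups[b].mean() - groups[a].mean()
                p_adj = 1.0 if diff == 0.0 else 0.0
                rows.append({"group_a": a, "group_b": b, "mean_diff": float(diff),
                             "p_adj": p_adj, "stars": significance_stars(p_adj)})
        return pd.DataFrame(rows)
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        res.summary().data[1:], columns=[c.strip() for c in res.summary().data[0]])
    out = pd.DataFrame({
        "group_a": table["group1"].astype(str),
        "group_b": table["group2"].astype(str),
        "mean_diff": res.meandiffs,
        "p_adj": np.clip(res.pvalues, 0.0, 1.0),
    })
    out["stars"] = [significance_stars(p) for p in out["p_adj"]]
    return out


def compare_groups(df: pd.DataFrame, value_col: str = "value",
                   group_col: str = "condition") -> ComparisonResult:
    """ANOVA plus Tukey post-hoc in one :class:`ComparisonResult`."""
    result = one_way_anova(df, value_col, group_col)
    result.pairwise = tukey_hsd(df, value_col, group_col)
    return result


def dose_response_summary(
    df: pd.DataFrame,
    value_col: str = "value",
    condition_col: str = "condition",
    control_label: str = "control",
    block_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Long-format dose–response summary against a control group.

    Per block (e.g. timepoint × assay arm) and condition: n, mean ± SD,
    fold-change of the mean versus the control mean, the block's
    overall ANOVA p-value and the Tukey-adjusted p versus control.
    Blocks are analysed independently (no correction across blocks).
    """
    if condition_col not in df.columns or value_col not in df.columns:
        raise ValueError(f"table needs columns {condition_col!r} and {value_col!r}")
    block_cols = tuple(c for c in block_cols if c in df.columns)
    blocks = df.groupby(list(block_cols), sort=True) if block_cols else [((), df)]
    rows = []
    for key, block in blocks:
        if not isinstance(key, tuple):
            key = (key,)
        conditions = set(block[condition_col].astype(str))
        if control_label not in conditions:
            raise ValueError(f"block {key!r} lacks the control group {control_label!r}")
        control_mean = block.loc[
            block[condition_col].astype(str) == control_label, value_col].mean()
        anova_p = float("nan")
        tukey = pd.DataFrame()
        if len(conditions) >= 2 and (block.groupby(condition_col)[value_col].count() >= 2).all():
            anova_p = one_way_anova(block, value_col, condition_col).p_value
            tukey = tukey_hsd(block, value_col, condition_col)
        for cond, sub in block.groupby(condition_col, sort=True):
            vals = sub[value_col].to_numpy(dtype=float)
            p_vs_control = float("nan")
            if len(tukey) and str(cond) != control_label:
                hit = tukey[((tukey.group_a == str(cond)) & (tukey.group_b == control_label)) |
                            ((tukey.group_b == str(cond)) & (tukey.group_a == control_label))]
                if len(hit):
                    p_vs_control = float(hit.iloc[0]["p_adj"])
            row = dict(zip(block_cols, key))
            row.update({
                "condition": str(cond),
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "fold_change": float(vals.mean() / control_mean) if control_mean else float("nan"),
                "anova_p": anova_p,
                "p_vs_control": p_vs_control,
                "stars": significance_stars(p_vs_control),
            })
            rows.append(row)
    return pd.DataFrame(rows)
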