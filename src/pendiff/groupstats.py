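"""Group-level statistics for the two-group, two-condition design.

All analyses operate on participant-level values (condition means or
parameter estimates), never on pooled trials. The core model is the
classical mixed-design ANOVA with one between-subjects factor (age group)
and one within-subjects factor (stimulus condition): sums of squares are
decomposed with subjects-within-groups as the error term for the group
effect and the condition-by-subjects interaction within groups as the error
term for the condition and interaction effects. Effect sizes are partial
eta squared for F-tests and ``t^2 / (t^2 + df)`` for t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import DataError

__all__ = [
    "GroupTestResult",
    "table2_summary",
    "mixed_anova",
    "pairwise_bonferroni",
    "ttest_between",
    "drift_sign_convert",
    "correlations",
    "CorrelationResult",
]


@dataclass
class GroupTestResult:
    """One statistical effect: test statistic, df, effect size, p-values."""

    effect: str
    statistic_type: str  # "F" | "t" | "r"
    value: float
    df: Tuple[float, ...]  # (df1, df2) for F, (df,) for t / r
    eta_squared: Optional[float]
    p_raw: float
    p_adjusted: Optional[float] = None
    n: Optional[int] = None

    def as_dict(self) -> dict:
        d = {
            "effect": self.effect,
            "statistic_type": self.statistic_type,
            "value": self.value,
            "df1": self.df[0],
            "df2": self.df[1] if len(self.df) > 1 else np.nan,
            "eta_squared": np.nan if self.eta_squared is None else self.eta_squared,
            "p_raw": self.p_raw,
            "p_adjusted": np.nan if self.p_adjusted is None else self.p_adjusted,
            "n": self.n,
        }
        return d


def table2_summary(trials: pd.DataFrame, groups: Dict[str, str]) -> pd.DataFrame:
    """RT and accuracy summary per group and condition.

    Participant-level means are computed first and then averaged within
    group; the reported SDs are across participants. A participant without
    error trials in a cell contributes nothing to that cell's error-RT mean.

    Parameters
    ----------
    trials
        Trimmed trial table (references are excluded here in any case).
    groups
        Mapping ``participant_id -> group label``.
    """
    t = trials[~trials["is_reference"].astype(bool)].copy()
    t = t[t["response"].notna() & t["rt_s"].notna()]
    t["correct"] = (t["response"] == t["condition"]).astype(float)
    t["group"] = t["participant_id"].map(groups)
    if t["group"].isna().any():
        raise DataError("trial table contains participants without group labels")

    per = (
        t.groupby(["group", "participant_id", "condition"])
        .apply(
            lambda d: pd.Series(
                {
                    "accuracy": d["correct"].mean(),
                    "rt_correct_s": d.loc[d["correct"] == 1, "rt_s"].mean(),
                    "rt_error_s": d.loc[d["correct"] == 0, "rt_s"].mean(),
                    "n_obs": float(len(d)),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    out = (
        per.groupby(["group", "condition"])
        .agg(
            accuracy=("accuracy", "mean"),
            accuracy_sd=("accuracy", "std"),
            rt_correct_s=("rt_correct_s", "mean"),
            rt_correct_sd_s=("rt_correct_s", "std"),
            rt_error_s=("rt_error_s", "mean"),
            rt_error_sd_s=("rt_error_s", "std"),
            n_obs=("n_obs", "mean"),
            n_obs_sd=("n_obs", "std"),
        )
        .reset_index()
    )
    return out


def _check_balanced(values: pd.DataFrame):
    counts = values.groupby("subject")["condition"].nunique()
    conditions = sorted(values["condition"].unique())
    if len(conditions) != 2 or (counts != 2).any():
        raise DataError("mixed ANOVA requires exactly two conditions per subject")
    if values.groupby(["subject", "condition"]).size().max() > 1:
        raise DataError("one value per subject and condition is required")
    return conditions


def mixed_anova(values: pd.DataFrame) -> List[GroupTestResult]:
    """2 (group, between) x 2 (condition, within) mixed-design ANOVA.

    ``values`` needs columns ``subject, group, condition, value`` with one
    value per subject-condition cell. Returns the group, condition and
    interaction effects with partial eta squared (``SS_effect /
    (SS_effect + SS_error_of_that_effect)``).
    """
    required = {"subject", "group", "condition", "value"}
    if not required.issubset(values.columns):
        raise DataError(f"mixed_anova needs columns {sorted(required)}")
    conditions = _check_balanced(values)
    groups = sorted(values["group"].unique())
    if len(groups) != 2:
        raise DataError("exactly two groups are required")

    y = values["value"].to_numpy(dtype=float)
    grand = y.mean()
    n_cond = len(conditions)

    subj = values.groupby("subject").agg(
        s_mean=("value", "mean"), group=("group", "first")
    )
    n_subj = len(subj)
    group_means = subj.groupby("group")["s_mean"].mean()
    group_sizes = subj.groupby("group").size()

    ss_group = float(
        n_cond * (group_sizes * (group_means - grand) ** 2).sum()
    )
    ss_subj_within = float(
        n_cond
        * ((subj["s_mean"] - subj["group"].map(group_means)) ** 2).sum()
    )
    cond_means = values.groupby("condition")["value"].mean()
    ss_cond = float(n_subj * ((cond_means - grand) ** 2).sum())
    cell = values.groupby(["group", "condition"])["value"].mean()
    ss_inter = 0.0
    for g in groups:
        for c in conditions:
            dev = cell[(g, c)] - group_means[g] - cond_means[c] + grand
            ss_inter += group_sizes[g] * dev**2
    ss_inter = float(ss_inter)
    ss_total = float(((y - grand) ** 2).sum())
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_cond - ss_inter
    ss_err_within = max(ss_err_within, 0.0)

    df_group = len(groups) - 1
    df_subj = n_subj - len(groups)
    df_cond = n_cond - 1
    df_err_w = df_subj * df_cond

    def f_result(effect, ss_eff, df_eff, ss_err, df_err):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, df_eff, df_err)) if ms_err > 0 else 1.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return GroupTestResult(
            effect=effect, statistic_type="F", value=float(F),
            df=(float(df_eff), float(df_err)), eta_squared=float(eta),
            p_raw=p, n=n_subj,
        )

    return [
        f_result("group", ss_group, df_group, ss_subj_within, df_subj),
        f_result("condition", ss_cond, df_cond, ss_err_within, df_err_w),
        f_result("group x condition", ss_inter, df_group * df_cond,
                 ss_err_within, df_err_w),
    ]


def _eta_from_t(t: float, df: float) -> float:
    return t * t / (t * t + df) if df > 0 else 0.0


def ttest_between(
    values: Sequence[float], groups: Sequence[str], effect: str = "group"
) -> GroupTestResult:
    """Independent two-sample t-test (pooled variance, df = n1 + n2 - 2)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise DataError("exactly two groups are required")
    x1 = values[groups == labels[0]]
    x2 = values[groups == labels[1]]
    if len(x1) < 2 or len(x2) < 2:
        raise DataError("each group needs at least 2 observations")
    n1, n2 = len(x1), len(x2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    if sp2 <= 0:
        raise DataError("zero pooled variance; t-test undefined")
    t = (x1.mean() - x2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = float(2 * sps.t.sf(abs(t), df))
    return GroupTestResult(
        effect=effect, statistic_type="t", value=float(t), df=(float(df),),
        eta_squared=float(_eta_from_t(t, df)), p_raw=p, n=n1 + n2,
    )


def _ttest_paired(x1, x2, effect):
    d = np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    n = d.size
    if n < 2:
        raise DataError("paired t-test needs at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DataError("zero variance of differences; t-test undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = float(2 * sps.t.sf(abs(t), df))
    return GroupTestResult(
        effect=effect, statistic_type="t", value=float(t), df=(float(df),),
        eta_squared=float(_eta_from_t(t, df)), p_raw=p, n=n,
    )


def pairwise_bonferroni(
    values: pd.DataFrame, family: List[dict]
) -> List[GroupTestResult]:
    """Simple-effect t-tests with Bonferroni adjustment over the family.

    ``values`` is the same table as for :func:`mixed_anova`. Each family
    member is a dict: ``{"kind": "between", "condition": c}`` compares the
    two groups within condition ``c`` (independent t), and ``{"kind":
    "within", "group": g}`` compares the two conditions within group ``g``
    (paired t). Adjusted p-values are ``min(1, p_raw * len(family))``.
    """
    if not family:
        raise DataError("the comparison family must not be empty")
    conditions = sorted(values["condition"].unique())
    m = len(family)
    out = []
    for comp in family:
        if comp["kind"] == "between":
            c = comp["condition"]
            sub = values[values["condition"] == c]
            res = ttest_between(
                sub["value"].to_numpy(), sub["group"].to_numpy(),
                effect=f"group @ {c}",
            )
        elif comp["kind"] == "within":
            g = comp["group"]
            sub = values[values["group"] == g]
            wide = sub.pivot(index="subject", columns="condition", values="value")
            res = _ttest_paired(
                wide[conditions[0]], wide[conditions[1]],
                effect=f"{conditions[0]} vs {conditions[1]} @ {g}",
            )
        else:
            raise DataError(f"unknown comparison kind {comp!r}")
        res.p_adjusted = float(min(1.0, res.p_raw * m))
        out.append(res)
    return out


def drift_sign_convert(fits: pd.DataFrame) -> pd.DataFrame:
    """Flip nonword drift rates to the word-drift sign for the ANOVAs.

    Performance in the nonword condition is better the more *negative* the
    drift; multiplying by -1 puts both conditions on a common
    better-is-larger scale. Word drifts are unchanged; applying the
    conversion twice is the identity.
    """
    out = fits.copy()
    out["v_nonword"] = -out["v_nonword"]
    return out


@dataclass
class CorrelationResult:
    """Bivariate and group-partialled Pearson correlation."""

    r_bivariate: float
    r_partial: float
    p_bivariate: float
    p_partial: float
    n: int


def correlations(
    x: Sequence[float], y: Sequence[float], group_labels: Sequence[str]
) -> CorrelationResult:
    """Pearson correlation of ``x`` and ``y`` plus the partial correlation
    controlling for the binary group indicator.

    The partial correlation uses the closed form
    ``(r_xy - r_xg r_yg) / sqrt((1 - r_xg^2)(1 - r_yg^2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = sorted(set(group_labels))
    if len(labels) != 2:
        raise DataError("partial correlation needs exactly two groups")
    g = np.asarray([1.0 if lab == labels[1] else 0.0 for lab in group_labels])
    n = x.size
    if n < 4:
        raise DataError("need at least 4 observations")
    for arr, name in ((x, "x"), (y, "y"), (g, "group")):
        if np.std(arr) == 0:
            raise DataError(f"zero variance in {name}")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xg = float(np.corrcoef(x, g)[0, 1])
    r_yg = float(np.corrcoef(y, g)[0, 1])
    denom = np.sqrt((1 - r_xg**2) * (1 - r_yg**2))
    r_p = float((r_xy - r_xg * r_yg) / denom) if denom > 0 else np.nan

    def r_pvalue(r, df):
        if abs(r) >= 1:
            return 0.0
        t = r * np.sqrt(df / (1 - r * r))
        return float(2 * sps.t.sf(abs(t), df))

    return CorrelationResult(
        r_bivariate=r_xy,
        r_partial=r_p,
        p_bivariate=r_pvalue(r_xy, n - 2),
        p_partial=r_pvalue(r_p, n - 3),
        n=n,
    )
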