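"""Neuronal survival quantification and statistics.

The experimental unit is the culture, not the neuron: each culture
contributes one vital fraction per condition.  Fractions are normalised to
the control condition of the same culture for display (control maps to 1.0
per culture), while one-way ANOVA and Tukey's HSD run on the raw per-culture
fractions: per-culture ratio normalisation leaves the reference condition
with zero within-group variance and ties every other group to a shared
denominator, which deflates the pooled error term and breaks family-wise
error control, so it is kept as a reporting scale only (``scale="normalized"``
is available for comparison).

ANOVA and Tukey are implemented long-hand (sums of squares, studentized
range); established routines serve as cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, ConfigError
from .survival_sim import SURVIVAL_COLUMNS

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))
MIN_CULTURES = 3  # replicates required for inference


def stars(p: float) -> str:
    """Significance label: *P<0.05, **P<0.01, ***P<0.001 (strict)."""
    if np.isnan(p):
        return "ns"
    for thr, label in STAR_THRESHOLDS:
        if p < thr:
            return label
    return "ns"


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVIVAL_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigError(f"survival table lacks columns {missing}")
    t = table.copy()
    if (t["vital"] < 0).any() or (t["degenerated"] < 0).any():
        raise ConfigError("counts must be non-negative")
    if ((t["vital"] + t["degenerated"]) <= 0).any():
        raise ConfigError("each row needs vital + degenerated > 0")
    t["fraction"] = t["vital"] / (t["vital"] + t["degenerated"])
    return t


def normalize_survival(table: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Per-culture vital fractions normalised to the control condition.

    Each culture's fraction is divided by the control fraction *of the same
    culture*, so the control condition maps to exactly 1.0 per culture.
    Cultures missing the control condition are excluded with a warning.

    Returns a tidy frame with columns culture_id, condition, fraction,
    normalized_fraction.
    """
    t = _validate_table(table)
    if control_condition not in set(t["condition"]):
        raise ConfigError(f"control condition {control_condition!r} absent from table")
    out_rows = []
    for culture, grp in t.groupby("culture_id", sort=False):
        ctrl = grp[grp["condition"] == control_condition]
        if ctrl.empty:
            warnings.warn(f"culture {culture!r} lacks the control condition; excluded",
                          stacklevel=2)
            continue
        ctrl_frac = float(ctrl["fraction"].iloc[0])
        if ctrl_frac == 0:
            warnings.warn(f"culture {culture!r} has zero control survival; excluded",
                          stacklevel=2)
            continue
        for _, row in grp.iterrows():
            out_rows.append((culture, row["condition"], row["fraction"],
                             row["fraction"] / ctrl_frac))
    return pd.DataFrame(out_rows, columns=["culture_id", "condition", "fraction",
                                           "normalized_fraction"])


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    note: str = ""


def anova_oneway(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA on culture-level values (long-hand).

    ``groups`` is a dict label -> values or a sequence of arrays.  With all
    values identical the F statistic is undefined and reported as NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in
              (groups.values() if isinstance(groups, dict) else groups)]
    if len(arrays) < 2:
        raise AnalysisError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise AnalysisError("each group needs at least two values")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    ms_w = ss_within / df_w
    if ss_within == 0 and ss_between == 0:
        return AnovaResult(np.nan, np.nan, df_b, df_w, 0.0,
                           note="all values identical: F undefined")
    if ms_w == 0:
        return AnovaResult(np.inf, 0.0, df_b, df_w, 0.0,
                           note="zero within-group variance")
    f = (ss_between / df_b) / ms_w
    return AnovaResult(f, float(sps.f.sf(f, df_b, df_w)), df_b, df_w, ms_w)


def tukey_hsd(groups) -> pd.DataFrame:
    """All pairwise Tukey HSD comparisons on culture-level values.

    Unbalanced designs use the Tukey-Kramer standard error
    sqrt(MSW/2 * (1/n_i + 1/n_j)); adjusted p-values come from the
    studentized range distribution with k groups and N-k error df.  Zero
    within-group variance is reported (p = 0 for unequal means, 1 for
    equal), never raised.

    Returns a frame with columns group1, group2, mean_diff, se, q, p_adj,
    stars.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i}" for i in range(len(arrays))]
    anova = anova_oneway(dict(zip(labels, arrays)))
    k, df_w, ms_w = len(arrays), anova.df_within, anova.ms_within

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = arrays[j].mean() - arrays[i].mean()
            se = np.sqrt(ms_w / 2.0 * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
            if se == 0:
                q = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
                p = min(max(p, 0.0), 1.0)
            rows.append((labels[i], labels[j], diff, se, q, p, stars(p)))
    return pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "se",
                                       "q", "p_adj", "stars"])


@dataclass
class SurvivalResults:
    """Results of a SurvivalAnalysis fit."""

    anova: AnovaResult
    comparisons: pd.DataFrame
    normalized: pd.DataFrame          # tidy per-culture table
    condition_summary: pd.DataFrame   # mean +/- SEM per condition (bar-plot ready)
    control_condition: str
    scale: str

    def summary(self) -> str:
        lines = [
            "Survival analysis (culture as experimental unit)",
            "=" * 60,
            f"inference scale : {self.scale} per-culture vital fractions",
            f"control         : {self.control_condition}",
            f"ANOVA           : F({self.anova.df_between}, {self.anova.df_within}) "
            f"= {self.anova.f_statistic:.3f}, p = {self.anova.p_value:.3g}"
            + (f"  [{self.anova.note}]" if self.anova.note else ""),
            "",
            "Normalized survival (mean +/- SEM over cultures):",
        ]
        for _, row in self.condition_summary.iterrows():
            lines.append(f"  {row['condition']:<16} {row['mean_normalized']:.3f} "
                         f"+/- {row['sem_normalized']:.3f}  (n={int(row['n_cultures'])})")
        lines.append("")
        lines.append("Tukey HSD (adjusted):")
        for _, row in self.comparisons.iterrows():
            lines.append(f"  {row['group1']:<14} vs {row['group2']:<14} "
                         f"diff={row['mean_diff']:+.3f}  p={row['p_adj']:.2e}  {row['stars']}")
        return "\n".join(lines)


class SurvivalAnalysis:
    """Model object: survival table in, ANOVA + Tukey + summary out.

    Parameters
    ----------
    table : DataFrame with culture_id, condition, vital, degenerated
    control_condition : reference condition present in every culture
    scale : "fraction" (default) runs inference on raw per-culture vital
        fractions; "normalized" runs it on the per-culture ratios (the
        degenerate control group is then included as-is).
    """

    def __init__(self, table: pd.DataFrame, control_condition: str,
                 scale: str = "fraction"):
        if scale not in ("fraction", "normalized"):
            raise ConfigError("scale must be 'fraction' or 'normalized'")
        self.table = _validate_table(table)
        self.control_condition = control_condition
        self.scale = scale

    def fit(self) -> SurvivalResults:
        norm = normalize_survival(self.table, self.control_condition)
        counts = norm.groupby("condition")["culture_id"].nunique()
        thin = counts[counts < MIN_CULTURES]
        if not thin.empty:
            raise AnalysisError(
                "conditions with fewer than "
                f"{MIN_CULTURES} cultures: {', '.join(thin.index)}"
            )
        value_col = "fraction" if self.scale == "fraction" else "normalized_fraction"
        groups = {cond: grp[value_col].to_numpy()
                  for cond, grp in norm.groupby("condition", sort=False)}
        anova = anova_oneway(groups)
        comparisons = tukey_hsd(groups)
        summary = (norm.groupby("condition", sort=False)
                   .agg(mean_normalized=("normalized_fraction", "mean"),
                        sem_normalized=("normalized_fraction", "sem"),
                        mean_fraction=("fraction", "mean"),
                        n_cultures=("culture_id", "nunique"))
                   .reset_index())
        summary["sem_normalized"] = summary["sem_normalized"].fillna(0.0)
        return SurvivalResults(anova=anova, comparisons=comparisons, normalized=norm,
                               condition_summary=summary,
                               control_condition=self.control_condition,
                               scale=self.scale)
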