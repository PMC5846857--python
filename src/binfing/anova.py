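"""Variance decomposition of SRD results by measure, class and metricity.

Bootstrap-mean normalized SRD values from several datasets are stacked into
a long table (one row per dataset x measure).  One-way ANOVA with the
measure, the concordance-symmetry class or the metricity group as the
factor tests whether the factor levels differ; datasets act as replicates.
Post-hoc pairwise comparisons (Tukey HSD and Bonferroni-corrected t-tests)
and pooled-error 95% confidence intervals accompany each decomposition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MeasureSpec, catalog as _catalog
from .srd import BootstrapSRDResult

__all__ = [
    "AnovaResult",
    "aggregate",
    "anova_by_factor",
    "classify_groups",
]

_FACTORS = {"measure": "measure_id", "class": "class_tag", "metricity": "metricity_tag"}


@dataclass
class AnovaResult:
    factor: str
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    level_means: pd.DataFrame  # level, mean, ci_low, ci_high, n
    tukey: pd.DataFrame  # level_1, level_2, p_adj
    bonferroni: pd.DataFrame  # level_1, level_2, p_raw, p_adj
    levene_p: float  # homoscedasticity diagnostic (non-blocking)


def aggregate(results: dict[int, list[BootstrapSRDResult]],
              measures: list[MeasureSpec] | None = None) -> pd.DataFrame:
    """Long table of bootstrap-mean normalized SRD with catalog tags joined.

    *results* maps a dataset id to the per-measure bootstrap results of that
    dataset.  Every dataset must contribute every measure.
    """
    if measures is None:
        measures = _catalog()
    tags = {m.id: (m.class_tag, m.metricity_tag) for m in measures}
    rows = []
    for dataset_id, dataset_results in results.items():
        seen = {r.measure_id for r in dataset_results}
        missing = set(tags) - seen
        if missing:
            raise ValueError(
                f"dataset {dataset_id}: missing bootstrap results for measures {sorted(missing)}"
            )
        for r in dataset_results:
            if r.measure_id not in tags:
                continue
            cls, met = tags[r.measure_id]
            rows.append((dataset_id, r.measure_id, cls, met, r.mean_srd_norm))
    table = pd.DataFrame(
        rows,
        columns=["dataset_id", "measure_id", "class_tag", "metricity_tag", "mean_srd_norm"],
    ).sort_values(["dataset_id", "measure_id"], kind="stable").reset_index(drop=True)
    if ((table.mean_srd_norm < 0) | (table.mean_srd_norm > 100)).any():
        raise ValueError("normalized SRD outside [0, 100]")
    return table


def anova_by_factor(table: pd.DataFrame, factor: str) -> AnovaResult:
    """One-way ANOVA of mean normalized SRD with *factor* as the grouping.

    Confidence intervals use the pooled within-group error (root mean square
    error with df_within degrees of freedom), matching the usual ANOVA
    means plot.
    """
    if factor not in _FACTORS:
        raise ValueError(f"factor must be one of {sorted(_FACTORS)}")
    col = _FACTORS[factor]
    groups = {level: g["mean_srd_norm"].to_numpy() for level, g in table.groupby(col)}
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    for level, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"level {level!r} has a single observation; ANOVA needs >= 2")

    levels = sorted(groups)
    arrays = [groups[lv] for lv in levels]
    f_stat, p_value = stats.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    df_between = len(levels) - 1
    df_within = n_total - len(levels)
    # pooled within-group error for the CI bars
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    mse = sse / df_within
    tcrit = stats.t.ppf(0.975, df_within)
    level_means = pd.DataFrame(
        {
            "level": levels,
            "n": [len(groups[lv]) for lv in levels],
            "mean": [groups[lv].mean() for lv in levels],
        }
    )
    half = tcrit * np.sqrt(mse / level_means["n"].to_numpy())
    level_means["ci_low"] = level_means["mean"] - half
    level_means["ci_high"] = level_means["mean"] + half

    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    from statsmodels.stats.multitest import multipletests

    tuk = pairwise_tukeyhsd(table["mean_srd_norm"].to_numpy(), table[col].to_numpy())
    tukey = pd.DataFrame(tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]])
    tukey = tukey.rename(columns={"group1": "level_1", "group2": "level_2", "p-adj": "p_adj"})[
        ["level_1", "level_2", "p_adj"]
    ]
    pairs, praw = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            t_p = stats.ttest_ind(groups[levels[i]], groups[levels[j]]).pvalue
            pairs.append((levels[i], levels[j]))
            praw.append(float(t_p))
    p_adj = multipletests(praw, method="bonferroni")[1]
    bonferroni = pd.DataFrame(
        {"level_1": [p[0] for p in pairs], "level_2": [p[1] for p in pairs],
         "p_raw": praw, "p_adj": p_adj}
    )
    levene_p = float(stats.levene(*arrays).pvalue)
    return AnovaResult(
        factor=factor,
        f_statistic=float(f_stat),
        p_value=float(p_value),
        df_between=df_between,
        df_within=df_within,
        level_means=level_means,
        tukey=tukey,
        bonferroni=bonferroni,
        levene_p=levene_p,
    )


def classify_groups(table: pd.DataFrame, low: float = 15.0, high: float = 25.0) -> dict[str, str]:
    """Best / medium / worst grouping by grand-mean normalized SRD.

    Measures with grand mean below *low* are the most consistent ("best"),
    between *low* and *high* "medium", above *high* "worst".
    """
    if not (0 < low < high < 100):
        raise ValueError("thresholds must satisfy 0 < low < high < 100")
    grand = table.groupby("measure_id")["mean_srd_norm"].mean()
    out = {}
    for measure_id, value in grand.items():
        if value < low:
            out[measure_id] = "best"
        elif value <= high:
            out[measure_id] = "medium"
        else:
            out[measure_id] = "worst"
    return out
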