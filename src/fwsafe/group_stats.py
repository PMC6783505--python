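"""Cohort statistics: log transform, one-way ANOVA, Tukey–Kramer post-hoc
pairwise differences, and ANCOVA adjusting for age and gender.

Metrics are natural-log transformed before analysis to improve normality
(group differences are therefore reported on the log scale).  ANOVA tests
the main effect of diagnostic group (NC, MCI, AD); the Tukey–Kramer
procedure handles the unequal group sizes; the ANCOVA re-tests the
NC-vs-patient contrasts in a linear model ``log(metric) ~ group + age +
gender`` with NC as the reference level.

Pair ordering is fixed as (NC, MCI), (NC, AD), (MCI, AD): a *negative*
NC − patient difference means the patient group has the higher metric.
Significance stars: * p < 0.05, ** p < 0.01, *** p < 0.001.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

GROUP_ORDER = ("NC", "MCI", "AD")

#: The standard per-subject metric columns of the cohort report, in report
#: order: rFW/muFW over the four masks, then WMH volume.
DEFAULT_METRICS = (
    "rFW_WM_safe_minus_WMHs", "muFW_WM_safe_minus_WMHs",
    "rFW_WM_safe", "muFW_WM_safe",
    "rFW_WM", "muFW_WM",
    "rFW_WMHs", "muFW_WMHs",
    "wmh_volume",
)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class TukeyResult:
    pair: tuple[str, str]
    diff: float
    se: float
    p_adj: float


@dataclass
class AncovaResult:
    """Group contrasts adjusted for age and gender, plus covariate tests.

    ``contrasts`` maps (reference, group) pairs to (diff, se, p); with no
    group-by-covariate interaction these contrasts are the same at every
    covariate value, i.e. they are the mean-age, gender-balanced adjusted
    differences.
    """

    contrasts: dict[tuple[str, str], tuple[float, float, float]]
    covariate_p: dict[str, float]
    n: int


def log_transform(values: Sequence[float],
                  subjects: Optional[Sequence[str]] = None) -> np.ndarray:
    """Natural log, elementwise; errors name the offending subject."""
    arr = np.asarray(values, dtype=float)
    bad = ~(arr > 0)
    if bad.any():
        i = int(np.argmax(bad))
        who = subjects[i] if subjects is not None else f"index {i}"
        raise ValueError(f"non-positive value {arr[i]} for subject {who}: "
                         "cannot log transform")
    return np.log(arr)


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need at least two groups")
    for k, v in clean.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    return clean


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA from between/within sums of squares."""
    clean = _check_groups(groups)
    all_vals = np.concatenate(list(clean.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in clean.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in clean.values())
    df_b = len(clean) - 1
    df_w = len(all_vals) - len(clean)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = float("inf") if ms_b > 0 else 0.0
    else:
        F = float(ms_b / ms_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=F, df_between=df_b, df_within=df_w, p=p)


def tukey_hsd(groups: Mapping[str, Sequence[float]],
              order: Sequence[str] = GROUP_ORDER) -> list[TukeyResult]:
    """Tukey–Kramer pairwise comparisons (valid for unequal group sizes).

    For each pair (i, j) in the fixed order: diff = mean_i − mean_j,
    se = sqrt(MSW (1/n_i + 1/n_j) / 2), and the adjusted p comes from the
    studentized range distribution with (k, df_within).
    """
    clean = _check_groups(groups)
    names = [g for g in order if g in clean]
    names += [g for g in clean if g not in names]
    k = len(names)
    df_w = sum(len(v) for v in clean.values()) - k
    ms_w = sum(((v - v.mean()) ** 2).sum() for v in clean.values()) / df_w
    results = []
    for a, b in itertools.combinations(names, 2):
        va, vb = clean[a], clean[b]
        diff = float(va.mean() - vb.mean())
        se = float(np.sqrt(ms_w * (1.0 / len(va) + 1.0 / len(vb)) / 2.0))
        if se == 0:
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
        results.append(TukeyResult(pair=(a, b), diff=diff, se=se,
                                   p_adj=min(max(p_adj, 0.0), 1.0)))
    return results


def ancova_adjusted(table: pd.DataFrame, metric: str,
                    reference: str = "NC") -> AncovaResult:
    """Linear model ``log(metric) ~ group + age + gender`` by least squares.

    Gender enters as a 0/1 indicator, group as indicators against the
    reference level.  Returns partial F-test p-values for age and gender
    and the adjusted reference-minus-group contrasts.
    Raises on rank deficiency, naming the constant covariate.
    """
    import statsmodels.api as sm

    required = {"group", "age", "gender", metric}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    df = table.dropna(subset=[metric]).copy()
    if df["age"].isna().any():
        raise ValueError("age missing for some subjects")
    if not set(df["gender"]).issubset({"M", "F"}):
        raise ValueError("gender must be coded M/F")
    y = log_transform(df[metric].to_numpy(), df.get("subject_id"))

    for name, col in (("age", df["age"].to_numpy(float)),
                      ("gender", (df["gender"] == "F").to_numpy(float))):
        if np.ptp(col) == 0:
            raise ValueError(f"covariate {name!r} is constant: design is rank deficient")

    groups = [g for g in GROUP_ORDER if g in set(df["group"])]
    groups += sorted(set(df["group"]) - set(groups))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    others = [g for g in groups if g != reference]

    X = pd.DataFrame({"const": 1.0}, index=df.index)
    for g in others:
        X[f"group_{g}"] = (df["group"] == g).astype(float)
    X["age"] = df["age"].astype(float)
    X["gender_F"] = (df["gender"] == "F").astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    fit = sm.OLS(y, X).fit()
    cov_p = {
        "age": float(fit.f_test("age = 0").pvalue),
        "gender": float(fit.f_test("gender_F = 0").pvalue),
    }
    contrasts = {}
    for g in others:
        name = f"group_{g}"
        # reference − group = −coefficient of the group indicator
        contrasts[(reference, g)] = (
            float(-fit.params[name]),
            float(fit.bse[name]),
            float(fit.pvalues[name]),
        )
    return AncovaResult(contrasts=contrasts, covariate_p=cov_p, n=len(df))


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def cohort_report(table: pd.DataFrame,
                  metrics: Sequence[str] = DEFAULT_METRICS,
                  group_order: Sequence[str] = GROUP_ORDER,
                  log: bool = True) -> pd.DataFrame:
    """ANOVA + Tukey report, one row per metric.

    ``table`` holds one row per subject with ``group`` plus metric columns.
    Metrics are natural-log transformed when ``log`` is true and all values
    are strictly positive; a metric containing zeros (possible for WMH
    volume when a subject has no lesions) is analysed on the raw scale and
    flagged in the ``scale`` column.  Columns per pairwise contrast:
    difference of group means on the analysis scale, its standard error,
    the Tukey-adjusted p and significance stars.
    """
    if "group" not in table.columns:
        raise ValueError("cohort table needs a 'group' column")
    present = [g for g in group_order if g in set(table["group"])]
    if len(present) < 2:
        raise ValueError("need at least two groups to compare")
    rows = []
    for metric in metrics:
        if metric not in table.columns:
            continue
        sub = table.dropna(subset=[metric])
        vals = sub[metric].to_numpy(float)
        use_log = bool(log) and np.all(vals > 0)
        scale = "log" if use_log else "raw"
        tvals = np.log(vals) if use_log else vals
        groups = {g: tvals[(sub["group"] == g).to_numpy()] for g in present}
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:  # too much missing data for this metric
            continue
        an = anova_oneway(groups)
        row = {
            "metric": metric,
            "scale": scale,
            "F": an.F,
            "df_between": an.df_between,
            "df_within": an.df_within,
            "p": an.p,
            "stars": stars(an.p),
        }
        for tk in tukey_hsd(groups, order=present):
            key = f"{tk.pair[0]}-{tk.pair[1]}"
            row[f"diff_{key}"] = tk.diff
            row[f"se_{key}"] = tk.se
            row[f"p_{key}"] = tk.p_adj
            row[f"stars_{key}"] = stars(tk.p_adj)
        rows.append(row)
    if not rows:
        raise ValueError("none of the requested metrics are in the table")
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, csv_path: Union[str, Path],
                 json_path: Optional[Union[str, Path]] = None) -> None:
    report.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report.to_dict(orient="records"), fh, indent=2,
                      default=float)
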