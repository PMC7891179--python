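"""Univariate group statistics for oculomotor parameter tables.

Reproduces the analysis layout of clinical oculomotor studies: a one-way
ANOVA with Tukey's post hoc test across the four diagnostic groups gives
the *crude* p-values, and a general linear model with age and sex (and,
where a Spearman screen at p < 0.1 flags a sedative association, the
sedative count) as covariates gives the *covariate-adjusted* pairwise
p-values.  No multiple-testing correction is applied across parameters;
adjusted pairwise p-values come from model contrasts without an additional
Tukey step (here "adjusted" means covariate-adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .protocol_io import GroupProfile

__all__ = [
    "StatResult",
    "anova_tukey",
    "adjusted_model",
    "sedative_screen",
    "group_contrast",
    "spearman_panel",
    "parameter_table",
]


@dataclass
class StatResult:
    """One parameter's group comparison."""

    parameter: str
    group_p: float
    f_stat: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    crude_pairwise_p: dict[tuple[str, str], float]
    adjusted_pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    mean_differences: dict[tuple[str, str], float] = field(default_factory=dict)
    covariates: tuple[str, ...] = ()

    def pair_p(self, a: str, b: str, adjusted: bool = False) -> float:
        table = self.adjusted_pairwise_p if adjusted else self.crude_pairwise_p
        return table.get((a, b), table.get((b, a), np.nan))


def anova_tukey(values_by_group: Mapping[str, Sequence[float]]) -> StatResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons (crude p-values)."""
    groups = {g: np.asarray(v, float) for g, v in values_by_group.items()}
    groups = {g: v[np.isfinite(v)] for g, v in groups.items()}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    arrays = list(groups.values())
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        raise ValueError("zero variance everywhere: ANOVA undefined")
    f, p = stats.f_oneway(*arrays)
    labels = list(groups)
    tk = stats.tukey_hsd(*arrays)
    pairwise = {}
    diffs = {}
    for i, j in combinations(range(len(labels)), 2):
        a, b = labels[i], labels[j]
        pairwise[(a, b)] = float(tk.pvalue[i, j])
        diffs[(a, b)] = float(np.mean(groups[a]) - np.mean(groups[b]))
        diffs[(b, a)] = -diffs[(a, b)]
    return StatResult(
        parameter="",
        group_p=float(p),
        f_stat=float(f),
        group_means={g: float(np.mean(v)) for g, v in groups.items()},
        group_sds={g: float(np.std(v, ddof=1)) for g, v in groups.items()},
        crude_pairwise_p=pairwise,
        mean_differences=diffs,
    )


def adjusted_model(
    data: pd.DataFrame,
    parameter: str,
    covariates: Sequence[str] = ("age", "sex"),
    group_col: str = "group",
) -> dict[tuple[str, str], float]:
    """Covariate-adjusted pairwise group p-values from a general linear model.

    Fits ``parameter ~ C(group) + covariates`` by ordinary least squares
    (sex coded as a binary indicator; rows with missing values dropped
    listwise) and tests each pairwise group contrast.  Raises on a
    rank-deficient design, naming the collinear column.
    """
    cols = [parameter, group_col, *covariates]
    df = data[cols].dropna().copy()
    if "sex" in covariates:
        df["sex"] = (df["sex"].astype(str) == "F").astype(float)
    terms = " + ".join([f"C({group_col})", *covariates])
    model = smf.ols(f"Q('{parameter}') ~ {terms}", data=df)
    x = model.exog
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify a collinear column for the error message
        names = model.exog_names
        for k in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : k + 1]) < k + 1:
                raise ValueError(f"rank-deficient design: column {names[k]!r}")
        raise ValueError("rank-deficient design")
    res = model.fit()
    levels = sorted(df[group_col].unique())
    names = res.model.exog_names

    def coef_vector(g: str) -> np.ndarray:
        vec = np.zeros(len(names))
        term = f"C({group_col})[T.{g}]"
        if term in names:
            vec[names.index(term)] = 1.0
        return vec

    out = {}
    for a, b in combinations(levels, 2):
        contrast = coef_vector(a) - coef_vector(b)
        tt = res.t_test(contrast)
        out[(a, b)] = float(np.squeeze(tt.pvalue))
    return out


def sedative_screen(
    values: Sequence[float],
    sedative_counts: Sequence[int],
    alpha: float = 0.1,
) -> tuple[bool, float]:
    """Spearman screen for a sedative-load association.

    Returns ``(include, p)``: the sedative count joins the covariate set
    iff the Spearman correlation has p < alpha.  Constant counts leave the
    correlation undefined and exclude the covariate.
    """
    v = np.asarray(values, float)
    c = np.asarray(sedative_counts, float)
    m = np.isfinite(v) & np.isfinite(c)
    v, c = v[m], c[m]
    if len(v) < 3 or np.ptp(c) == 0 or np.ptp(v) == 0:
        return False, np.nan
    rho, p = stats.spearmanr(v, c)
    return bool(p < alpha), float(p)


def group_contrast(
    source: pd.DataFrame | Mapping[str, GroupProfile],
    parameter: str,
    group_a: str,
    group_b: str,
) -> float:
    """Mean difference mean(A) - mean(B) for a parameter.

    ``source`` is either a feature table (DataFrame with a ``group``
    column) or a map of group profiles, in which case the published table
    means are contrasted directly.
    """
    if isinstance(source, pd.DataFrame):
        for g in (group_a, group_b):
            if g not in set(source["group"]):
                raise KeyError(f"missing group {g!r}")
        ma = source.loc[source["group"] == group_a, parameter].mean()
        mb = source.loc[source["group"] == group_b, parameter].mean()
        return float(ma - mb)
    for g in (group_a, group_b):
        if g not in source:
            raise KeyError(f"missing group {g!r}")
    return float(source[group_a].mean(parameter) - source[group_b].mean(parameter))


def spearman_panel(
    features: pd.DataFrame,
    feature_names: Sequence[str],
    score_names: Sequence[str],
    group_col: str = "group",
    age_col: str = "age",
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Spearman correlations between oculomotor features and test scores.

    For each (feature, score, group) cell: Spearman rho with its crude p,
    plus an age-adjusted p from a linear model on the raw scale
    (``score ~ feature + age``).  Cells with fewer than ``min_pairs``
    complete observations are left NaN.
    """
    rows = []
    for group, sub in features.groupby(group_col):
        for feat in feature_names:
            for score in score_names:
                cell = {
                    "group": group,
                    "feature": feat,
                    "score": score,
                    "rho": np.nan,
                    "p": np.nan,
                    "adjusted_p": np.nan,
                    "n": 0,
                }
                cols = [feat, score, age_col]
                d = sub[cols].dropna()
                cell["n"] = len(d)
                if len(d) >= min_pairs and d[feat].nunique() > 1 and d[score].nunique() > 1:
                    rho, p = stats.spearmanr(d[feat], d[score])
                    cell["rho"], cell["p"] = float(rho), float(p)
                    res = smf.ols(
                        f"Q('{score}') ~ Q('{feat}') + Q('{age_col}')", data=d
                    ).fit()
                    cell["adjusted_p"] = float(res.pvalues.iloc[1])
                rows.append(cell)
    return pd.DataFrame(rows)


def parameter_table(
    features: pd.DataFrame,
    parameters: Sequence[str],
    base_covariates: Sequence[str] = ("age", "sex"),
    sedative_col: str = "sedatives",
    screen_alpha: float = 0.1,
) -> dict[str, StatResult]:
    """Full univariate table: crude ANOVA/Tukey plus adjusted GLM per parameter.

    The sedative count joins the covariates for exactly those parameters
    flagged by the Spearman screen.
    """
    out: dict[str, StatResult] = {}
    for param in parameters:
        values_by_group = {
            g: sub[param].to_numpy(float)
            for g, sub in features.groupby("group")
        }
        try:
            res = anova_tukey(values_by_group)
        except ValueError:
            continue
        res.parameter = param
        covs = list(base_covariates)
        if sedative_col in features.columns:
            include, _ = sedative_screen(features[param], features[sedative_col])
            if include:
                covs.append(sedative_col)
        res.covariates = tuple(covs)
        try:
            res.adjusted_pairwise_p = adjusted_model(features, param, covs)
        except ValueError:
            res.adjusted_pairwise_p = {}
        out[param] = res
    return out
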