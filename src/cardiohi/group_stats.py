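"""Group comparisons: mixed-effect models on well-level values and
cohort-characteristics association tests.

Well-level cell sizes (or HI values) are compared across subject groups
with a linear mixed model — group fixed effects, patient random
intercept, REML — because replicate wells of one patient's plasma are
correlated.  Reported per group: the model mean estimate, its SE, and
the Wald p of the contrast against the reference group.

Cohort tables use Pearson chi-squared (no continuity correction) for
categorical characteristics and one-way ANOVA for continuous ones.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["GroupContrast", "mixed_model_cellsize", "cohort_table_tests"]


@dataclass
class GroupContrast:
    group: str
    estimate: float
    se: float
    p_vs_reference: float  # NaN for the reference group itself
    reference: str
    model: str = "mixed"  # "mixed" or "ols" (fallback)


def mixed_model_cellsize(
    values: pd.DataFrame,
    value_col: str = "hi",
    group_col: str = "group",
    sample_col: str = "sample_id",
    reference: str = "Ctrl",
) -> list[GroupContrast]:
    """Per-group mean estimates from a random-intercept model.

    ``values`` holds one row per well with the measured value, the
    sample (patient) id and the group label.  When no patient has more
    than one well the random intercept is unidentifiable and the model
    falls back to ordinary least squares with an explicit warning.
    """
    df = values[[sample_col, group_col, value_col]].dropna().copy()
    groups = list(pd.unique(df[group_col]))
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present in data")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to contrast")
    df[group_col] = pd.Categorical(
        df[group_col], categories=[reference] + [g for g in sorted(groups, key=str) if g != reference]
    )

    formula = f"{value_col} ~ C({group_col})"
    max_reps = df.groupby(sample_col).size().max()
    model_kind = "mixed"
    if max_reps < 2:
        warnings.warn(
            "every patient has a single well: random intercept unidentifiable; "
            "falling back to a fixed-effects (OLS) model",
            stacklevel=2,
        )
        model_kind = "ols"
        res = smf.ols(formula, data=df).fit()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, data=df, groups=df[sample_col])
            res = md.fit(reml=True)

    params = res.params
    cov = res.cov_params()
    intercept = "Intercept"
    out = [
        GroupContrast(
            group=reference,
            estimate=float(params[intercept]),
            se=float(np.sqrt(cov.loc[intercept, intercept])),
            p_vs_reference=float("nan"),
            reference=reference,
            model=model_kind,
        )
    ]
    for g in df[group_col].cat.categories[1:]:
        term = f"C({group_col})[T.{g}]"
        est = float(params[intercept] + params[term])
        var = (
            cov.loc[intercept, intercept]
            + cov.loc[term, term]
            + 2.0 * cov.loc[intercept, term]
        )
        out.append(
            GroupContrast(
                group=str(g),
                estimate=est,
                se=float(np.sqrt(var)),
                p_vs_reference=float(res.pvalues[term]),
                reference=reference,
                model=model_kind,
            )
        )
    return out


def cohort_table_tests(
    patients: pd.DataFrame,
    variables: dict[str, str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Association tests between the diagnosis group and characteristics.

    ``variables`` maps column name -> "categorical" | "continuous".
    Categorical: Pearson chi-squared on the group-by-level contingency
    table, no continuity correction, levels with zero total count dropped
    with a warning.  Continuous: one-way ANOVA F test.  Returns one row
    per variable: variable, test, statistic, df, p.
    """
    rows = []
    for var, kind in variables.items():
        sub = patients[[group_col, var]].dropna()
        if kind == "categorical":
            tab = pd.crosstab(sub[var], sub[group_col])
            empty = tab.index[tab.sum(axis=1) == 0]
            if len(empty):
                warnings.warn(
                    f"{var}: dropping zero-count level(s) {list(empty)}", stacklevel=2
                )
                tab = tab.drop(index=empty)
            stat, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            # a table with identical proportions across groups gives stat 0, p 1
            rows.append(
                {"variable": var, "test": "chi-squared", "statistic": float(stat),
                 "df": int(dof), "p": float(p)}
            )
        elif kind == "continuous":
            samples = [g[var].to_numpy(float) for _, g in sub.groupby(group_col)]
            samples = [s for s in samples if len(s) > 0]
            if np.ptp(np.concatenate(samples)) == 0:
                stat, p = 0.0, 1.0  # all values identical: no variance to test
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    stat, p = stats.f_oneway(*samples)
                if np.isnan(stat):  # zero between-group variance
                    stat, p = 0.0, 1.0
            dof = len(samples) - 1
            rows.append(
                {"variable": var, "test": "anova", "statistic": float(stat),
                 "df": int(dof), "p": float(p)}
            )
        else:
            raise ValueError(f"variable {var!r}: unknown kind {kind!r}")
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "df", "p"])
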