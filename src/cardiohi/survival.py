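"""Endpoint construction, Kaplan-Meier and Cox proportional-hazards analyses.

Endpoints: HTX (death of any cause or heart transplantation), DMP
(hospitalization for cardiac decompensation) and MACE (the composite of
either).  Cox fits use Efron's tie approximation; p-values reported are
Wald for uni-/multivariate fits (cluster-robust on request) and the
likelihood-ratio test of the group term for Kaplan-Meier comparisons.
Follow-up is summarized by the reverse Kaplan-Meier median (censoring
treated as the event).

Biomarker utilities: GFR adjustment of NTproBNP,
adjusted = measured / exp(a - b * GFR) with a = 1.892, b = 0.025 per
ml/min, and biomarker-defined subcohorts (cTnT strictly > 50 pg/ml;
GFR-adjusted NTproBNP >= an age-band cutoff that must be configured).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import median_survival_times

from .config import BiomarkerRules, ConfigurationError

__all__ = [
    "ENDPOINTS",
    "endpoint_columns",
    "SurvivalFit",
    "fit_cox",
    "fit_cox_multivariate",
    "univariate_battery",
    "km_analysis",
    "median_followup",
    "adjust_ntprobnp",
    "define_subcohorts",
]

ENDPOINTS = ("HTX", "DMP", "MACE")
_EP_COLS = {
    "HTX": ("time_htx", "event_htx"),
    "DMP": ("time_dmp", "event_dmp"),
    "MACE": ("time_mace", "event_mace"),
}


def endpoint_columns(endpoint: str) -> tuple[str, str]:
    """(time_col, event_col) for an endpoint name (case-insensitive)."""
    key = endpoint.upper()
    if key not in _EP_COLS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    return _EP_COLS[key]


@dataclass
class SurvivalFit:
    """One feature's hazard-ratio estimate for one endpoint."""

    feature: str
    transform: str
    endpoint: str
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    lr_p: float
    n: int
    n_events: int
    cluster_adjusted: bool = False
    converged: bool = True
    flags: str = ""


def _apply_transform(x: pd.Series, transform: str, feature: str) -> pd.Series:
    if transform == "none":
        return x.astype(float)
    if transform in ("log", "log10"):
        vals = x.astype(float)
        if (vals <= 0).any():
            raise ValueError(
                f"feature {feature!r} has non-positive values; cannot {transform}-transform"
            )
        return np.log(vals) if transform == "log" else np.log10(vals)
    if transform == "dichotomous":
        uniq = pd.unique(x.dropna())
        if len(uniq) != 2:
            raise ValueError(
                f"dichotomous feature {feature!r} must have exactly 2 levels, got {len(uniq)}"
            )
        if set(uniq) == {"high", "low"}:
            return (x == "high").astype(float)
        levels = sorted(uniq, key=str)
        return (x == levels[1]).astype(float)
    raise ValueError(f"unknown transform {transform!r}")


def fit_cox(
    data: pd.DataFrame,
    feature: str,
    transform: str = "none",
    endpoint: str = "MACE",
    cluster_by: str | None = None,
) -> SurvivalFit:
    """Univariate Cox PH fit of one (optionally transformed) feature.

    Returns the hazard ratio per unit of the transformed feature with its
    95% CI, the two-sided Wald p (cluster-robust when ``cluster_by``
    names a grouping column) and the likelihood-ratio p.  Rows with
    missing values are excluded (complete-case).
    """
    time_col, event_col = endpoint_columns(endpoint)
    cols = [time_col, event_col, feature] + ([cluster_by] if cluster_by else [])
    df = data[cols].dropna(subset=[feature, time_col, event_col]).copy()
    n_events = int(df[event_col].sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events to fit, got {n_events}")
    df["_x"] = _apply_transform(df[feature], transform, feature)
    if df["_x"].nunique() < 2:
        raise ValueError(f"degenerate covariate: {feature!r} is constant")

    cph = CoxPHFitter()
    fit_cols = [time_col, event_col, "_x"] + ([cluster_by] if cluster_by else [])
    opts = {"fit_options": {"precision": 1e-11, "max_steps": 500}}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if cluster_by:
                cph.fit(df[fit_cols], time_col, event_col, cluster_col=cluster_by, **opts)
            else:
                cph.fit(df[fit_cols], time_col, event_col, **opts)
    except ConvergenceError as exc:
        return SurvivalFit(
            feature, transform, endpoint.upper(), np.nan, np.nan, np.nan,
            np.nan, np.nan, len(df), n_events,
            cluster_adjusted=cluster_by is not None, converged=False,
            flags=f"non-convergent: {exc}",
        )
    s = cph.summary.loc["_x"]
    lr_p = float(cph.log_likelihood_ratio_test().p_value)
    return SurvivalFit(
        feature=feature,
        transform=transform,
        endpoint=endpoint.upper(),
        hr=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        wald_p=float(s["p"]),
        lr_p=lr_p,
        n=len(df),
        n_events=n_events,
        cluster_adjusted=cluster_by is not None,
    )


def fit_cox_multivariate(
    data: pd.DataFrame,
    features: list[str] | dict[str, str],
    endpoint: str = "MACE",
) -> list[SurvivalFit]:
    """Joint Cox PH fit; one adjusted SurvivalFit per feature.

    ``features`` is a list of column names or a mapping name->transform.
    Complete cases across all features are used and the reported n
    reflects that.  Exactly collinear designs are not fit: every feature
    comes back flagged "collinear" with the design condition number.
    """
    if isinstance(features, dict):
        feat_items = list(features.items())
    else:
        feat_items = [(f, "none") for f in features]
    time_col, event_col = endpoint_columns(endpoint)
    cols = [time_col, event_col] + [f for f, _ in feat_items]
    df = data[cols].dropna().copy()
    n_events = int(df[event_col].sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events to fit, got {n_events}")
    xcols = []
    for f, tr in feat_items:
        col = f"x_{f}"
        df[col] = _apply_transform(df[f], tr, f)
        xcols.append(col)

    X = df[xcols].to_numpy(float)
    Xc = X - X.mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if cond > 1e8:
        return [
            SurvivalFit(
                f, tr, endpoint.upper(), np.nan, np.nan, np.nan, np.nan, np.nan,
                len(df), n_events, converged=False,
                flags=f"collinear (design condition number {cond:.3g})",
            )
            for f, tr in feat_items
        ]

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df[[time_col, event_col] + xcols], time_col, event_col,
            fit_options={"precision": 1e-11, "max_steps": 500},
        )
    lr_p = float(cph.log_likelihood_ratio_test().p_value)
    fits = []
    for (f, tr), col in zip(feat_items, xcols):
        s = cph.summary.loc[col]
        fits.append(
            SurvivalFit(
                feature=f,
                transform=tr,
                endpoint=endpoint.upper(),
                hr=float(s["exp(coef)"]),
                ci_low=float(s["exp(coef) lower 95%"]),
                ci_high=float(s["exp(coef) upper 95%"]),
                wald_p=float(s["p"]),
                lr_p=lr_p,
                n=len(df),
                n_events=n_events,
            )
        )
    return fits


def univariate_battery(
    data: pd.DataFrame,
    features: dict[str, str],
    endpoints: tuple[str, ...] = ENDPOINTS,
    cluster_by: str | None = None,
) -> pd.DataFrame:
    """Univariate fits of each feature (name -> transform) per endpoint."""
    rows = []
    for ep in endpoints:
        for f, tr in features.items():
            try:
                fit = fit_cox(data, f, tr, ep, cluster_by=cluster_by)
            except ValueError as exc:
                rows.append(
                    {"endpoint": ep, "feature": f, "transform": tr, "flags": str(exc)}
                )
                continue
            rows.append(
                {
                    "endpoint": ep,
                    "feature": f,
                    "transform": tr,
                    "hr": fit.hr,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                    "wald_p": fit.wald_p,
                    "lr_p": fit.lr_p,
                    "n": fit.n,
                    "n_events": fit.n_events,
                    "flags": fit.flags,
                }
            )
    return pd.DataFrame(rows)


def km_analysis(
    data: pd.DataFrame,
    group_col: str,
    endpoint: str = "MACE",
) -> tuple[pd.DataFrame, float | None]:
    """Kaplan-Meier curves per group plus the Cox LR test of the group term.

    Returns ``(curves, lr_p)`` with curves columns group, time, at_risk,
    survival.  With a single group, curves are returned and the test is
    not applicable (p is None).  With no events, all curves are constant
    at 1.0 and p is NaN.
    """
    time_col, event_col = endpoint_columns(endpoint)
    df = data.dropna(subset=[group_col, time_col, event_col])
    groups = sorted(df[group_col].unique(), key=str)
    frames = []
    for g in groups:
        sub = df[df[group_col] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        et = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        frames.append(
            pd.DataFrame(
                {
                    "group": str(g),
                    "time": surv.index.to_numpy(float),
                    "at_risk": et["at_risk"].reindex(surv.index).to_numpy(float),
                    "survival": surv.to_numpy(float),
                }
            )
        )
    curves = pd.concat(frames, ignore_index=True)
    if len(groups) < 2:
        return curves, None
    if df[event_col].sum() == 0:
        return curves, float("nan")
    dummies = pd.get_dummies(df[group_col].astype(str), prefix="g", drop_first=True)
    fit_df = pd.concat(
        [df[[time_col, event_col]].reset_index(drop=True), dummies.astype(float).reset_index(drop=True)],
        axis=1,
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(fit_df, time_col, event_col)
    return curves, float(cph.log_likelihood_ratio_test().p_value)


def median_followup(
    data: pd.DataFrame,
    endpoint: str = "MACE",
) -> dict[str, float]:
    """Median follow-up (months) by reverse Kaplan-Meier, with 95% CI.

    Censoring is treated as the event of interest, so patients are
    "at risk of being followed" until their event removes them.
    """
    time_col, event_col = endpoint_columns(endpoint)
    df = data.dropna(subset=[time_col, event_col])
    if df.empty:
        raise ValueError("no follow-up times")
    kmf = KaplanMeierFitter()
    kmf.fit(df[time_col], 1 - df[event_col])
    ci = median_survival_times(kmf.confidence_interval_)
    return {
        "median": float(kmf.median_survival_time_),
        "ci_low": float(ci.iloc[0, 0]),
        "ci_high": float(ci.iloc[0, 1]),
    }


def adjust_ntprobnp(measured, gfr, rules: BiomarkerRules | None = None):
    """GFR-adjusted NTproBNP: measured / exp(a - b * GFR).

    At the default a = 1.892, b = 0.025 the exponent vanishes at
    GFR = 75.68 ml/min, where adjusted equals measured; the adjustment
    increases monotonically with GFR.  Accepts scalars or arrays.
    """
    rules = (rules or BiomarkerRules()).validate()
    measured = np.asarray(measured, dtype=float)
    gfr = np.asarray(gfr, dtype=float)
    if np.any(measured < 0):
        raise ValueError("measured NTproBNP must be >= 0")
    if np.any(gfr <= 0):
        raise ValueError("GFR must be > 0")
    out = measured / np.exp(rules.ntprobnp_a - rules.ntprobnp_b * gfr)
    return float(out) if out.ndim == 0 else out


def define_subcohorts(
    patients: pd.DataFrame, rules: BiomarkerRules
) -> pd.DataFrame:
    """Label biomarker-defined subcohorts.

    tnt_class: "tnt_pos" iff cTnT strictly > rules.tnt_cutoff (pg/ml),
    else "tnt_neg"; bnp_class: "bnp_pos" iff GFR-adjusted NTproBNP >= the
    patient's age-band cutoff.  Patients with missing inputs come back
    "unclassified".  The age-band table is mandatory for NTproBNP
    subcohorting; bands map inclusive upper age bounds to cutoffs.
    """
    rules.validate()
    if rules.age_cutoff_table is None:
        raise ConfigurationError(
            "BiomarkerRules.age_cutoff_table is required for NTproBNP subcohorts; "
            "no default values are assumed"
        )
    bands = sorted(rules.age_cutoff_table.items())

    def _bnp_cutoff(age: float) -> float | None:
        for upper, cut in bands:
            if age <= upper:
                return cut
        return None

    rows = []
    for _, p in patients.iterrows():
        tnt = p.get("ctnt", np.nan)
        tnt_class = (
            "unclassified"
            if pd.isna(tnt)
            else ("tnt_pos" if tnt > rules.tnt_cutoff else "tnt_neg")
        )
        age, gfr, bnp = p.get("age", np.nan), p.get("gfr", np.nan), p.get("ntprobnp", np.nan)
        if pd.isna(age) or pd.isna(gfr) or pd.isna(bnp):
            bnp_class = "unclassified"
        else:
            cut = _bnp_cutoff(float(age))
            if cut is None:
                bnp_class = "unclassified"
            else:
                adj = adjust_ntprobnp(float(bnp), float(gfr), rules)
                bnp_class = "bnp_pos" if adj >= cut else "bnp_neg"
        rows.append(
            {
                "patient_id": p["patient_id"],
                "tnt_class": tnt_class,
                "bnp_class": bnp_class,
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "tnt_class", "bnp_class"])
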