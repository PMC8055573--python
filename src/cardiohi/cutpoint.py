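"""Optimal-cutoff search for prognostic dichotomization of the HI.

The scan walks incremental candidate cutoffs — the midpoints between
consecutive distinct observed HI values — and, at each candidate, fits a
Cox proportional-hazards model of the chosen endpoint on the high/low
indicator.  In ``well_level`` mode (the default) every well-wise HI value
contributes a row and the Wald test uses a sandwich variance clustered by
patient, accounting for the correlation of replicate wells; in
``patient_level`` mode one row per patient (median HI) is used.  The
selected cutoff minimizes the two-sided Wald p over admissible candidates
(both patient groups at least ``min_group_frac`` of the cohort).

The minimized p is reported as-is, with no multiplicity correction: under
the null it is anti-conservative, and a cutoff selected this way is
exploratory.  Patients are classified high iff their median well-wise HI
is >= the selected cutoff.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .survival import endpoint_columns

__all__ = ["CutoffScan", "scan_cutoffs", "select_cutoff", "classify_patients"]

logger = logging.getLogger(__name__)


@dataclass
class CutoffScan:
    """Result of an incremental cutoff scan."""

    endpoint: str
    level: str
    min_group_frac: float
    n_patients: int
    #: columns: candidate, p, n_low, n_high, admissible, flagged
    table: pd.DataFrame = field(repr=False)
    optimal_cutoff: float = np.nan
    optimal_p: float = np.nan


#: |log HR| beyond this is treated as monotone-likelihood separation: the
#: partial likelihood has no interior maximum and the Wald p is meaningless
SEPARATION_LOG_HR = 15.0


def _wald_p_high_low(
    df: pd.DataFrame, time_col: str, event_col: str, cluster: bool
) -> float:
    """Two-sided Wald p for the binary ``high`` covariate in a Cox PH fit.

    Returns NaN for degenerate fits (separation or underflowed p), which
    the scan flags and excludes.
    """
    cph = CoxPHFitter()
    cols = [time_col, event_col, "high"] + (["pid"] if cluster else [])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if cluster:
            cph.fit(df[cols], time_col, event_col, cluster_col="pid")
        else:
            cph.fit(df[cols], time_col, event_col)
    coef = float(cph.summary.loc["high", "coef"])
    p = float(cph.summary.loc["high", "p"])
    if not np.isfinite(coef) or abs(coef) > SEPARATION_LOG_HR or not (0.0 < p <= 1.0):
        return float("nan")
    return p


def scan_cutoffs(
    well_hi: pd.DataFrame,
    outcomes: pd.DataFrame,
    endpoint: str = "MACE",
    min_group_frac: float = 0.1,
    level: str = "well_level",
) -> CutoffScan:
    """Scan incremental HI cutoffs for the best prognostic separation.

    ``well_hi`` needs columns sample_id and hi (one row per well-wise
    value, already restricted to one plasma concentration and HI mode);
    ``outcomes`` is the per-patient outcome table.  Candidates are the
    midpoints between consecutive distinct values of the scanned variable
    (well values or patient medians, by ``level``).  Candidates where a
    fit fails to converge are flagged and excluded from the minimum.
    """
    if level not in ("well_level", "patient_level"):
        raise ValueError(f"level must be 'well_level' or 'patient_level', got {level!r}")
    if not (0.0 <= min_group_frac < 0.5):
        raise ValueError("min_group_frac must be in [0, 0.5)")
    time_col, event_col = endpoint_columns(endpoint)

    medians = well_hi.groupby("sample_id")["hi"].median()
    missing = set(medians.index) - set(outcomes["patient_id"])
    if missing:
        raise ValueError(f"no outcome row for sample {sorted(missing)[0]!r}")
    out_idx = outcomes.set_index("patient_id")
    n_events = int(out_idx.loc[medians.index, event_col].sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 {endpoint} events for a cutoff scan, got {n_events}")
    n_patients = len(medians)

    if level == "well_level":
        fit_df = pd.DataFrame(
            {
                "pid": well_hi["sample_id"].to_numpy(),
                "value": well_hi["hi"].to_numpy(float),
            }
        )
    else:
        fit_df = pd.DataFrame(
            {"pid": medians.index.to_numpy(), "value": medians.to_numpy(float)}
        )
    fit_df[time_col] = out_idx.loc[fit_df["pid"], time_col].to_numpy(float)
    fit_df[event_col] = out_idx.loc[fit_df["pid"], event_col].to_numpy(int)

    values = np.sort(fit_df["value"].unique())
    if len(values) < 2:
        raise ValueError("need >= 2 distinct HI values to form candidate cutoffs")
    candidates = (values[:-1] + values[1:]) / 2.0

    min_group = min_group_frac * n_patients
    med_vals = medians.to_numpy(float)
    rows: list[dict] = []
    for c in candidates:
        n_high = int((med_vals >= c).sum())
        n_low = n_patients - n_high
        admissible = min(n_low, n_high) >= min_group
        p = np.nan
        flagged = False
        if admissible:
            fit_df["high"] = (fit_df["value"] >= c).astype(float)
            if fit_df["high"].nunique() < 2:
                flagged = True
            else:
                try:
                    p = _wald_p_high_low(
                        fit_df, time_col, event_col, cluster=(level == "well_level")
                    )
                except (ConvergenceError, Exception) as exc:  # noqa: BLE001
                    flagged = True
                    logger.warning("cutoff %.6g: fit failed (%s); excluded", c, exc)
                if np.isnan(p) and not flagged:
                    flagged = True
                    logger.info("cutoff %.6g: degenerate fit (separation); excluded", c)
        rows.append(
            {
                "candidate": float(c),
                "p": p,
                "n_low": n_low,
                "n_high": n_high,
                "admissible": admissible,
                "flagged": flagged,
            }
        )

    table = pd.DataFrame(rows)
    scan = CutoffScan(
        endpoint=endpoint,
        level=level,
        min_group_frac=min_group_frac,
        n_patients=n_patients,
        table=table,
    )
    usable = table[table["admissible"] & ~table["flagged"] & table["p"].notna()]
    if not usable.empty:
        scan.optimal_cutoff = select_cutoff(scan)
        scan.optimal_p = float(
            usable.loc[usable["candidate"] == scan.optimal_cutoff, "p"].iloc[0]
        )
    return scan


def select_cutoff(scan: CutoffScan) -> float:
    """Argmin-p cutoff over admissible candidates; ties -> smaller cutoff."""
    usable = scan.table[
        scan.table["admissible"] & ~scan.table["flagged"] & scan.table["p"].notna()
    ]
    if usable.empty:
        raise ValueError("no admissible cutoff")
    pmin = usable["p"].min()
    return float(usable.loc[usable["p"] == pmin, "candidate"].min())


def classify_patients(
    patient_hi: pd.Series | pd.DataFrame, cutoff: float
) -> pd.Series:
    """Classify patients as "high" (median HI >= cutoff) or "low".

    Accepts a Series indexed by patient or a frame with sample_id /
    patient_hi columns.  Missing values yield "unclassifiable" rather
    than silently dropping the patient.  Warns when the classification is
    degenerate (a single group).
    """
    if isinstance(patient_hi, pd.DataFrame):
        patient_hi = patient_hi.set_index("sample_id")["patient_hi"]
    vals = patient_hi.astype(float)
    labels = pd.Series(
        np.where(vals >= cutoff, "high", "low"), index=vals.index, name="hi_class"
    )
    labels[vals.isna()] = "unclassifiable"
    classified = labels[labels != "unclassifiable"]
    if len(classified) > 0 and classified.nunique() == 1:
        warnings.warn(
            f"all classified patients fall in the {classified.iloc[0]!r} group "
            f"at cutoff {cutoff:.6g}",
            stacklevel=2,
        )
    return labels
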