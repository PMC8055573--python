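"""Plate normalization and the Hypertrophic Index (HI).

Well mean areas are first expressed as a percentage of the plate's FCS
control mean (FCS = 100), removing plate-to-plate scale effects.  The HI
of a PE-stimulated well is the relative growth over the matching
unstimulated condition of the same sample, plasma concentration and
experiment:

    linear mode:  HI = (S - U) / U
    log mode:     HI = (ln S - ln U) / ln U

where S is the PE well's normalized size and U the experiment-level mean
of the sample's unstimulated normalized sizes.  The log form is the one
used for inference; because sizes sit on the percent-of-FCS scale,
ln U ~ ln 100 is comfortably positive and the ratio is numerically
stable.  The logarithm base cancels in the ratio, so any base gives the
same HI.

A patient-level HI per sample x plasma concentration is the median of the
well-wise values (up to experiments x wells-per-condition of them, 12 at
the default design).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["normalize_to_fcs", "well_hi", "patient_hi", "hi_table"]

logger = logging.getLogger(__name__)


def normalize_to_fcs(wells: pd.DataFrame) -> pd.DataFrame:
    """Add ``norm_area_pct``: well mean area as percent of plate FCS mean.

    The FCS reference of a plate is the mean of its retained FCS wells'
    mean areas, so the FCS wells of a plate map to 100 on average exactly.
    Raises if any plate has no retained FCS well.
    """
    out = wells.copy()
    fcs = out[out["plasma_source"] == "FCS"]
    fcs_mean = fcs.groupby("plate_id")["mean_area"].mean()
    missing = set(out["plate_id"]) - set(fcs_mean.index)
    if missing:
        raise ValueError(
            f"plate {sorted(missing)[0]!r} has no retained FCS control well"
        )
    out["norm_area_pct"] = 100.0 * out["mean_area"] / out["plate_id"].map(fcs_mean)
    return out


def well_hi(norm_wells: pd.DataFrame, mode: str = "log") -> pd.DataFrame:
    """Well-wise HI: one row per retained PE well.

    Within each (sample, plasma_pct, experiment), U is the mean of the
    unstimulated wells' ``norm_area_pct``; every PE well S contributes one
    HI value.  Experiments without an unstimulated well contribute
    nothing; samples with no usable experiment at a concentration are
    excluded with a log entry.

    Returns columns: sample_id, plasma_pct, experiment_id, well_id, mode, hi.
    """
    if mode not in ("log", "linear"):
        raise ValueError(f"mode must be 'log' or 'linear', got {mode!r}")
    pat = norm_wells[norm_wells["plasma_source"] != "FCS"]
    rows: list[dict] = []
    for (sid, pct), g in pat.groupby(["sample_id", "plasma_pct"], sort=True):
        n_before = len(rows)
        for exp, ge in g.groupby("experiment_id"):
            unstim = ge.loc[ge["pe"] == 0, "norm_area_pct"]
            stim = ge[ge["pe"] == 1]
            if unstim.empty or stim.empty:
                continue
            u = float(unstim.mean())
            for _, w in stim.iterrows():
                s = float(w["norm_area_pct"])
                if mode == "linear":
                    hi = (s - u) / u
                else:
                    hi = (np.log(s) - np.log(u)) / np.log(u)
                rows.append(
                    {
                        "sample_id": sid,
                        "plasma_pct": pct,
                        "experiment_id": exp,
                        "well_id": w["well_id"],
                        "mode": mode,
                        "hi": hi,
                    }
                )
        if len(rows) == n_before:
            logger.warning(
                "sample %s at %s%% plasma has no experiment with both PE and "
                "unstimulated wells; excluded from HI",
                sid,
                pct,
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "plasma_pct", "experiment_id", "well_id", "mode", "hi"],
    )


def patient_hi(hi_records: pd.DataFrame) -> pd.DataFrame:
    """Patient-level HI: median of well-wise values per sample x pct x mode.

    With an even number of wells the median is the mean of the two central
    values.  Returns sample_id, plasma_pct, mode, n_wells,
    n_experiments_used, patient_hi.
    """
    if hi_records.empty:
        raise ValueError("no well-wise HI values to aggregate")
    agg = (
        hi_records.groupby(["sample_id", "plasma_pct", "mode"])
        .agg(
            n_wells=("hi", "size"),
            n_experiments_used=("experiment_id", "nunique"),
            patient_hi=("hi", "median"),
        )
        .reset_index()
    )
    return agg


def hi_table(norm_wells: pd.DataFrame, mode: str = "log") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: well-wise and patient-level HI in one call."""
    wh = well_hi(norm_wells, mode=mode)
    return wh, patient_hi(wh)
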