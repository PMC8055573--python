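"""Single-cell vitality QC and aggregation to per-well mean sizes.

Cells pass QC when the cell-to-nucleus area ratio is at least
``ratio_min`` (inclusive, default 1.5) and the nuclear stain intensity is
adequate.  "Adequate" defaults to plate-local robust bounds — the median
+/- ``dapi_mad_k`` raw MADs of the intensities measured in that plate's
FCS control wells — and can be overridden with absolute bounds.

Filtering is pure flagging: no measurement value is altered and no row is
silently dropped; rejected cells and dropped wells are accounted for in
returned log tables.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import QCParams

__all__ = [
    "apply_cell_filters",
    "aggregate_to_wells",
    "retention_summary",
    "plate_dapi_bounds",
]

LAYOUT_COLS = [
    "well_id",
    "plate_id",
    "experiment_id",
    "sample_id",
    "plasma_source",
    "plasma_pct",
    "pe",
]


def plate_dapi_bounds(
    cells: pd.DataFrame, layout: pd.DataFrame, k: float = 3.0
) -> pd.DataFrame:
    """Robust per-plate DAPI bounds from FCS control wells.

    Returns a frame indexed by plate_id with columns dapi_low/dapi_high =
    median -/+ k * MAD, where MAD is the raw (unscaled) median absolute
    deviation of the plate's FCS-well intensities.
    """
    fcs_wells = layout.loc[layout["plasma_source"] == "FCS", ["well_id", "plate_id"]]
    fcs_cells = cells.merge(fcs_wells, on="well_id", how="inner")
    if fcs_cells.empty:
        raise ValueError("no FCS control cells found; cannot derive DAPI bounds")

    def _bounds(x: pd.Series) -> pd.Series:
        med = x.median()
        mad = (x - med).abs().median()
        return pd.Series({"dapi_low": med - k * mad, "dapi_high": med + k * mad})

    return fcs_cells.groupby("plate_id")["dapi_intensity"].apply(_bounds).unstack()


def apply_cell_filters(
    cells: pd.DataFrame,
    params: QCParams | None = None,
    layout: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flag each cell with ``passes_qc`` and a ``qc_reason``.

    passes_qc is True iff area_cell/area_nucleus >= ratio_min AND
    dapi_low <= dapi_intensity <= dapi_high.  Rows with non-positive areas
    are rejected with reason "invalid_area" rather than raising, so a bad
    segmentation does not take down a run.  ``layout`` is required when
    the intensity bounds are plate-local (the default).
    """
    params = (params or QCParams()).validate()
    out = cells.copy()
    area_ok = (out["area_cell"] > 0) & (out["area_nucleus"] > 0)
    ratio = np.where(area_ok, out["area_cell"] / np.where(area_ok, out["area_nucleus"], 1.0), np.nan)

    if params.dapi_low is not None and params.dapi_high is not None:
        lo = np.full(len(out), float(params.dapi_low))
        hi = np.full(len(out), float(params.dapi_high))
    else:
        if layout is None:
            raise ValueError(
                "layout is required to derive per-plate DAPI bounds; "
                "pass absolute dapi_low/dapi_high to avoid it"
            )
        bounds = plate_dapi_bounds(cells, layout, k=params.dapi_mad_k)
        plate_of = layout.set_index("well_id")["plate_id"]
        plates = out["well_id"].map(plate_of)
        if plates.isna().any():
            missing = out.loc[plates.isna(), "well_id"].iloc[0]
            raise KeyError(f"well {missing!r} not present in layout")
        lo = plates.map(bounds["dapi_low"]).to_numpy(float)
        hi = plates.map(bounds["dapi_high"]).to_numpy(float)

    ratio_ok = area_ok & (ratio >= params.ratio_min)
    dapi_ok = (out["dapi_intensity"] >= lo) & (out["dapi_intensity"] <= hi)
    out["passes_qc"] = (ratio_ok & dapi_ok).to_numpy()

    reason = np.full(len(out), "", dtype=object)
    reason[~dapi_ok.to_numpy()] = "dapi_out_of_range"
    reason[~ratio_ok.to_numpy()] = "ratio_below_min"
    reason[~area_ok.to_numpy()] = "invalid_area"
    reason[out["passes_qc"].to_numpy()] = ""
    out["qc_reason"] = reason
    return out


def aggregate_to_wells(
    cells: pd.DataFrame,
    layout: pd.DataFrame,
    params: QCParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate QC-passing cells to per-well arithmetic mean areas.

    Returns ``(wells, drop_log)``.  ``wells`` has the layout columns plus
    n_cells_retained and mean_area, restricted to wells retaining at
    least ``min_cells_per_well`` cells.  ``drop_log`` lists every well of
    the layout that was dropped, with a reason ("empty" or "too_few_cells")
    and the retained count.
    """
    params = (params or QCParams()).validate()
    if "passes_qc" not in cells:
        raise ValueError("cells lack passes_qc; run apply_cell_filters first")
    unknown = set(cells["well_id"]) - set(layout["well_id"])
    if unknown:
        raise KeyError(f"well {sorted(unknown)[0]!r} in cells is absent from layout")

    retained = cells[cells["passes_qc"]]
    agg = (
        retained.groupby("well_id")["area_cell"]
        .agg(n_cells_retained="size", mean_area="mean")
        .reset_index()
    )
    wells = layout[LAYOUT_COLS].merge(agg, on="well_id", how="left")
    wells["n_cells_retained"] = wells["n_cells_retained"].fillna(0).astype(int)

    ok = wells["n_cells_retained"] >= params.min_cells_per_well
    dropped = wells[~ok]
    drop_log = pd.DataFrame(
        {
            "well_id": dropped["well_id"],
            "reason": np.where(
                dropped["n_cells_retained"] == 0, "empty", "too_few_cells"
            ),
            "n_retained": dropped["n_cells_retained"],
        }
    ).reset_index(drop=True)
    return wells[ok].reset_index(drop=True), drop_log


def retention_summary(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-sample replicate retention after QC.

    An experiment is usable for a sample when it retains at least one PE
    and one unstimulated well (any plasma concentration).  Samples with
    fewer than three usable experiments are flagged; samples with none
    are excluded from downstream analysis.
    """
    pat = wells[wells["plasma_source"] != "FCS"]
    rows = []
    for sid, g in pat.groupby("sample_id"):
        usable = 0
        for _, ge in g.groupby("experiment_id"):
            if (ge["pe"] == 1).any() and (ge["pe"] == 0).any():
                usable += 1
        if usable == 0:
            flag = "no_usable_experiment"
        elif usable == 1:
            flag = "single-experiment"
        elif usable == 2:
            flag = "two-experiments"
        else:
            flag = ""
        rows.append(
            {
                "sample_id": sid,
                "n_wells_retained": len(g),
                "n_experiments_usable": usable,
                "flag": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "n_wells_retained", "n_experiments_usable", "flag"],
    )
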