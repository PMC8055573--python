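"""Deterministic end-to-end pipeline runner.

Stage order: simulate (or load) -> qc -> normalize -> hi -> cutoff ->
survival -> group_stats -> report.  Every stage's table is written to the
output directory; summary.json carries the headline numbers (optimal
cutoff, group sizes, hazard ratios, group HI estimates, median follow-up)
and manifest.json the config, seed and artifact checksums.  Identical
config + seed reproduces every file byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import sys
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .cutpoint import classify_patients, scan_cutoffs
from .group_stats import cohort_table_tests, mixed_model_cellsize
from .hi import hi_table, normalize_to_fcs
from .io import read_tables, write_results
from .qc import aggregate_to_wells, apply_cell_filters, retention_summary
from .survival import (
    adjust_ntprobnp,
    define_subcohorts,
    endpoint_columns,
    fit_cox,
    fit_cox_multivariate,
    km_analysis,
    median_followup,
    univariate_battery,
)
from .synthetic import generate_dataset

__all__ = ["run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "hi", "cutoff", "survive", "groupstats", "report")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | None = None,
    stop_after: str = "report",
) -> dict[str, Any]:
    """Run the pipeline and write the report bundle.

    Returns a dict with the in-memory tables, the cutoff scan and the
    summary.  ``stop_after`` truncates the run after the named stage
    (tables computed so far are still written).
    """
    config.validate()
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; expected one of {STAGES}")
    out_dir = out_dir or config.out_dir
    stop = STAGES.index(stop_after)
    bundle: dict[str, pd.DataFrame] = {}
    summary: dict[str, Any] = {}

    # -- simulate / load --------------------------------------------------
    if config.input_dir is None:
        logger.info("simulating synthetic cohort (seed=%d)", config.seed)
        tables = generate_dataset(config.sim, config.seed)
    else:
        logger.info("loading input tables from %s", config.input_dir)
        tables = read_tables(config.input_dir)
    bundle.update(tables)
    patients, layout = tables["patients"], tables["wells"]
    cells, outcomes = tables["cells"], tables["outcomes"]
    summary["n_patients"] = int(len(patients))
    summary["n_wells"] = int(len(layout))
    summary["n_cells"] = int(len(cells))

    try:
        if stop >= 1:
            # -- qc --------------------------------------------------------
            flagged = apply_cell_filters(cells, config.qc, layout)
            wells_qc, drop_log = aggregate_to_wells(flagged, layout, config.qc)
            retention = retention_summary(wells_qc)
            bundle["wells_qc"] = wells_qc
            bundle["qc_drop_log"] = drop_log
            bundle["retention"] = retention
            summary["qc"] = {
                "n_cells_retained": int(flagged["passes_qc"].sum()),
                "n_wells_retained": int(len(wells_qc)),
                "n_wells_dropped": int(len(drop_log)),
            }

        if stop >= 2:
            # -- normalize + HI ---------------------------------------------
            norm = normalize_to_fcs(wells_qc)
            bundle["wells_norm"] = norm
            hi_frames, pat_frames = [], []
            for mode in ("log", "linear"):
                wh, ph = hi_table(norm, mode=mode)
                hi_frames.append(wh)
                pat_frames.append(ph)
            hi_wells = pd.concat(hi_frames, ignore_index=True)
            hi_patients = pd.concat(pat_frames, ignore_index=True)
            bundle["hi"] = hi_wells
            bundle["hi_patient"] = hi_patients

        if stop >= 3:
            # -- cutoff scan -------------------------------------------------
            sel = hi_wells[
                (hi_wells["mode"] == config.hi_mode)
                & (hi_wells["plasma_pct"] == config.hi_plasma_pct)
            ]
            scan = scan_cutoffs(
                sel,
                outcomes,
                endpoint=config.cutoff_endpoint,
                min_group_frac=config.cutoff_min_group_frac,
                level=config.cutoff_level,
            )
            bundle["cutoff_scan"] = scan.table
            pat_sel = hi_patients[
                (hi_patients["mode"] == config.hi_mode)
                & (hi_patients["plasma_pct"] == config.hi_plasma_pct)
            ]
            labels = classify_patients(pat_sel, scan.optimal_cutoff)
            n_low = int((labels == "low").sum())
            n_high = int((labels == "high").sum())
            summary["cutoff"] = {
                "endpoint": scan.endpoint,
                "level": scan.level,
                "mode": config.hi_mode,
                "plasma_pct": config.hi_plasma_pct,
                "optimal_cutoff": float(scan.optimal_cutoff),
                "optimal_cutoff_pct": float(100.0 * scan.optimal_cutoff),
                "optimal_p": float(scan.optimal_p),
                "n_low": n_low,
                "n_high": n_high,
            }

        if stop >= 4:
            # -- survival ----------------------------------------------------
            surv = patients.merge(outcomes, on="patient_id", how="inner").copy()
            surv["hi_class"] = surv["patient_id"].map(labels)
            surv["ntprobnp_adj"] = adjust_ntprobnp(
                surv["ntprobnp"].to_numpy(), surv["gfr"].to_numpy(), config.biomarkers
            )
            classified = surv[surv["hi_class"].isin(["high", "low"])]

            fu = median_followup(surv, endpoint="MACE")
            summary["median_followup_months"] = fu
            summary["n_events"] = {
                ep: int(surv[endpoint_columns(ep)[1]].sum()) for ep in ("HTX", "DMP", "MACE")
            }

            km_frames = []
            hi_hrs: dict[str, Any] = {}
            for ep in ("MACE", "DMP", "HTX"):
                curves, lr_p = km_analysis(classified, "hi_class", endpoint=ep)
                curves.insert(0, "endpoint", ep)
                km_frames.append(curves)
                fit = fit_cox(classified, "hi_class", "dichotomous", ep)
                hi_hrs[ep] = {
                    "hr_high_vs_low": fit.hr,
                    "ci95": [fit.ci_low, fit.ci_high],
                    "wald_p": fit.wald_p,
                    "km_lr_p": lr_p,
                    "n": fit.n,
                    "n_events": fit.n_events,
                }
            bundle["km_curves"] = pd.concat(km_frames, ignore_index=True)
            summary["hi_prognosis"] = hi_hrs

            features = {
                "hi_class": "dichotomous",
                "ntprobnp": "log",
                "ntprobnp_adj": "log",
                "ctnt": "log",
                "gfr": "none",
                "age": "none",
                "sex": "dichotomous",
            }
            bundle["survival_univariate"] = univariate_battery(classified, features)
            multi = fit_cox_multivariate(
                classified,
                {
                    "hi_class": "dichotomous",
                    "ntprobnp_adj": "log",
                    "ctnt": "log",
                    "gfr": "none",
                    "age": "none",
                    "sex": "dichotomous",
                },
                endpoint="MACE",
            )
            bundle["survival_multivariate"] = pd.DataFrame(
                [dataclasses.asdict(f) for f in multi]
            )

            # biomarker-defined subcohorts (cTnT always; NTproBNP only when
            # the age-band cutoff table is configured)
            sub_summary = {}
            if config.biomarkers.age_cutoff_table is not None:
                sub = define_subcohorts(patients, config.biomarkers)
                surv2 = classified.merge(sub, on="patient_id")
                pairs = [("tnt_class", "tnt_pos"), ("tnt_class", "tnt_neg"),
                         ("bnp_class", "bnp_pos"), ("bnp_class", "bnp_neg")]
            else:
                sub = patients[["patient_id", "ctnt"]].copy()
                sub["tnt_class"] = np.where(
                    sub["ctnt"] > config.biomarkers.tnt_cutoff, "tnt_pos", "tnt_neg"
                )
                surv2 = classified.merge(
                    sub[["patient_id", "tnt_class"]], on="patient_id"
                )
                pairs = [("tnt_class", "tnt_pos"), ("tnt_class", "tnt_neg")]
            for col, lvl in pairs:
                grp = surv2[surv2[col] == lvl]
                if grp["hi_class"].nunique() < 2 or grp["event_mace"].sum() < 2:
                    sub_summary[lvl] = {"km_lr_p": None, "n": int(len(grp))}
                    continue
                _, p = km_analysis(grp, "hi_class", endpoint="MACE")
                sub_summary[lvl] = {"km_lr_p": p, "n": int(len(grp))}
            summary["subcohorts"] = sub_summary

        if stop >= 5:
            # -- group stats -------------------------------------------------
            lin = hi_wells[
                (hi_wells["mode"] == "linear")
                & (hi_wells["plasma_pct"] == config.hi_plasma_pct)
            ].merge(
                patients[["patient_id", "group"]],
                left_on="sample_id",
                right_on="patient_id",
            )
            contrasts = mixed_model_cellsize(lin, value_col="hi", reference="Ctrl")
            bundle["group_contrasts"] = pd.DataFrame(
                [dataclasses.asdict(c) for c in contrasts]
            )
            summary["group_hi_pct"] = {
                c.group: {
                    "estimate": 100.0 * c.estimate,
                    "se": 100.0 * c.se,
                    "p_vs_reference": None if math.isnan(c.p_vs_reference) else c.p_vs_reference,
                }
                for c in contrasts
            }
            bundle["cohort_tests"] = cohort_table_tests(
                patients,
                {
                    "sex": "categorical",
                    "age": "continuous",
                    "gfr": "continuous",
                    "ctnt": "continuous",
                    "ntprobnp": "continuous",
                },
            )
            summary["cohort_tests"] = {
                r["variable"]: {"test": r["test"], "p": r["p"]}
                for _, r in bundle["cohort_tests"].iterrows()
            }
    except Exception as exc:
        stage = _current_stage(bundle)
        logger.error("pipeline aborted in stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    write_results(
        bundle,
        out_dir,
        summary=summary,
        manifest_extra={
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "versions": {
                "cardiohi": __version__,
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        },
    )
    result: dict[str, Any] = {"tables": bundle, "summary": summary, "out_dir": out_dir}
    if stop >= 3:
        result["scan"] = scan
        result["labels"] = labels
    return result


def _current_stage(bundle: dict) -> str:
    if "group_contrasts" in bundle:
        return "report"
    if "km_curves" in bundle:
        return "groupstats"
    if "cutoff_scan" in bundle:
        return "survive"
    if "hi" in bundle:
        return "cutoff"
    if "wells_norm" in bundle:
        return "hi"
    if "wells_qc" in bundle:
        return "hi"
    return "qc"
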