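"""Seeded synthetic cohorts, plate data and time-to-event outcomes.

The generator emulates the hierarchical structure of a plasma-treatment
hypertrophy assay: each subject's plasma is applied to neonatal rat
cardiomyocytes at two concentrations, with and without phenylephrine (PE),
in quadruplicate wells across three independent experiments; every plate
carries fetal-calf-serum (FCS) control wells used for per-plate
normalization.  A patient-level latent relative growth ("latent HI") links
the cell-level data to outcomes: PE multiplies the median cell area by
``1 + latent_hi``, and patients whose latent HI falls below a generative
threshold carry an elevated event hazard.

Everything is deterministic given (config, seed): stage streams are spawned
from a single :class:`numpy.random.SeedSequence`.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import GROUPS, ConfigurationError, SimConfig

__all__ = [
    "generate_patients",
    "generate_plate_data",
    "generate_outcomes",
    "generate_dataset",
]

# stage tags keep the per-stage RNG streams independent of one another
_STAGE_PATIENTS = 1
_STAGE_PLATES = 2
_STAGE_OUTCOMES = 3
_STAGE_PLATE_EFFECTS = 4


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _lognormal_from_mean_sd(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Draw a lognormal sample matching a target mean and SD (> 0)."""
    if sd <= 0:
        return np.full(size, mean)
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def generate_patients(config: SimConfig, seed: int) -> pd.DataFrame:
    """Generate the patient table: one row per subject.

    Columns: patient_id, group, age (years), sex (M/F), gfr (ml/min),
    ctnt (pg/ml), ntprobnp (pg/ml), latent_hi (dimensionless).

    Group sizes come from ``config.group_sizes``; latent HI is normal
    around the group mean with SD ``config.latent_sd``.  Biomarkers are
    drawn from distributions matched to the configured per-group
    mean/SE summaries (SE -> SD via sqrt(n)); strictly positive markers
    use lognormals so their positivity invariants hold.
    """
    config.validate()
    rng = _rng(seed, _STAGE_PATIENTS)
    bp = config.biomarker_params
    rows: list[dict] = []
    idx = 0
    for group in GROUPS:  # fixed iteration order => deterministic ids
        n = int(config.group_sizes.get(group, 0))
        if n == 0:
            continue
        latent = rng.normal(config.group_hi_latent[group], config.latent_sd, n)
        age_m, age_se = bp["age"][group]
        age = np.clip(rng.normal(age_m, age_se * math.sqrt(n), n), 19.0, 89.0)
        male_frac = bp["male_frac"][group][0]
        sex = np.where(rng.random(n) < male_frac, "M", "F")
        gfr_m, gfr_se = bp["gfr"][group]
        gfr = _lognormal_from_mean_sd(rng, gfr_m, gfr_se * math.sqrt(n), n)
        tnt_m, tnt_se = bp["ctnt"][group]
        ctnt = _lognormal_from_mean_sd(rng, tnt_m, tnt_se * math.sqrt(n), n)
        bnp_m, bnp_se = bp["ntprobnp"][group]
        ntprobnp = _lognormal_from_mean_sd(rng, bnp_m, bnp_se * math.sqrt(n), n)
        for i in range(n):
            rows.append(
                {
                    "patient_id": f"P{idx + i + 1:03d}",
                    "group": group,
                    "age": float(age[i]),
                    "sex": str(sex[i]),
                    "gfr": float(gfr[i]),
                    "ctnt": float(ctnt[i]),
                    "ntprobnp": float(ntprobnp[i]),
                    "latent_hi": float(latent[i]),
                }
            )
        idx += n
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "group",
            "age",
            "sex",
            "gfr",
            "ctnt",
            "ntprobnp",
            "latent_hi",
        ],
    )


def _plate_layout(patients: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Assign wells to plates: one plate per (experiment, sample batch)."""
    sample_ids = list(patients["patient_id"])
    source = {
        pid: ("control_subject" if grp == "Ctrl" else "patient")
        for pid, grp in zip(patients["patient_id"], patients["group"])
    }
    batches = [
        sample_ids[i : i + config.samples_per_plate]
        for i in range(0, len(sample_ids), config.samples_per_plate)
    ]
    rows: list[dict] = []
    for exp in range(1, config.n_experiments + 1):
        for b, batch in enumerate(batches, start=1):
            plate_id = f"E{exp}B{b:02d}"
            w = 0
            for _ in range(config.fcs_wells_per_plate):
                w += 1
                rows.append(
                    {
                        "well_id": f"{plate_id}_W{w:03d}",
                        "plate_id": plate_id,
                        "experiment_id": exp,
                        "sample_id": "FCS",
                        "plasma_source": "FCS",
                        "plasma_pct": np.nan,
                        "pe": 0,
                    }
                )
            for pid in batch:
                for pct in sorted(config.plasma_pcts):
                    for pe in (0, 1):
                        for _ in range(config.wells_per_condition):
                            w += 1
                            rows.append(
                                {
                                    "well_id": f"{plate_id}_W{w:03d}",
                                    "plate_id": plate_id,
                                    "experiment_id": exp,
                                    "sample_id": pid,
                                    "plasma_source": source[pid],
                                    "plasma_pct": float(pct),
                                    "pe": pe,
                                }
                            )
    return pd.DataFrame(rows)


def generate_plate_data(
    patients: pd.DataFrame, config: SimConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the well layout and single-cell measurement tables.

    Returns ``(layout, cells)``.  Cell areas are log-normal with a median
    of ``base_cell_area`` scaled by a per-plate multiplicative effect and,
    in PE wells, by the condition effect ``1 + pe_effect_scale * latent_hi``
    (attenuated at 20% plasma).  A ``dead_fraction`` of cells is injected
    as low-quality: inflated nucleus (cell/nucleus ratio < 1.5) and/or
    out-of-range nuclear stain intensity, so downstream QC has something
    to reject.
    """
    config.validate()
    if patients.empty:
        raise ValueError("patients table is empty")
    rng = _rng(seed, _STAGE_PLATES)
    layout = _plate_layout(patients, config)

    latent = dict(zip(patients["patient_id"], patients["latent_hi"]))

    # plate effects come from their own stream so that runs differing only
    # in plate_effect_sd share identical cell-level draws
    rng_pe = _rng(seed, _STAGE_PLATE_EFFECTS)
    plate_ids = layout["plate_id"].unique()
    plate_eff = dict(
        zip(
            plate_ids,
            np.exp(config.plate_effect_sd * rng_pe.standard_normal(len(plate_ids))),
        )
    )

    # per-well median area = base * plate effect * condition effect
    cond_scale = np.ones(len(layout))
    for i, (sid, pct, pe) in enumerate(
        zip(layout["sample_id"], layout["plasma_pct"], layout["pe"])
    ):
        if sid != "FCS" and pe == 1:
            eff = config.pe_effect_scale * latent[sid]
            if pct == 20:
                eff *= config.plasma20_attenuation
            cond_scale[i] = 1.0 + eff
    well_median = (
        config.base_cell_area
        * layout["plate_id"].map(plate_eff).to_numpy()
        * cond_scale
    )

    n_cells = rng.poisson(config.cells_measured_per_well, len(layout))
    n_cells = np.maximum(n_cells, 1)  # a measured well yields at least a cell
    total = int(n_cells.sum())
    well_idx = np.repeat(np.arange(len(layout)), n_cells)

    area_cell = well_median[well_idx] * rng.lognormal(
        0.0, config.area_lognormal_sigma, total
    )
    # live-cell morphology/stain: ratio bounded away from the QC threshold,
    # intensity on bounded support inside the robust per-plate bounds
    ratio = 1.6 + rng.lognormal(math.log(4.0), 0.4, total)
    dapi = rng.uniform(
        config.dapi_center - config.dapi_halfwidth,
        config.dapi_center + config.dapi_halfwidth,
        total,
    )

    dead = rng.random(total) < config.dead_fraction
    n_dead = int(dead.sum())
    if n_dead:
        # (ratio hit, dapi hit) ~ independent Bernoulli(0.7)/(0.5),
        # conditioned on at least one hit
        u = rng.random(n_dead)
        both = u < 0.35 / 0.85
        ratio_only = (u >= 0.35 / 0.85) & (u < 0.70 / 0.85)
        dapi_only = u >= 0.70 / 0.85
        ratio_hit = both | ratio_only
        dapi_hit = both | dapi_only
        dead_ix = np.flatnonzero(dead)
        rh = dead_ix[ratio_hit]
        ratio[rh] = rng.uniform(0.8, 1.45, len(rh))
        dh = dead_ix[dapi_hit]
        low = rng.random(len(dh)) < 0.5
        vals = np.where(
            low,
            rng.uniform(50.0, 200.0, len(dh)),
            rng.uniform(900.0, 1200.0, len(dh)),
        )
        dapi[dh] = vals

    cells = pd.DataFrame(
        {
            "cell_id": [f"C{i + 1:07d}" for i in range(total)],
            "well_id": layout["well_id"].to_numpy()[well_idx],
            "area_cell": area_cell,
            "area_nucleus": area_cell / ratio,
            "dapi_intensity": dapi,
        }
    )
    return layout, cells


def generate_outcomes(
    patients: pd.DataFrame, config: SimConfig, seed: int
) -> pd.DataFrame:
    """Simulate time-to-event outcomes under a proportional-hazards model.

    Two independent exponential clocks (HTX: death/transplantation; DMP:
    decompensation) run per patient with rates ``baseline_event_rate *
    htx_share`` and ``* (1 - htx_share)``.  Patients with
    ``latent_hi >= latent_threshold`` (a preserved hypertrophic response)
    have both rates multiplied by ``hazard_hr_high_vs_low``; everyone is
    administratively censored at the follow-up horizon.  MACE is the
    composite: first of HTX/DMP when either occurs, else the censoring
    time.
    """
    config.validate()
    if "latent_hi" not in patients:
        raise ValueError("patients table lacks latent_hi")
    rng = _rng(seed, _STAGE_OUTCOMES)
    n = len(patients)
    horizon = config.followup_horizon_months
    high = patients["latent_hi"].to_numpy() >= config.latent_threshold
    rr = np.where(high, config.hazard_hr_high_vs_low, 1.0)
    r_htx = config.baseline_event_rate * config.htx_share * rr
    r_dmp = config.baseline_event_rate * (1.0 - config.htx_share) * rr
    t_htx = rng.exponential(1.0 / r_htx)
    t_dmp = rng.exponential(1.0 / r_dmp)
    event_htx = t_htx <= horizon
    event_dmp = t_dmp <= horizon
    time_htx = np.minimum(t_htx, horizon)
    time_dmp = np.minimum(t_dmp, horizon)
    event_mace = event_htx | event_dmp
    time_mace = np.where(
        event_mace, np.minimum(time_htx, time_dmp), horizon
    )
    return pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "time_htx": time_htx,
            "event_htx": event_htx.astype(int),
            "time_dmp": time_dmp,
            "event_dmp": event_dmp.astype(int),
            "time_mace": time_mace,
            "event_mace": event_mace.astype(int),
        }
    )


def generate_dataset(
    config: SimConfig, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Generate all four tables (patients, wells layout, cells, outcomes)."""
    seed = config.seed if seed is None else seed
    patients = generate_patients(config, seed)
    layout, cells = generate_plate_data(patients, config, seed)
    outcomes = generate_outcomes(patients, config, seed)
    return {
        "patients": patients,
        "wells": layout,
        "cells": cells,
        "outcomes": outcomes,
    }
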