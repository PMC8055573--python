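"""Generator contracts: cohort structure, plate hierarchy, outcome model."""
import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from cardiohi.config import ConfigurationError, SimConfig
from cardiohi.qc import apply_cell_filters
from cardiohi.synthetic import (
    generate_dataset,
    generate_outcomes,
    generate_patients,
    generate_plate_data,
)
from conftest import small_sim_config


class TestPatients:
    def test_default_cohort_matches_study_group_sizes(self):
        pats = generate_patients(SimConfig(), seed=0)
        assert len(pats) == 105
        counts = pats["group"].value_counts()
        assert counts["ATTRv-CA"] == 36
        assert counts["ATTRv-PN"] == 23
        assert counts["ATTRwt"] == 30
        assert counts["Ctrl"] == 16

    def test_zero_sizes_give_empty_cohort(self):
        cfg = SimConfig(group_sizes={g: 0 for g in ("Ctrl", "ATTRwt")})
        assert generate_patients(cfg, seed=0).empty

    def test_unknown_group_name_is_a_configuration_error(self):
        cfg = SimConfig(group_sizes={"Ctrl": 5, "ATTRxx": 3})
        with pytest.raises(ConfigurationError, match="ATTRxx"):
            generate_patients(cfg, seed=0)

    def test_biomarker_invariants(self):
        pats = generate_patients(SimConfig(), seed=3)
        assert (pats["gfr"] > 0).all()
        assert (pats[["ctnt", "ntprobnp"]] >= 0).all().all()
        assert pats["sex"].isin(["M", "F"]).all()

    def test_determinism_same_seed_identical(self):
        cfg = small_sim_config()
        assert_frame_equal(generate_patients(cfg, 5), generate_patients(cfg, 5))
        ds1, ds2 = generate_dataset(cfg, 5), generate_dataset(cfg, 5)
        for k in ds1:
            assert_frame_equal(ds1[k], ds2[k])

    def test_different_seeds_differ(self):
        cfg = small_sim_config()
        a, b = generate_patients(cfg, 1), generate_patients(cfg, 2)
        assert not a["latent_hi"].equals(b["latent_hi"])


class TestPlateData:
    def test_single_patient_well_count_follows_layout_rules(self):
        # 2 plasma pcts x 2 PE states x 3 experiments x 4 wells = 48
        cfg = small_sim_config(group_sizes={"Ctrl": 1})
        pats = generate_patients(cfg, 0)
        layout, _ = generate_plate_data(pats, cfg, 0)
        patient_wells = layout[layout["plasma_source"] != "FCS"]
        assert len(patient_wells) == 48
        fcs = layout[layout["plasma_source"] == "FCS"]
        assert len(fcs) == 3 * cfg.fcs_wells_per_plate  # one plate per experiment
        per_plate = fcs.groupby("plate_id").size()
        assert (per_plate >= 4).all()

    def test_hierarchy_every_cell_and_well_resolves(self, small_dataset):
        layout, cells = small_dataset["wells"], small_dataset["cells"]
        assert set(cells["well_id"]) <= set(layout["well_id"])
        pats = set(small_dataset["patients"]["patient_id"]) | {"FCS"}
        assert set(layout["sample_id"]) <= pats
        assert layout["well_id"].is_unique

    def test_dead_fraction_zero_passes_default_qc_entirely(self):
        cfg = small_sim_config(dead_fraction=0.0, group_sizes={"Ctrl": 2})
        pats = generate_patients(cfg, 2)
        layout, cells = generate_plate_data(pats, cfg, 2)
        flagged = apply_cell_filters(cells, layout=layout)
        assert flagged["passes_qc"].all()

    def test_dead_fraction_injects_filterable_cells(self):
        cfg = small_sim_config(dead_fraction=0.2, group_sizes={"Ctrl": 2})
        pats = generate_patients(cfg, 2)
        layout, cells = generate_plate_data(pats, cfg, 2)
        flagged = apply_cell_filters(cells, layout=layout)
        frac = 1.0 - flagged["passes_qc"].mean()
        assert 0.12 < frac < 0.28

    def test_no_plate_effect_equalizes_fcs_means_across_plates(self):
        # ~100 plates via 1 sample per plate; with plate_effect_sd = 0 the
        # spread of FCS well means is pure cell-sampling noise
        cfg = small_sim_config(
            group_sizes={"Ctrl": 17, "ATTRwt": 17},
            samples_per_plate=1,
            cells_measured_per_well=120.0,
            dead_fraction=0.0,
        )
        pats = generate_patients(cfg, 4)

        def fcs_cv(sd):
            cfg2 = small_sim_config(**{**cfg.__dict__, "plate_effect_sd": sd})
            layout, cells = generate_plate_data(pats, cfg2, 4)
            fcs_wells = layout[layout["plasma_source"] == "FCS"]["well_id"]
            m = (
                cells[cells["well_id"].isin(fcs_wells)]
                .groupby("well_id")["area_cell"]
                .mean()
            )
            return m.std() / m.mean()

        # pure sampling noise of the well mean: sqrt(exp(sigma^2)-1)/sqrt(n)
        # ~ 0.42/sqrt(120) ~ 0.038 at the defaults
        assert fcs_cv(0.0) < 0.05
        assert fcs_cv(0.25) > 3 * fcs_cv(0.0)

    def test_zero_wells_per_condition_rejected(self):
        cfg = small_sim_config(wells_per_condition=0)
        pats = generate_patients(small_sim_config(), 0)
        with pytest.raises(ConfigurationError):
            generate_plate_data(pats, cfg, 0)


class TestOutcomes:
    def test_censoring_bound_and_mace_composition(self):
        cfg = small_sim_config(followup_horizon_months=24.0)
        pats = generate_patients(SimConfig(), 9)
        out = generate_outcomes(pats, cfg, 9)
        for col in ("time_htx", "time_dmp", "time_mace"):
            assert (out[col] > 0).all() and (out[col] <= 24.0).all()
        np.testing.assert_array_equal(
            out["event_mace"], out["event_htx"] | out["event_dmp"]
        )
        either = out["event_mace"] == 1
        np.testing.assert_allclose(
            out.loc[either, "time_mace"],
            out.loc[either, ["time_htx", "time_dmp"]].min(axis=1),
        )
        assert (out.loc[~either, "time_mace"] == 24.0).all()

    def test_null_mean_loghr_near_zero(self):
        """Under HR = 1 the estimated log-HR of the generative dichotomy is
        unbiased: mean over replicate cohorts ~ 0."""
        from lifelines import CoxPHFitter

        cfg = SimConfig(hazard_hr_high_vs_low=1.0)
        pats = generate_patients(cfg, 123)
        high = (pats["latent_hi"] >= cfg.latent_threshold).astype(float).to_numpy()
        cph = CoxPHFitter()
        logs = []
        for r in range(500):
            out = generate_outcomes(pats, cfg, 50_000 + r)
            df = pd.DataFrame(
                {"T": out["time_mace"], "E": out["event_mace"], "x": high}
            )
            cph.fit(df, "T", "E")
            logs.append(cph.params_.iloc[0])
        assert abs(np.mean(logs)) < 0.05

    def test_protective_hr_raises_events_in_low_group(self):
        """At the default HR 0.24 the low-latent group has the higher event
        proportion in nearly every replicate cohort."""
        cfg = SimConfig()
        pats = generate_patients(cfg, 7)
        low = (pats["latent_hi"] < cfg.latent_threshold).to_numpy()
        wins = 0
        for r in range(200):
            out = generate_outcomes(pats, cfg, 9_000 + r)
            ev = out["event_mace"].to_numpy()
            wins += ev[low].mean() > ev[~low].mean()
        assert wins >= 190  # >= 95%

    def test_nonpositive_event_rate_rejected(self):
        cfg = small_sim_config(baseline_event_rate=0.0)
        pats = generate_patients(small_sim_config(), 0)
        with pytest.raises(ConfigurationError):
            generate_outcomes(pats, cfg, 0)

    def test_null_logrank_rejection_rate_is_nominal(self):
        """With no group effect the two generative strata have identical
        survival: two-sided log-rank rejects at ~ the 5% nominal rate."""
        from lifelines.statistics import logrank_test

        cfg = SimConfig(hazard_hr_high_vs_low=1.0)
        pats = generate_patients(cfg, 21)
        low = (pats["latent_hi"] < cfg.latent_threshold).to_numpy()
        rejections = 0
        for r in range(400):
            out = generate_outcomes(pats, cfg, 70_000 + r)
            res = logrank_test(
                out.loc[low, "time_mace"], out.loc[~low, "time_mace"],
                out.loc[low, "event_mace"], out.loc[~low, "event_mace"],
            )
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / 400 <= 0.08  # 5% +/- 3 points
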