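"""Cox/KM analyses, follow-up summaries and biomarker rules."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cardiohi.config import BiomarkerRules, ConfigurationError
from cardiohi.survival import (
    adjust_ntprobnp,
    define_subcohorts,
    fit_cox,
    fit_cox_multivariate,
    km_analysis,
    median_followup,
    univariate_battery,
)
from cardiohi.synthetic import generate_dataset
from conftest import small_sim_config


def cox_partial_loglik(beta, times, events, x):
    """Hand-coded Cox partial log-likelihood (no ties)."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        at_risk = times >= times[i]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def _toy6():
    # 6 subjects, distinct times, two groups
    return pd.DataFrame(
        {
            "time_mace": [2.0, 3.5, 5.0, 7.25, 9.0, 12.0],
            "event_mace": [1, 1, 0, 1, 1, 0],
            "x": [1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
        }
    )


class TestCox:
    def test_loghr_matches_partial_likelihood_oracle(self):
        df = _toy6()
        fit = fit_cox(df, "x", "none", "MACE")
        t, e, x = df["time_mace"].to_numpy(), df["event_mace"].to_numpy(), df["x"].to_numpy()
        res = minimize_scalar(lambda b: -cox_partial_loglik(b, t, e, x),
                              bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-10})
        assert abs(math.log(fit.hr) - res.x) < 1e-6

    def test_constant_feature_is_degenerate(self):
        df = _toy6()
        df["x"] = 1.0
        with pytest.raises(ValueError, match="degenerate covariate"):
            fit_cox(df, "x", "none", "MACE")

    def test_ci_contains_hr_and_events_counted(self):
        fit = fit_cox(_toy6(), "x", "none", "MACE")
        assert fit.ci_low <= fit.hr <= fit.ci_high
        assert fit.n == 6 and fit.n_events == 4

    def test_cluster_robust_changes_wald_not_estimate(self):
        df = pd.concat([_toy6()] * 3, ignore_index=True)
        df["pid"] = np.repeat([f"P{i}" for i in range(6)], 1).tolist() * 3
        plain = fit_cox(df, "x", "none", "MACE")
        clus = fit_cox(df, "x", "none", "MACE", cluster_by="pid")
        assert clus.hr == pytest.approx(plain.hr, rel=1e-9)
        assert clus.wald_p > plain.wald_p  # 3x-replicated rows carry no new info
        assert clus.cluster_adjusted

    def test_single_feature_multivariate_reduces_to_univariate(self):
        df = _toy6()
        uni = fit_cox(df, "x", "none", "MACE")
        multi = fit_cox_multivariate(df, ["x"], "MACE")[0]
        assert abs(math.log(multi.hr) - math.log(uni.hr)) < 1e-10

    def test_duplicated_feature_flagged_collinear(self):
        df = _toy6()
        df["x2"] = df["x"]
        fits = fit_cox_multivariate(df, ["x", "x2"], "MACE")
        assert all("collinear" in f.flags for f in fits)
        assert not fits[0].converged

    def test_independent_covariates_nearly_unconfounded(self):
        rng = np.random.default_rng(10)
        n = 400
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x1 - 0.3 * x2)))
        df = pd.DataFrame(
            {"time_mace": np.minimum(t, 24), "event_mace": (t <= 24).astype(int),
             "x1": x1, "x2": x2}
        )
        uni = fit_cox(df, "x1", "none", "MACE")
        multi = {f.feature: f for f in fit_cox_multivariate(df, ["x1", "x2"], "MACE")}
        assert math.log(multi["x1"].hr) == pytest.approx(math.log(uni.hr), abs=0.1)

    def test_battery_reports_each_feature_endpoint(self):
        ds = generate_dataset(small_sim_config(), 13)
        df = ds["patients"].merge(ds["outcomes"], on="patient_id")
        out = univariate_battery(df, {"age": "none", "ctnt": "log"},
                                 endpoints=("MACE",))
        assert set(out["feature"]) == {"age", "ctnt"}


class TestKM:
    def test_toy_product_limit_steps(self):
        df = pd.DataFrame(
            {"time_mace": [1.0, 2.0, 3.0], "event_mace": [1, 1, 0], "g": "a"}
        )
        curves, p = km_analysis(df, "g", "MACE")
        surv = curves.set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(1 / 3)  # censored: no step
        assert p is None  # single group: test not applicable

    def test_no_events_curves_constant_one(self):
        df = pd.DataFrame(
            {"time_mace": [5.0, 9.0, 12.0, 20.0], "event_mace": 0,
             "g": ["a", "a", "b", "b"]}
        )
        curves, p = km_analysis(df, "g", "MACE")
        assert (curves["survival"] == 1.0).all()
        assert np.isnan(p)

    def test_identical_groups_duplicated_give_null_p(self):
        base = pd.DataFrame(
            {"time_mace": [2.0, 4.0, 6.0, 8.0, 10.0], "event_mace": [1, 0, 1, 1, 0]}
        )
        df = pd.concat([base.assign(g="a"), base.assign(g="b")], ignore_index=True)
        _, p = km_analysis(df, "g", "MACE")
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_mace_curve_dominated_by_component_endpoints(self, small_dataset):
        out = small_dataset["outcomes"].assign(g="all")
        curves = {
            ep: km_analysis(out, "g", ep)[0].set_index("time")["survival"]
            for ep in ("MACE", "HTX", "DMP")
        }
        grid = np.linspace(0.01, 24.0, 60)

        def at(s, t):  # step function value at t
            idx = s.index[s.index <= t]
            return 1.0 if len(idx) == 0 else s.loc[idx.max()]

        for t in grid:
            assert at(curves["MACE"], t) <= at(curves["HTX"], t) + 1e-12
            assert at(curves["MACE"], t) <= at(curves["DMP"], t) + 1e-12


class TestFollowup:
    def test_point_mass_censoring(self):
        df = pd.DataFrame({"time_mace": [14.8] * 8, "event_mace": [0] * 8})
        assert median_followup(df)["median"] == pytest.approx(14.8)

    def test_reverse_km_hand_computed(self):
        # censorings at 2, 5, 8; events at 3, 6 (events act as censored in
        # reverse KM). Hand product-limit on the censoring distribution:
        # S(2) = 4/5 = 0.8; S(5) = 0.8 * 2/3 = 0.533; S(8) = 0 -> median 8.
        df = pd.DataFrame(
            {"time_mace": [2.0, 3.0, 5.0, 6.0, 8.0],
             "event_mace": [0, 1, 0, 1, 0]}
        )
        assert median_followup(df)["median"] == pytest.approx(8.0)

    def test_single_subject(self):
        df = pd.DataFrame({"time_mace": [7.5], "event_mace": [0]})
        assert median_followup(df)["median"] == pytest.approx(7.5)

    def test_empty_raises(self):
        df = pd.DataFrame({"time_mace": [], "event_mace": []})
        with pytest.raises(ValueError):
            median_followup(df)


class TestBiomarkers:
    def test_adjustment_fixed_point_at_gfr_7568(self):
        assert adjust_ntprobnp(812.0, 75.68) == pytest.approx(812.0, rel=1e-12)

    def test_adjustment_worked_example(self):
        assert adjust_ntprobnp(1000.0, 50.0) == pytest.approx(526.2, abs=0.1)

    def test_adjustment_monotone_in_gfr(self):
        gfrs = np.linspace(10, 120, 25)
        vals = adjust_ntprobnp(np.full_like(gfrs, 500.0), gfrs)
        assert (np.diff(vals) > 0).all()

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjust_ntprobnp(-1.0, 50.0)
        with pytest.raises(ValueError):
            adjust_ntprobnp(10.0, 0.0)

    def test_tnt_boundary_is_strict(self):
        pats = pd.DataFrame(
            {"patient_id": ["P1", "P2", "P3"], "ctnt": [50.0, 51.0, np.nan],
             "age": [60.0] * 3, "gfr": [80.0] * 3, "ntprobnp": [900.0] * 3}
        )
        rules = BiomarkerRules(age_cutoff_table={999.0: 1000.0})
        sub = define_subcohorts(pats, rules).set_index("patient_id")
        assert sub.loc["P1", "tnt_class"] == "tnt_neg"
        assert sub.loc["P2", "tnt_class"] == "tnt_pos"
        assert sub.loc["P3", "tnt_class"] == "unclassified"

    def test_bnp_requires_age_cutoff_table(self):
        pats = pd.DataFrame(
            {"patient_id": ["P1"], "ctnt": [10.0], "age": [60.0],
             "gfr": [80.0], "ntprobnp": [900.0]}
        )
        with pytest.raises(ConfigurationError, match="age_cutoff_table"):
            define_subcohorts(pats, BiomarkerRules())

    def test_missing_gfr_unclassified_for_bnp(self):
        pats = pd.DataFrame(
            {"patient_id": ["P1"], "ctnt": [10.0], "age": [60.0],
             "gfr": [np.nan], "ntprobnp": [900.0]}
        )
        rules = BiomarkerRules(age_cutoff_table={999.0: 1000.0})
        sub = define_subcohorts(pats, rules)
        assert sub.loc[0, "bnp_class"] == "unclassified"
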