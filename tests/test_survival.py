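"""Survival preparation, trait transform, Cox fits and the adjustment ladder."""

import math

import numpy as np
import pandas as pd
import pytest

from liposig import (
    AdjustmentSet,
    CohortConfig,
    cox_assoc,
    prepare_survival,
    run_adjustment_ladder,
    simulate_cohort,
    transform_trait,
)
from liposig.survival import DEFAULT_LADDER


class TestTransformTrait:
    def test_log_then_sd_scale(self):
        out = transform_trait([1.0, math.e, math.e**2])
        assert np.allclose(out, [-1.0, 0.0, 1.0])

    def test_multiplicative_invariance(self):
        x = np.array([0.5, 1.2, 3.3, 0.9])
        assert np.allclose(transform_trait(x), transform_trait(7.0 * x))

    def test_nonpositive_rejected_without_offset(self):
        with pytest.raises(ValueError, match="non-positive"):
            transform_trait([1.0, 0.0, 2.0])

    def test_zero_offset_mode(self):
        out = transform_trait([0.0, 1.0, 2.0], zero_offset=True)
        assert np.isfinite(out).all()

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            transform_trait([2.0, 2.0, 2.0])

    def test_missing_propagates(self):
        out = transform_trait([1.0, np.nan, math.e])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2]]).all()


class TestPrepareSurvival:
    def test_censoring_and_prevalent_exclusion(self, survival_cohort):
        table, log = prepare_survival(survival_cohort, censor_years=8.0)
        s = survival_cohort.samples
        assert log["prevalent_chd_removed"] == int(s["prevalent_chd"].sum())
        assert (table["time"] <= 8.0).all()
        assert ((table["time"] < 8.0) | (table["event"] == 0)
                | (table["time"] == 8.0)).all()
        # nobody censored early is an event beyond the horizon
        late = s[(s["prevalent_chd"] == 0) & (s["followup_years"] > 8.0)]
        assert (table.loc[table["time"] == 8.0, "event"] == 0).sum() >= len(late)

    def test_event_timing_rules(self):
        import liposig.survival as surv
        from liposig import CohortDataset
        from conftest import panel_from_rows

        n = 4
        samples = pd.DataFrame({
            "sample_id": list("abcd"),
            "age": [50.0] * n, "sex": [0] * n, "batch": [0] * n,
            **{f"PC{k}": [0.0] * n for k in range(1, 11)},
            "region_or_ethnicity": ["east"] * n,
            "smoking": [0] * n, "mean_arterial_pressure": [95.0] * n,
            "diabetes": [0] * n, "lipid_medication": [0] * n,
            "pregnant": [0] * n, "prevalent_chd": [0, 0, 0, 1],
            "followup_years": [9.2, 7.5, 8.0, 2.0],
            "chd_event": [1, 1, 1, 1],
        })
        # summaries must vary: prepare_survival log-SD-standardizes them
        panel = panel_from_rows({
            "TOTC": [4.0, 5.0, 6.0, 5.5], "TOTTG": [1.0, 1.5, 1.2, 0.9],
            "HDLC": [1.2, 1.5, 1.1, 1.6], "APOB": [0.9, 1.1, 1.0, 1.2],
            "APOA1": [1.3, 1.5, 1.4, 1.2],
        }, n)
        cohort = CohortDataset("toy", samples,
                               pd.DataFrame({"v": [0] * n}), panel)
        table, log = surv.prepare_survival(cohort)
        assert log["prevalent_chd_removed"] == 1
        # 9.2y event -> censored non-event at 8.0; 7.5y event unchanged;
        # event at exactly 8.0 retained as event
        assert table["time"].tolist() == [8.0, 7.5, 8.0]
        assert table["event"].tolist() == [0, 1, 1]

    def test_no_events_is_error(self, small_cohort):
        from liposig import CohortDataset

        s = small_cohort.samples.copy()
        s["chd_event"] = 0
        c = CohortDataset("x", s, small_cohort.dosages, small_cohort.panel)
        with pytest.raises(ValueError, match="no events"):
            prepare_survival(c)


def _toy_table(times, events, x):
    n = len(times)
    return pd.DataFrame({
        "time": times, "event": events, "trait": x,
        "age": [50.0] * n, "sex": [0] * n,
    })


class TestCoxAssoc:
    def test_toy_matches_grid_search_partial_likelihood(self):
        """Untied n=4 fit equals brute-force maximization of the
        hand-written Cox partial likelihood over a fine grid."""
        times = [2.0, 5.0, 7.0, 9.0]
        events = [1, 1, 1, 1]
        x = np.array([1.0, 0.0, 1.0, 0.0])
        table = _toy_table(times, events, x)
        est = cox_assoc(table, "trait", AdjustmentSet("none", ()),
                        transform=False)

        grid = np.arange(-3.0, 3.0, 1e-4)
        order = np.argsort(times)  # event ordering defines the risk sets
        ll = np.zeros_like(grid)
        for i in order:
            at_risk = [j for j in range(4) if times[j] >= times[i]]
            ll += x[i] * grid - np.log(
                np.exp(np.outer(x[at_risk], grid)).sum(axis=0))
        b_hat = grid[np.argmax(ll)]
        assert est.log_hr == pytest.approx(b_hat, abs=1e-4)

    def test_null_trait(self):
        rng = np.random.default_rng(0)
        n = 10_000
        t = rng.exponential(50, size=n)
        table = _toy_table(np.minimum(t, 8.0), (t <= 8.0).astype(int),
                           rng.lognormal(size=n))
        est = cox_assoc(table, "trait", AdjustmentSet("none", ()))
        assert abs(est.log_hr) < 4 * est.se

    def test_time_unit_invariance(self):
        rng = np.random.default_rng(1)
        n = 500
        x = rng.lognormal(size=n)
        t = rng.exponential(10.0 / x, size=n)
        table = _toy_table(np.minimum(t, 8.0), (t <= 8.0).astype(int), x)
        days = table.copy()
        days["time"] = days["time"] * 365.25
        a = cox_assoc(table, "trait", AdjustmentSet("none", ()))
        b = cox_assoc(days, "trait", AdjustmentSet("none", ()))
        assert a.log_hr == pytest.approx(b.log_hr, abs=1e-8)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.lognormal(size=n)
        t = rng.exponential(5.0 / x, size=n)
        table = _toy_table(t, np.ones(n, dtype=int), x)
        a = cox_assoc(table, "trait", AdjustmentSet("none", ()), ties="breslow")
        b = cox_assoc(table, "trait", AdjustmentSet("none", ()), ties="efron")
        assert a.log_hr == pytest.approx(b.log_hr, abs=1e-6)

    def test_cross_check_against_lifelines(self):
        """Independent implementation agreement on one realistic fit."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 2000
        x = rng.lognormal(size=n)
        age = rng.uniform(40, 70, size=n)
        lam = 0.02 * np.exp(0.3 * np.log(x) + 0.02 * (age - 55))
        t = rng.exponential(1.0 / lam)
        table = _toy_table(np.minimum(t, 8.0), (t <= 8.0).astype(int), x)
        table["age"] = age
        est = cox_assoc(table, "trait", AdjustmentSet("age", ("age",)))
        ll_df = pd.DataFrame({
            "T": table["time"], "E": table["event"],
            "z": transform_trait(x), "age": age,
        })
        cph = CoxPHFitter().fit(ll_df, duration_col="T", event_col="E")
        assert est.log_hr == pytest.approx(cph.params_["z"], abs=1e-4)
        assert est.se == pytest.approx(cph.standard_errors_["z"], rel=1e-3)

    def test_hr_ci_consistent_with_log_scale(self, survival_cohort):
        table, _ = prepare_survival(survival_cohort)
        est = cox_assoc(table, "M-HDL-TG-pct", DEFAULT_LADDER[0])
        assert est.hr == pytest.approx(math.exp(est.log_hr), rel=1e-12)
        assert est.ci_low == pytest.approx(math.exp(est.log_hr - 1.96 * est.se))

    def test_injected_hazard_recovered(self, survival_cohort):
        table, _ = prepare_survival(survival_cohort)
        est = cox_assoc(table, "M-HDL-TG-pct", DEFAULT_LADDER[0])
        assert abs(est.log_hr - 0.3) < 3 * est.se


class TestAdjustmentLadder:
    def test_single_rung_single_cohort_equals_direct_fit(self, survival_cohort):
        table, _ = prepare_survival(survival_cohort)
        est_direct = cox_assoc(table, "M-HDL-TG-pct", DEFAULT_LADDER[0],
                               cohort_id="c")
        estimates, meta = run_adjustment_ladder(
            {"c": table}, ["M-HDL-TG-pct"], [DEFAULT_LADDER[0]])
        row = estimates.iloc[0]
        assert row["log_hr"] == pytest.approx(est_direct.log_hr)
        assert meta.iloc[0]["log_hr"] == pytest.approx(est_direct.log_hr)
        assert meta.iloc[0]["n_events"] == est_direct.n_events

    def test_independent_covariate_barely_moves_estimate(self, survival_cohort):
        table, _ = prepare_survival(survival_cohort)
        base = AdjustmentSet("small", ("age", "sex"))
        plus = AdjustmentSet("small+diab", ("age", "sex", "diabetes"))
        a = cox_assoc(table, "M-HDL-TG-pct", base)
        b = cox_assoc(table, "M-HDL-TG-pct", plus)
        assert abs(a.log_hr - b.log_hr) < 2 * a.se

    def test_mediated_effect_attenuates(self):
        """Hazard acting only through total TG: the subclass TG trait's
        association vanishes once total TG enters the model."""
        cfg = CohortConfig("med", 6000, target_event_fraction=0.10,
                           loghr_map={"total-TG": 0.5})
        cohort = simulate_cohort(cfg, seed=11)
        table, _ = prepare_survival(cohort)
        rungs = [
            AdjustmentSet("basic-lite", ("age", "sex")),
            AdjustmentSet("basic-lite+totalTG", ("age", "sex", "total_tg")),
        ]
        _, meta = run_adjustment_ladder({"med": table}, ["S-VLDL-TG"], rungs)
        m = meta.set_index("adjustment")
        raw = m.loc["basic-lite"]
        adj = m.loc["basic-lite+totalTG"]
        assert raw["log_hr"] > 4 * raw["se"]  # marginal association present
        assert abs(adj["log_hr"]) < 3 * adj["se"]  # conditional effect gone
        assert abs(adj["log_hr"]) < 0.5 * abs(raw["log_hr"])

    def test_cell_failures_are_recorded_not_fatal(self, survival_cohort):
        table, _ = prepare_survival(survival_cohort)
        bad = table.copy()
        bad["M-HDL-TG-pct"] = -1.0  # log undefined -> per-cell error
        estimates, meta = run_adjustment_ladder(
            {"ok": table, "bad": bad}, ["M-HDL-TG-pct"], [DEFAULT_LADDER[0]])
        errs = estimates[estimates["error"] != ""]
        assert len(errs) == 1 and errs.iloc[0]["cohort_id"] == "bad"
        assert len(meta) == 1 and meta.iloc[0]["n_cohorts"] == 1

    def test_empty_ladder_rejected(self, survival_cohort):
        table, _ = prepare_survival(survival_cohort)
        with pytest.raises(ValueError, match="non-empty"):
            run_adjustment_ladder({"c": table}, ["M-HDL-TG-pct"], [])

    def test_default_ladder_names(self):
        names = [r.name for r in DEFAULT_LADDER]
        assert names[0] == "basic"
        assert "basic+apoB+HDL-C" in names and "basic+TC+totalTG" in names
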