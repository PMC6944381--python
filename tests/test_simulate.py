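"""Generator contracts: HWE, determinism, effect injection, event process."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from liposig import (
    CETP_PROFILE,
    CETP_VARIANT,
    HMGCR_PROFILE,
    CohortConfig,
    EffectProfile,
    VariantSpec,
    simulate_cohort,
    simulate_covariates,
    simulate_followup,
    simulate_genotypes,
    simulate_multicohort,
    simulate_panel,
)
from liposig.panel import CONSTITUENTS, analysis_traits, derive_compositions
from liposig.simulate import DEFAULT_PROSPECTIVE, PanelConfig, cohort_seed


class TestVariantSpec:
    def test_rejects_bad_alleles_and_freq(self):
        with pytest.raises(ValueError):
            VariantSpec("v", "A", "A", 0.5, 0.01, 0.01)
        with pytest.raises(ValueError):
            VariantSpec("v", "A", "X", 0.5, 0.01, 0.01)
        with pytest.raises(ValueError):
            VariantSpec("v", "A", "C", 1.0, 0.01, 0.01)
        with pytest.raises(ValueError):
            VariantSpec("v", "A", "C", 0.5, 0.01, 0.0)

    def test_defaults_carry_external_chd_constants(self):
        assert CETP_VARIANT.chd_logor_per_allele == 0.0309
        assert CETP_VARIANT.effect_allele_freq == 0.69
        from liposig import HMGCR_VARIANT

        assert HMGCR_VARIANT.chd_logor_per_allele == 0.0358
        assert HMGCR_VARIANT.effect_allele_freq == 0.57
        assert CETP_VARIANT.chd_logor_se == HMGCR_VARIANT.chd_logor_se == 0.01


class TestGenotypes:
    def test_rare_allele_limit(self):
        d = simulate_genotypes(100, VariantSpec("v", "A", "C", 1e-9, 0.01, 0.01), 1)
        assert (d == 0).all()

    def test_binomial_mean(self):
        spec = VariantSpec("v", "C", "A", 0.69, 0.01, 0.01)
        d = simulate_genotypes(100_000, spec, 11)
        sd_mean = np.sqrt(2 * 0.69 * 0.31 / 100_000)
        assert abs(d.mean() - 1.38) < 3 * sd_mean

    def test_hwe_proportions(self):
        spec = VariantSpec("v", "A", "T", 0.5, 0.01, 0.01)
        d = simulate_genotypes(100_000, spec, 5)
        obs = np.bincount(d, minlength=3)
        exp = np.array([0.25, 0.5, 0.25]) * len(d)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, 2) > 0.001
        assert np.allclose(obs / len(d), [0.25, 0.5, 0.25], atol=0.01)

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_genotypes(0, CETP_VARIANT, 1)


class TestPanelGeneration:
    def _null_slopes(self, n, seed):
        cov = simulate_covariates(n, seed)
        dos = {"v": simulate_genotypes(n, CETP_VARIANT, seed + 1)}
        panel = simulate_panel(n, dos, {"v": EffectProfile()}, cov, seed + 2)
        traits = analysis_traits(panel)
        from liposig import additive_assoc

        return [
            additive_assoc(np.log(traits[t]), dos["v"])
            for t in ("HDL-C", "VLDL-C", "M-HDL-TG-pct", "LDL-C-size-specific")
        ]

    def test_null_profile_gives_null_slopes(self):
        for est in self._null_slopes(50_000, 100):
            assert abs(est.beta) < 4 * est.se

    def test_injected_hdl_shift_recovered(self):
        """Slope on log HDL-C equals the injected latent CE/FC shift.

        The shift multiplies every HDL cholesterol constituent by
        exp(shift * dosage), so the log-scale slope is the shift exactly
        in expectation (the expectation-differencing oracle).
        """
        n, seed = 50_000, 200
        cov = simulate_covariates(n, seed)
        dos = {"v": simulate_genotypes(n, CETP_VARIANT, seed + 1)}
        panel = simulate_panel(n, dos, {"v": CETP_PROFILE}, cov, seed + 2)
        from liposig import additive_assoc

        traits = analysis_traits(panel)
        est = additive_assoc(np.log(traits["HDL-C"]), dos["v"])
        assert abs(est.beta - CETP_PROFILE.hdl_ce_shift) < 3 * est.se

    def test_ldl_contrast_between_profiles(self):
        """HMGCR-like lowers size-specific LDL-C; CETP-like does not."""
        n, seed = 50_000, 300
        cov = simulate_covariates(n, seed)
        from liposig import additive_assoc

        slopes = {}
        for name, prof in (("cetp", CETP_PROFILE), ("hmgcr", HMGCR_PROFILE)):
            dos = {"v": simulate_genotypes(n, CETP_VARIANT, seed + 1)}
            panel = simulate_panel(n, dos, {"v": prof}, cov, seed + 2)
            traits = analysis_traits(panel)
            slopes[name] = additive_assoc(
                np.log(traits["LDL-C-size-specific"]), dos["v"])
        # the HMGCR-like risk allele raises apoB cholesterol incl. LDL
        expected = HMGCR_PROFILE.apob_chol_shift_by_class["LDL"]
        assert abs(slopes["hmgcr"].beta - expected) < 3 * slopes["hmgcr"].se
        assert slopes["hmgcr"].beta > 4 * slopes["hmgcr"].se
        assert abs(slopes["cetp"].beta) < 3 * slopes["cetp"].se

    def test_compositions_survive_effect_injection(self, small_cohort):
        comp = derive_compositions(small_cohort.panel)
        for sub in small_cohort.panel.scheme.names:
            total = sum(comp[f"{sub}_{c}_pct"] for c in CONSTITUENTS)
            assert np.allclose(total, 100.0, atol=1e-9)

    def test_negative_variance_component_is_named_error(self):
        with pytest.raises(ValueError, match="sd_class"):
            PanelConfig(sd_class=-0.1)


class TestFollowup:
    def test_closed_form_event_fraction(self):
        """Null exponential hazards: P(event) = 1 - exp(-rate * horizon)."""
        n = 100_000
        fu = simulate_followup(n, None, {}, baseline_hazard=0.005,
                               admin_censor_years=8.0, seed=4)
        p = 1 - np.exp(-0.04)
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(fu["chd_event"].mean() - p) < tol

    def test_vanishing_hazard_limit(self):
        fu = simulate_followup(1000, None, {}, baseline_hazard=1e-12,
                               admin_censor_years=8.0, seed=4)
        assert fu["chd_event"].sum() == 0
        assert (fu["followup_years"] == 8.0).all()

    def test_weibull_shape_changes_timing_not_validity(self):
        fu = simulate_followup(5000, None, {}, baseline_hazard=0.01,
                               admin_censor_years=8.0, seed=9,
                               dist="weibull", weibull_shape=1.5)
        assert fu["followup_years"].between(0, 8.0).all()

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError, match="distribution"):
            simulate_followup(10, None, {}, baseline_hazard=0.01, seed=1,
                              dist="gamma")


class TestMulticohort:
    def test_tiny_cohort_invariants(self):
        (c,) = simulate_multicohort([CohortConfig("tiny", 10)], 1)
        assert c.n == 10
        assert c.samples["followup_years"].ge(0).all()
        assert c.samples["chd_event"].isin([0, 1]).all()
        assert np.isin(c.dosages.to_numpy(), [0, 1, 2]).all()

    def test_determinism_same_master_seed(self):
        a = simulate_multicohort([CohortConfig("x", 200), CohortConfig("y", 150)], 9)
        b = simulate_multicohort([CohortConfig("x", 200), CohortConfig("y", 150)], 9)
        for ca, cb in zip(a, b):
            pd.testing.assert_frame_equal(ca.samples, cb.samples)
            pd.testing.assert_frame_equal(ca.dosages, cb.dosages)
            pd.testing.assert_frame_equal(ca.panel.data, cb.panel.data)

    def test_cohort_regenerable_in_isolation(self):
        a = simulate_multicohort([CohortConfig("x", 200), CohortConfig("y", 150)], 9)
        y_alone = simulate_cohort(CohortConfig("y", 150), cohort_seed(9, "y"))
        pd.testing.assert_frame_equal(a[1].panel.data, y_alone.panel.data)

    def test_duplicate_cohort_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_multicohort([CohortConfig("x", 10), CohortConfig("x", 10)], 1)

    def test_pooled_case_count_matches_study_targets(self):
        """Three prospective-style cohorts reproduce the pooled case count.

        Cohort event settings target the post-exclusion case fractions
        287/6,484, 270/3,318 and 59/4,378; the pooled simulated case
        count should land within binomial tolerance of 616.
        """
        cohorts = simulate_multicohort(list(DEFAULT_PROSPECTIVE), 17)
        cases = sum(int(c.samples["chd_event"].sum()) for c in cohorts)
        var = sum(
            cfg.n * cfg.target_event_fraction * (1 - cfg.target_event_fraction)
            for cfg in DEFAULT_PROSPECTIVE
        )
        assert abs(cases - 616) < 3 * np.sqrt(var) + 10
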