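"""Generator tests: calibration targets, structural invariants, determinism."""

import numpy as np
import pandas as pd
import pytest

from mrsurv import (LEAF_CAUSES, ParameterError, SimulationParams,
                    apply_exclusions, simulate_cohort, simulate_genotypes,
                    simulate_panel, simulate_phenotypes, simulate_survival)
from mrsurv.causes import ancestors, matches
from mrsurv.params import substream
from mrsurv.simulate import EXCLUSION_ORDER, simulate_exclusion_flags


class TestPanel:
    def test_weight_scaling_hits_target_variance(self):
        p = SimulationParams(n_variants_bmi=50, n_variants_diab=30,
                             target_r2=0.03, seed=1)
        panel = simulate_panel(p)
        for trait in ("bmi", "diab"):
            sub = panel[panel.trait == trait]
            hw = 2 * sub.allele_freq * (1 - sub.allele_freq)
            assert np.isclose((sub.weight**2 * hw).sum(), 0.03, atol=1e-12)

    def test_panels_disjoint_and_freqs_bounded(self):
        panel = simulate_panel(SimulationParams(seed=2, n_variants_bmi=40,
                                                n_variants_diab=40))
        bmi = set(panel[panel.trait == "bmi"].variant_id)
        diab = set(panel[panel.trait == "diab"].variant_id)
        assert not bmi & diab
        assert panel.allele_freq.between(0.05, 0.95).all()
        assert (panel.effect_allele != panel.other_allele).all()

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ParameterError):
            SimulationParams(n_variants_bmi=0)
        with pytest.raises(ParameterError):
            SimulationParams(n_individuals=0)
        with pytest.raises(ParameterError):
            SimulationParams(target_r2=1.5)
        with pytest.raises(ParameterError):
            SimulationParams(mediated_fraction=1.2)


class TestGenotypes:
    def test_hard_call_dosages_and_hw_variance(self):
        # no ancestry structure: dosage variance matches 2p(1-p)
        p = SimulationParams(n_individuals=100_000, n_variants_bmi=3,
                             n_variants_diab=1, ancestry_freq_shift=0.0,
                             hard_calls=True, seed=5)
        panel = simulate_panel(p)
        g = simulate_genotypes(panel, p)
        d = g.dosages.to_numpy()
        assert set(np.unique(d)) <= {0.0, 1.0, 2.0}
        freq = panel.allele_freq.to_numpy()
        expected = 2 * freq * (1 - freq)
        observed = d.var(axis=0)
        # Monte-Carlo tolerance ~ 4 relative SEs of a variance estimate
        assert np.allclose(observed, expected, rtol=0.04)

    def test_pc1_tracks_ancestry_with_default_shift(self):
        p = SimulationParams(n_individuals=5000, seed=6)
        g = simulate_genotypes(simulate_panel(p), p)
        r = np.corrcoef(g.pcs[:, 0], g.ancestry_prop)[0, 1]
        assert abs(r) > 0.9

    def test_no_shift_no_structure(self):
        p = SimulationParams(n_individuals=5000, n_variants_bmi=80,
                             n_variants_diab=40, ancestry_freq_shift=0.0,
                             seed=7)
        g = simulate_genotypes(simulate_panel(p), p)
        r = np.corrcoef(g.pcs[:, 0], g.ancestry_prop)[0, 1]
        assert abs(r) < 0.1

    def test_ancestry_median_near_two_thirds(self, small_sim):
        med = np.median(small_sim.geno.ancestry_prop)
        assert 0.6 < med < 0.75


@pytest.fixture(scope="module")
def cohort50k():
    p = SimulationParams(n_individuals=50_000, seed=11)
    return simulate_cohort(p)


class TestPhenotypes:

    def test_bmi_calibration_by_sex(self, cohort50k):
        c = cohort50k.cohort
        for sex, mean, sd in (("male", 28.0, 4.2), ("female", 29.7, 5.2)):
            sub = c[c.sex == sex].bmi_measured
            assert abs(sub.mean() - mean) < 0.25
            assert abs(sub.std() - sd) < 0.35

    def test_diabetes_prevalence_and_diagnosed_split(self, cohort50k):
        c = cohort50k.cohort
        any_diab = (c.diabetes != "none").mean()
        assert abs(any_diab - 0.18) < 0.02
        diag = (c.diabetes == "diagnosed").sum() / (c.diabetes != "none").sum()
        assert abs(diag - 13 / 18) < 0.03

    def test_no_reverse_causality_measured_equals_true_plus_noise(self):
        p = SimulationParams(n_individuals=6000, n_variants_bmi=40,
                             n_variants_diab=30, reverse_causality_delta=0.0,
                             seed=12)
        sim = simulate_cohort(p)
        diff = sim.cohort.bmi_measured - sim.cohort.bmi_true
        assert abs(diff.mean()) < 0.03
        assert abs(diff.std() - p.measurement_noise_sd) < 0.02

    def test_measured_bmi_subtracts_delta_in_diagnosed(self, small_sim):
        c = small_sim.cohort
        diff = c.bmi_measured - c.bmi_true
        diag = c.diabetes == "diagnosed"
        delta = small_sim.params.reverse_causality_delta
        assert abs(diff[diag].mean() + delta) < 0.05
        assert abs(diff[~diag].mean()) < 0.05
        assert (c.bmi_measured > 0).all()


class TestSurvival:
    def test_exit_after_entry_and_cause_iff_died(self, small_sim):
        s = small_sim.survival
        assert (s.exit_age > s.entry_age).all()
        assert ((s.cause == "none") == ~s.died).all()

    def test_cause_hierarchy_additivity(self, small_sim):
        from mrsurv.causes import CAUSE_PARENT
        s = small_sim.survival[small_sim.survival.died]
        assert s.cause.isin(LEAF_CAUSES).all()
        counts = {node: sum(matches(c, node) for c in s.cause)
                  for node in CAUSE_PARENT}
        # every internal node's count equals the sum over its children
        for node in CAUSE_PARENT:
            children = [c for c, p in CAUSE_PARENT.items() if p == node]
            if children:
                assert counts[node] == sum(counts[c] for c in children)
        assert counts["all"] == len(s)

    def test_null_model_score_independent_of_mortality(self):
        p = SimulationParams(n_individuals=8000, n_variants_bmi=50,
                             n_variants_diab=30, causal_loghr_per_unit=0.0,
                             mediated_fraction=0.0, confounder_loghr=0.0,
                             seed=13)
        sim = simulate_cohort(p)
        from mrsurv import HazardModelSpec, compute_score, fit_cox
        gs = compute_score(sim.geno.dosages, sim.panel, "bmi")
        rec = sim.table.assign(score=gs.std.to_numpy())
        fit = fit_cox(rec, "score", HazardModelSpec(cause="all"))
        assert abs(fit.beta_zy) < 3 * fit.se_zy

    def test_diabetes_upweights_renal_and_crisis_causes(self, small_sim):
        t = small_sim.table
        dead = t[t.died]
        frac = {}
        for has in (True, False):
            sub = dead[(dead.diabetes != "none") == has]
            frac[has] = sub.cause.isin(
                ["renal", "acute-diabetic-crisis"]).mean()
        assert frac[True] > frac[False]

    def test_quadratic_hazard_option_runs(self):
        p = SimulationParams(n_individuals=3000, n_variants_bmi=30,
                             n_variants_diab=20, bmi_loghr_quadratic=0.01,
                             seed=14)
        sim = simulate_cohort(p)
        assert sim.survival.died.any()


class TestExclusions:
    def _cohort(self, n=10):
        return pd.DataFrame({
            "individual_id": range(n),
            "entry_age": [50.0] * (n - 1) + [80.0],
        })

    def test_hand_enumerated_cascade(self):
        # one individual fails each successive flag; one is aged 75-89
        cohort = self._cohort(10)
        flags = pd.DataFrame(False, index=range(10),
                             columns=list(EXCLUSION_ORDER))
        for i, name in enumerate(EXCLUSION_ORDER):
            flags.loc[i, name] = True
        young, old, ledger = apply_exclusions(cohort, flags)
        assert ledger.n_removed.tolist() == [1, 1, 1, 1]
        assert len(young) == 5 and len(old) == 1

    def test_no_flags_identity(self):
        cohort = self._cohort(8)
        flags = pd.DataFrame(False, index=range(8),
                             columns=list(EXCLUSION_ORDER))
        young, old, ledger = apply_exclusions(cohort, flags)
        assert ledger.n_removed.sum() == 0
        assert len(young) + len(old) == 8

    def test_double_failure_counted_once_under_first_step(self):
        cohort = self._cohort(5)
        flags = pd.DataFrame(False, index=range(5),
                             columns=list(EXCLUSION_ORDER))
        flags.loc[0, "qc_fail"] = True
        flags.loc[0, "age_ge_90"] = True
        young, old, ledger = apply_exclusions(cohort, flags)
        assert ledger.set_index("step").n_removed["qc_fail"] == 1
        assert ledger.set_index("step").n_removed["age_ge_90"] == 0

    def test_unknown_flag_is_configuration_error(self):
        cohort = self._cohort(3)
        flags = pd.DataFrame(False, index=range(3), columns=["qc_fail"])
        with pytest.raises(ParameterError):
            apply_exclusions(cohort, flags)

    def test_flag_rates_roughly_match_configuration(self, small_params):
        flags = simulate_exclusion_flags(small_params)
        assert abs(flags.qc_fail.mean() - 0.133) < 0.02


class TestDeterminism:
    def test_identical_params_identical_outputs(self):
        p = SimulationParams(n_individuals=1500, n_variants_bmi=30,
                             n_variants_diab=20, seed=99)
        a = simulate_cohort(p)
        b = simulate_cohort(p)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        pd.testing.assert_frame_equal(a.panel, b.panel)
        assert a.cohort.to_csv() == b.cohort.to_csv()

    def test_substreams_are_independent_and_stable(self):
        x = substream(3, "phenotypes").normal(size=4)
        y = substream(3, "phenotypes").normal(size=4)
        z = substream(3, "survival").normal(size=4)
        assert np.allclose(x, y)
        assert not np.allclose(x, z)

    def test_mediated_fraction_beyond_pathway_capacity_rejected(self):
        p = SimulationParams(n_individuals=2000, n_variants_bmi=20,
                             n_variants_diab=20, mediated_fraction=1.0,
                             bmi_liability_slope=0.01, seed=4)
        geno = simulate_genotypes(simulate_panel(p), p)
        cohort = simulate_phenotypes(geno, simulate_panel(p), p)
        with pytest.raises(ParameterError):
            simulate_survival(cohort, p)
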