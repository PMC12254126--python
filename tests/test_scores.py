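"""Score construction, clumping, instrument strength, fifths tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsurv import FitError, compute_score, fifths_table, instrument_strength, ld_clump
from mrsurv.scores import AlleleError, assign_fifths


class TestComputeScore:
    def test_zero_weights_zero_score(self, toy_panel, toy_dosages):
        panel = toy_panel.assign(weight=0.0)
        gs = compute_score(toy_dosages, panel, "bmi")
        assert np.allclose(gs.raw, 0.0)

    def test_single_variant_dosage_scaling(self):
        panel = pd.DataFrame({
            "variant_id": ["v1"], "effect_allele": ["A"],
            "other_allele": ["G"], "weight": [0.7], "allele_freq": [0.4],
            "trait": ["bmi"],
        })
        dosages = pd.DataFrame({"v1": [0.0, 1.0, 2.0]})
        gs = compute_score(dosages, panel, "bmi")
        assert np.allclose(gs.raw, [0.0, 0.7, 1.4])

    def test_std_score_standardized(self, toy_panel, toy_dosages):
        gs = compute_score(toy_dosages, toy_panel, "bmi")
        assert abs(gs.std.mean()) < 1e-8
        assert abs(gs.std.std(ddof=0) - 1.0) < 1e-8

    def test_mean_imputation_equals_2p(self, toy_panel, toy_dosages):
        d = toy_dosages.copy()
        d.loc[0, "v1"] = np.nan
        gs_missing = compute_score(d, toy_panel, "bmi")
        d2 = toy_dosages.copy()
        d2.loc[0, "v1"] = 2 * toy_panel.set_index("variant_id").allele_freq["v1"]
        gs_imputed = compute_score(d2, toy_panel, "bmi")
        assert np.allclose(gs_missing.raw, gs_imputed.raw, atol=1e-12)
        assert gs_missing.n_imputed == 1

    def test_excess_missingness_hard_fail(self, toy_panel, toy_dosages):
        d = toy_dosages.copy()
        d.loc[: int(0.2 * len(d)), "v2"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            compute_score(d, toy_panel, "bmi")

    def test_strand_flip_invariance(self, toy_panel, toy_dosages):
        base = compute_score(toy_dosages, toy_panel, "bmi",
                             coded_allele=dict(zip(toy_panel.variant_id,
                                                   toy_panel.effect_allele)),
                             other_allele=dict(zip(toy_panel.variant_id,
                                                   toy_panel.other_allele)))
        # represent v2 on the opposite strand orientation: dosage counts the
        # other allele instead
        flipped = toy_dosages.copy()
        flipped["v2"] = 2.0 - flipped["v2"]
        coded = dict(zip(toy_panel.variant_id, toy_panel.effect_allele))
        coded["v2"] = toy_panel.set_index("variant_id").other_allele["v2"]
        with pytest.warns(UserWarning, match="flipped"):
            gs = compute_score(flipped, toy_panel, "bmi",
                               coded_allele=coded,
                               other_allele=dict(
                                   zip(toy_panel.variant_id,
                                       toy_panel.other_allele)))
        assert np.allclose(gs.raw, base.raw, atol=1e-12)
        assert gs.n_flipped == 1

    def test_unresolvable_allele_hard_error(self, toy_panel, toy_dosages):
        coded = dict(zip(toy_panel.variant_id, toy_panel.effect_allele))
        coded["v1"] = "T"  # matches neither effect nor other allele
        with pytest.raises(AlleleError):
            compute_score(toy_dosages, toy_panel, "bmi",
                          coded_allele=coded,
                          other_allele=dict(zip(toy_panel.variant_id,
                                                toy_panel.other_allele)))

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=15, deadline=None)
    def test_variant_order_invariance(self, rnd):
        rng = np.random.default_rng(rnd.randint(0, 10**6))
        k = 6
        panel = pd.DataFrame({
            "variant_id": [f"v{j}" for j in range(k)],
            "effect_allele": ["A"] * k, "other_allele": ["G"] * k,
            "weight": rng.normal(size=k),
            "allele_freq": rng.uniform(0.1, 0.9, k),
            "trait": ["bmi"] * k,
        })
        dosages = pd.DataFrame(rng.integers(0, 3, (30, k)).astype(float),
                               columns=panel.variant_id)
        base = compute_score(dosages, panel, "bmi")
        perm = panel.sample(frac=1, random_state=rnd.randint(0, 99))
        again = compute_score(dosages, perm, "bmi")
        assert np.allclose(base.raw, again.raw, atol=1e-12)


class TestClump:
    def _variants(self, pvals):
        return pd.DataFrame({
            "variant_id": [f"v{j}" for j in range(len(pvals))],
            "p_value": pvals,
        })

    def _r2(self, ids, mat):
        return pd.DataFrame(mat, index=ids, columns=ids)

    def test_independent_variants_all_retained(self):
        v = self._variants([0.5, 0.1, 0.9])
        r2 = self._r2(v.variant_id, np.eye(3) * 0.0)
        assert set(ld_clump(v, r2, 0.01)) == set(v.variant_id)

    def test_perfect_pair_keeps_smaller_p(self):
        v = self._variants([0.5, 0.001])
        m = np.array([[0.0, 0.99], [0.99, 0.0]])
        assert ld_clump(v, self._r2(v.variant_id, m), 0.01) == ["v1"]

    def test_threshold_one_retains_everything(self):
        v = self._variants([0.5, 0.2, 0.7, 0.4])
        rng = np.random.default_rng(5)
        m = rng.uniform(0, 0.95, (4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        assert set(ld_clump(v, self._r2(v.variant_id, m), 1.0)) == set(
            v.variant_id)

    def test_tiny_threshold_one_per_block(self):
        ids = [f"v{j}" for j in range(6)]
        m = np.zeros((6, 6))
        for block in ([0, 1], [2, 3, 4], [5]):
            for a in block:
                for b in block:
                    if a != b:
                        m[a, b] = 0.5
        v = self._variants([0.1, 0.2, 0.3, 0.05, 0.4, 0.6])
        kept = ld_clump(v, self._r2(ids, m), 1e-9)
        assert len(kept) == 3  # one per r2-connected block

    def test_matches_bruteforce_greedy_replay(self):
        # 10 variants in 3 correlation blocks; an independent replay of the
        # greedy rule must select the identical set
        rng = np.random.default_rng(7)
        ids = [f"v{j}" for j in range(10)]
        blocks = [ids[:4], ids[4:7], ids[7:]]
        m = np.zeros((10, 10))
        for block in blocks:
            for a in block:
                for b in block:
                    if a != b:
                        m[ids.index(a), ids.index(b)] = rng.uniform(0.2, 0.9)
        m = (m + m.T) / 2
        pvals = rng.uniform(0, 1, 10)
        v = self._variants(pvals)
        r2 = self._r2(ids, m)
        got = ld_clump(v, r2, 0.3)

        order = sorted(ids, key=lambda x: (pvals[ids.index(x)], x))
        kept = []
        for cand in order:
            if all(m[ids.index(cand), ids.index(k)] < 0.3 for k in kept):
                kept.append(cand)
        assert got == kept

    def test_symmetry_and_finiteness_validated(self):
        v = self._variants([0.1, np.inf])
        r2 = self._r2(v.variant_id, np.zeros((2, 2)))
        with pytest.raises(ValueError):
            ld_clump(v, r2, 0.1)


class TestInstrumentStrength:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=200)
        s = (s - s.mean()) / s.std(ddof=0)
        fit = instrument_strength(s, 2.0 * s)
        assert np.isclose(fit.beta_zx, 2.0)
        assert np.isclose(fit.r_squared, 1.0)

    def test_permuted_score_null(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=5000)
        y = rng.normal(size=5000)
        fit = instrument_strength(s, y)
        assert fit.r_squared < 0.003
        assert fit.f_statistic < 8

    def test_partial_f_identity_no_covariates(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=400)
        y = 0.3 * s + rng.normal(size=400)
        fit = instrument_strength(s, y)
        n = 400
        f_oracle = (n - 2) * fit.r_squared / (1 - fit.r_squared)
        assert abs(fit.f_statistic - f_oracle) < 1e-9

    def test_small_subset_refused(self):
        with pytest.raises(FitError):
            instrument_strength(np.arange(10.0), np.arange(10.0))

    def test_covariate_adjustment_removes_shared_variance(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=3000)
        s = 0.9 * c + rng.normal(size=3000) * 0.4
        y = 2.0 * c + rng.normal(size=3000)
        raw = instrument_strength(s, y)
        adj = instrument_strength(s, y, covariates=c[:, None])
        assert raw.r_squared > 0.2
        assert adj.r_squared < 0.01


class TestFifths:
    def test_constant_characteristic_zero_gradient(self, scored_cohort):
        df = scored_cohort.assign(flat=1.5)
        tab = fifths_table(df, df["bmi_score"], ["flat"])
        row = tab.iloc[0]
        assert row.gradient == 0.0

    def test_score_itself_strictly_increasing(self, scored_cohort):
        df = scored_cohort.assign(sc=scored_cohort["bmi_score"])
        tab = fifths_table(df, df["bmi_score"], ["sc"])
        vals = tab.iloc[0][[f"fifth_{i}" for i in range(1, 6)]].to_numpy()
        assert (np.diff(vals.astype(float)) > 0).all()

    def test_exposure_and_diabetes_gradients_positive(self, scored_cohort):
        df = scored_cohort.assign(
            diab01=(scored_cohort.diabetes != "none").astype(int))
        tab = fifths_table(df, df["bmi_score"], ["bmi_measured", "diab01"])
        tab = tab.set_index("characteristic")
        assert tab.loc["bmi_measured", "gradient"] > 0
        assert tab.loc["diab01", "gradient"] > 0

    def test_independent_confounder_gradient_null(self, scored_cohort):
        tab = fifths_table(scored_cohort, scored_cohort["bmi_score"],
                           ["confounder"])
        n5 = len(scored_cohort) / 5
        se = np.sqrt(2.0 / n5)  # difference of two independent fifth means
        assert abs(tab.iloc[0].gradient) < 4 * se

    def test_fifths_equal_sizes_within_sex(self, scored_cohort):
        fifth = assign_fifths(scored_cohort["bmi_score"],
                              scored_cohort["sex"])
        for sex in ("male", "female"):
            counts = fifth[scored_cohort.sex == sex].value_counts()
            assert counts.max() - counts.min() <= 1
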