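"""Summary-statistic estimators: harmonization, IVW, median, Egger."""

import numpy as np
import pandas as pd
import pytest

from mrsurv import (FitError, HazardModelSpec, harmonize, ivw_2s, mr_egger,
                    per_snp_summaries, weighted_median)

PCS = ("pc1", "pc2", "pc3", "pc4")


def _summaries(ratios, weights=None, se_zx=0.01):
    """Build a summary frame whose per-variant ratios and weights are known:
    beta_zx fixed at 1 so beta_zy = ratio and weight = 1/se_zy²."""
    k = len(ratios)
    if weights is None:
        weights = np.ones(k)
    se_zy = 1.0 / np.sqrt(np.asarray(weights, float))
    return pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(k)],
        "beta_zx": np.ones(k), "se_zx": np.full(k, se_zx),
        "beta_zy": np.asarray(ratios, float), "se_zy": se_zy,
    })


class TestHarmonize:
    def test_flip_restores_orientation(self):
        s = pd.DataFrame({"variant_id": ["a", "b"],
                          "beta_zx": [0.2, -0.3], "se_zx": [0.01, 0.01],
                          "beta_zy": [0.02, 0.05], "se_zy": [0.01, 0.01]})
        h = harmonize(s)
        assert (h.beta_zx >= 0).all()
        assert h.loc[1, "beta_zy"] == -0.05

    def test_allele_flip_invariance_end_to_end(self, small_sim, scored_cohort):
        ids = small_sim.panel[small_sim.panel.trait == "bmi"]
        ids = ids.variant_id.tolist()[:10]
        dos = small_sim.geno.dosages.loc[scored_cohort.index]
        spec = HazardModelSpec(cause="all", covariates=PCS)
        base = per_snp_summaries(scored_cohort, dos, ids, "bmi_measured",
                                 spec, covariate_cols=PCS)
        flipped = dos.copy()
        flipped[ids[0]] = 2.0 - flipped[ids[0]]
        again = per_snp_summaries(scored_cohort, flipped, ids,
                                  "bmi_measured", spec, covariate_cols=PCS)
        pd.testing.assert_frame_equal(base, again, atol=1e-8)


class TestPerSnp:
    def test_matches_bruteforce_refit_on_small_fixture(self, small_sim,
                                                       scored_cohort):
        import statsmodels.api as sm
        from lifelines import CoxPHFitter
        sub = scored_cohort.head(400)
        ids = small_sim.panel[small_sim.panel.trait == "bmi"]
        ids = ids.variant_id.tolist()[:4]
        dos = small_sim.geno.dosages.loc[sub.index]
        spec = HazardModelSpec(cause="all", covariates=(), min_events=5)
        summ = per_snp_summaries(sub, dos, ids, "bmi_measured", spec)
        from mrsurv.assoc import restrict_window
        w = restrict_window(sub, 35.0, 75.0)
        for _, row in summ.iterrows():
            d = dos.loc[w.index, row.variant_id].to_numpy(float)
            flip = np.corrcoef(d, w.bmi_measured)[0, 1] < 0
            X = sm.add_constant(d)
            ols = sm.OLS(w.bmi_measured.to_numpy(), X).fit()
            bx = -ols.params[1] if flip else ols.params[1]
            assert abs(row.beta_zx - bx) < 1e-8
            assert abs(row.se_zx - ols.bse[1]) < 1e-8
            df = pd.DataFrame({"d": d, "entry": w.entry_age,
                               "T": w.exit_age,
                               "E": w.died.astype(int)})
            cph = CoxPHFitter()
            cph.fit(df, duration_col="T", event_col="E", entry_col="entry")
            by = -cph.params_["d"] if flip else cph.params_["d"]
            # agreement limited by the oracle's own convergence tolerance
            assert abs(row.beta_zy - by) < 1e-4

    def test_sample_split_mode_runs_and_differs(self, small_sim,
                                                scored_cohort):
        ids = small_sim.panel[small_sim.panel.trait == "bmi"]
        ids = ids.variant_id.tolist()[:5]
        dos = small_sim.geno.dosages.loc[scored_cohort.index]
        spec = HazardModelSpec(cause="all", covariates=PCS, min_events=5)
        whole = per_snp_summaries(scored_cohort, dos, ids, "bmi_measured",
                                  spec, covariate_cols=PCS)
        split = per_snp_summaries(scored_cohort, dos, ids, "bmi_measured",
                                  spec, covariate_cols=PCS,
                                  sample_split=True, seed=4)
        # halves carry less information: larger SEs on both sides
        assert (split.se_zx > whole.se_zx).all()
        assert (split.se_zy > whole.se_zy).all()

    def test_too_few_variants_refused(self, scored_cohort, small_sim):
        with pytest.raises(FitError):
            per_snp_summaries(scored_cohort, small_sim.geno.dosages,
                              ["bmi_0000", "bmi_0001"], "bmi_measured",
                              HazardModelSpec(cause="all"))

    def test_monomorphic_variant_dropped(self, small_sim, scored_cohort):
        ids = small_sim.panel[small_sim.panel.trait == "bmi"]
        ids = ids.variant_id.tolist()[:5]
        dos = small_sim.geno.dosages.loc[scored_cohort.index].copy()
        dos[ids[2]] = 1.0
        spec = HazardModelSpec(cause="all", covariates=PCS)
        with pytest.warns(UserWarning, match="monomorphic"):
            summ = per_snp_summaries(scored_cohort, dos, ids,
                                     "bmi_measured", spec,
                                     covariate_cols=PCS)
        assert ids[2] not in set(summ.variant_id)


class TestIvw2s:
    def test_shared_ratio_recovered_with_zero_q(self):
        s = _summaries([0.07] * 5)
        est = ivw_2s(s)
        assert np.isclose(est.beta_iv, 0.07)
        assert np.isclose(est.extra["Q"], 0.0, atol=1e-20)

    def test_dominant_precision_variant_wins(self):
        s = _summaries([0.02, 0.3], weights=[1e6, 1e-2])
        est = ivw_2s(s)
        assert abs(est.beta_iv - 0.02) < 1e-3

    def test_matches_grid_search_minimizer(self):
        rng = np.random.default_rng(2)
        s = _summaries(rng.normal(0.08, 0.03, 5),
                       weights=rng.uniform(0.5, 4.0, 5))
        est = ivw_2s(s)
        grid = np.linspace(-0.2, 0.4, 600_001)
        w = 1.0 / s.se_zy.to_numpy() ** 2
        loss = sum(wj * (yj - grid * xj) ** 2
                   for wj, xj, yj in zip(w, s.beta_zx, s.beta_zy))
        assert abs(est.beta_iv - grid[np.argmin(loss)]) < 2e-6

    def test_random_effects_inflation_kicks_in(self):
        s = _summaries([0.0, 0.05, 0.20, -0.1, 0.3], weights=[400] * 5)
        est = ivw_2s(s)
        assert est.extra["Q"] > 4
        assert est.method == "ivw_2s_random"


class TestWeightedMedian:
    def test_equal_weights_simple_median(self):
        est = weighted_median(_summaries([1.0, 2.0, 3.0, 4.0, 5.0]), seed=0)
        assert np.isclose(est.beta_iv, 3.0)

    def test_majority_weight_variant_dominates(self):
        # centred-cumulative interpolation converges on the dominant
        # variant's ratio as its weight share grows
        est = weighted_median(
            _summaries([0.1, 0.1, 0.9], weights=[1, 1, 1000]), seed=0)
        assert abs(est.beta_iv - 0.9) < 0.01

    def test_matches_independent_cumulative_scan(self):
        rng = np.random.default_rng(3)
        ratios = rng.normal(0.1, 0.05, 7)
        weights = rng.uniform(0.5, 3.0, 7)
        est = weighted_median(_summaries(ratios, weights), seed=0)

        # independent replay: scan the centred cumulative weights
        order = np.argsort(ratios)
        r, w = ratios[order], weights[order]
        cum = (np.cumsum(w) - 0.5 * w) / w.sum()
        below = np.searchsorted(cum, 0.5) - 1
        frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
        oracle = r[below] + frac * (r[below + 1] - r[below])
        assert abs(est.beta_iv - oracle) < 1e-10

    def test_bootstrap_se_deterministic(self):
        s = _summaries([0.05, 0.07, 0.1, 0.12, 0.2])
        a = weighted_median(s, seed=9, n_boot=200)
        b = weighted_median(s, seed=9, n_boot=200)
        assert a.se_iv == b.se_iv


class TestEgger:
    def test_two_variants_refused(self):
        with pytest.raises(FitError):
            mr_egger(_summaries([0.1, 0.2]))

    def test_degenerate_spread_refused(self):
        s = _summaries([0.1, 0.12, 0.14])
        s["beta_zx"] = 0.5  # identical exposure betas
        with pytest.raises(FitError, match="spread"):
            mr_egger(s)

    def test_constant_pleiotropy_moves_intercept_not_slope(self):
        rng = np.random.default_rng(5)
        k = 12
        bx = rng.uniform(0.05, 0.3, k)
        by = 0.1 * bx + rng.normal(0, 0.005, k)
        s = pd.DataFrame({"variant_id": [f"v{j}" for j in range(k)],
                          "beta_zx": bx, "se_zx": np.full(k, 0.01),
                          "beta_zy": by, "se_zy": np.full(k, 0.02)})
        base = mr_egger(s)
        shifted = s.assign(beta_zy=s.beta_zy + 0.04)
        res = mr_egger(shifted)
        assert np.isclose(res["intercept"], base["intercept"] + 0.04,
                          atol=1e-10)
        assert np.isclose(res["slope"].beta_iv, base["slope"].beta_iv,
                          atol=1e-10)

    def test_null_intercept_calibrated(self):
        rng = np.random.default_rng(6)
        hits = 0
        reps = 50
        for _ in range(reps):
            k = 30
            bx = rng.uniform(0.05, 0.3, k)
            se_zy = np.full(k, 0.02)
            by = 0.1 * bx + rng.normal(0, se_zy)
            s = pd.DataFrame({"variant_id": [f"v{j}" for j in range(k)],
                              "beta_zx": bx, "se_zx": np.full(k, 0.01),
                              "beta_zy": by, "se_zy": se_zy})
            res = mr_egger(s)
            hits += abs(res["intercept"]) < 2 * res["se_intercept"]
        assert hits >= 0.9 * reps
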