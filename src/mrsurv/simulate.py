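"""Synthetic admixed-cohort generator with known causal parameters.

Every downstream estimator in the package is exercised against cohorts from
this module, in which the complete data-generating process is known: a
two-sex admixed population with polygenic BMI and diabetes-liability scores,
confounding of measured BMI with mortality, diabetes arising on a
liability-threshold scale from true BMI and the diabetes score,
hyperglycaemia-driven weight loss in diagnosed diabetes (reverse causality),
and a Gompertz-baseline proportional-hazards mortality process over attained
age with a hierarchical cause-of-death mix and administrative censoring.

The hazard coefficients are derived from two interpretable inputs: the total
causal log hazard ratio per kg/m² of lifelong BMI, and the fraction of that
effect routed through diabetes. The direct BMI coefficient is
``(1 - mediated_fraction) * causal_loghr_per_unit``; the diabetes-state
coefficient is calibrated analytically so that the average marginal effect of
BMI on the (severity-weighted) diabetes state times that coefficient equals
the mediated share. Undiagnosed diabetes carries a configurable fraction of
the diagnosed log hazard, and the weight-loss delta applies to diagnosed
diabetes only, which together reproduce the motivating bias: an observational
fit of mortality on measured BMI among diabetics is biased below the causal
value, while MR on the same data is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.utils.extmath import randomized_svd

from .causes import LEAF_CAUSES
from .params import ParameterError, SimulationParams

_ALLELES = np.array(list("ACGT"))

EXCLUSION_ORDER = (
    "qc_fail",
    "age_ge_90",
    "implausible_anthropometry",
    "uncertain_linkage",
)


# ---------------------------------------------------------------------------
# variant panels
# ---------------------------------------------------------------------------


def simulate_panel(params: SimulationParams) -> pd.DataFrame:
    """Variant panels for the BMI and diabetes-liability scores.

    Returns a frame with columns ``variant_id, effect_allele, other_allele,
    weight, allele_freq, trait``. The two trait panels are disjoint by
    construction. Per-allele weights are scaled so that the implied score
    variance under Hardy-Weinberg dosage variance ``2p(1-p)`` equals
    ``target_r2`` (score in exposure-SD units), i.e. the score explains
    ``target_r2`` of an exposure with unit variance.
    """
    params.validate()
    rng = params.rng("panel")
    rows = []
    for trait, n_var in (("bmi", params.n_variants_bmi),
                         ("diab", params.n_variants_diab)):
        freq = rng.uniform(0.05, 0.95, n_var)
        raw_w = rng.normal(size=n_var)
        hw_var = 2.0 * freq * (1.0 - freq)
        scale = np.sqrt(params.target_r2 / np.sum(raw_w**2 * hw_var))
        a_idx = rng.integers(0, 4, n_var)
        b_idx = (a_idx + rng.integers(1, 4, n_var)) % 4
        for j in range(n_var):
            rows.append({
                "variant_id": f"{trait}_{j:04d}",
                "effect_allele": _ALLELES[a_idx[j]],
                "other_allele": _ALLELES[b_idx[j]],
                "weight": raw_w[j] * scale,
                "allele_freq": freq[j],
                "trait": trait,
            })
    panel = pd.DataFrame(rows)
    validate_panel(panel)
    return panel


def validate_panel(panel: pd.DataFrame) -> None:
    if panel["variant_id"].duplicated().any():
        raise ParameterError("variant ids must be unique")
    if not ((panel["allele_freq"] > 0) & (panel["allele_freq"] < 1)).all():
        raise ParameterError("allele frequencies must lie in (0, 1)")
    by_trait = panel.groupby("trait")["variant_id"].apply(set)
    if len(by_trait) > 1:
        inter = set.intersection(*by_trait.tolist())
        if inter:
            raise ParameterError(
                f"trait panels must be disjoint; shared: {sorted(inter)[:5]}"
            )


# ---------------------------------------------------------------------------
# genotypes, ancestry, principal components
# ---------------------------------------------------------------------------


@dataclass
class GenotypeData:
    dosages: pd.DataFrame  # n x V, float32, columns = variant ids
    coded_allele: dict  # variant id -> allele counted by the dosage
    other_allele: dict
    ancestry_prop: np.ndarray  # fraction Indigenous-American-like
    pcs: np.ndarray  # n x n_pcs
    family_id: np.ndarray | None = None  # sibling blocks, if simulated


def simulate_genotypes(panel: pd.DataFrame,
                       params: SimulationParams) -> GenotypeData:
    """Draw dosages with ancestry-dependent allele frequencies.

    Each individual draws an admixture proportion from a Beta distribution
    (median near 0.67). Per-variant allele frequencies shift linearly with
    ancestry (random per-variant sign and magnitude up to
    ``ancestry_freq_shift``), so the leading principal component of the
    centred dosage matrix tracks ancestry. Dosages are posterior-mean style
    (imputation quality ~0.95) unless ``hard_calls`` is set.
    """
    validate_panel(panel)
    n = params.n_individuals
    rng = params.rng("genotypes")
    anc = rng.beta(params.ancestry_beta_a, params.ancestry_beta_b, n)
    anc_c = anc - anc.mean()

    V = len(panel)
    freqs = panel["allele_freq"].to_numpy()
    signs = rng.choice([-1.0, 1.0], V)
    mags = rng.uniform(0.5, 1.0, V) * params.ancestry_freq_shift
    dos = np.empty((n, V), dtype=np.float32)
    q = 0.95  # imputation-quality shrinkage toward 2p for soft dosages
    for j in range(V):
        pj = np.clip(freqs[j] + signs[j] * mags[j] * anc_c, 0.01, 0.99)
        g = rng.binomial(2, pj).astype(np.float32)
        if params.hard_calls:
            dos[:, j] = g
        else:
            dos[:, j] = q * g + (1.0 - q) * 2.0 * pj

    fam = None
    if params.sibling_block_frac > 0:
        # sibling pairs share ~half their deviations from expectation
        n_pairs = int(params.sibling_block_frac * n / 2)
        fam = np.arange(n)
        idx = rng.choice(n, size=2 * n_pairs, replace=False)
        a, b = idx[:n_pairs], idx[n_pairs:]
        share = rng.random((n_pairs, V)) < 0.5
        dos[b] = np.where(share, dos[a], dos[b])
        fam[b] = fam[a]

    centred = dos - dos.mean(axis=0, keepdims=True)
    k = min(params.n_pcs, V, n - 1)
    svd_seed = int(params.rng("pca").integers(2**31 - 1))
    U, S, _ = randomized_svd(centred, n_components=k, random_state=svd_seed)
    pcs = U * S
    # stable sign convention: largest-|score| coordinate positive
    for c in range(k):
        j = np.argmax(np.abs(pcs[:, c]))
        if pcs[j, c] < 0:
            pcs[:, c] = -pcs[:, c]
    pcs = pcs / pcs.std(axis=0, ddof=0)

    dosages = pd.DataFrame(dos, columns=panel["variant_id"].tolist())
    return GenotypeData(
        dosages=dosages,
        coded_allele=dict(zip(panel["variant_id"], panel["effect_allele"])),
        other_allele=dict(zip(panel["variant_id"], panel["other_allele"])),
        ancestry_prop=anc,
        pcs=pcs,
        family_id=fam,
    )


def _raw_score(dosages: pd.DataFrame, panel: pd.DataFrame,
               trait: str) -> np.ndarray:
    sub = panel[panel["trait"] == trait]
    cols = sub["variant_id"].tolist()
    w = sub["weight"].to_numpy(float)
    d = dosages[cols].to_numpy()
    out = np.zeros(d.shape[0])
    for lo in range(0, d.shape[1], 128):
        hi = min(lo + 128, d.shape[1])
        out += d[:, lo:hi].astype(float) @ w[lo:hi]
    return out


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(geno: GenotypeData, panel: pd.DataFrame,
                        params: SimulationParams) -> pd.DataFrame:
    """Generate the cohort table: sex, ages, BMI, diabetes, covariates.

    True lifelong BMI combines a sex-specific intercept, the genetic score
    (sex-specific slope per score SD), an ancestry effect, a latent
    confounder, and residual noise, with per-sex residual variances chosen so
    that the measured-BMI mean/SD land on the calibration targets. Diabetes
    arises from a probit-style liability on true BMI and the diabetes score,
    thresholded empirically at the target prevalence; the most severe 13/18
    of diabetic liability is "diagnosed". Measured BMI subtracts the
    weight-loss delta in diagnosed diabetes and adds measurement noise.
    """
    params.validate()
    n = params.n_individuals
    rng = params.rng("phenotypes")

    sex = np.where(rng.random(n) < params.frac_female, "female", "male")
    female = sex == "female"

    entry = rng.normal(params.entry_age_mean, params.entry_age_sd, n)
    bad = (entry < 35) | (entry >= 90)
    while bad.any():
        entry[bad] = rng.normal(params.entry_age_mean, params.entry_age_sd,
                                int(bad.sum()))
        bad = (entry < 35) | (entry >= 90)

    s_bmi = _raw_score(geno.dosages, panel, "bmi")
    s_bmi_std = (s_bmi - s_bmi.mean()) / s_bmi.std(ddof=0)
    s_diab = _raw_score(geno.dosages, panel, "diab")
    s_diab_std = (s_diab - s_diab.mean()) / s_diab.std(ddof=0)

    # planted selection defect: high-score individuals cannot enter old
    if params.entry_truncation_strength > 0:
        cap = 74.0 - 15.0 * params.entry_truncation_strength
        mask = (s_bmi_std > 0) & (entry > cap)
        entry[mask] = rng.uniform(35.0, cap, int(mask.sum()))

    confounder = rng.normal(size=n)
    anc_c = geno.ancestry_prop - geno.ancestry_prop.mean()
    anc_var = float(anc_c.var())

    diag_prev = params.diabetes_prevalence * params.diagnosed_fraction
    bmi_true = np.empty(n)
    for s, is_s in (("male", ~female), ("female", female)):
        slope = params.slope_by_sex[s]
        sd_target = params.bmi_sd_by_sex[s]
        resid_var = (sd_target**2 - slope**2
                     - params.confounder_strength**2
                     - params.ancestry_bmi_effect**2 * anc_var
                     - params.measurement_noise_sd**2)
        if resid_var <= 0:
            raise ParameterError(
                f"BMI variance components exceed the target SD for {s}")
        intercept = (params.bmi_mean_by_sex[s]
                     + params.reverse_causality_delta * diag_prev)
        k = int(is_s.sum())
        bmi_true[is_s] = (
            intercept
            + slope * s_bmi_std[is_s]
            + params.ancestry_bmi_effect * anc_c[is_s]
            + params.confounder_strength * confounder[is_s]
            + rng.normal(0.0, np.sqrt(resid_var), k)
        )

    # diabetes liability (unit-variance scale)
    bmi_c = bmi_true - bmi_true.mean()
    mu = (params.bmi_liability_slope * bmi_c
          + params.diab_score_liability_sd * s_diab_std)
    resid = 1.0 - float(mu.var())
    sigma_e = np.sqrt(max(resid, 0.1))
    liability = mu + rng.normal(0.0, sigma_e, n)
    tau1 = float(np.quantile(liability, 1.0 - params.diabetes_prevalence))
    tau2 = float(np.quantile(liability, 1.0 - diag_prev))
    diabetes = np.where(
        liability > tau2, "diagnosed",
        np.where(liability > tau1, "undiagnosed", "none"))

    bmi_measured = (bmi_true
                    - params.reverse_causality_delta * (diabetes == "diagnosed")
                    + rng.normal(0.0, params.measurement_noise_sd, n))
    if np.any(bmi_measured <= 0):
        raise ParameterError("non-positive measured BMI generated; "
                             "check variance parameters")

    cohort = pd.DataFrame({
        "individual_id": np.arange(n),
        "sex": sex,
        "entry_age": entry,
        "bmi_true": bmi_true,
        "bmi_measured": bmi_measured,
        "diabetes": diabetes,
        "ancestry_prop": geno.ancestry_prop,
        "district": np.where(rng.random(n) < 0.39, "A", "B"),
        "smoking": rng.choice(["never", "former", "current"], n,
                              p=[0.47, 0.20, 0.33]),
        "activity": np.where(rng.random(n) < 0.22, "any", "none"),
        "confounder": confounder,
        "liability_mu": mu,
    })
    for c in range(geno.pcs.shape[1]):
        cohort[f"pc{c + 1}"] = geno.pcs[:, c]
    if geno.family_id is not None:
        cohort["family_id"] = geno.family_id
    cohort.attrs["liability_sigma"] = float(sigma_e)
    cohort.attrs["liability_tau1"] = tau1
    cohort.attrs["liability_tau2"] = tau2
    return cohort


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _gompertz_rate(params: SimulationParams) -> float:
    """Baseline Gompertz rate giving the reference cumulative mortality
    over ``followup_years`` from the mean entry age at linear predictor 0."""
    gam = params.gompertz_shape
    e0 = params.entry_age_mean - 35.0
    span = np.exp(gam * (e0 + params.followup_years)) - np.exp(gam * e0)
    return float(-np.log1p(-params.ref_cum_mortality) * gam / span)


def derived_hazard_coefficients(cohort: pd.DataFrame,
                                params: SimulationParams) -> dict:
    """Hazard coefficients implied by the causal parameters.

    ``causal_loghr_per_unit`` is defined as the estimand of a correctly
    specified MR analysis on this cohort: the slope of the log hazard per
    kg/m² of genetically shifted *measured* BMI. Three analytic corrections
    make the nominal parameter equal that estimand:

    * the mediated log-hazard slope per individual is ``a F'(mu)/F(mu)``
      with ``F(mu) = E[exp(beta_D * state_w) | mu]`` under the probit
      liability model (a plain mean-state calibration would understate it
      by Jensen's inequality, since diagnosed diabetes carries a large
      hazard multiplier);
    * individuals are weighted by their expected event probability when
      averaging that slope, because the partial likelihood learns the
      covariate effect from events, and the mediated slope is steepest
      exactly where events concentrate;
    * the first-stage denominator regresses *measured* BMI on the score,
      and diagnosed-diabetes weight loss shrinks that slope by the factor
      ``kappa = 1 - delta * dP(diagnosed)/d bmi``; the hazard-side target
      is scaled by ``kappa`` so the ratio estimand stays on the nominal
      value.

    ``beta_D`` then solves ``weighted_mean(a F'/F) = f * kappa * causal``
    by bracketed root finding, jointly with the event weights that depend
    on it (fixed-point over a few iterations), and
    ``beta_BMI = (1 - f) * kappa * causal``.
    """
    f = params.mediated_fraction
    if params.diab_loghr is not None:
        return {"beta_bmi": (1.0 - f) * params.causal_loghr_per_unit,
                "beta_diab": params.diab_loghr, "marginal_effect": np.nan,
                "kappa": 1.0}
    sigma = cohort.attrs["liability_sigma"]
    tau1 = cohort.attrs["liability_tau1"]
    tau2 = cohort.attrs["liability_tau2"]
    mu = cohort["liability_mu"].to_numpy()
    wu = params.undiagnosed_hazard_weight
    a = params.bmi_liability_slope
    z1 = (tau1 - mu) / sigma
    z2 = (tau2 - mu) / sigma
    p_none = stats.norm.cdf(z1)
    p_diag = stats.norm.sf(z2)
    p_undiag = np.clip(1.0 - p_none - p_diag, 0.0, 1.0)
    phi1 = stats.norm.pdf(z1)
    phi2 = stats.norm.pdf(z2)

    kappa = 1.0 - params.reverse_causality_delta * float(
        np.mean(a * phi2 / sigma))

    # deterministic subsample keeps the quadrature cheap at large n
    n = len(cohort)
    if n > 20_000:
        idx = params.rng("calibration").choice(n, 20_000, replace=False)
    else:
        idx = np.arange(n)
    mu_s = mu[idx]
    bmi_ref = float(np.mean(list(params.bmi_mean_by_sex.values())))
    bmi_c = cohort["bmi_true"].to_numpy()[idx] - bmi_ref
    anc = cohort["ancestry_prop"].to_numpy()
    is_male = cohort["sex"].to_numpy()[idx] == "male"
    eta_x = (params.confounder_loghr * cohort["confounder"].to_numpy()[idx]
             + params.sex_loghr * is_male
             + params.ancestry_loghr * (anc - anc.mean())[idx])
    gam = params.gompertz_shape
    lam = _gompertz_rate(params)
    entry = cohort["entry_age"].to_numpy()[idx]
    censor = np.minimum(entry + params.followup_years,
                        np.minimum(params.admin_censor_age, 75.0))

    # age quadrature over the primary analysis window [35, 75)
    tgrid = np.linspace(35.5, 74.5, 14)
    H0 = lambda t: (lam / gam) * np.expm1(gam * (t - 35.0))  # noqa: E731
    h0 = lam * np.exp(gam * (tgrid - 35.0))
    at_risk = (tgrid[None, :] > entry[:, None]) & (
        tgrid[None, :] < censor[:, None])
    dH = np.clip(H0(tgrid)[None, :] - H0(entry)[:, None], 0.0, None)

    delta = 0.25
    band_cache = {}
    for shift in (0.0, +delta, -delta):
        mu2 = mu_s + a * shift
        z1s = (tau1 - mu2) / sigma
        z2s = (tau2 - mu2) / sigma
        band_cache[shift] = [
            stats.norm.cdf(z1s),
            np.clip(stats.norm.cdf(z2s) - stats.norm.cdf(z1s), 0, 1),
            stats.norm.sf(z2s)]

    def hazard_pieces(beta_bmi: float, beta_d: float, shift: float,
                      move_liability: bool):
        """A = E[r e^{-r dH}], B = E[e^{-r dH}] per (individual, age).

        ``shift`` perturbs BMI; for the total-effect gradient the liability
        bands move with it, for the direct-effect gradient they are held
        fixed (a BMI change at constant genetic diabetes liability).
        """
        probs = band_cache[shift if move_liability else 0.0]
        bshift = bmi_c + shift
        r0 = np.exp(beta_bmi * bshift
                    + params.bmi_loghr_quadratic * bshift**2 + eta_x)
        A = np.zeros_like(dH)
        B = np.zeros_like(dH)
        for p_s, w_s in zip(probs, (0.0, wu, 1.0)):
            r = (r0 * np.exp(beta_d * w_s))[:, None]
            e = np.exp(-r * dH)
            A += p_s[:, None] * r * e
            B += p_s[:, None] * e
        return A, B

    def realized_slope(beta_bmi: float, beta_d: float,
                       move_liability: bool) -> float:
        """Event-weighted d/d(bmi) of the log population marginal hazard.

        A uniform BMI shift is what a score shift induces (scaled by the
        first-stage slope), so the derivative of the at-risk-pooled hazard
        ``sum_i A_i / sum_i B_i`` per age, averaged over ages with expected
        event weights, is the large-sample Cox slope on that pathway.
        Aggregation is within sex (the analysis is sex-stratified) before
        pooling the per-(sex, age) gradients.
        """
        A0, _ = hazard_pieces(beta_bmi, beta_d, 0.0, move_liability)
        Ap, Bp = hazard_pieces(beta_bmi, beta_d, +delta, move_liability)
        Am, Bm = hazard_pieces(beta_bmi, beta_d, -delta, move_liability)
        num = 0.0
        den = 0.0
        for grp in (is_male, ~is_male):
            if not grp.any():
                continue
            occupied = at_risk[grp].any(axis=0)
            if not occupied.any():
                continue
            sAp = (at_risk[grp] * Ap[grp]).sum(axis=0)[occupied]
            sBp = (at_risk[grp] * Bp[grp]).sum(axis=0)[occupied]
            sAm = (at_risk[grp] * Am[grp]).sum(axis=0)[occupied]
            sBm = (at_risk[grp] * Bm[grp]).sum(axis=0)[occupied]
            grad_t = (np.log(sAp / sBp) - np.log(sAm / sBm)) / (2 * delta)
            w_t = (h0[occupied]
                   * (at_risk[grp] * A0[grp]).sum(axis=0)[occupied])
            num += (w_t * grad_t).sum()
            den += w_t.sum()
        if den <= 0:
            raise ParameterError(
                "no individuals at risk inside the analysis window; "
                "cannot calibrate the hazard coefficients")
        return float(num / den)

    target_total = kappa * params.causal_loghr_per_unit
    target_direct = (1.0 - f) * target_total
    from scipy.optimize import brentq
    beta_bmi = target_direct
    beta_d = 0.0
    for _ in range(4):
        # direct coefficient compensates for risk-set depletion attenuation
        if target_direct > 0:
            realized = realized_slope(beta_bmi, beta_d, move_liability=False)
            beta_bmi = beta_bmi * target_direct / realized if realized > 0 \
                else target_direct
        else:
            beta_bmi = 0.0
        if f == 0.0:
            break
        # the total-effect slope rises with beta_D and then falls again once
        # the diabetes pathway depletes the risk set; root-find on the
        # rising branch (after the first pass, bracket near the last root)
        fun = lambda b: realized_slope(beta_bmi, b, True) - target_total  # noqa: E731
        if beta_d > 0 and fun(0.6 * beta_d) < 0 < fun(1.4 * beta_d):
            beta_d = brentq(fun, 0.6 * beta_d, 1.4 * beta_d, xtol=1e-8)
            continue
        grid = np.linspace(0.0, 8.0, 9)
        vals = np.array([fun(b) for b in grid])
        above = np.nonzero(vals >= 0)[0]
        if len(above) == 0:
            raise ParameterError(
                f"mediated_fraction {f} is not attainable through the "
                "diabetes pathway under the current liability parameters")
        j = above[0]
        beta_d = 0.0 if j == 0 else brentq(fun, grid[j - 1], grid[j],
                                           xtol=1e-8)
    return {"beta_bmi": float(beta_bmi), "beta_diab": float(beta_d),
            "marginal_effect": realized_slope(beta_bmi, beta_d, True),
            "kappa": kappa}


def simulate_survival(cohort: pd.DataFrame, params: SimulationParams,
                      dosages: pd.DataFrame | None = None,
                      panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Draw left-truncated, right-censored survival records.

    Event times come from a Gompertz-baseline proportional-hazards model on
    attained age, conditional on survival to recruitment (inverse-transform
    sampling of the conditional cumulative hazard). Administrative censoring
    at ``entry + followup_years`` and ``admin_censor_age``. On death, a leaf
    cause is drawn from ``cause_mix``; any-diabetes up-weights renal and
    acute-diabetic-crisis causes by ``diab_cause_multiplier``.

    If ``pleiotropy_frac > 0``, the first ``frac * n_variants_bmi`` BMI
    variants get a direct per-allele effect ``pleiotropy_loghr`` on the
    hazard (exclusion-restriction violation); this requires ``dosages`` and
    ``panel``.
    """
    params.validate()
    rng = params.rng("survival")
    n = len(cohort)
    coef = derived_hazard_coefficients(cohort, params)

    bmi_ref = float(np.mean(list(params.bmi_mean_by_sex.values())))
    bmi_c = cohort["bmi_true"].to_numpy() - bmi_ref
    state_w = np.select(
        [cohort["diabetes"] == "diagnosed", cohort["diabetes"] == "undiagnosed"],
        [1.0, params.undiagnosed_hazard_weight], 0.0)
    anc_c = cohort["ancestry_prop"].to_numpy()
    anc_c = anc_c - anc_c.mean()
    eta = (coef["beta_bmi"] * bmi_c
           + params.bmi_loghr_quadratic * bmi_c**2
           + coef["beta_diab"] * state_w
           + params.confounder_loghr * cohort["confounder"].to_numpy()
           + params.sex_loghr * (cohort["sex"].to_numpy() == "male")
           + params.ancestry_loghr * anc_c)
    if params.pleiotropy_frac > 0:
        if dosages is None or panel is None:
            raise ParameterError(
                "pleiotropy_frac > 0 requires dosages and panel")
        bmi = panel[panel["trait"] == "bmi"].set_index("variant_id")
        k = int(round(params.pleiotropy_frac * len(bmi)))
        # pleiotropy sits on the variants with the weakest primary-trait
        # effects, mirroring the enrichment of pleiotropy-dominated signals
        # among borderline GWAS hits
        bad = bmi["weight"].abs().sort_values().index[:k]
        d = dosages[list(bad)].to_numpy(float)
        # direct effects aligned with each variant's BMI-increasing allele,
        # so the planted pleiotropy is directional after harmonization
        sign = np.sign(bmi.loc[bad, "weight"].to_numpy())
        centred = d - 2.0 * bmi.loc[bad, "allele_freq"].to_numpy()
        eta = eta + params.pleiotropy_loghr * (centred * sign).sum(axis=1)
    if not np.all(np.isfinite(eta)):
        raise ParameterError("non-finite hazard linear predictor; "
                             "generation aborted")

    gam = params.gompertz_shape
    lam = _gompertz_rate(params)

    entry = cohort["entry_age"].to_numpy()
    H0_entry = (lam / gam) * np.expm1(gam * (entry - 35.0))
    E = rng.exponential(1.0, n)
    H0_T = H0_entry + E * np.exp(-eta)
    T = 35.0 + np.log1p((gam / lam) * H0_T) / gam

    censor = np.minimum(entry + params.followup_years,
                        params.admin_censor_age)
    died = T < censor
    exit_age = np.where(died, T, censor)

    cause = np.full(n, "none", dtype=object)
    leaf = list(LEAF_CAUSES)
    base_p = np.array([params.cause_mix[c] for c in leaf])
    boosted = base_p.copy()
    for c in ("renal", "acute-diabetic-crisis"):
        boosted[leaf.index(c)] *= params.diab_cause_multiplier
    boosted = boosted / boosted.sum()
    has_diab = (cohort["diabetes"] != "none").to_numpy()
    for mask, probs in ((died & ~has_diab, base_p), (died & has_diab, boosted)):
        k = int(mask.sum())
        if k:
            cause[mask] = rng.choice(leaf, size=k, p=probs)

    return pd.DataFrame({
        "individual_id": cohort["individual_id"].to_numpy(),
        "entry_age": entry,
        "exit_age": exit_age,
        "died": died,
        "cause": cause,
    })


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------


def simulate_exclusion_flags(params: SimulationParams,
                             n: int | None = None) -> pd.DataFrame:
    """Independent Bernoulli exclusion flags at the configured rates."""
    rng = params.rng("exclusions")
    n = params.n_individuals if n is None else n
    return pd.DataFrame({
        name: rng.random(n) < rate
        for name, rate in params.exclusion_rates.items()
    })


def apply_exclusions(cohort: pd.DataFrame, flags: pd.DataFrame,
                     order: tuple = EXCLUSION_ORDER):
    """Sequential exclusion cascade with a ledger.

    Flags are applied in ``order``; each step's removed count is conditional
    on surviving all prior steps (an individual failing two criteria is
    counted only under the first). Returns the 35-74 analysis set, the 75-89
    older set, and the ledger with per-step counts and percentages of the
    initial cohort.
    """
    unknown = [f for f in order if f not in flags.columns]
    if unknown:
        raise ParameterError(f"unknown exclusion flags: {unknown}")
    n0 = len(cohort)
    alive = np.ones(n0, dtype=bool)
    rows = []
    for name in order:
        fail = flags[name].to_numpy(bool) & alive
        rows.append({
            "step": name,
            "n_before": int(alive.sum()),
            "n_removed": int(fail.sum()),
            "pct_of_initial": round(100.0 * fail.sum() / n0, 1),
        })
        alive &= ~fail
    kept = cohort[alive].copy()
    ledger = pd.DataFrame(rows)
    ledger["n_remaining"] = ledger["n_before"] - ledger["n_removed"]
    young = kept[kept["entry_age"] < 75.0].copy()
    old = kept[(kept["entry_age"] >= 75.0) & (kept["entry_age"] < 90.0)].copy()
    return young, old, ledger


# ---------------------------------------------------------------------------
# one-call cohort bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    params: SimulationParams
    panel: pd.DataFrame
    geno: GenotypeData
    cohort: pd.DataFrame
    survival: pd.DataFrame
    flags: pd.DataFrame
    hazard_coefficients: dict

    @property
    def table(self) -> pd.DataFrame:
        """Cohort and survival columns merged on individual id."""
        return self.cohort.merge(
            self.survival.drop(columns="entry_age"), on="individual_id")


def simulate_cohort(params: SimulationParams) -> SimulatedCohort:
    """Run the full generator pipeline under one seed."""
    panel = simulate_panel(params)
    geno = simulate_genotypes(panel, params)
    cohort = simulate_phenotypes(geno, panel, params)
    survival = simulate_survival(cohort, params, geno.dosages, panel)
    flags = simulate_exclusion_flags(params)
    coef = derived_hazard_coefficients(cohort, params)
    return SimulatedCohort(params=params, panel=panel, geno=geno,
                           cohort=cohort, survival=survival, flags=flags,
                           hazard_coefficients=coef)
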