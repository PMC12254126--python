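"""Summary-statistic MR sensitivity estimators.

Each variant acts as a separate instrument: per-variant marginal
associations with the exposure (linear) and with mortality (cause-specific
Cox) are harmonized to the exposure-increasing allele, then combined by
inverse-variance weighting, by the weighted median (consistent when valid
instruments carry a majority of the weight), and by MR-Egger regression
(whose intercept estimates directional pleiotropy). Although the summary
statistics here come from one cohort, the estimators are the standard
two-sample forms used as sensitivity analyses alongside the one-sample
allele-score estimate; an optional 50/50 sample split computes the exposure
and outcome associations in disjoint halves.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import (FitError, HazardModelSpec, cox_ph, event_indicator,
                    restrict_window)
from .onesample import CausalEstimate, cochran_q


def per_snp_summaries(records: pd.DataFrame, dosages: pd.DataFrame,
                      variant_ids: list[str], exposure: str,
                      spec: HazardModelSpec, covariate_cols: tuple = (),
                      sample_split: bool = False,
                      seed: int = 0) -> pd.DataFrame:
    """Per-variant marginal exposure and outcome associations, harmonized.

    Exposure betas come from per-variant OLS of the exposure on dosage plus
    covariates (via residualization); outcome betas from per-variant Cox
    fits with the same covariates. Orientation is harmonized so that every
    ``beta_zx >= 0``, flipping the outcome beta in tandem. Monomorphic
    variants are dropped with a warning.
    """
    if len(variant_ids) < 3:
        raise FitError("need at least 3 variants for summary-statistic MR")
    df = restrict_window(records, spec.age_lo, spec.age_hi)
    rows_idx = df.index
    D = dosages.loc[rows_idx, variant_ids].to_numpy(float)
    keep = D.std(axis=0) > 1e-8
    if not keep.all():
        dropped = [v for v, k in zip(variant_ids, keep) if not k]
        warnings.warn(f"dropped {len(dropped)} monomorphic variants")
        variant_ids = [v for v, k in zip(variant_ids, keep) if k]
        D = D[:, keep]
    n = len(df)
    if sample_split:
        rng = np.random.default_rng(seed)
        half = rng.permutation(n) < n // 2
    else:
        half = np.ones(n, dtype=bool)

    y = df[exposure].to_numpy(float)
    C = (df[list(covariate_cols)].to_numpy(float)
         if covariate_cols else np.empty((n, 0)))
    Caug = np.column_stack([np.ones(n), C])

    def residualize(M, mask):
        A = Caug[mask]
        coef = np.linalg.lstsq(A, M[mask], rcond=None)[0]
        return M[mask] - A @ coef

    # exposure side (first half under sample splitting)
    ym = residualize(y, half)
    Dm = residualize(D, half)
    ssx = (Dm**2).sum(axis=0)
    beta_zx = Dm.T @ ym / ssx
    k_cov = Caug.shape[1]
    dof = int(half.sum()) - k_cov - 1
    rss = (ym**2).sum() - beta_zx**2 * ssx
    se_zx = np.sqrt(np.maximum(rss / dof, 0.0) / ssx)

    # outcome side (second half under sample splitting)
    out_mask = ~half if sample_split else half
    sub = df[out_mask]
    ev = event_indicator(sub, spec.cause)
    if int(ev.sum()) < spec.min_events:
        raise FitError(f"too few {spec.cause!r} events for per-SNP fits")
    entry = sub["entry_age"].to_numpy(float)
    exit_ = sub["exit_age"].to_numpy(float)
    Csub = C[out_mask]
    beta_zy = np.empty(len(variant_ids))
    se_zy = np.empty(len(variant_ids))
    init = None
    for j in range(len(variant_ids)):
        X = np.column_stack([D[out_mask, j], Csub])
        fit = cox_ph(X, entry, exit_, ev, init=init)
        if init is None:
            init = fit.beta.copy()
            init[0] = 0.0
        beta_zy[j], se_zy[j] = float(fit.beta[0]), float(fit.se[0])

    out = pd.DataFrame({
        "variant_id": variant_ids,
        "beta_zx": beta_zx, "se_zx": se_zx,
        "beta_zy": beta_zy, "se_zy": se_zy,
    })
    return harmonize(out)


def harmonize(summaries: pd.DataFrame) -> pd.DataFrame:
    """Orient every variant to its exposure-increasing allele."""
    out = summaries.copy()
    neg = out["beta_zx"] < 0
    out.loc[neg, "beta_zx"] *= -1.0
    out.loc[neg, "beta_zy"] *= -1.0
    return out


def _check(summaries: pd.DataFrame, min_variants: int) -> pd.DataFrame:
    if len(summaries) < min_variants:
        raise FitError(
            f"need >= {min_variants} variants, got {len(summaries)}")
    if (summaries[["se_zx", "se_zy"]] <= 0).any().any():
        raise ValueError("standard errors must be positive")
    return summaries


def ivw_2s(summaries: pd.DataFrame, report_scale: float = 5.0,
           label: str = "ivw") -> CausalEstimate:
    """IVW estimate: weighted regression of beta_zy on beta_zx through the
    origin with weights 1/se_zy²; multiplicative random-effects SE inflation
    when Cochran Q exceeds its degrees of freedom."""
    s = _check(summaries, 2)
    bx, by = s["beta_zx"].to_numpy(), s["beta_zy"].to_numpy()
    w = 1.0 / s["se_zy"].to_numpy() ** 2
    theta = float((w * bx * by).sum() / (w * bx**2).sum())
    se = float(1.0 / np.sqrt((w * bx**2).sum()))
    q = float((w * (by - theta * bx) ** 2).sum())
    dof = len(s) - 1
    overdispersion = max(1.0, q / dof) if dof > 0 else 1.0
    model = "random" if overdispersion > 1.0 else "fixed"
    se *= np.sqrt(overdispersion)
    return CausalEstimate(
        label=label, beta_iv=theta, se_iv=se, report_scale=report_scale,
        method=f"ivw_2s_{model}",
        extra={"Q": q, "Q_dof": dof,
               "Q_p": float(stats.chi2.sf(q, dof)) if dof > 0 else np.nan},
    )


def weighted_median(summaries: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0, report_scale: float = 5.0,
                    label: str = "weighted_median") -> CausalEstimate:
    """Weighted median of per-variant ratio estimates.

    Ratios are ordered and weighted by inverse ratio-variance (first-order
    delta approximation ``se_zy/|beta_zx|``); the estimate interpolates
    where the centred cumulative weight crosses 50%. The SE comes from a
    parametric bootstrap of the summary statistics.
    """
    s = _check(summaries, 3)

    def wm(bx, by, se_zy):
        ratio = by / bx
        w = (bx / se_zy) ** 2
        order = np.argsort(ratio, kind="stable")
        ratio, w = ratio[order], w[order]
        cum = (np.cumsum(w) - 0.5 * w) / w.sum()
        return float(np.interp(0.5, cum, ratio))

    bx = s["beta_zx"].to_numpy()
    by = s["beta_zy"].to_numpy()
    sx = s["se_zx"].to_numpy()
    sy = s["se_zy"].to_numpy()
    est = wm(bx, by, sy)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(len(bx))
        byb = by + sy * rng.standard_normal(len(by))
        draws[b] = wm(bxb, byb, sy)
    se = float(draws.std(ddof=1))
    return CausalEstimate(label=label, beta_iv=est, se_iv=se,
                          report_scale=report_scale, method="weighted_median")


def mr_egger(summaries: pd.DataFrame, report_scale: float = 5.0,
             label: str = "mr_egger") -> dict:
    """MR-Egger regression: WLS of beta_zy on beta_zx with a free intercept.

    The slope is the causal estimate; the intercept estimates the average
    directional pleiotropy per variant, with a two-sided p-value. Standard
    errors use multiplicative overdispersion (never deflated below 1). The
    I²_GX statistic quantifies regression-dilution risk from first-stage
    imprecision. Refuses when the spread in beta_zx is degenerate.
    """
    s = _check(summaries, 3)
    bx, by = s["beta_zx"].to_numpy(), s["beta_zy"].to_numpy()
    w = 1.0 / s["se_zy"].to_numpy() ** 2
    xbar = (w * bx).sum() / w.sum()
    sxx = (w * (bx - xbar) ** 2).sum()
    if sxx < 1e-12 or bx.std() < 1e-8 * max(1.0, np.abs(bx).mean()):
        raise FitError("no spread in beta_zx; MR-Egger is unidentified")
    ybar = (w * by).sum() / w.sum()
    slope = float((w * (bx - xbar) * by).sum() / sxx)
    intercept = float(ybar - slope * xbar)
    k = len(s)
    resid = by - intercept - slope * bx
    sigma2 = float((w * resid**2).sum() / (k - 2))
    overdispersion = max(1.0, sigma2)
    se_slope = float(np.sqrt(overdispersion / sxx))
    se_int = float(np.sqrt(overdispersion * (1.0 / w.sum() + xbar**2 / sxx)))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), k - 2))

    wx = 1.0 / s["se_zx"].to_numpy() ** 2
    xw = (wx * bx).sum() / wx.sum()
    q_gx = float((wx * (bx - xw) ** 2).sum())
    i2_gx = max(0.0, (q_gx - (k - 1)) / q_gx) if q_gx > 0 else 0.0

    est = CausalEstimate(label=label, beta_iv=slope, se_iv=se_slope,
                         report_scale=report_scale, method="mr_egger",
                         extra={"i2_gx": i2_gx})
    return {"slope": est, "intercept": intercept, "se_intercept": se_int,
            "p_intercept": p_int, "i2_gx": i2_gx}


def estimator_suite(summaries: pd.DataFrame, seed: int = 0,
                    report_scale: float = 5.0) -> pd.DataFrame:
    """All two-sample estimators on one summary set, as a tidy table."""
    rows = []
    ivw = ivw_2s(summaries, report_scale)
    rows.append(ivw.as_row() | ivw.extra)
    med = weighted_median(summaries, seed=seed, report_scale=report_scale)
    rows.append(med.as_row())
    egger = mr_egger(summaries, report_scale)
    rows.append(egger["slope"].as_row()
                | {"egger_intercept": egger["intercept"],
                   "egger_intercept_p": egger["p_intercept"],
                   "i2_gx": egger["i2_gx"]})
    q, qp = cochran_q(summaries["beta_zy"].to_numpy()
                      / summaries["beta_zx"].to_numpy(),
                      summaries["se_zy"].to_numpy()
                      / summaries["beta_zx"].abs().to_numpy())
    rows.append({"label": "per_snp_heterogeneity", "method": "cochran_q",
                 "Q": q, "Q_p": qp})
    return pd.DataFrame(rows)
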