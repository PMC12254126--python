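"""One-sample MR: Wald ratios, sex pooling, 2SLS, subgroup analyses.

The primary estimator is the Wald ratio: the log hazard ratio per SD of
score (Cox second stage) divided by the exposure change per SD of score
(linear first stage), giving a log HR per exposure unit. Per-sex ratios are
pooled by inverse-variance weighting on the log-HR-per-unit scale, and
results are reported as hazard ratios per ``report_scale`` (default 5)
exposure units with 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import (FitError, HazardModelSpec, InstrumentOutcomeFit, cox_ph,
                    event_indicator, fit_linear, restrict_window)
from .scores import InstrumentExposureFit, instrument_strength

Z95 = 1.959963984540054


@dataclass
class CausalEstimate:
    label: str
    beta_iv: float  # log HR per 1 exposure unit
    se_iv: float
    report_scale: float = 5.0
    n_events: int | None = None
    method: str = "wald_ratio"
    weak_instrument: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def hr_scaled(self) -> float:
        return float(np.exp(self.report_scale * self.beta_iv))

    @property
    def ci_lo(self) -> float:
        return float(np.exp(self.report_scale
                            * (self.beta_iv - Z95 * self.se_iv)))

    @property
    def ci_hi(self) -> float:
        return float(np.exp(self.report_scale
                            * (self.beta_iv + Z95 * self.se_iv)))

    def covers(self, beta_true: float) -> bool:
        lo = self.beta_iv - Z95 * self.se_iv
        hi = self.beta_iv + Z95 * self.se_iv
        return lo <= beta_true <= hi

    def as_row(self) -> dict:
        return {
            "label": self.label, "method": self.method,
            "beta_iv": self.beta_iv, "se_iv": self.se_iv,
            "report_scale": self.report_scale, "hr_scaled": self.hr_scaled,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
            "n_events": self.n_events,
            "weak_instrument": self.weak_instrument,
        }


def wald_ratio(zy: InstrumentOutcomeFit, zx: InstrumentExposureFit,
               report_scale: float = 5.0,
               weak_f_floor: float = 10.0) -> CausalEstimate:
    """Wald ratio with the two-term delta-method standard error.

    ``beta_iv = beta_zy / beta_zx`` and
    ``se_iv = sqrt(se_zy²/beta_zx² + beta_zy²·se_zx²/beta_zx⁴)``.
    A first-stage F below ``weak_f_floor`` flags (never suppresses) the
    estimate.
    """
    if zx.beta_zx == 0:
        raise FitError("first-stage coefficient is exactly zero")
    weak = zx.f_statistic < weak_f_floor
    if weak:
        warnings.warn(
            f"weak instrument (F={zx.f_statistic:.1f} < {weak_f_floor}) for "
            f"{zy.cause!r}/{zy.subset!r}; estimate flagged")
    b = zy.beta_zy / zx.beta_zx
    se = np.sqrt(zy.se_zy**2 / zx.beta_zx**2
                 + zy.beta_zy**2 * zx.se_zx**2 / zx.beta_zx**4)
    return CausalEstimate(
        label=f"{zy.cause}|{zy.subset}", beta_iv=float(b), se_iv=float(se),
        report_scale=report_scale, n_events=zy.n_events,
        method="wald_ratio", weak_instrument=bool(weak),
    )


def ivw_pool(estimates: list[CausalEstimate],
             label: str | None = None) -> CausalEstimate:
    """Inverse-variance-weighted average of log-HR-per-unit estimates."""
    if not estimates:
        raise ValueError("nothing to pool")
    scales = {e.report_scale for e in estimates}
    if len(scales) > 1:
        raise ValueError(f"mixed report scales: {sorted(scales)}")
    w = np.array([1.0 / e.se_iv**2 for e in estimates])
    b = np.array([e.beta_iv for e in estimates])
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    events = [e.n_events for e in estimates]
    n_events = None if any(v is None for v in events) else int(sum(events))
    return CausalEstimate(
        label=label or " + ".join(e.label for e in estimates),
        beta_iv=beta, se_iv=se, report_scale=estimates[0].report_scale,
        n_events=n_events, method="ivw_pool",
        weak_instrument=any(e.weak_instrument for e in estimates),
    )


def onesample_mr(records: pd.DataFrame, score_col: str, exposure_col: str,
                 spec: HazardModelSpec, by: str = "sex",
                 report_scale: float = 5.0,
                 covariate_cols: tuple = ()) -> dict:
    """Sex-stratified Wald ratios and their IVW pool for one cause.

    ``records`` must carry the score (standardized within each analysis
    subset downstream of exclusions), the exposure, survival columns and any
    covariates. Returns per-level estimates plus the pooled one under key
    ``"pooled"``.
    """
    out = {}
    per_level = []
    levels = sorted(records[by].unique()) if by else ["all"]
    for level in levels:
        sub = records if by is None else records[records[by] == level]
        s = sub[score_col].to_numpy(float)
        s = (s - s.mean()) / s.std(ddof=0)
        zx = instrument_strength(
            s, sub[exposure_col].to_numpy(float),
            sub[list(covariate_cols)].to_numpy(float) if covariate_cols
            else None,
            subset=str(level))
        sub = sub.assign(**{score_col: s})
        zy = fit_cox_records(sub, score_col, spec, subset=str(level))
        est = wald_ratio(zy, zx, report_scale=report_scale)
        out[level] = est
        per_level.append(est)
    out["pooled"] = ivw_pool(per_level, label=f"{spec.cause}|pooled")
    return out


def fit_cox_records(records: pd.DataFrame, score: str, spec: HazardModelSpec,
                    subset: str = "all") -> InstrumentOutcomeFit:
    from .assoc import fit_cox
    return fit_cox(records, score, spec, subset=subset)


def tsls_estimate(records: pd.DataFrame, score_cols: list[str] | str,
                  exposure_col: str, spec: HazardModelSpec,
                  covariate_cols: tuple = (),
                  report_scale: float = 5.0,
                  subset: str = "all") -> CausalEstimate:
    """Two-stage least squares with a proportional-hazards second stage.

    Stage 1 regresses the exposure on the score(s) plus covariates; stage 2
    fits the Cox model on the stage-1 fitted values plus the same
    covariates. The second-stage standard error is reported as-is (it
    ignores first-stage uncertainty; the Wald-ratio delta SE is the primary
    inferential path, and the mediation bootstrap covers joint uncertainty).
    """
    if isinstance(score_cols, str):
        score_cols = [score_cols]
    df = restrict_window(records, spec.age_lo, spec.age_hi)
    Z = df[score_cols].to_numpy(float)
    C = df[list(covariate_cols)].to_numpy(float) if covariate_cols else None
    X1 = Z if C is None else np.column_stack([Z, C])
    stage1 = fit_linear(df[exposure_col].to_numpy(float), X1)
    pred = stage1.fitted
    cols = ["_pred_exposure"] + list(covariate_cols)
    df = df.assign(_pred_exposure=pred)
    ev = event_indicator(df, spec.cause)
    if int(ev.sum()) < spec.min_events:
        raise FitError(f"too few {spec.cause!r} events for 2SLS")
    fit = cox_ph(df[cols].to_numpy(float), df["entry_age"].to_numpy(float),
                 df["exit_age"].to_numpy(float), ev, names=cols)
    b, se = fit.coef("_pred_exposure")
    return CausalEstimate(
        label=f"{spec.cause}|{subset}", beta_iv=b, se_iv=se,
        report_scale=report_scale, n_events=fit.n_events, method="2sls",
    )


# ---------------------------------------------------------------------------
# subgroup analyses
# ---------------------------------------------------------------------------


def cochran_q(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Cochran heterogeneity Q across estimates and its chi-square p-value."""
    w = 1.0 / ses**2
    pooled = (w * betas).sum() / w.sum()
    q = float((w * (betas - pooled) ** 2).sum())
    dof = len(betas) - 1
    p = float(stats.chi2.sf(q, dof)) if dof > 0 else np.nan
    return q, p


def ivw_trend(betas: np.ndarray, ses: np.ndarray,
              x: np.ndarray) -> dict:
    """Inverse-variance-weighted linear trend of estimates on ``x``.

    Weighted least squares of beta on x with weights 1/se²; returns the
    slope, its SE and the two-sided normal p-value.
    """
    w = 1.0 / ses**2
    xbar = (w * x).sum() / w.sum()
    bbar = (w * betas).sum() / w.sum()
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx <= 0:
        return {"slope": np.nan, "se": np.nan, "p": np.nan}
    slope = float((w * (x - xbar) * (betas - bbar)).sum() / sxx)
    se = float(1.0 / np.sqrt(sxx))
    z = slope / se
    return {"slope": slope, "se": se, "p": float(2 * stats.norm.sf(abs(z)))}


#: ordered age-band windows used for the age subgroup analysis
AGE_BANDS = ((35.0, 60.0), (60.0, 70.0), (70.0, 75.0))


def subgroup_analysis(records: pd.DataFrame, score_col: str,
                      exposure_col: str, spec: HazardModelSpec,
                      dimension: str,
                      denominator: str = "global",
                      report_scale: float = 5.0,
                      covariate_cols: tuple = (),
                      min_events: int = 10) -> dict:
    """Per-level Wald ratios along one subgroup dimension.

    ``dimension`` is either ``"age-band"`` (window restriction to the
    ordered bands 35-59 / 60-69 / 70-74), ``"ancestry-tertile"``, or a
    categorical column (district, smoking, activity). ``denominator``
    selects the first-stage beta: ``"global"`` (one first stage on all
    records) or ``"subgroup"`` (level-specific). Returns per-level
    estimates, Cochran Q, and for ordered dimensions an IVW linear trend on
    level midpoints.
    """
    if denominator not in ("global", "subgroup"):
        raise ValueError("denominator must be 'global' or 'subgroup'")
    s_all = records[score_col].to_numpy(float)
    s_all = (s_all - s_all.mean()) / s_all.std(ddof=0)
    records = records.assign(**{score_col: s_all})
    cov = (records[list(covariate_cols)].to_numpy(float)
           if covariate_cols else None)
    zx_global = instrument_strength(
        s_all, records[exposure_col].to_numpy(float), cov, subset="global")

    levels: list[tuple[str, pd.DataFrame, HazardModelSpec, float]] = []
    if dimension == "age-band":
        for lo, hi in AGE_BANDS:
            lo2, hi2 = max(lo, spec.age_lo), min(hi, spec.age_hi)
            sub_spec = HazardModelSpec(
                cause=spec.cause, age_lo=lo2, age_hi=hi2,
                covariates=spec.covariates, min_events=min_events)
            levels.append((f"{lo2:.0f}-{hi2:.0f}", records, sub_spec,
                           (lo2 + hi2) / 2.0))
        ordered = True
    elif dimension == "ancestry-tertile":
        anc = records["ancestry_prop"]
        cut = pd.qcut(anc, 3, labels=["low", "mid", "high"])
        for i, lev in enumerate(["low", "mid", "high"]):
            sub = records[cut == lev]
            levels.append((lev, sub, spec,
                           float(anc[cut == lev].mean())))
        ordered = True
    else:
        if dimension not in records.columns:
            raise ValueError(f"unknown subgroup dimension {dimension!r}")
        for lev in sorted(records[dimension].astype(str).unique()):
            sub = records[records[dimension].astype(str) == lev]
            levels.append((lev, sub, spec, np.nan))
        ordered = False

    estimates = {}
    xs, bs, ss = [], [], []
    for name, sub, sub_spec, midpoint in levels:
        if len(sub) == 0:
            warnings.warn(f"empty subgroup level {name!r} dropped")
            continue
        try:
            zy = fit_cox_records(sub, score_col, sub_spec, subset=name)
        except FitError as err:
            warnings.warn(f"level {name!r} dropped: {err}")
            continue
        if denominator == "subgroup":
            c = (sub[list(covariate_cols)].to_numpy(float)
                 if covariate_cols else None)
            s = sub[score_col].to_numpy(float)
            zx = instrument_strength(
                s, sub[exposure_col].to_numpy(float), c, subset=name)
        else:
            zx = zx_global
        est = wald_ratio(zy, zx, report_scale=report_scale)
        est.label = f"{spec.cause}|{dimension}={name}"
        estimates[name] = est
        xs.append(midpoint)
        bs.append(est.beta_iv)
        ss.append(est.se_iv)

    bs, ss, xs = np.array(bs), np.array(ss), np.array(xs)
    q, q_p = cochran_q(bs, ss) if len(bs) > 1 else (0.0, np.nan)
    trend = (ivw_trend(bs, ss, xs)
             if ordered and len(bs) > 1 else
             {"slope": np.nan, "se": np.nan, "p": np.nan})
    return {"estimates": estimates, "Q": q, "Q_p": q_p, "trend": trend,
            "denominator": denominator}
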