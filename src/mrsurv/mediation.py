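"""Two-score mediation MR: direct effects and the proportion mediated.

The total effect of genetically predicted BMI on mortality is estimated by
2SLS with the BMI score; the direct effect (not mediated by diabetes) comes
from a joint Cox model containing genetically predicted BMI and genetically
predicted diabetes liability, where each stage-1 fit regresses its exposure
on BOTH scores (multivariable first stage). With disjoint instruments this
cross-instrumentation is what lets predicted diabetes liability absorb the
diabetes pathway of the BMI score; regressing each exposure only on its own
score would leave the two predictors orthogonal and the adjustment inert
(that variant remains available via ``cross_instruments=False``).

The proportion mediated is ``(loghr_total - loghr_direct) / loghr_total``,
with a bias-corrected (BC) percentile bootstrap CI over individual-level
resamples in which the full two-stage procedure is recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import (FitError, HazardModelSpec, cox_ph, event_indicator,
                    restrict_window)


@dataclass
class MediationResult:
    cause: str
    loghr_total: float  # per exposure unit
    loghr_direct: float
    proportion_mediated: float
    se_total: float
    se_direct: float
    ci_lo: float | None = None
    ci_hi: float | None = None
    n_boot_used: int | None = None
    n_boot_requested: int | None = None
    ci_unreliable: bool = False


def proportion_mediated(loghr_total: float, loghr_direct: float,
                        floor: float = 0.01) -> float:
    """``(total - direct) / total`` on the log-HR scale.

    Undefined (NaN) when ``|total|`` is below ``floor``, which guards the
    ratio against blow-up in null resamples.
    """
    if abs(loghr_total) < floor:
        return np.nan
    return (loghr_total - loghr_direct) / loghr_total


class _MediationData:
    """Pre-windowed arrays for fast repeated two-stage fits."""

    def __init__(self, records: pd.DataFrame, bmi_score: str,
                 diab_score: str, exposure: str, diabetes: str,
                 spec: HazardModelSpec, covariate_cols: tuple):
        df = restrict_window(records, spec.age_lo, spec.age_hi)
        self.zb = df[bmi_score].to_numpy(float)
        self.zd = df[diab_score].to_numpy(float)
        self.zb = (self.zb - self.zb.mean()) / self.zb.std(ddof=0)
        self.zd = (self.zd - self.zd.mean()) / self.zd.std(ddof=0)
        self.exposure = df[exposure].to_numpy(float)
        diab = df[diabetes]
        if diab.dtype == object or str(diab.dtype) == "category":
            self.diab = (diab.astype(str) != "none").to_numpy(float)
        else:
            self.diab = diab.to_numpy(float)
        self.C = (df[list(covariate_cols)].to_numpy(float)
                  if covariate_cols else np.empty((len(df), 0)))
        self.entry = df["entry_age"].to_numpy(float)
        self.exit = df["exit_age"].to_numpy(float)
        self.event = event_indicator(df, spec.cause)
        self.n = len(df)
        self.spec = spec


def _ols_fitted(y, Z, C):
    X = np.column_stack([np.ones(len(y)), Z, C])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return X @ beta


def _point_estimates(d: _MediationData, idx=None, cross: bool = True,
                     diab_stage1: str = "linear",
                     warm: dict | None = None) -> dict:
    if idx is None:
        zb, zd, y, db, C = d.zb, d.zd, d.exposure, d.diab, d.C
        entry, exit_, ev = d.entry, d.exit, d.event
    else:
        zb, zd, y, db = d.zb[idx], d.zd[idx], d.exposure[idx], d.diab[idx]
        C = d.C[idx]
        entry, exit_, ev = d.entry[idx], d.exit[idx], d.event[idx]
    if ev.sum() < d.spec.min_events:
        raise FitError("too few events in resample")
    from .assoc import cox_risk_plan
    plan = cox_risk_plan(entry, exit_, ev)

    # total effect: 2SLS with the BMI score alone
    pred_total = _ols_fitted(y, zb[:, None], C)
    Xt = np.column_stack([pred_total, C])
    warm = warm or {}
    fit_t = cox_ph(Xt, entry, exit_, ev, init=warm.get("total"), plan=plan)
    total, se_t = float(fit_t.beta[0]), float(fit_t.se[0])

    # direct effect: joint Cox on predicted BMI and predicted liability
    Z1 = np.column_stack([zb, zd]) if cross else zb[:, None]
    Z2 = np.column_stack([zb, zd]) if cross else zd[:, None]
    pred_bmi = _ols_fitted(y, Z1, C)
    if diab_stage1 == "linear":
        pred_diab = _ols_fitted(db, Z2, C)
    elif diab_stage1 == "probit":
        import statsmodels.api as sm
        X = np.column_stack([np.ones(len(db)), Z2, C])
        res = sm.Probit(db, X).fit(disp=0)
        pred_diab = X @ res.params  # latent liability index
    else:
        raise ValueError(f"unknown diab_stage1 {diab_stage1!r}")
    Xd = np.column_stack([pred_bmi, pred_diab, C])
    fit_d = cox_ph(Xd, entry, exit_, ev, init=warm.get("direct"), plan=plan)
    direct, se_d = float(fit_d.beta[0]), float(fit_d.se[0])
    return {"total": total, "direct": direct, "se_total": se_t,
            "se_direct": se_d,
            "warm": {"total": fit_t.beta, "direct": fit_d.beta}}


def mediation_mr(records: pd.DataFrame, bmi_score: str, diab_score: str,
                 exposure: str, diabetes: str, spec: HazardModelSpec,
                 covariate_cols: tuple = (), panel: pd.DataFrame | None = None,
                 cross_instruments: bool = True,
                 diab_stage1: str = "linear",
                 floor: float = 0.01) -> MediationResult:
    """Point estimates of total and direct effects and proportion mediated.

    If ``panel`` is given, the BMI and diabetes trait panels must be
    disjoint (overlap is a hard error: the construction requires
    non-overlapping instruments).
    """
    if panel is not None:
        by_trait = panel.groupby("trait")["variant_id"].apply(set)
        if len(by_trait) > 1:
            inter = set.intersection(*by_trait.tolist())
            if inter:
                raise ValueError(
                    f"instrument panels overlap ({len(inter)} shared "
                    "variants); mediation requires disjoint scores")
    d = _MediationData(records, bmi_score, diab_score, exposure, diabetes,
                       spec, covariate_cols)
    pt = _point_estimates(d, cross=cross_instruments,
                          diab_stage1=diab_stage1)
    prop = proportion_mediated(pt["total"], pt["direct"], floor=floor)
    return MediationResult(
        cause=spec.cause, loghr_total=pt["total"],
        loghr_direct=pt["direct"], proportion_mediated=prop,
        se_total=pt["se_total"], se_direct=pt["se_direct"],
    )


def bc_interval(boot: np.ndarray, point: float,
                level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected percentile interval.

    ``z0`` is the normal quantile of the fraction of bootstrap estimates
    below the point estimate; the bounds are the bootstrap percentiles at
    ``Phi(2 z0 -/+ z_(1-alpha/2))``.
    """
    B = len(boot)
    frac = np.clip((boot < point).mean(), 1.0 / (B + 1), B / (B + 1.0))
    z0 = stats.norm.ppf(frac)
    za = stats.norm.ppf(0.5 + level / 2.0)
    lo_q = stats.norm.cdf(2 * z0 - za)
    hi_q = stats.norm.cdf(2 * z0 + za)
    return (float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q)))


def bootstrap_proportion(records: pd.DataFrame, bmi_score: str,
                         diab_score: str, exposure: str, diabetes: str,
                         spec: HazardModelSpec, covariate_cols: tuple = (),
                         n_boot: int = 1000, seed: int = 0,
                         cross_instruments: bool = True,
                         diab_stage1: str = "linear",
                         floor: float = 0.01,
                         max_fail_frac: float = 0.20) -> MediationResult:
    """Proportion mediated with a bias-corrected bootstrap 95% CI.

    Individuals are resampled with replacement and the full two-stage
    procedure (both stage-1 fits and both Cox models) is recomputed per
    resample. Resamples where a fit fails or ``|total|`` falls below the
    floor are dropped and counted; if more than ``max_fail_frac`` are
    dropped the CI is flagged unreliable.
    """
    d = _MediationData(records, bmi_score, diab_score, exposure, diabetes,
                       spec, covariate_cols)
    pt = _point_estimates(d, cross=cross_instruments, diab_stage1=diab_stage1)
    point = proportion_mediated(pt["total"], pt["direct"], floor=floor)
    if not np.isfinite(point):
        raise FitError(
            f"total log HR {pt['total']:.4f} below floor {floor}; "
            "proportion mediated undefined")
    rng = np.random.default_rng(seed)
    boot = []
    n_fail = 0
    warm = pt["warm"]
    for _ in range(n_boot):
        idx = rng.integers(0, d.n, d.n)
        try:
            b = _point_estimates(d, idx=idx, cross=cross_instruments,
                                 diab_stage1=diab_stage1, warm=warm)
        except (FitError, np.linalg.LinAlgError):
            n_fail += 1
            continue
        p = proportion_mediated(b["total"], b["direct"], floor=floor)
        if np.isfinite(p):
            boot.append(p)
        else:
            n_fail += 1
    boot = np.array(boot)
    if len(boot) == 0:
        raise FitError("all bootstrap resamples failed")
    lo, hi = bc_interval(boot, point)
    unreliable = n_fail > max_fail_frac * n_boot
    if unreliable:
        warnings.warn(
            f"{n_fail}/{n_boot} bootstrap resamples failed; CI unreliable")
    return MediationResult(
        cause=spec.cause, loghr_total=pt["total"], loghr_direct=pt["direct"],
        proportion_mediated=point, se_total=pt["se_total"],
        se_direct=pt["se_direct"], ci_lo=lo, ci_hi=hi,
        n_boot_used=len(boot), n_boot_requested=n_boot,
        ci_unreliable=unreliable,
    )
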