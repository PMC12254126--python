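"""Stratified non-linear MR with negative-control diagnostics.

Log-linearity of the exposure-mortality relation is probed by estimating
the MR effect within strata of the exposure distribution, formed either
from the exposure residual after removing the instrument-predicted
component (residual method) or by double ranking (rank on the score into
consecutive pre-strata, then by exposure within each pre-stratum), which
tolerates heterogeneity of the score-exposure effect. Per-stratum Wald
ratios use stratum-specific first-stage denominators; heterogeneity is
summarized by Cochran Q and an inverse-variance-weighted linear trend of
the stratum estimates on stratum mean exposure.

Because stratification conditions on a collider-prone quantity, the same
machinery applied to variables the score cannot affect (entry age, sex)
serves as a negative control: non-null per-stratum associations flag
selection distortion. The diagnostic table is reported without a verdict.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import FitError, HazardModelSpec, fit_cox, fit_linear
from .onesample import cochran_q, ivw_trend, wald_ratio
from .scores import instrument_strength


def _equal_groups(values: np.ndarray, q: int) -> np.ndarray:
    """1..q labels from a stable argsort split into near-equal groups."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    g = np.empty(n, dtype=int)
    bounds = np.linspace(0, n, q + 1).round().astype(int)
    for i in range(q):
        g[order[bounds[i]:bounds[i + 1]]] = i + 1
    return g


def residual_strata(exposure, score, covariates=None, q: int = 10):
    """Exposure-residual quantile strata.

    The residual is the exposure minus its fitted value on the score (and
    covariates); strata are equal-size residual quantile groups 1..q.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    exposure = np.asarray(exposure, float)
    score = np.asarray(score, float)
    if covariates is None:
        X = score[:, None]
    else:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != exposure.shape[0]:
            covariates = covariates.T
        X = np.column_stack([score, covariates])
    fit = fit_linear(exposure, X)
    return _equal_groups(fit.resid, q)


def doubly_ranked_strata(exposure, score, q: int = 10) -> np.ndarray:
    """Doubly ranked strata (rank by score, then by exposure within blocks).

    Individuals are ranked by the score and cut into consecutive pre-strata
    of size ``q``; within each pre-stratum, the ``k``-th exposure-ranked
    individual joins stratum ``k``. A short remainder pre-stratum of size
    ``r`` maps its ``j``-th ranked member to stratum
    ``floor((j + 1/2) q / r) + 1`` (proportional assignment). Refuses when
    ``n < q²``, where pre-strata would be degenerate.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    exposure = np.asarray(exposure, float)
    score = np.asarray(score, float)
    n = len(exposure)
    if n < q * q:
        raise FitError(f"doubly ranked stratification needs n >= q² "
                       f"({n} < {q * q})")
    by_score = np.argsort(score, kind="stable")
    strata = np.empty(n, dtype=int)
    n_full = n // q
    for b in range(n_full + 1):
        block = by_score[b * q:(b + 1) * q]
        r = len(block)
        if r == 0:
            continue
        by_exp = block[np.argsort(exposure[block], kind="stable")]
        if r == q:
            strata[by_exp] = np.arange(1, q + 1)
        else:
            j = np.arange(r)
            strata[by_exp] = np.minimum(
                np.floor((j + 0.5) * q / r).astype(int) + 1, q)
    return strata


def _merge_sparse(records: pd.DataFrame, strata: np.ndarray, spec,
                  min_events: int) -> np.ndarray:
    """Merge strata lacking events into their lower neighbour, warning."""
    from .assoc import event_indicator, restrict_window
    strata = strata.copy()
    while True:
        df = records.assign(_s=strata)
        dfw = restrict_window(df, spec.age_lo, spec.age_hi)
        ev = event_indicator(dfw, spec.cause)
        counts = pd.Series(ev).groupby(dfw["_s"].to_numpy()).sum()
        labels = sorted(np.unique(strata))
        if len(labels) <= 1:
            break
        sparse = [s for s in labels if counts.get(s, 0) < min_events]
        if not sparse:
            break
        s = sparse[0]
        i = labels.index(s)
        target = labels[i - 1] if i > 0 else labels[i + 1]
        warnings.warn(f"stratum {s} has {int(counts.get(s, 0))} events; "
                      f"merged into stratum {target}")
        strata[strata == s] = target
    return strata


def stratum_mr(records: pd.DataFrame, strata: np.ndarray, score_col: str,
               exposure_col: str, spec: HazardModelSpec,
               covariate_cols: tuple = (), report_scale: float = 5.0,
               method: str = "doubly_ranked",
               min_events: int = 10) -> dict:
    """Per-stratum Wald ratios with stratum-specific first stages.

    Returns the stratum table (index, n, mean exposure, estimate), the
    across-strata Cochran Q, and the IVW linear trend of the stratum log
    HRs on stratum mean exposure (its p-value is the log-linearity test).
    """
    strata = _merge_sparse(records, np.asarray(strata), spec, min_events)
    rows = []
    ests = []
    for s in sorted(np.unique(strata)):
        sub = records[strata == s]
        sc = sub[score_col].to_numpy(float)
        sc = (sc - sc.mean()) / sc.std(ddof=0)
        sub = sub.assign(**{score_col: sc})
        cov = (sub[list(covariate_cols)].to_numpy(float)
               if covariate_cols else None)
        zx = instrument_strength(sc, sub[exposure_col].to_numpy(float), cov,
                                 subset=f"stratum_{s}")
        zy = fit_cox(sub, score_col, spec, subset=f"stratum_{s}")
        est = wald_ratio(zy, zx, report_scale=report_scale)
        est.label = f"{spec.cause}|{method}|stratum_{s}"
        mean_exp = float(sub[exposure_col].mean())
        rows.append({"stratum": int(s), "n": len(sub),
                     "mean_exposure": mean_exp, **est.as_row()})
        ests.append((mean_exp, est))
    tab = pd.DataFrame(rows)
    bs = tab["beta_iv"].to_numpy()
    ss = tab["se_iv"].to_numpy()
    xs = tab["mean_exposure"].to_numpy()
    q, q_p = cochran_q(bs, ss) if len(bs) > 1 else (0.0, np.nan)
    trend = (ivw_trend(bs, ss, xs) if len(bs) > 1
             else {"slope": np.nan, "se": np.nan, "p": np.nan})
    return {"table": tab, "Q": q, "Q_p": q_p, "trend": trend,
            "method": method}


def negative_control(records: pd.DataFrame, strata: np.ndarray,
                     score_col: str, control: str) -> pd.DataFrame:
    """Per-stratum association of the score with a negative-control variable.

    Linear regression for ``entry_age``; score-on-sex log-odds (logistic
    regression slope) for ``sex``. A valid stratification yields null
    associations in every stratum; the table is returned as a diagnostic
    and no verdict is attached.
    """
    if control not in ("entry_age", "sex"):
        raise ValueError("control must be 'entry_age' or 'sex'")
    rows = []
    for s in sorted(np.unique(strata)):
        sub = records[strata == s]
        sc = sub[score_col].to_numpy(float)
        sc = (sc - sc.mean()) / sc.std(ddof=0)
        if control == "entry_age":
            fit = fit_linear(sub["entry_age"].to_numpy(float), sc[:, None],
                             names=["score"])
            j = fit.names.index("score")
            beta, se = float(fit.beta[j]), float(fit.se[j])
        else:
            import statsmodels.api as sm
            ymale = (sub["sex"].astype(str) == "male").to_numpy(float)
            X = np.column_stack([np.ones(len(sc)), sc])
            res = sm.Logit(ymale, X).fit(disp=0)
            beta, se = float(res.params[1]), float(res.bse[1])
        z = beta / se if se > 0 else np.nan
        rows.append({"stratum": int(s), "n": len(sub), "control": control,
                     "beta": beta, "se": se, "z": z,
                     "p": float(2 * stats.norm.sf(abs(z)))})
    return pd.DataFrame(rows)
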