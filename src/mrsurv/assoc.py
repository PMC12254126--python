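"""Regression engines shared by every MR stage.

Two models are composed throughout: an ordinary-least-squares first stage
(instrument → exposure) and a cause-specific proportional-hazards second stage
(instrument → mortality) on the attained-age timescale with delayed entry.

The Cox engine is a vectorized Newton solver for the Efron-approximated
partial likelihood. Left truncation is handled by suffix-sum bookkeeping: the
risk set at time ``t`` is ``{i : entry_i < t <= exit_i}``, so every risk-set
sum is a (suffix sum over exits >= t) minus a (suffix sum over entries >= t).
This makes a single fit cheap enough to be run tens of thousands of times
inside bootstrap and replicate loops; agreement with an established
implementation is checked in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causes import matches, validate_cause


class FitError(RuntimeError):
    """A model refused to fit (too few events, empty risk sets, ...)."""


# ---------------------------------------------------------------------------
# linear first stage
# ---------------------------------------------------------------------------


@dataclass
class LinearFit:
    names: list
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    resid: np.ndarray
    fitted: np.ndarray
    sigma2: float
    r_squared: float
    n: int
    dropped: list = field(default_factory=list)


def fit_linear(y, X, names=None, add_intercept: bool = True) -> LinearFit:
    """OLS with classical standard errors.

    Rank-deficient design matrices have their aliased columns dropped (with a
    warning) rather than failing, mirroring standard survival-software
    behaviour for collinear covariates.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n = y.shape[0]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["const"] + names
    if n <= X.shape[1]:
        raise FitError(f"n={n} too small for {X.shape[1]} regressors")

    # drop aliased columns greedily (pivoted rank check)
    keep = list(range(X.shape[1]))
    dropped = []
    while True:
        Xk = X[:, keep]
        r = np.linalg.matrix_rank(Xk)
        if r == len(keep):
            break
        # find first column linearly dependent on its predecessors
        for pos in range(1, len(keep) + 1):
            if np.linalg.matrix_rank(X[:, keep[:pos]]) < pos:
                dropped.append(names[keep[pos - 1]])
                del keep[pos - 1]
                break
    if dropped:
        warnings.warn(f"dropped aliased regressors: {dropped}")
    Xk = X[:, keep]
    kept_names = [names[j] for j in keep]

    beta, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    fitted = Xk @ beta
    resid = y - fitted
    dof = n - len(keep)
    sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0
    XtX_inv = np.linalg.pinv(Xk.T @ Xk)
    cov = sigma2 * XtX_inv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return LinearFit(
        names=kept_names, beta=beta, se=se, cov=cov, resid=resid,
        fitted=fitted, sigma2=sigma2, r_squared=r2, n=n, dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards with delayed entry
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    names: list
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    n_iter: int
    converged: bool

    def coef(self, name) -> tuple[float, float]:
        j = self.names.index(name)
        return float(self.beta[j]), float(self.se[j])


@dataclass
class CoxRiskPlan:
    """Precomputed risk-set bookkeeping shared by fits on the same rows."""

    ex_order: np.ndarray
    en_order: np.ndarray
    tie_start: np.ndarray
    death_group: np.ndarray
    j_frac: np.ndarray
    idx_exit: np.ndarray
    idx_entry: np.ndarray
    d_order: np.ndarray
    n: int
    n_events: int


def cox_risk_plan(entry, time, event) -> CoxRiskPlan:
    entry = np.asarray(entry, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if np.any(time <= entry):
        raise FitError("every exit time must exceed the entry time")
    n_events = int(event.sum())
    if n_events == 0:
        raise FitError("no events in the fitting window; refusing to fit")
    ex_order = np.argsort(time, kind="stable")
    en_order = np.argsort(entry, kind="stable")
    t_ex = time[ex_order]
    t_en = entry[en_order]
    dtimes = time[event]
    d_order = np.argsort(dtimes, kind="stable")
    dtimes = dtimes[d_order]
    tie_times, tie_start, tie_counts = np.unique(
        dtimes, return_index=True, return_counts=True)
    m = tie_times.shape[0]
    death_group = np.repeat(np.arange(m), tie_counts)
    j_idx = np.arange(n_events) - np.repeat(tie_start, tie_counts)
    j_frac = j_idx / np.repeat(tie_counts, tie_counts).astype(float)
    return CoxRiskPlan(
        ex_order=ex_order, en_order=en_order, tie_start=tie_start,
        death_group=death_group, j_frac=j_frac,
        idx_exit=np.searchsorted(t_ex, tie_times, side="left"),
        idx_entry=np.searchsorted(t_en, tie_times, side="left"),
        d_order=d_order, n=time.shape[0], n_events=n_events,
    )


def cox_ph(X, entry, time, event, names=None, tol: float = 1e-8,
           max_iter: int = 100, init=None,
           plan: CoxRiskPlan | None = None) -> CoxFit:
    """Cox partial-likelihood fit with Efron ties and left truncation.

    Parameters
    ----------
    X : (n, p) covariate matrix.
    entry, time : delayed-entry and exit times on the same (age) scale.
    event : boolean event indicator; non-events are right-censored at ``time``.
    init : optional starting coefficient vector (warm start for bootstrap
        refits of nearly identical data).
    plan : optional precomputed risk-set bookkeeping (from
        :func:`cox_risk_plan`) when several fits share the same rows.

    Notes
    -----
    Each Newton iteration needs, at every distinct event time ``t``, the sums
    of ``w``, ``w*x`` and ``w*x*x'`` over the risk set ``{entry < t <= exit}``.
    All of these columns are packed into one matrix and suffix-summed once per
    side (exit-sorted and entry-sorted), so the per-iteration cost is two
    cumulative sums of shape ``(n, 1 + p + p(p+1)/2)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    entry = np.asarray(entry, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if X.shape[0] != time.shape[0]:
        X = X.T
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if plan is None:
        plan = cox_risk_plan(entry, time, event)
    n_events = plan.n_events
    ex_order = plan.ex_order
    en_order = plan.en_order

    # packed columns: [1, x_a, x_a*x_b (a<=b)]
    iu_a, iu_b = np.triu_indices(p)
    K = 1 + p + iu_a.shape[0]

    def pack(M):
        out = np.empty((M.shape[0], K))
        out[:, 0] = 1.0
        out[:, 1:1 + p] = M
        out[:, 1 + p:] = M[:, iu_a] * M[:, iu_b]
        return out

    # rows in *reversed* sort order so suffix sums become plain contiguous
    # cumulative sums; suffix(i) over the original order is row n-i
    ex_order_rev = ex_order[::-1]
    en_order_rev = en_order[::-1]
    # (K, n) layout keeps the per-iteration cumulative sums cache-friendly
    A_ex = np.ascontiguousarray(pack(X[ex_order_rev]).T)
    A_en = np.ascontiguousarray(pack(X[en_order_rev]).T)

    # tied event-time groups, in death-time order
    dX = X[event][plan.d_order]
    dA = pack(dX)
    tie_start = plan.tie_start
    death_group = plan.death_group
    j_frac = plan.j_frac
    idx_exit = plan.idx_exit
    idx_entry = plan.idx_entry
    d_order = plan.d_order
    dX_sum = dX.sum(axis=0)

    def unpack2(G):
        # (m, K) packed rows -> R0 (m,), R1 (m,p), R2 (m,p,p)
        R2 = np.empty((G.shape[0], p, p))
        R2[:, iu_a, iu_b] = G[:, 1 + p:]
        R2[:, iu_b, iu_a] = G[:, 1 + p:]
        return G[:, 0], G[:, 1:1 + p], R2

    S_ex = np.zeros((K, n + 1))
    S_en = np.zeros((K, n + 1))
    gather_ex = n - idx_exit
    gather_en = n - idx_entry

    beta = np.zeros(p) if init is None else np.asarray(init, float).copy()
    beta_prev = beta
    loglik_prev = -np.inf
    info = np.eye(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        eta_scale = float(eta.mean())
        w = np.exp(eta - eta_scale)

        np.cumsum(A_ex * w[ex_order_rev][None, :], axis=1, out=S_ex[:, 1:])
        np.cumsum(A_en * w[en_order_rev][None, :], axis=1, out=S_en[:, 1:])
        G = (S_ex[:, gather_ex] - S_en[:, gather_en]).T
        R0, R1, R2 = unpack2(G)

        dW = w[event][d_order]
        D = np.add.reduceat(dA * dW[:, None], tie_start, axis=0)
        D0, D1, D2 = unpack2(D)

        denom = R0[death_group] - j_frac * D0[death_group]
        if np.any(denom <= 0):
            raise FitError("empty or degenerate risk set at an event time")
        S1 = R1[death_group] - j_frac[:, None] * D1[death_group]
        S2 = R2[death_group] - j_frac[:, None, None] * D2[death_group]

        loglik = float((eta[event] - eta_scale).sum() - np.log(denom).sum())
        u = S1 / denom[:, None]
        grad = dX_sum - u.sum(axis=0)
        info = (S2 / denom[:, None, None]).sum(axis=0) - np.einsum(
            "ka,kb->ab", u, u)

        if not np.all(np.isfinite(grad)) or not np.isfinite(loglik):
            raise FitError("non-finite partial likelihood; fit aborted")

        if np.max(np.abs(grad)) < tol:
            converged = True
            loglik_prev = loglik
            break

        # step-halving if the likelihood did not improve
        if loglik < loglik_prev - 1e-10:
            beta = beta_prev + 0.5 * (beta - beta_prev)
            continue

        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        beta_prev = beta
        loglik_prev = loglik
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            converged = True
            break

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return CoxFit(
        names=list(names), beta=beta, se=se, cov=cov, loglik=loglik_prev,
        n=n, n_events=n_events, n_iter=it, converged=converged,
    )


# ---------------------------------------------------------------------------
# survival-record plumbing
# ---------------------------------------------------------------------------


@dataclass
class HazardModelSpec:
    """Cause-specific mortality model on the attained-age timescale.

    Events are deaths from ``cause`` (or any of its sub-causes) inside the
    half-open age window ``[age_lo, age_hi)``; deaths from competing causes
    and deaths at or beyond ``age_hi`` are censored, the latter at the window
    edge. Entry is delayed to recruitment age.
    """

    cause: str = "all"
    age_lo: float = 35.0
    age_hi: float = 75.0
    covariates: tuple = ()
    min_events: int = 10

    def __post_init__(self):
        validate_cause(self.cause)
        if not self.age_lo < self.age_hi:
            raise ValueError("age_lo must be below age_hi")


@dataclass
class InstrumentOutcomeFit:
    subset: str
    cause: str
    beta_zy: float  # log HR per unit of the score variable
    se_zy: float
    n_events: int
    n_at_risk: int
    fit: CoxFit | None = None


def restrict_window(records: pd.DataFrame, age_lo: float,
                    age_hi: float) -> pd.DataFrame:
    """Restrict survival records to the analysis age window ``[lo, hi)``.

    Entry is delayed to ``age_lo``; individuals who exited at or before
    ``age_lo`` are dropped; deaths at ``age_hi`` or later are recoded as
    censored at ``age_hi``.
    """
    if not age_lo < age_hi:
        raise ValueError("age_lo must be below age_hi")
    out = records.copy()
    out["entry_age"] = np.maximum(out["entry_age"].to_numpy(float), age_lo)
    out = out[out["exit_age"].to_numpy(float) > age_lo]
    out = out[out["entry_age"].to_numpy(float) < age_hi].copy()
    over = out["exit_age"].to_numpy(float) >= age_hi
    out.loc[over, "exit_age"] = age_hi
    out.loc[over, "died"] = False
    if "cause" in out.columns:
        out.loc[over, "cause"] = "none"
    return out


def event_indicator(records: pd.DataFrame, cause: str) -> np.ndarray:
    """Boolean indicator of death from ``cause`` (competing causes censored)."""
    validate_cause(cause)
    died = records["died"].to_numpy(bool)
    if cause == "all":
        return died
    lab = records["cause"].astype(str).to_numpy()
    hit = np.array([c != "none" and matches(c, cause) for c in lab])
    return died & hit


def fit_cox(records: pd.DataFrame, score: str, spec: HazardModelSpec,
            subset: str = "all") -> InstrumentOutcomeFit:
    """Cause-specific Cox fit of mortality on a score variable.

    ``score`` names the column whose coefficient is reported; columns in
    ``spec.covariates`` are adjusted for. Refuses when there are fewer than
    ``spec.min_events`` target-cause events in the window.
    """
    df = restrict_window(records, spec.age_lo, spec.age_hi)
    ev = event_indicator(df, spec.cause)
    if int(ev.sum()) < spec.min_events:
        raise FitError(
            f"only {int(ev.sum())} {spec.cause!r} events in "
            f"[{spec.age_lo},{spec.age_hi}) for subset {subset!r}; "
            f"need >= {spec.min_events}"
        )
    cols = [score] + list(spec.covariates)
    X = df[cols].to_numpy(float)
    fit = cox_ph(X, df["entry_age"].to_numpy(float),
                 df["exit_age"].to_numpy(float), ev, names=cols)
    if not fit.converged:
        warnings.warn(
            f"Cox fit did not converge for {spec.cause!r}/{subset!r}; "
            "estimate flagged"
        )
    b, s = fit.coef(score)
    return InstrumentOutcomeFit(
        subset=subset, cause=spec.cause, beta_zy=b, se_zy=s,
        n_events=fit.n_events, n_at_risk=fit.n, fit=fit,
    )
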