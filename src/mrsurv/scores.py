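"""Weighted allele-score instruments and their diagnostics.

A genetic score is the additive, weighted sum of effect-allele dosages over a
variant panel. The module also provides the instrument diagnostics reported
alongside one-sample MR analyses: the variance in the exposure explained by
the score with its partial F-statistic, the table of cohort characteristics
across fifths of the (sex-specific) score distribution, and greedy LD
clumping for sensitivity re-weighting of the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import FitError, fit_linear


class AlleleError(ValueError):
    """A panel variant cannot be reconciled with the dosage orientation."""


@dataclass
class GeneticScore:
    trait: str
    raw: pd.Series  # exposure-weight units, indexed by individual
    std: pd.Series  # mean 0, SD 1 within the scored set
    n_flipped: int = 0
    n_imputed: int = 0


def compute_score(dosages: pd.DataFrame, panel: pd.DataFrame,
                  trait: str | None = None,
                  coded_allele: dict | None = None,
                  other_allele: dict | None = None,
                  missing_policy: str = "mean",
                  max_missing_frac: float = 0.10) -> GeneticScore:
    """Additive weighted allele score.

    ``raw = sum_j weight_j * dosage_j`` over the panel variants for ``trait``
    (all panel rows if ``trait`` is None), where ``dosage_j`` counts copies of
    the panel's effect allele. If ``coded_allele`` is supplied and disagrees
    with the effect allele for a variant, the dosage is flipped to ``2 - d``
    (with a warning); an allele matching neither orientation is a hard error.
    Missing dosages (NaN) are mean-imputed at ``2 * allele_freq`` under the
    default policy, or propagate NaN under ``"omit"``; a variant missing in
    more than ``max_missing_frac`` of individuals is a hard error.
    """
    sub = panel if trait is None else panel[panel["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no panel variants for trait {trait!r}")
    missing_vars = [v for v in sub["variant_id"] if v not in dosages.columns]
    if missing_vars:
        raise ValueError(f"panel variants absent from dosages: "
                         f"{missing_vars[:5]} ...")
    if missing_policy not in ("mean", "omit"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    n = len(dosages)
    raw = np.zeros(n)
    n_imputed = 0
    flipped_names = []
    variant_ids = sub["variant_id"].tolist()
    weights = sub["weight"].to_numpy(float)
    freqs = sub["allele_freq"].to_numpy(float)
    effect = sub["effect_allele"].tolist()
    flip = np.zeros(len(sub), dtype=bool)
    if coded_allele is not None:
        for j, v in enumerate(variant_ids):
            coded = coded_allele[v]
            if coded == effect[j]:
                continue
            if other_allele is None or coded == other_allele.get(v):
                flip[j] = True
                flipped_names.append(v)
            else:
                raise AlleleError(
                    f"{v}: coded allele {coded!r} matches neither the effect "
                    f"allele {effect[j]!r} nor the other allele")
    for lo in range(0, len(sub), 128):
        hi = min(lo + 128, len(sub))
        D = dosages[variant_ids[lo:hi]].to_numpy(float)
        fl = flip[lo:hi]
        if fl.any():
            D[:, fl] = 2.0 - D[:, fl]
        miss = ~np.isfinite(D)
        if miss.any():
            frac = miss.mean(axis=0)
            if (frac > max_missing_frac).any():
                worst = variant_ids[lo:hi][int(np.argmax(frac))]
                raise ValueError(
                    f"{worst}: {frac.max():.1%} missing exceeds "
                    f"{max_missing_frac:.0%}")
            n_imputed += int(miss.sum())
            if missing_policy == "mean":
                imput = np.broadcast_to(2.0 * freqs[lo:hi], D.shape)
                D = np.where(miss, imput, D)
        raw += D @ weights[lo:hi]
    n_flipped = int(flip.sum())
    if flipped_names:
        warnings.warn(
            f"flipped dosage orientation for {len(flipped_names)} variants "
            f"(e.g. {flipped_names[:3]})")
    raw = pd.Series(raw, index=dosages.index, name="raw_score")
    sd = raw.std(ddof=0)
    std = (raw - raw.mean()) / sd if sd > 0 else raw * 0.0
    return GeneticScore(trait=trait or "all", raw=raw,
                        std=std.rename("std_score"),
                        n_flipped=n_flipped, n_imputed=n_imputed)


def ld_clump(variants: pd.DataFrame, r2: pd.DataFrame,
             r2_threshold: float = 0.01) -> list[str]:
    """Greedy p-value-ordered clumping under a pairwise-r² threshold.

    Variants are visited in ascending p-value (ties broken by variant id);
    a variant is retained iff its r² with every already-retained variant is
    below ``r2_threshold``. ``r2`` is a symmetric matrix indexed by variant
    id in both dimensions.
    """
    if not np.all(np.isfinite(variants["p_value"])):
        raise ValueError("p-values must be finite")
    r2m = r2.to_numpy(float)
    if r2m.shape[0] != r2m.shape[1] or not np.allclose(r2m, r2m.T, atol=1e-12):
        raise ValueError("r2 overlay must be square and symmetric")
    if (r2m < -1e-12).any() or (r2m > 1 + 1e-12).any():
        raise ValueError("r2 values must lie in [0, 1]")
    order = variants.sort_values(
        ["p_value", "variant_id"], kind="stable")["variant_id"].tolist()
    kept: list[str] = []
    for v in order:
        if all(r2.loc[v, u] < r2_threshold for u in kept):
            kept.append(v)
    return kept


@dataclass
class InstrumentExposureFit:
    subset: str
    beta_zx: float  # exposure units per SD of score
    se_zx: float
    r_squared: float  # partial variance explained by the score
    f_statistic: float
    n: int


def instrument_strength(score: np.ndarray, exposure: np.ndarray,
                        covariates: np.ndarray | None = None,
                        subset: str = "all",
                        min_n: int = 30) -> InstrumentExposureFit:
    """First-stage fit: exposure on standardized score plus covariates.

    ``r_squared`` is the partial variance explained by the score given the
    covariates, and the F-statistic follows the partial-F identity
    ``F = (n - k - 1) R2_partial / (1 - R2_partial)`` with ``k`` covariates,
    which reduces to ``(n - 2) R2 / (1 - R2)`` without covariates.
    """
    score = np.asarray(score, float)
    exposure = np.asarray(exposure, float)
    n = score.shape[0]
    if n < min_n:
        raise FitError(f"subset {subset!r} has n={n} < {min_n}")
    if covariates is None:
        X = score[:, None]
        names = ["score"]
        k = 0
    else:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        X = np.column_stack([score, covariates])
        names = ["score"] + [f"c{j}" for j in range(covariates.shape[1])]
        k = covariates.shape[1]
    full = fit_linear(exposure, X, names=names)
    k = len(full.names) - 2  # covariates surviving the collinearity drop
    j = full.names.index("score")
    beta, se = float(full.beta[j]), float(full.se[j])
    # partial R2 of the score from the nested fit without it
    if k > 0:
        reduced = fit_linear(exposure, X[:, 1:], names=names[1:])
        rss_red = float(reduced.resid @ reduced.resid)
    else:
        rss_red = float(((exposure - exposure.mean()) ** 2).sum())
    rss_full = float(full.resid @ full.resid)
    r2_partial = 1.0 - rss_full / rss_red if rss_red > 0 else 0.0
    dof = n - k - 2  # intercept + score + k covariates
    f_stat = dof * r2_partial / (1.0 - r2_partial) if r2_partial < 1 else np.inf
    return InstrumentExposureFit(subset=subset, beta_zx=beta, se_zx=se,
                                 r_squared=r2_partial, f_statistic=f_stat, n=n)


def assign_fifths(score: pd.Series, by: pd.Series | None = None,
                  q: int = 5) -> pd.Series:
    """Quantile-group assignment (1..q), within levels of ``by`` if given.

    Boundaries sit at the 20/40/60/80 percentiles; individuals tied across a
    boundary are separated by their stable sort order, so groups are always
    as equal as the sample size allows.
    """
    def _groups(s: pd.Series) -> pd.Series:
        order = np.argsort(s.to_numpy(), kind="stable")
        g = np.empty(len(s), dtype=int)
        # equal-size split of the sorted order
        bounds = np.linspace(0, len(s), q + 1).round().astype(int)
        for i in range(q):
            g[order[bounds[i]:bounds[i + 1]]] = i + 1
        return pd.Series(g, index=s.index)

    if by is None:
        return _groups(score)
    out = pd.Series(0, index=score.index)
    for _, idx in score.groupby(by).groups.items():
        out.loc[idx] = _groups(score.loc[idx])
    return out


def fifths_table(cohort: pd.DataFrame, score: pd.Series,
                 characteristics: list[str], by_sex: bool = True,
                 q: int = 5) -> pd.DataFrame:
    """Mean (continuous) or percentage (binary/boolean) per fifth of score.

    Fifths are defined within sex by default. The returned frame has one row
    per characteristic with columns ``fifth_1..fifth_q`` and the
    top-minus-bottom ``gradient``.
    """
    fifth = assign_fifths(score, cohort["sex"] if by_sex else None, q=q)
    rows = []
    for ch in characteristics:
        col = cohort[ch]
        if col.dtype == bool or set(col.dropna().unique()) <= {0, 1}:
            vals = col.astype(float).groupby(fifth).mean() * 100.0
            kind = "%"
        else:
            vals = col.astype(float).groupby(fifth).mean()
            kind = "mean"
        row = {"characteristic": ch, "kind": kind}
        for i in range(1, q + 1):
            row[f"fifth_{i}"] = float(vals.get(i, np.nan))
        row["gradient"] = row[f"fifth_{q}"] - row["fifth_1"]
        rows.append(row)
    return pd.DataFrame(rows)
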