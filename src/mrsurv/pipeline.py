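"""Pipeline orchestration: simulate/load → score → diagnose → estimate.

``run_pipeline`` executes the full analysis graph in dependency order and
writes plain CSV tables (UTF-8, RFC 4180) plus a structured run log; every
table is stamped with the configuration hash and seed, and a rerun with an
identical configuration reproduces byte-identical tables. ``make_report``
renders a markdown summary of whichever tables a bundle contains.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .assoc import FitError, HazardModelSpec
from .causes import CAUSE_PARENT, validate_cause
from .mediation import bootstrap_proportion
from .nonlinear import (doubly_ranked_strata, negative_control,
                        residual_strata, stratum_mr)
from .onesample import onesample_mr
from .params import ParameterError, SimulationParams
from .scores import compute_score, fifths_table, instrument_strength
from .simulate import apply_exclusions, simulate_cohort
from .twosample import estimator_suite, per_snp_summaries

DEFAULT_CAUSES = (
    "all", "vascular-metabolic", "non-vascular-metabolic",
    "vascular", "renal", "hepatobiliary", "acute-diabetic-crisis",
    "cancer", "respiratory", "infective", "external-other",
)


@dataclass
class AnalysisConfig:
    simulation: SimulationParams | None = None
    dosages_path: str | None = None
    weights_path: str | None = None
    phenotypes_path: str | None = None
    causes: tuple = DEFAULT_CAUSES
    age_lo: float = 35.0
    age_hi: float = 75.0
    n_pcs: int = 4
    exposure: str = "bmi_measured"
    report_scale: float = 5.0
    run_onesample: bool = True
    run_mediation: bool = True
    run_twosample: bool = True
    run_nonlinear: bool = True
    nonlinear_q: int = 10
    n_boot: int = 200
    seed: int = 0
    out_dir: str = "results/pipeline"

    def __post_init__(self):
        has_sim = self.simulation is not None
        has_paths = any([self.dosages_path, self.weights_path,
                         self.phenotypes_path])
        if has_sim == has_paths:
            raise ParameterError(
                "config must have exactly one of a simulation block or "
                "input paths")
        if has_paths and not all([self.dosages_path, self.weights_path,
                                  self.phenotypes_path]):
            raise ParameterError(
                "dosages, weights and phenotypes paths are all required")
        for c in self.causes:
            validate_cause(c)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationParams(**raw["simulation"])
        if "causes" in raw:
            raw["causes"] = tuple(raw["causes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land does not define the run
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_inputs(config: AnalysisConfig):
    if config.simulation is not None:
        sim = simulate_cohort(config.simulation)
        return (sim.panel, sim.geno.dosages, sim.geno.coded_allele,
                sim.geno.other_allele, sim.table, sim.flags)
    panel = mio.read_weights_tsv(config.weights_path)
    if str(config.dosages_path).endswith(".vcf"):
        dosages, coded, other = mio.read_vcf_dosages(config.dosages_path)
    else:
        dosages, coded, other = mio.read_dosages_tsv(config.dosages_path)
    table = mio.read_phenotypes_csv(config.phenotypes_path)
    return panel, dosages, coded, other, table, None


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute all requested stages; returns the result bundle.

    The bundle maps table names to DataFrames; the same tables are written
    under ``config.out_dir``. A stage failure aborts the run with that
    stage's diagnostic; tables already written are retained under a
    ``failed/`` marker directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    log_lines = []
    bundle: dict = {"stamp": stamp}
    t_start = time.time()

    def log(stage, **kw):
        entry = {"stage": stage, "t": round(time.time() - t_start, 2), **kw}
        log_lines.append(json.dumps(entry))

    def save(name: str, df: pd.DataFrame):
        df = df.copy()
        for k, v in stamp.items():
            df[k] = v
        bundle[name] = df
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.8g")

    try:
        panel, dosages, coded, other, table, flags = _load_inputs(config)
        log("load", n=len(table), variants=len(panel))

        if flags is not None:
            analysis, older, ledger = apply_exclusions(table, flags)
            save("exclusions", ledger)
            log("exclusions", n_analysis=len(analysis), n_older=len(older))
        else:
            analysis = table[table["entry_age"] < 75.0].copy()
            older = table[table["entry_age"] >= 75.0].copy()
        bundle["analysis_set"] = analysis
        dosages_a = dosages.loc[analysis.index]

        bmi_gs = compute_score(dosages_a, panel, "bmi", coded, other)
        diab_gs = compute_score(dosages_a, panel, "diab", coded, other)
        analysis = analysis.assign(bmi_score=bmi_gs.std.to_numpy(),
                                   diab_score=diab_gs.std.to_numpy())
        pcs = tuple(f"pc{i + 1}" for i in range(config.n_pcs)
                    if f"pc{i + 1}" in analysis.columns)
        log("scores", n=len(analysis))

        # instrument diagnostics
        rows = []
        for label, sub in [("all", analysis),
                           ("male", analysis[analysis.sex == "male"]),
                           ("female", analysis[analysis.sex == "female"])]:
            cov_cols = list(pcs) + ["entry_age"]
            if label == "all":
                cov_cols += ["_sex_num"]
                sub = sub.assign(_sex_num=(sub["sex"] == "male").astype(float))
            s = sub["bmi_score"].to_numpy(float)
            s = (s - s.mean()) / s.std(ddof=0)
            fitres = instrument_strength(
                s, sub[config.exposure].to_numpy(float),
                sub[cov_cols].to_numpy(float), subset=label)
            rows.append(dataclasses.asdict(fitres))
        save("instrument_strength", pd.DataFrame(rows))
        chars = [config.exposure, "ancestry_prop", "entry_age"]
        analysis["_diab01"] = (analysis["diabetes"] != "none").astype(int)
        tab = fifths_table(analysis, analysis["bmi_score"],
                           chars + ["_diab01"], by_sex=True)
        save("fifths", tab)
        log("diagnostics")

        spec_for = {c: HazardModelSpec(cause=c, age_lo=config.age_lo,
                                       age_hi=config.age_hi, covariates=pcs)
                    for c in config.causes}

        if config.run_onesample:
            forest = []
            for c in config.causes:
                try:
                    res = onesample_mr(analysis, "bmi_score",
                                       config.exposure, spec_for[c],
                                       report_scale=config.report_scale,
                                       covariate_cols=pcs)
                except FitError as err:
                    log("onesample", cause=c, skipped=str(err))
                    continue
                for level, est in res.items():
                    forest.append({"cause": c, "subset": str(level),
                                   **est.as_row()})
            save("forest", pd.DataFrame(forest))
            log("onesample", causes=len(config.causes))

        if config.run_mediation:
            med_rows = []
            for c in ("all", "vascular-metabolic", "non-vascular-metabolic"):
                try:
                    res = bootstrap_proportion(
                        analysis, "bmi_score", "diab_score", config.exposure,
                        "diabetes", spec_for.get(c) or HazardModelSpec(
                            cause=c, age_lo=config.age_lo,
                            age_hi=config.age_hi, covariates=pcs),
                        covariate_cols=pcs, n_boot=config.n_boot,
                        seed=config.seed + 1)
                except FitError as err:
                    # an undefined proportion (null total effect) is a
                    # statistical refusal for that cause, not a stage failure
                    log("mediation", cause=c, skipped=str(err))
                    continue
                med_rows.append(dataclasses.asdict(res))
            save("mediation", pd.DataFrame(med_rows))
            log("mediation", n_boot=config.n_boot)

        if config.run_twosample:
            bmi_vars = panel.loc[panel.trait == "bmi", "variant_id"].tolist()
            summ = per_snp_summaries(analysis, dosages_a, bmi_vars,
                                     config.exposure, spec_for["all"],
                                     covariate_cols=pcs)
            save("snp_summaries", summ)
            save("twosample", estimator_suite(summ, seed=config.seed + 2,
                                              report_scale=config.report_scale))
            log("twosample", variants=len(summ))

        if config.run_nonlinear:
            nl_rows = []
            nc_rows = []
            for method, maker in (
                    ("residual", lambda: residual_strata(
                        analysis[config.exposure], analysis["bmi_score"],
                        analysis[list(pcs)].to_numpy(float) if pcs else None,
                        q=config.nonlinear_q)),
                    ("doubly_ranked", lambda: doubly_ranked_strata(
                        analysis[config.exposure], analysis["bmi_score"],
                        q=config.nonlinear_q))):
                strata = maker()
                res = stratum_mr(analysis, strata, "bmi_score",
                                 config.exposure, spec_for["all"],
                                 covariate_cols=pcs, method=method,
                                 report_scale=config.report_scale)
                t = res["table"].assign(method=method, Q=res["Q"],
                                        Q_p=res["Q_p"],
                                        trend_slope=res["trend"]["slope"],
                                        trend_p=res["trend"]["p"])
                nl_rows.append(t)
                for ctrl in ("entry_age", "sex"):
                    nc = negative_control(analysis, strata, "bmi_score", ctrl)
                    nc_rows.append(nc.assign(method=method))
            save("nonlinear_strata", pd.concat(nl_rows, ignore_index=True))
            save("negative_controls", pd.concat(nc_rows, ignore_index=True))
            log("nonlinear", q=config.nonlinear_q)

    except Exception:
        (out / "failed").mkdir(exist_ok=True)
        (out / "failed" / "run_log.txt").write_text("\n".join(log_lines))
        raise

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True, default_flow_style=False)
    bundle["log"] = log_lines
    return bundle


def make_report(bundle: dict, path=None) -> str:
    """Markdown summary of a result bundle.

    Sections for which the bundle has no table are omitted, never
    fabricated. Forest rows are grouped by the cause hierarchy.
    """
    lines = ["# Analysis report", ""]
    stamp = bundle.get("stamp", {})
    if stamp:
        lines.append(f"Config hash `{stamp.get('config_hash')}`, "
                     f"seed {stamp.get('seed')}.")
        lines.append("")

    if "exclusions" in bundle:
        lines.append("## Exclusion cascade")
        led = bundle["exclusions"]
        for _, r in led.iterrows():
            lines.append(f"- {r['step']}: removed {r['n_removed']} "
                         f"({r['pct_of_initial']}%), "
                         f"{r['n_remaining']} remaining")
        lines.append("")

    if "instrument_strength" in bundle:
        lines.append("## Instrument strength")
        for _, r in bundle["instrument_strength"].iterrows():
            lines.append(
                f"- {r['subset']}: beta {r['beta_zx']:.3f} kg/m² per SD, "
                f"partial R² {r['r_squared']:.4f}, "
                f"F {r['f_statistic']:.0f} (n={r['n']})")
        lines.append("")

    if "forest" in bundle:
        lines.append("## Hazard ratios per report-scale units of "
                     "genetically predicted exposure")
        f = bundle["forest"]
        for c in f["cause"].unique():
            sub = f[(f["cause"] == c) & (f["subset"] == "pooled")]
            if len(sub):
                r = sub.iloc[0]
                depth = 0
                node = c
                while CAUSE_PARENT.get(node):
                    node = CAUSE_PARENT[node]
                    depth += 1
                pad = "  " * depth
                lines.append(
                    f"{pad}- {c}: HR {r['hr_scaled']:.2f} "
                    f"({r['ci_lo']:.2f}-{r['ci_hi']:.2f}), "
                    f"{int(r['n_events'])} events")
        lines.append("")

    if "mediation" in bundle:
        lines.append("## Mediation through diabetes liability")
        for _, r in bundle["mediation"].iterrows():
            lines.append(
                f"- {r['cause']}: total log HR {r['loghr_total']:.4f}, "
                f"direct {r['loghr_direct']:.4f}, proportion mediated "
                f"{r['proportion_mediated']:.3f} "
                f"(95% CI {r['ci_lo']:.3f} to {r['ci_hi']:.3f})")
        lines.append("")

    if "twosample" in bundle:
        lines.append("## Two-sample sensitivity estimators")
        for _, r in bundle["twosample"].iterrows():
            if isinstance(r.get("beta_iv"), float) and np.isfinite(
                    r.get("beta_iv", np.nan)):
                lines.append(f"- {r['method']}: beta {r['beta_iv']:.4f} "
                             f"(SE {r['se_iv']:.4f})")
        lines.append("")

    if "nonlinear_strata" in bundle:
        lines.append("## Non-linear MR")
        nl = bundle["nonlinear_strata"]
        for method in nl["method"].unique():
            sub = nl[nl["method"] == method]
            lines.append(f"- {method}: Q p {sub['Q_p'].iloc[0]:.3f}, "
                         f"trend p {sub['trend_p'].iloc[0]:.3f} across "
                         f"{len(sub)} strata")
        lines.append("")

    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
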