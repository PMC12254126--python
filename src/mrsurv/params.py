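"""Simulation parameters for the synthetic admixed cohort.

The defaults are calibrated to the marginal structure of a large prospective
study of Mexican adults: two sexes with different score-to-BMI slopes, BMI
means/SDs near 28.0 (4.2) in men and 29.7 (5.2) in women, ~18% prevalence of
any diabetes of which 13/18 is diagnosed, a mortality process over ages 35-74
producing roughly 10% cumulative mortality over 20 years of follow-up, and a
hierarchical cause-of-death mix. The causal structure is fully known:
``causal_loghr_per_unit`` is the total lifelong effect of BMI on the log
hazard, of which ``mediated_fraction`` is routed through diabetes.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .causes import DEFAULT_CAUSE_MIX, LEAF_CAUSES


class ParameterError(ValueError):
    """Invalid simulation or analysis parameter."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent pseudo-random substream.

    One global seed per run; each sub-generator draws from its own stream keyed
    by a stable hash of its name, so adding a new generator does not perturb
    the draws of existing ones.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SimulationParams:
    n_individuals: int = 50_000
    n_variants_bmi: int = 724
    n_variants_diab: int = 200
    target_r2: float = 0.03
    # kg/m2 of BMI per SD of the BMI score, by sex
    slope_by_sex: dict = field(
        default_factory=lambda: {"male": 0.70, "female": 0.94}
    )
    causal_loghr_per_unit: float = 0.10  # log HR per 1 kg/m2 lifelong BMI
    mediated_fraction: float = 0.5  # fraction of the BMI effect via diabetes
    diab_loghr: float | None = None  # derived from mediated_fraction if None
    confounder_strength: float = 1.0  # kg/m2 of BMI per SD of confounder
    confounder_loghr: float = 0.25  # log HR per SD of confounder
    reverse_causality_delta: float = 1.5  # kg/m2 lost in diagnosed diabetes
    admin_censor_age: float = 90.0
    followup_years: float = 20.0
    cause_mix: dict = field(default_factory=lambda: dict(DEFAULT_CAUSE_MIX))
    seed: int = 0

    # cohort composition
    frac_female: float = 0.68
    bmi_mean_by_sex: dict = field(
        default_factory=lambda: {"male": 28.0, "female": 29.7}
    )
    bmi_sd_by_sex: dict = field(
        default_factory=lambda: {"male": 4.2, "female": 5.2}
    )
    entry_age_mean: float = 50.0
    entry_age_sd: float = 11.0
    diabetes_prevalence: float = 0.18
    diagnosed_fraction: float = 13.0 / 18.0
    undiagnosed_hazard_weight: float = 1.0 / 3.0  # share of diab_loghr carried
    diab_score_liability_sd: float = 0.25  # liability SD per SD of diab score
    bmi_liability_slope: float = 0.08  # liability SD per kg/m2 of true BMI
    ancestry_beta_a: float = 4.0  # Beta() shape parameters; median ~0.67
    ancestry_beta_b: float = 2.0
    ancestry_bmi_effect: float = 1.0  # kg/m2 per unit ancestry proportion
    ancestry_freq_shift: float = 0.20  # max allele-frequency shift vs ancestry
    ancestry_loghr: float = 0.15  # log HR per unit ancestry proportion
    n_pcs: int = 4
    measurement_noise_sd: float = 0.3  # kg/m2, BMI measurement error
    sex_loghr: float = 0.40  # male excess log hazard
    gompertz_shape: float = 0.09  # per year of attained age
    ref_cum_mortality: float = 0.07  # 20-yr cumulative mortality at reference
    diab_cause_multiplier: float = 3.0  # renal/acute-crisis up-weighting
    hard_calls: bool = False  # dosages in {0,1,2} instead of expected dosage

    # optional generator distortions (all off by default)
    bmi_loghr_quadratic: float = 0.0  # curvature per (kg/m2)^2, J-shape
    pleiotropy_frac: float = 0.0  # fraction of BMI variants with direct effect
    pleiotropy_loghr: float = 0.0  # per-allele direct log HR of those variants
    entry_truncation_strength: float = 0.0  # score-dependent entry-age defect
    sibling_block_frac: float = 0.0  # fraction of cohort in sibling pairs

    # exclusion-flag rates (QC failure, age>=90, implausible anthropometry,
    # uncertain mortality linkage)
    exclusion_rates: dict = field(
        default_factory=lambda: {
            "qc_fail": 0.133,
            "age_ge_90": 0.005,
            "implausible_anthropometry": 0.011,
            "uncertain_linkage": 0.015,
        }
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ParameterError("n_individuals must be >= 1")
        if self.n_variants_bmi < 1 or self.n_variants_diab < 1:
            raise ParameterError("variant counts must be >= 1")
        if not 0.0 < self.target_r2 < 1.0:
            raise ParameterError("target_r2 must lie in (0, 1)")
        if not 0.0 <= self.mediated_fraction <= 1.0:
            raise ParameterError("mediated_fraction must lie in [0, 1]")
        bad = set(self.cause_mix) - set(LEAF_CAUSES)
        if bad:
            raise ParameterError(f"cause_mix has non-leaf causes: {sorted(bad)}")
        total = sum(self.cause_mix.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ParameterError(f"cause_mix must sum to 1 (got {total:.6f})")
        for sex in ("male", "female"):
            if sex not in self.slope_by_sex:
                raise ParameterError(f"slope_by_sex missing {sex!r}")

    def rng(self, name: str) -> np.random.Generator:
        return substream(self.seed, name)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ParameterError(f"unknown simulation parameters: {sorted(bad)}")
        return cls(**raw)

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)
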