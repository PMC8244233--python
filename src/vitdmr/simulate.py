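"""Synthetic individual-level cohort generator.

Emulates the statistical structure a one-sample MR analysis of serum
25(OH)D assumes, so that every downstream stage (phenotyping, observational
models, MR estimators) can be exercised and calibrated without access to
the original cohort:

* genotypes at four instrument SNPs drawn independently per SNP with
  Hardy-Weinberg proportions (1-p)^2, 2p(1-p), p^2;
* serum 25(OH)D built additively from an intercept, per-allele genetic
  effects, a latent standard-normal confounder U, and Gaussian noise,
  truncated at 1 nmol/L;
* a binary disease outcome drawn from a logistic model with a causal
  25(OH)D term, a confounder term, and optional direct (pleiotropic)
  per-allele SNP effects;
* biomarkers and covariates drawn from configurable distributions, with
  optional loadings on 25(OH)D and the confounder so that derived
  phenotypes (MS, T2D, abnormal blood pressure) inherit a vitamin-D signal.

Default parameter values reproduce the study conditions: n = 2393
middle-aged and elderly participants, per-allele 25(OH)D effects of
2.14 / 1.10 / 2.94 / 0.74 nmol/L, and a marginal 25(OH)D distribution
(median ~41 nmol/L, quintile cutpoints near 28.4 / 36.7 / 45.9 / 57.4)
matching the published cohort summaries.

Reproducibility: one global seed; every variable draws from its own
substream derived deterministically from (seed, variable name), so adding
a variable never perturbs earlier draws, and the same seed and config give
a byte-identical cohort.
"""

from __future__ import annotations

import logging
import zlib
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import expit

logger = logging.getLogger(__name__)

SNP_RSIDS = ("rs12785878", "rs10741657", "rs2282679", "rs6013897")

#: Per-allele 25(OH)D effects (nmol/L) of the four instrument SNPs, oriented
#: to the 25(OH)D-increasing allele.
DEFAULT_PER_ALLELE_EFFECTS = {
    "rs12785878": 2.14,
    "rs10741657": 1.10,
    "rs2282679": 2.94,
    "rs6013897": 0.74,
}

DEFAULT_ALLELE_FREQS = {
    "rs12785878": 0.45,
    "rs10741657": 0.40,
    "rs2282679": 0.30,
    "rs6013897": 0.25,
}

VITD_TRUNCATION_NMOL_L = 1.0


class CovariateSpec(BaseModel):
    """Distributions for demographic covariates, lifestyle and medication flags."""

    age_mean: float = 59.5
    age_sd: float = 7.0
    age_min: float = 45.0
    female_prob: float = 0.60
    income_probs: tuple[float, float, float, float] = (0.35, 0.30, 0.20, 0.15)
    smoking_probs: tuple[float, float, float] = (0.62, 0.10, 0.28)
    alcohol_probs: tuple[float, float, float] = (0.60, 0.08, 0.32)
    activity_prob: float = 0.28
    family_history_ms_prob: float = 0.11
    family_history_t2d_prob: float = 0.14
    med_tg_lowering_prob: float = 0.05
    med_hdl_raising_prob: float = 0.01
    med_antihypertensive_prob: float = 0.15
    med_antidiabetic_prob: float = 0.06
    prior_t2d_diagnosis_prob: float = 0.05
    ogtt_present_prob: float = 0.30
    ogtt_mean: float = 7.0
    ogtt_sd: float = 2.2


class BiomarkerSpec(BaseModel):
    """One biomarker's generative distribution.

    The base value is drawn from a normal or lognormal distribution
    (lognormal parameters are on the log scale); ``vitd_slope`` and
    ``confounder_slope`` add linear dependence on (25(OH)D - reference) and
    on the latent confounder, which is how derived disease phenotypes
    inherit a vitamin-D signal.  Values are clipped at ``clip_min`` and the
    clip count logged.
    """

    dist: Literal["normal", "lognormal"] = "normal"
    mean: float = 0.0
    sd: float = 1.0
    vitd_slope: float = 0.0
    confounder_slope: float = 0.0
    clip_min: Optional[float] = None


def _default_biomarkers() -> dict[str, BiomarkerSpec]:
    # Centres match the published per-quintile summaries (FBG median ~5.6
    # mmol/L, insulin ~83 pmol/L = 12 uIU/mL, TG ~1.15, HDL ~1.26, WC ~83 cm);
    # negative vitd slopes for FBG/insulin/TG/WC and a positive one for HDL
    # reproduce the qualitative gradient across 25(OH)D quintiles.
    return {
        "fbg_mmol_l": BiomarkerSpec(dist="lognormal", mean=np.log(5.5), sd=0.15,
                                    vitd_slope=-0.006, confounder_slope=0.15, clip_min=2.0),
        "insulin_uiu_ml": BiomarkerSpec(dist="lognormal", mean=np.log(11.8), sd=0.45,
                                        vitd_slope=-0.05, confounder_slope=1.0, clip_min=0.5),
        "tg_mmol_l": BiomarkerSpec(dist="lognormal", mean=np.log(1.15), sd=0.5,
                                   vitd_slope=-0.006, confounder_slope=0.1, clip_min=0.2),
        "hdl_mmol_l": BiomarkerSpec(dist="lognormal", mean=np.log(1.45), sd=0.25,
                                    vitd_slope=0.003, confounder_slope=-0.05, clip_min=0.3),
        "sbp_mmhg": BiomarkerSpec(mean=125.0, sd=18.0, vitd_slope=-0.10,
                                  confounder_slope=3.0, clip_min=70.0),
        "dbp_mmhg": BiomarkerSpec(mean=78.0, sd=10.0, vitd_slope=-0.06,
                                  confounder_slope=2.0, clip_min=40.0),
        "wc_cm": BiomarkerSpec(mean=79.0, sd=10.5, vitd_slope=-0.22,
                               confounder_slope=2.0, clip_min=50.0),
        "weight_kg": BiomarkerSpec(mean=61.0, sd=10.0, vitd_slope=-0.08,
                                   confounder_slope=1.5, clip_min=30.0),
        "height_m": BiomarkerSpec(mean=1.62, sd=0.08, clip_min=1.30),
        "hc_cm": BiomarkerSpec(mean=95.0, sd=7.0, vitd_slope=-0.05,
                               confounder_slope=1.0, clip_min=60.0),
    }


class SimulationConfig(BaseModel):
    """All generative parameters of the synthetic cohort."""

    n_individuals: int = Field(default=2393, ge=1)
    allele_freqs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_ALLELE_FREQS))
    vitd_intercept: float = 36.4
    per_allele_effects: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PER_ALLELE_EFFECTS)
    )
    vitd_noise_sd: float = Field(default=16.3, gt=0)
    confounder_effect_on_vitd: float = 5.0
    causal_log_or_per_nmol: float = -0.004
    confounder_log_or: float = 0.2
    pleiotropy_log_or: dict[str, float] = Field(default_factory=dict)
    outcome_baseline_log_odds: float = -0.63
    vitd_reference: float = 41.3
    covariate_spec: CovariateSpec = Field(default_factory=CovariateSpec)
    biomarker_spec: dict[str, BiomarkerSpec] = Field(default_factory=_default_biomarkers)
    seed: int = 0

    @field_validator("allele_freqs")
    @classmethod
    def _freqs_in_open_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for rsid, p in v.items():
            if not np.isfinite(p) or not (0.0 < p < 1.0):
                raise ValueError(f"allele frequency for {rsid} must be in (0, 1), got {p}")
        return v

    @field_validator(
        "vitd_intercept", "confounder_effect_on_vitd", "causal_log_or_per_nmol",
        "confounder_log_or", "outcome_baseline_log_odds",
    )
    @classmethod
    def _finite(cls, v: float) -> float:
        if not np.isfinite(v):
            raise ValueError("simulation parameters must be finite")
        return v

    @model_validator(mode="after")
    def _consistent_snps(self) -> "SimulationConfig":
        if set(self.per_allele_effects) != set(self.allele_freqs):
            raise ValueError(
                "per_allele_effects and allele_freqs must cover the same rsids"
            )
        for rsid, eff in self.per_allele_effects.items():
            if not np.isfinite(eff):
                raise ValueError(f"per-allele effect for {rsid} must be finite")
        for rsid in self.pleiotropy_log_or:
            if rsid not in self.allele_freqs:
                raise ValueError(f"pleiotropy specified for unknown SNP {rsid}")
        return self

    @property
    def rsids(self) -> list[str]:
        return list(self.allele_freqs)


def genotype_probabilities(p: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2)."""
    if not np.isfinite(p) or not (0.0 < p < 1.0):
        raise ValueError(f"allele frequency must be in the open interval (0, 1), got {p!r}")
    q = 1.0 - p
    return (q * q, 2.0 * p * q, p * p)


def _substream(seed: int, name: str) -> np.random.Generator:
    # (seed, crc32(name)) keys a stable per-variable stream: adding variables
    # later cannot perturb existing draws.
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())]))


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a full synthetic cohort table.

    Returns a DataFrame with one row per participant: genotype columns
    (``snp_<rsid>``), ``vitd_nmol_l``, biomarkers, covariates, medication
    flags, the simulated binary ``outcome``, and the ``latent_confounder``
    (retained in memory; excluded from CSV export unless requested).
    Clipping / truncation counts are recorded in ``df.attrs``.
    """
    n = config.n_individuals
    cov = config.covariate_spec

    data: dict[str, object] = {"id": [f"P{i:06d}" for i in range(n)]}

    genotypes = {}
    for rsid in config.rsids:
        p = config.allele_freqs[rsid]
        genotype_probabilities(p)  # validates the frequency
        g = _substream(config.seed, f"genotype:{rsid}").binomial(2, p, size=n)
        genotypes[rsid] = g
        data[f"snp_{rsid}"] = g.astype(np.int64)

    u = _substream(config.seed, "confounder").standard_normal(n)
    eps = _substream(config.seed, "vitd_noise").normal(0.0, config.vitd_noise_sd, size=n)
    vitd = config.vitd_intercept + config.confounder_effect_on_vitd * u + eps
    for rsid, g in genotypes.items():
        vitd = vitd + config.per_allele_effects[rsid] * g
    n_truncated = int(np.sum(vitd < VITD_TRUNCATION_NMOL_L))
    if n_truncated:
        logger.info("truncated %d 25(OH)D values at %.1f nmol/L", n_truncated, VITD_TRUNCATION_NMOL_L)
    vitd = np.maximum(vitd, VITD_TRUNCATION_NMOL_L)
    data["vitd_nmol_l"] = vitd

    logit = (
        config.outcome_baseline_log_odds
        + config.causal_log_or_per_nmol * vitd
        + config.confounder_log_or * u
    )
    for rsid, kappa in config.pleiotropy_log_or.items():
        logit = logit + kappa * genotypes[rsid]
    data["outcome"] = (
        _substream(config.seed, "outcome").random(n) < expit(logit)
    ).astype(np.int64)

    clipped: dict[str, int] = {}
    vitd_centered = vitd - config.vitd_reference
    for name, spec in config.biomarker_spec.items():
        rng = _substream(config.seed, f"biomarker:{name}")
        if spec.dist == "lognormal":
            base = np.exp(rng.normal(spec.mean, spec.sd, size=n))
        else:
            base = rng.normal(spec.mean, spec.sd, size=n)
        values = base + spec.vitd_slope * vitd_centered + spec.confounder_slope * u
        if spec.clip_min is not None:
            n_clip = int(np.sum(values < spec.clip_min))
            if n_clip:
                clipped[name] = n_clip
                logger.info("clipped %d values of %s at %g", n_clip, name, spec.clip_min)
            values = np.maximum(values, spec.clip_min)
        data[name] = values

    age_rng = _substream(config.seed, "age")
    age = age_rng.normal(cov.age_mean, cov.age_sd, size=n)
    age = np.maximum(age, cov.age_min)  # cohort restricted to >= 45 years
    data["age_years"] = age
    data["sex"] = np.where(
        _substream(config.seed, "sex").random(n) < cov.female_prob, "female", "male"
    )
    income_levels = ["<2000", "2000-3499", "3500-4999", ">=5000"]
    data["income_band"] = _substream(config.seed, "income").choice(
        income_levels, size=n, p=np.asarray(cov.income_probs) / np.sum(cov.income_probs)
    )
    smoke_levels = ["never", "former", "current"]
    data["smoking_status"] = _substream(config.seed, "smoking").choice(
        smoke_levels, size=n, p=np.asarray(cov.smoking_probs) / np.sum(cov.smoking_probs)
    )
    data["alcohol_status"] = _substream(config.seed, "alcohol").choice(
        smoke_levels, size=n, p=np.asarray(cov.alcohol_probs) / np.sum(cov.alcohol_probs)
    )
    data["physical_activity"] = (
        _substream(config.seed, "activity").random(n) < cov.activity_prob
    ).astype(np.int64)
    data["family_history_ms"] = (
        _substream(config.seed, "fh_ms").random(n) < cov.family_history_ms_prob
    ).astype(np.int64)
    data["family_history_t2d"] = (
        _substream(config.seed, "fh_t2d").random(n) < cov.family_history_t2d_prob
    ).astype(np.int64)
    for flag, prob in [
        ("med_tg_lowering", cov.med_tg_lowering_prob),
        ("med_hdl_raising", cov.med_hdl_raising_prob),
        ("med_antihypertensive", cov.med_antihypertensive_prob),
        ("med_antidiabetic", cov.med_antidiabetic_prob),
        ("prior_t2d_diagnosis", cov.prior_t2d_diagnosis_prob),
    ]:
        data[flag] = (_substream(config.seed, flag).random(n) < prob).astype(np.int64)

    ogtt_rng = _substream(config.seed, "ogtt")
    ogtt = ogtt_rng.normal(cov.ogtt_mean, cov.ogtt_sd, size=n)
    ogtt = np.maximum(ogtt, 2.0)
    present = ogtt_rng.random(n) < cov.ogtt_present_prob
    data["ogtt_2h_mmol_l"] = np.where(present, ogtt, np.nan)

    data["latent_confounder"] = u

    df = pd.DataFrame(data)
    df.attrs["n_vitd_truncated"] = n_truncated
    df.attrs["n_clipped"] = clipped
    df.attrs["seed"] = config.seed
    return df


def write_cohort_csv(cohort: pd.DataFrame, path, export_latent: bool = False) -> None:
    """Write the cohort as RFC-4180 CSV (UTF-8, header row, missing = empty).

    The latent confounder is a simulation-only variable a real study cannot
    observe; it is excluded from export unless ``export_latent`` is set.
    """
    out = cohort
    if not export_latent and "latent_confounder" in out.columns:
        out = out.drop(columns=["latent_confounder"])
    out.to_csv(path, index=False, na_rep="")


def load_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return SimulationConfig.model_validate(raw)


def dump_config(config: SimulationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
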