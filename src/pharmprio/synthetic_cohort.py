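"""Synthetic cohort generation.

Produces cohorts with the statistical structure the downstream analysis
assumes: genotypes drawn under Hardy-Weinberg equilibrium (with an optional
per-variant inbreeding coefficient for HWE departures), therapy response from
a logistic model with planted per-variant odds ratios, disease-free survival
from an exponential proportional-hazards model with independent exponential
and administrative censoring, completely-at-random missingness, and clinical
covariates drawn from configurable categorical distributions.

All randomness flows from a single config seed; each generation stage uses a
deterministic substream, so regenerating any one stage is reproducible
independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .variant_io import MISSING, ClinicalTable, GenotypeMatrix

GENETIC_MODELS = ("additive", "dominant", "recessive")

# stage tags for seed substreams
_STAGE_GENOTYPES = 0
_STAGE_RESPONSE = 1
_STAGE_SURVIVAL = 2
_STAGE_MISSING = 3
_STAGE_COVARIATES = 4
_STAGE_EVIDENCE = 5

#: Default categorical covariate distributions (testing-set-like composition).
DEFAULT_COVARIATE_SPEC: dict[str, tuple[tuple, tuple]] = {
    "arm": (("neoadjuvant", "adjuvant"), (0.65, 0.35)),
    "stage": ((1, 2, 3), (0.45, 0.44, 0.11)),
    "grade": ((1, 2, 3), (0.11, 0.35, 0.54)),
    "er": (("positive", "negative"), (0.38, 0.62)),
    "pr": (("positive", "negative"), (0.39, 0.61)),
    "her2": (("positive", "negative"), (0.02, 0.98)),
    "subtype": (
        ("luminal A", "luminal B", "HER2", "triple negative"),
        (0.16, 0.24, 0.0, 0.60),
    ),
}


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class VariantEffect:
    """Planted effect of one variant on response and/or survival."""

    model: str = "additive"
    response_or: float = 1.0
    dfs_hr: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in GENETIC_MODELS:
            raise InvalidConfigError(f"unknown genetic model {self.model!r}")
        if self.response_or <= 0 or self.dfs_hr <= 0:
            raise InvalidConfigError("odds and hazard ratios must be > 0")

    def dose(self, calls: np.ndarray) -> np.ndarray:
        """Genetic dose per sample; missing calls contribute zero dose."""
        g = np.asarray(calls, dtype=float)
        g = np.where(g == MISSING, 0.0, g)
        if self.model == "additive":
            return g
        if self.model == "dominant":
            return np.minimum(g, 1.0)
        return (g == 2).astype(float)


@dataclass
class SimulationConfig:
    n_samples: int = 200
    n_variants: int = 10
    maf: float | np.ndarray = 0.3           # rare-allele frequency, scalar or per-variant
    inbreeding_f: float | np.ndarray = 0.0  # 0 = HWE
    effects: dict[str, VariantEffect] = field(default_factory=dict)
    baseline_response_rate: float = 0.5
    baseline_hazard: float = 0.01           # events / month
    censoring_rate: float = 0.005           # events / month
    followup_horizon: float = 120.0         # months
    missing_rate: float = 0.0
    lost_to_followup_rate: float = 0.0
    covariate_spec: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_SPEC))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_variants < 1:
            raise InvalidConfigError("n_samples and n_variants must be >= 1")
        if not 0.0 <= self.baseline_response_rate <= 1.0:
            raise InvalidConfigError("baseline_response_rate outside [0,1]")
        for name in ("missing_rate", "lost_to_followup_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0,1)")
        if self.baseline_hazard <= 0 or self.censoring_rate < 0:
            raise InvalidConfigError("hazards must be positive (censoring may be 0)")
        if self.followup_horizon <= 0:
            raise InvalidConfigError("followup_horizon must be > 0")
        q = self.maf_vector()
        if ((q < 0) | (q > 1)).any():
            raise InvalidConfigError("allele frequencies outside [0,1]")
        f = self.f_vector()
        p = 1.0 - q
        poly = (q > 0) & (q < 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_min = -np.minimum(p, q) / np.maximum(p, q)
        if (f > 1.0).any() or (f[poly] < f_min[poly] - 1e-12).any():
            raise InvalidConfigError("inbreeding_f outside the admissible range")

    def maf_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.maf, dtype=float), (self.n_variants,)).copy()

    def f_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.inbreeding_f, dtype=float), (self.n_variants,)
        ).copy()

    def variant_ids(self) -> list[str]:
        return [f"var{i:05d}" for i in range(self.n_variants)]

    def sample_ids(self) -> list[str]:
        return [f"S{i:05d}" for i in range(self.n_samples)]

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


def gen_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Draw genotypes per variant with P(het) = 2pq(1-f) and homozygote
    probabilities p^2 + pqf and q^2 + pqf (f = inbreeding coefficient)."""
    rng = cfg.rng(_STAGE_GENOTYPES)
    q = cfg.maf_vector()
    p = 1.0 - q
    f = cfg.f_vector()
    p0 = p * p + p * q * f
    p1 = 2.0 * p * q * (1.0 - f)
    p2 = q * q + p * q * f
    probs = np.clip(np.stack([p0, p1, p2], axis=1), 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random((cfg.n_variants, cfg.n_samples))
    cum = np.cumsum(probs, axis=1)
    calls = (u[:, :, None] > cum[:, None, :]).sum(axis=2).astype(np.int8)
    return GenotypeMatrix(cfg.variant_ids(), cfg.sample_ids(), calls)


def _total_dose_effect(
    genotypes: GenotypeMatrix, cfg: SimulationConfig, which: str
) -> np.ndarray:
    """Sum of log-effect * dose over all planted variants, per sample."""
    unknown = [v for v in cfg.effects if v not in genotypes.variant_ids]
    if unknown:
        raise InvalidConfigError(f"effect map refers to unknown variants: {unknown}")
    total = np.zeros(genotypes.n_samples)
    for vid, eff in cfg.effects.items():
        ratio = eff.response_or if which == "response" else eff.dfs_hr
        if ratio == 1.0:
            continue
        total += np.log(ratio) * eff.dose(genotypes.row(vid))
    return total


def gen_response(genotypes: GenotypeMatrix, cfg: SimulationConfig) -> np.ndarray:
    """Bernoulli responder flags from the logistic planted-effect model."""
    rng = cfg.rng(_STAGE_RESPONSE)
    base = np.clip(cfg.baseline_response_rate, 1e-12, 1 - 1e-12)
    lin = logit(base) + _total_dose_effect(genotypes, cfg, "response")
    return rng.random(genotypes.n_samples) < expit(lin)


def gen_survival(
    genotypes: GenotypeMatrix, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(dfs_months, event flags) from exponential PH event times with
    independent exponential censoring and administrative censoring at the
    follow-up horizon."""
    rng = cfg.rng(_STAGE_SURVIVAL)
    n = genotypes.n_samples
    rate = cfg.baseline_hazard * np.exp(_total_dose_effect(genotypes, cfg, "survival"))
    t_event = rng.exponential(1.0 / rate)
    if cfg.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, cfg.followup_horizon)
    months = np.minimum(t_event, t_cens)
    events = t_event <= t_cens
    return months, events


def gen_missing(matrix: GenotypeMatrix, cfg: SimulationConfig) -> GenotypeMatrix:
    """Mask each call independently with probability ``cfg.missing_rate``."""
    if not 0.0 <= cfg.missing_rate < 1.0:
        raise InvalidConfigError("missing_rate must be in [0,1)")
    if cfg.missing_rate == 0.0:
        return GenotypeMatrix(matrix.variant_ids, matrix.sample_ids, matrix.calls.copy())
    rng = cfg.rng(_STAGE_MISSING)
    mask = rng.random(matrix.calls.shape) < cfg.missing_rate
    calls = np.where(mask, MISSING, matrix.calls).astype(np.int8)
    return GenotypeMatrix(matrix.variant_ids, matrix.sample_ids, calls)


def gen_covariates(cfg: SimulationConfig) -> pd.DataFrame:
    """Clinical covariates drawn independently of genotype."""
    rng = cfg.rng(_STAGE_COVARIATES)
    out = {"sample_id": cfg.sample_ids()}
    for name, (categories, probs) in cfg.covariate_spec.items():
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum()
        out[name] = rng.choice(np.asarray(categories, dtype=object), size=cfg.n_samples, p=probs)
    return pd.DataFrame(out)


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix      # with missingness applied
    clinical: ClinicalTable
    truth: dict                    # full (pre-missingness) responder/survival vectors


def generate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Full cohort: genotypes (+missingness), clinical table, ground truth.

    Response is recorded only for neoadjuvant samples; survival is recorded
    for every sample not lost to follow-up.
    """
    complete = gen_genotypes(cfg)
    responders = gen_response(complete, cfg)
    months, events = gen_survival(complete, cfg)
    covs = gen_covariates(cfg)
    observed = gen_missing(complete, cfg)

    rng = cfg.rng(_STAGE_COVARIATES + 100)
    lost = rng.random(cfg.n_samples) < cfg.lost_to_followup_rate

    arm = covs["arm"].to_numpy() if "arm" in covs else np.repeat("neoadjuvant", cfg.n_samples)
    response_col = [
        ("responder" if r else "non-responder") if a == "neoadjuvant" else None
        for r, a in zip(responders, arm)
    ]
    clin = pd.DataFrame(
        {
            "sample_id": cfg.sample_ids(),
            "arm": arm,
            "response": response_col,
            "dfs_months": np.where(lost, np.nan, months),
            "dfs_event": np.where(lost, False, events),
            "stage": covs.get("stage", pd.Series([np.nan] * cfg.n_samples)),
            "grade": covs.get("grade", pd.Series([np.nan] * cfg.n_samples)),
            "er": covs.get("er", pd.Series([None] * cfg.n_samples)),
            "pr": covs.get("pr", pd.Series([None] * cfg.n_samples)),
            "her2": covs.get("her2", pd.Series([None] * cfg.n_samples)),
            "subtype": covs.get("subtype", pd.Series([None] * cfg.n_samples)),
            "lost_to_followup": lost,
        }
    )
    truth = {
        "responders": responders,
        "dfs_months": months,
        "dfs_events": events,
        "complete_genotypes": complete,
    }
    return SyntheticCohort(observed, ClinicalTable(clin), truth)


def gen_evidence(
    variant_ids: list[str],
    seed: int = 0,
    p_associated: float = 0.3,
    p_clinvar_hit: float = 0.3,
    p_deleterious_tools: float = 0.5,
) -> pd.DataFrame:
    """Random evidence table covering ``variant_ids`` (testing convenience).

    Generates missense records with complete four-tool predictions so that
    the in-silico consensus is always callable; database flags are Bernoulli
    draws with the given rates.
    """
    rng = np.random.default_rng([int(seed), _STAGE_EVIDENCE])
    n = len(variant_ids)
    deleterious = rng.random(n) < p_deleterious_tools
    df = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "variant_class": "missense",
            "pharmgkb": np.where(rng.random(n) < p_associated, "associated", "no-data"),
            "clinvar": np.where(rng.random(n) < p_clinvar_hit, "drug-response", "no-data"),
            "cancer_related": False,
            "mutation_assessor": np.where(deleterious, "M", "L"),
            "sift_score": np.where(deleterious, 0.01, 0.6),
            "lrt_pred": np.where(deleterious, "D", "N"),
            "provean_pred": np.where(deleterious, "D", "N"),
            "cadd_phred": np.round(rng.uniform(0, 15, size=n), 2),
            "dbscsnv_ada": np.nan,
            "maxentscan_ref": np.nan,
            "maxentscan_alt": np.nan,
            "regulome_category": None,
            "pines_p": np.nan,
            "iw_score": np.nan,
            "mirna_site": None,
        }
    )
    return df
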