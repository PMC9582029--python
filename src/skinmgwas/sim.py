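"""Synthetic two-cohort, multi-site study generator with known ground truth.

Every downstream stage of the pipeline is exercised on data from this
module: HWE genotypes with block-wise LD, adult covariates, hierarchical
negative-binomial ASV counts driven by sequencing-depth offsets,
confounders and planted SNP effects, and two-sample MR summary statistics
with a known causal effect.

Determinism: one master seed; each sub-generator derives an independent
child stream via ``numpy.random.SeedSequence.spawn``-style keying, so the
same config reproduces byte-identical outputs regardless of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from skinmgwas.datatypes import (
    AbundanceTable,
    AlignmentError,
    GenotypeMatrix,
    RANK_ORDER,
)

_NUCLEOTIDES = np.array(list("ACGT"))

# stream labels for child-seed derivation (order-independent reproducibility)
_STREAMS = {
    "genotypes": 11,
    "covariates": 23,
    "microbiome": 37,
    "mr": 53,
}


class InvalidConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``planted_effects`` entries are ``(variant_index, asv_name, beta)``
    acting on the log-mean scale; ``confounder_effects`` maps an ASV name
    to ``(beta_age, beta_sex, beta_bmi)`` on standardized covariates.
    """

    n_individuals: int = 300
    n_variants: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    n_asvs: int = 50
    taxonomy_depth: int = 6  # number of ranks, ASV included
    depth_lognormal_params: tuple[float, float] = (math.log(20_000.0), 0.5)
    planted_effects: list[tuple[int, str, float]] = field(default_factory=list)
    confounder_effects: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    dispersion_range: tuple[float, float] = (2.0, 20.0)
    age_range: tuple[float, float] = (39.0, 78.0)
    frac_unclassified_genus: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.n_individuals <= 0 or self.n_variants <= 0 or self.n_asvs <= 0:
            raise InvalidConfigError("sizes must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise InvalidConfigError("ld_rho must be in [0, 1)")
        if self.ld_block_size <= 0:
            raise InvalidConfigError("ld_block_size must be positive")
        lo, hi = self.dispersion_range
        if not (0.0 < lo <= hi):
            raise InvalidConfigError("dispersion_range must be positive")
        for idx, asv, _beta in self.planted_effects:
            if not (0 <= idx < self.n_variants):
                raise InvalidConfigError(f"planted variant index {idx} out of range")
            if asv not in self.asv_names():
                raise InvalidConfigError(f"planted feature {asv!r} not among ASVs")

    def asv_names(self) -> list[str]:
        width = max(3, len(str(self.n_asvs)))
        return [f"ASV{i:0{width}d}" for i in range(1, self.n_asvs + 1)]

    def rng(self, stream: str, extra: int = 0) -> np.random.Generator:
        """Deterministic child generator for a named sub-stream."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream], extra))
        )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig, cohort: str = "cohortA") -> GenotypeMatrix:
    """HWE genotypes with AR(1) Gaussian-copula LD inside blocks.

    Two latent standard-normal haplotype variables per individual follow an
    AR(1) process with parameter ``ld_rho`` along each block of
    ``ld_block_size`` variants; thresholding at the allele-frequency
    quantile yields alleles, so adjacent-variant r^2 rises monotonically
    with ``ld_rho`` while marginal frequencies stay at their HWE values.
    """
    rng = config.rng("genotypes")
    n, m = config.n_individuals, config.n_variants
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(maf)

    rho = config.ld_rho
    block = config.ld_block_size
    dos = np.empty((n, m), dtype=float)
    # two haplotypes per individual, generated variant-by-variant within blocks
    z = np.empty((2, n, m))
    innov = rng.standard_normal(size=(2, n, m))
    scale = math.sqrt(1.0 - rho * rho)
    for j in range(m):
        if j % block == 0 or rho == 0.0:
            z[:, :, j] = innov[:, :, j]
        else:
            z[:, :, j] = rho * z[:, :, j - 1] + scale * innov[:, :, j]
    alleles = (z < thresholds[None, None, :]).astype(np.int8)
    dos = alleles.sum(axis=0).astype(float)

    snp_ids = [f"rs{i + 1:06d}" for i in range(m)]
    positions = 10_000 + 1_000 * np.arange(m)  # 1-based, evenly spaced
    ea = rng.choice(_NUCLEOTIDES, size=m)
    shift = rng.integers(1, 4, size=m)
    nuc_idx = np.array([np.where(_NUCLEOTIDES == a)[0][0] for a in ea])
    oa = _NUCLEOTIDES[(nuc_idx + shift) % 4]
    samples = [f"{cohort}_s{i + 1:04d}" for i in range(n)]

    dosages = pd.DataFrame(dos, index=samples, columns=snp_ids)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": positions,
            "ea": ea,
            "oa": oa,
            "eaf": dosages.mean(axis=0).to_numpy() / 2.0,
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    cohort_labels = pd.Series(cohort, index=samples, name="cohort")
    return GenotypeMatrix(dosages=dosages, variants=variants, cohort=cohort_labels)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def simulate_covariates(config: SimulationConfig, samples: list[str] | None = None) -> pd.DataFrame:
    """Age (uniform in ``age_range``), binary sex and lognormal BMI."""
    rng = config.rng("covariates")
    n = config.n_individuals
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    sex = rng.integers(0, 2, size=n)
    bmi = rng.lognormal(mean=math.log(26.0), sigma=0.15, size=n)
    if samples is None:
        samples = [f"s{i + 1:04d}" for i in range(n)]
    return pd.DataFrame({"age": age, "sex": sex, "bmi": bmi}, index=samples)


def _standardize_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Center/scale covariates for use inside the count generator only."""
    out = pd.DataFrame(index=cov.index)
    out["age"] = (cov["age"] - cov["age"].mean()) / 10.0
    out["sex"] = cov["sex"] - cov["sex"].mean()
    out["bmi"] = (cov["bmi"] - cov["bmi"].mean()) / 4.0
    return out


# ---------------------------------------------------------------------------
# taxonomy + microbiome counts
# ---------------------------------------------------------------------------

def build_taxonomy(config: SimulationConfig) -> pd.DataFrame:
    """Nested random taxonomy: ASVs grouped into genera, genera into
    families, and so on up to phylum.  A fraction of ASVs is left
    unclassified at genus rank (NaN) to exercise rank-aggregation rules."""
    rng = config.rng("microbiome", extra=1)
    asvs = config.asv_names()
    ranks = [r for r in RANK_ORDER if r != "asv"][-(config.taxonomy_depth - 1):]
    # deepest non-ASV rank first when assigning groups
    ladder = list(reversed(ranks))  # e.g. genus, family, order, class, phylum
    tax = pd.DataFrame(index=pd.Index(asvs, name="asv"), columns=ranks, dtype=object)

    n_groups = max(1, config.n_asvs // 3)
    labels = [f"{ladder[0][0].upper()}{i + 1:03d}" for i in range(n_groups)]
    assign = rng.integers(0, n_groups, size=config.n_asvs)
    current = np.array([labels[g] for g in assign], dtype=object)
    unclassified = rng.random(config.n_asvs) < config.frac_unclassified_genus
    current[unclassified] = None
    tax[ladder[0]] = current

    # coarser ranks: merge pairs of groups going up; unclassified ASVs get a
    # classified coarse clade so they are only missing at the deep rank
    parent_of = {lab: i // 2 for i, lab in enumerate(labels)}
    deep_assign = assign.copy()
    for level, rank in enumerate(ladder[1:], start=1):
        n_here = max(1, n_groups // (2**level))
        lab_here = [f"{rank[0].upper()}{i + 1:03d}" for i in range(n_here)]
        tax[rank] = [lab_here[min(a // (2**level), n_here - 1)] for a in deep_assign]
    return tax


def simulate_microbiome(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    site: str = "siteA",
) -> AbundanceTable:
    """NB counts per ASV with log-link mean: baseline + confounders +
    planted SNP effects + log sequencing depth (offset)."""
    if list(genotypes.dosages.index) != list(covariates.index):
        raise AlignmentError("genotype and covariate sample sets differ")

    rng = config.rng("microbiome", extra=_site_key(site))
    n = genotypes.n_samples
    asvs = config.asv_names()
    taxonomy = build_taxonomy(config)

    depth = rng.lognormal(
        mean=config.depth_lognormal_params[0],
        sigma=config.depth_lognormal_params[1],
        size=n,
    )

    base_rng = config.rng("microbiome", extra=2)
    base = base_rng.normal(0.0, 1.2, size=config.n_asvs)
    base -= np.log(np.exp(base).sum())  # relative abundances sum to ~1
    theta = base_rng.uniform(*config.dispersion_range, size=config.n_asvs)

    covs = _standardize_covariates(covariates)
    log_mu = np.tile(base, (n, 1)) + np.log(depth)[:, None]
    for asv, (b_age, b_sex, b_bmi) in config.confounder_effects.items():
        j = asvs.index(asv)
        log_mu[:, j] += (
            b_age * covs["age"].to_numpy()
            + b_sex * covs["sex"].to_numpy()
            + b_bmi * covs["bmi"].to_numpy()
        )
    for v_idx, asv, beta in config.planted_effects:
        j = asvs.index(asv)
        dose = genotypes.dosages.iloc[:, v_idx].to_numpy()
        log_mu[:, j] += beta * dose

    mu = np.exp(log_mu)
    # NB draws: gamma-Poisson mixture, Var = mu + mu^2/theta
    shape = np.tile(theta, (n, 1))
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)

    frame = pd.DataFrame(counts, index=genotypes.dosages.index, columns=asvs)
    meta = pd.DataFrame(
        {"site": site, "cohort": genotypes.cohort.reindex(frame.index)}, index=frame.index
    )
    return AbundanceTable(counts=frame, taxonomy=taxonomy, sample_meta=meta)


def _site_key(site: str) -> int:
    return 100 + (sum(ord(c) for c in site) % 1000)


# ---------------------------------------------------------------------------
# MR summary statistics
# ---------------------------------------------------------------------------

def simulate_mr_summary(
    config: SimulationConfig,
    causal_beta: float,
    n_instruments: int,
    pleiotropy_sd: float = 0.0,
    exposure_beta_sd: float = 0.15,
    n_exposure: int = 20_000,
    n_outcome: int = 50_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sample summary statistics with a planted causal effect.

    Instrument effects on the exposure are drawn with typical magnitude
    ``exposure_beta_sd``; outcome effects are ``causal_beta`` times the true
    exposure effect plus pleiotropy noise; both tables carry independent
    estimation noise at the standard error implied by their sample size.
    """
    if n_instruments < 1:
        raise InvalidConfigError("n_instruments must be >= 1")
    rng = config.rng("mr")
    m = n_instruments
    eaf = rng.uniform(0.1, 0.9, size=m)
    beta_true = rng.normal(0.0, exposure_beta_sd, size=m)
    # keep instruments away from zero so F statistics are informative
    beta_true += np.sign(beta_true + 1e-12) * exposure_beta_sd / 2.0

    se_exp = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_exposure)
    se_out = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_outcome)
    beta_exp = beta_true + rng.normal(0.0, se_exp)
    pleio = rng.normal(0.0, pleiotropy_sd, size=m) if pleiotropy_sd > 0 else 0.0
    beta_out = causal_beta * beta_true + pleio + rng.normal(0.0, se_out)

    ea = rng.choice(_NUCLEOTIDES, size=m)
    shift = rng.integers(1, 4, size=m)
    nuc_idx = np.array([np.where(_NUCLEOTIDES == a)[0][0] for a in ea])
    oa = _NUCLEOTIDES[(nuc_idx + shift) % 4]

    def table(beta: np.ndarray, se: np.ndarray, n_eff: int) -> pd.DataFrame:
        z = beta / se
        return pd.DataFrame(
            {
                "SNP": [f"iv{i + 1:04d}" for i in range(m)],
                "CHR": "1",
                # spaced beyond the default 10 Mb clump window: instruments
                # are independent by construction
                "POS": 10_000 + 20_000_000 * np.arange(m),
                "EA": ea,
                "OA": oa,
                "EAF": eaf,
                "BETA": beta,
                "SE": se,
                "P": 2.0 * stats.norm.sf(np.abs(z)),
                "N": n_eff,
            }
        )

    return table(beta_exp, se_exp, n_exposure), table(beta_out, se_out, n_outcome)


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------

#: study design mirroring a two-cohort, three-microenvironment layout
DEFAULT_SITES = {
    "cohortA": ["antecubital_fossa", "retroauricular_fold"],
    "cohortB": ["antecubital_fossa", "forehead", "dorsal_forearm", "volar_forearm"],
}

MICROENV_SITES = {
    "moist": ["antecubital_fossa@cohortA", "antecubital_fossa@cohortB"],
    "sebaceous": ["retroauricular_fold@cohortA", "forehead@cohortB"],
    "dry": ["dorsal_forearm@cohortB", "volar_forearm@cohortB"],
}


def simulate_study(config: SimulationConfig, sites: dict[str, list[str]] | None = None):
    """Simulate genotypes, covariates and per-site abundance tables for a
    two-cohort study.  Returns ``(genotypes, covariates, tables)`` where
    each dict is keyed by cohort (and ``tables`` by ``site@cohort``)."""
    sites = sites if sites is not None else DEFAULT_SITES
    genotypes: dict[str, GenotypeMatrix] = {}
    covariates: dict[str, pd.DataFrame] = {}
    tables: dict[str, AbundanceTable] = {}
    for k, (cohort, site_list) in enumerate(sorted(sites.items())):
        cfg = SimulationConfig(**{**config.__dict__, "seed": config.seed + 7919 * k})
        g = simulate_genotypes(cfg, cohort=cohort)
        cov = simulate_covariates(cfg, samples=list(g.dosages.index))
        genotypes[cohort] = g
        covariates[cohort] = cov
        for site in site_list:
            tables[f"{site}@{cohort}"] = simulate_microbiome(g, cov, cfg, site=site)
    return genotypes, covariates, tables
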