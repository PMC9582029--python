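"""Shared domain types.

All tabular payloads are pandas objects; the dataclasses here add the
invariants and metadata that a bare frame cannot carry (allele columns,
taxonomy ladders, eigenvalues, significance verdicts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical rank ladder from shallowest to deepest
RANK_ORDER = ("phylum", "class", "order", "family", "genus", "asv")

#: single-letter prefixes used in feature names (a.ASV001, g.Staphylococcus, ...)
RANK_PREFIX = {
    "asv": "a.",
    "genus": "g.",
    "family": "f.",
    "order": "o.",
    "class": "c.",
    "phylum": "p.",
}


class AlignmentError(ValueError):
    """Sample sets of two tables that must be aligned do not match."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    Dosages are 0/1/2 counts of the effect allele; missing values are NaN.
    ``variants`` has one row per variant with columns
    ``snp, chrom, pos, ea, oa, eaf`` (1-based positions).
    """

    dosages: pd.DataFrame  # index: sample ids, columns: variant ids
    variants: pd.DataFrame  # index: variant ids
    cohort: pd.Series | None = None  # per-sample cohort label

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants.index):
            raise AlignmentError("dosage columns and variant metadata disagree")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def realized_eaf(self) -> pd.Series:
        """Effect-allele frequency from non-missing dosages, in [0, 1]."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def subset_variants(self, keep: pd.Index | list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages.loc[:, keep],
            variants=self.variants.loc[keep],
            cohort=self.cohort,
        )


@dataclass
class AbundanceTable:
    """Samples x features count table with a taxonomy ladder.

    ``counts`` holds non-negative integers.  ``taxonomy`` maps each base
    feature (ASV) to its clade at every rank; NaN marks an unclassified
    rank.  ``sample_meta`` carries per-sample site/cohort labels.
    """

    counts: pd.DataFrame  # index: sample ids, columns: feature ids
    taxonomy: pd.DataFrame | None = None  # index: asv ids, columns: ranks
    sample_meta: pd.DataFrame | None = None  # columns: site, cohort

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class PCMatrix:
    """Genetic principal-component scores (samples x k) with eigenvalues."""

    scores: pd.DataFrame
    eigenvalues: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class AssociationResult:
    """One (feature, variant, site) association test."""

    feature: str
    snp: str
    site: str
    beta: float  # NaN for multivariate pseudo-F tests
    se: float  # NaN for multivariate pseudo-F tests
    p: float
    n: int
    stat_type: str = "t"  # "t" or "pseudo_F"
    statistic: float = float("nan")
    tested: bool = True
    note: str = ""


@dataclass
class MetaResult:
    """Combined per-microenvironment result plus significance verdict."""

    feature: str
    snp: str
    microenv: str
    beta: float
    se: float
    z: float
    p_meta: float
    site_p: dict = field(default_factory=dict)
    n_total: int = 0
    verdict: str = "not_significant"  # not_significant | genome_wide | study_wide
    rule: str = ""  # "two_cohort" | "dry_single_cohort"
    q_het: float = float("nan")  # Cochran's Q heterogeneity p (logged, unused)
    note: str = ""


@dataclass
class Locus:
    """A fine-mapping locus around a lead variant."""

    lead: str
    variants: pd.DataFrame  # index snp; columns pos, beta, se, p, r2_to_lead
    stat_type: str = "t"

    def __post_init__(self) -> None:
        if self.lead not in self.variants.index:
            raise ValueError("lead variant absent from locus table")


@dataclass
class CredibleSet:
    """Posterior-sorted credible set under a single causal variant."""

    table: pd.DataFrame  # index snp; columns log_abf, posterior, in_cs (sorted)
    coverage: float
    valid: bool  # False when the set has >= max_size variants

    @property
    def members(self) -> list[str]:
        return list(self.table.index[self.table["in_cs"]])

    @property
    def size(self) -> int:
        return int(self.table["in_cs"].sum())


@dataclass
class MREstimate:
    """One Mendelian-randomization estimate."""

    method: str  # wald | ivw | egger | weighted_median
    beta: float
    se: float
    p: float
    n_snps: int
    intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_p: float = float("nan")


@dataclass
class MRResult:
    """Primary + sensitivity MR output for one exposure-outcome pair."""

    exposure: str
    outcome: str
    primary: MREstimate
    egger: MREstimate | None = None
    weighted_median: MREstimate | None = None
    verdict: str = "weak_or_inconclusive"
    verdict_reason: str = ""
    q_trait: float = float("nan")
    q_global: float = float("nan")


SUMMARY_STAT_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
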