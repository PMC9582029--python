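"""Variant-level genotype QC and genetic principal components.

Filters follow standard GWAS practice: MAF, missingness, exact HWE,
biallelic-only and removal of monomorphic variants; the PCA of the
column-standardized dosage matrix supplies the genetic-background
covariates used by every association model.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd

from skinmgwas.datatypes import GenotypeMatrix, PCMatrix

_SNV = set("ACGT")


def hwe_exact_test(n_aa_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Sums, over all heterozygote counts attainable given the observed allele
    counts, the conditional probabilities that are no larger than that of
    the observed configuration.
    """
    n_AA, n_Aa, n_aa = int(n_aa_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = n_Aa + 2 * n_aa  # minor-or-not does not matter: test is symmetric
    n_A = n_Aa + 2 * n_AA
    rare = min(n_a, n_A)

    probs = _hwe_het_probabilities(n, rare)
    p_obs = probs.get(n_Aa)
    if p_obs is None:  # parity mismatch cannot happen with consistent counts
        raise ValueError("inconsistent genotype counts")
    p = sum(pr for pr in probs.values() if pr <= p_obs * (1 + 1e-12))
    return min(1.0, p)


@lru_cache(maxsize=4096)
def _hwe_het_probabilities(n: int, rare: int) -> dict[int, float]:
    """Conditional probabilities of each attainable heterozygote count given
    ``rare`` copies of the rarer allele among ``2n`` alleles."""
    common = 2 * n - rare
    lg = math.lgamma
    out: dict[int, float] = {}
    logs = []
    hets = []
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = (common - het) // 2
        if hom_common < 0:
            continue
        # log P(het | allele counts) up to the common normalizer
        val = (
            het * math.log(2.0)
            + lg(n + 1)
            - lg(hom_rare + 1)
            - lg(het + 1)
            - lg(hom_common + 1)
        )
        logs.append(val)
        hets.append(het)
    m = max(logs)
    weights = [math.exp(v - m) for v in logs]
    total = sum(weights)
    for het, w in zip(hets, weights):
        out[het] = w / total
    return out


def _genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    d = dosage[~np.isnan(dosage)]
    d = np.rint(d).astype(int)
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def variant_filters(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    hwe_alpha: float = 1e-5,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the variant-level filters; returns the filtered matrix and a
    per-variant log with the first rule each removed variant failed.

    Retains variants that are biallelic SNVs, non-monomorphic, with
    MAF >= ``maf_min``, missingness <= ``miss_max`` and exact HWE
    p >= ``hwe_alpha``.
    """
    dos = g.dosages.to_numpy(dtype=float)
    records = []
    keep = []
    for j, snp in enumerate(g.dosages.columns):
        meta = g.variants.iloc[j]
        col = dos[:, j]
        nonmiss = ~np.isnan(col)
        reason = ""
        ea, oa = str(meta["ea"]), str(meta["oa"])
        if ea == oa or ea not in _SNV or oa not in _SNV:
            reason = "non_biallelic"
        elif nonmiss.sum() == 0:
            reason = "all_missing"
        else:
            eaf = float(col[nonmiss].mean()) / 2.0
            maf = min(eaf, 1.0 - eaf)
            miss = 1.0 - nonmiss.mean()
            if maf == 0.0:
                reason = "monomorphic"
            elif maf < maf_min:
                reason = "maf"
            elif miss > miss_max:
                reason = "missingness"
            else:
                n0, n1, n2 = _genotype_counts(col)
                if hwe_exact_test(n0, n1, n2) < hwe_alpha:
                    reason = "hwe"
        records.append({"snp": snp, "removed": bool(reason), "reason": reason})
        keep.append(not reason)
    log = pd.DataFrame.from_records(records).set_index("snp")
    kept_ids = g.dosages.columns[np.asarray(keep)]
    return g.subset_variants(kept_ids), log


def genetic_pcs(g: GenotypeMatrix, k: int = 10) -> PCMatrix:
    """PCA of the column-standardized dosage matrix.

    Missing dosages are mean-imputed per variant.  Sign convention: each
    component's largest-magnitude variant loading is positive, so scores
    are deterministic.
    """
    if k > min(g.n_samples, g.n_variants):
        raise ValueError(f"k={k} exceeds min(n_samples, n_variants)")
    x = g.dosages.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x -= col_mean
    sd = x.std(axis=0, ddof=0)
    informative = sd > 0
    x = x[:, informative] / sd[informative]

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic signs via the loadings
    for i in range(min(k, len(s))):
        lead = np.argmax(np.abs(vt[i]))
        if vt[i, lead] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u[:, :k] * s[:k]
    frame = pd.DataFrame(
        scores, index=g.dosages.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    eigvals = (s**2) / max(g.n_samples - 1, 1)
    return PCMatrix(scores=frame, eigenvalues=eigvals[:k])
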