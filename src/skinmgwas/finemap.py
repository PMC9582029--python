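"""Single-causal-variant Bayesian fine-mapping with LD fallback.

Per locus: approximate Bayes factors from per-variant beta/SE under a
normal prior on the effect size, posterior inclusion probabilities under a
uniform prior over variants, the smallest posterior-sorted 95% set, and an
LD-based fallback (r^2 to the lead variant) when the credible set is too
large or the statistic carries no effect direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from skinmgwas.datatypes import CredibleSet, GenotypeMatrix, Locus

DEFAULT_PRIOR_W = 0.04  # prior effect-size variance (SD 0.2 on residual scale)
DEFAULT_WINDOW = 500_000  # bp to each side of the lead variant
MAX_CS_SIZE = 50


def log_abf(beta: float, se: float, prior_w: float = DEFAULT_PRIOR_W) -> float:
    """Log approximate Bayes factor for one variant.

    ABF = sqrt(V / (V + W)) * exp(W z^2 / (2 (V + W))) with V = se^2,
    z = beta / se, W the prior effect variance.  W = 0 gives ABF = 1.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    if prior_w < 0:
        raise ValueError("prior variance must be non-negative")
    v = se * se
    z = beta / se
    return 0.5 * np.log(v / (v + prior_w)) + prior_w * z * z / (2.0 * (v + prior_w))


def credible_set(
    locus: Locus,
    prior_w: float = DEFAULT_PRIOR_W,
    coverage: float = 0.95,
    max_size: int = MAX_CS_SIZE,
) -> CredibleSet:
    """95% credible set under one causal variant and a uniform variant prior.

    Posterior_i = ABF_i / sum_j ABF_j; the set is the smallest prefix of
    the posterior-sorted variants whose cumulative posterior reaches
    ``coverage``.  Sets of ``max_size`` or more variants are flagged
    invalid (fine-mapping "did not find a credible set").
    """
    tab = locus.variants
    labf = np.array([log_abf(b, s, prior_w) for b, s in zip(tab["beta"], tab["se"])])
    shifted = labf - labf.max()
    post = np.exp(shifted)
    post /= post.sum()
    order = np.argsort(-post, kind="stable")
    cum = np.cumsum(post[order])
    n_in = int(np.searchsorted(cum, coverage - 1e-12) + 1)
    out = tab.iloc[order].copy()
    out["log_abf"] = labf[order]
    out["posterior"] = post[order]
    out["in_cs"] = np.arange(len(out)) < n_in
    return CredibleSet(table=out, coverage=coverage, valid=n_in < max_size)


def ld_r2(g: GenotypeMatrix | pd.DataFrame, i: str, j: str) -> float:
    """Squared Pearson correlation of two dosage columns over samples
    non-missing at both variants."""
    dos = g.dosages if isinstance(g, GenotypeMatrix) else g
    x = dos[i].to_numpy(dtype=float)
    y = dos[j].to_numpy(dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("monomorphic variant in LD computation")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def build_locus(
    stats_frame: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    window: int = DEFAULT_WINDOW,
    stat_type: str = "t",
) -> Locus:
    """Assemble a locus around the lowest-p variant of a summary frame.

    ``stats_frame`` needs SNP, POS, BETA, SE, P columns; r^2 to the lead is
    filled from ``genotypes`` when provided.
    """
    f = stats_frame.dropna(subset=["P"]).copy()
    f = f.sort_values(["P", "POS"], kind="stable")
    lead = f.iloc[0]
    members = f[(f["POS"] - lead["POS"]).abs() <= window].copy()
    members = members.set_index("SNP")
    r2 = np.full(len(members), np.nan)
    if genotypes is not None:
        for k, snp in enumerate(members.index):
            try:
                r2[k] = ld_r2(genotypes, snp, lead["SNP"]) if snp != lead["SNP"] else 1.0
            except ValueError:
                r2[k] = np.nan
    tab = pd.DataFrame(
        {
            "pos": members["POS"],
            "beta": members["BETA"],
            "se": members["SE"],
            "p": members["P"],
            "r2_to_lead": r2,
        },
        index=members.index,
    )
    return Locus(lead=str(lead["SNP"]), variants=tab, stat_type=stat_type)


def locus_fallback(locus: Locus, cs: CredibleSet, ld_cut: float = 0.6) -> list[str]:
    """Candidate causal variants: the credible set when valid, otherwise
    (and always for direction-free multivariate loci) all variants with
    r^2 > ``ld_cut`` to the lead, plus the lead itself."""
    if cs.valid and locus.stat_type != "pseudo_F":
        return cs.members
    r2 = locus.variants["r2_to_lead"]
    hits = list(locus.variants.index[(r2 > ld_cut).fillna(False)])
    if locus.lead not in hits:
        hits.insert(0, locus.lead)
    return hits


def finemap_locus(
    stats_frame: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    prior_w: float = DEFAULT_PRIOR_W,
    coverage: float = 0.95,
    window: int = DEFAULT_WINDOW,
    ld_cut: float = 0.6,
    stat_type: str = "t",
) -> pd.DataFrame:
    """End-to-end fine-mapping of one locus; returns the per-variant table
    with posteriors, credible-set membership and the fallback candidates."""
    locus = build_locus(stats_frame, genotypes, window=window, stat_type=stat_type)
    if stat_type == "pseudo_F":
        candidates = locus_fallback(locus, CredibleSet(
            table=locus.variants.assign(log_abf=np.nan, posterior=np.nan, in_cs=False),
            coverage=coverage, valid=False), ld_cut)
        out = locus.variants.copy()
        out["log_abf"] = np.nan
        out["posterior"] = np.nan
        out["in_cs"] = False
    else:
        cs = credible_set(locus, prior_w=prior_w, coverage=coverage)
        candidates = locus_fallback(locus, cs, ld_cut)
        out = cs.table
    out["candidate"] = out.index.isin(candidates)
    out["lead"] = out.index == locus.lead
    return out
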