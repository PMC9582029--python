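"""Microbial feature construction.

From a per-site ASV count table to the set of tested features: taxonomy
aggregation, rarefaction, median/prevalence filtering with the both-sites
rule, Spearman redundancy clustering and Bray-Curtis dissimilarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from skinmgwas.datatypes import AbundanceTable, DistanceMatrix, RANK_ORDER, RANK_PREFIX

logger = logging.getLogger(__name__)

#: deeper ranks win when choosing a cluster representative
_RANK_DEPTH = {rank: i for i, rank in enumerate(RANK_ORDER)}  # phylum=0 ... asv=5


@dataclass
class FeatureSet:
    """Retained features for one microenvironment after redundancy clustering."""

    microenv: str
    features: list[str]  # prefixed names, e.g. "g.G001"
    clusters: dict[str, list[str]] = field(default_factory=dict)  # rep -> members
    representative_rule: str = "deepest rank, ties broken alphabetically"


def aggregate_taxonomy(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum ASV counts sharing the same taxon at ``rank``.

    ASVs unclassified at the rank are excluded from the aggregation (they
    remain available as ASV-level features).  ``rank='asv'`` is the
    identity.
    """
    if rank not in RANK_ORDER:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANK_ORDER}")
    if rank == "asv":
        return table
    if table.taxonomy is None or rank not in table.taxonomy.columns:
        raise ValueError(f"taxonomy not defined at rank {rank!r}")
    tax = table.taxonomy[rank].reindex(table.counts.columns)
    classified = tax.notna()
    grouped = table.counts.loc[:, classified.to_numpy()].T.groupby(tax[classified]).sum().T
    grouped = grouped.sort_index(axis=1)
    return AbundanceTable(counts=grouped, taxonomy=table.taxonomy, sample_meta=table.sample_meta)


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with total count below ``depth`` are dropped (and logged).
    Each sample uses an independent child seed so results do not depend on
    sample order.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    dropped = list(table.counts.index[~keep])
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s", len(dropped), depth, dropped)
    kept = table.counts.loc[keep]
    out = np.empty(kept.shape, dtype=np.int64)
    for i, (_, row) in enumerate(kept.iterrows()):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        counts = row.to_numpy().astype(np.int64)
        if counts.sum() == depth:
            out[i] = counts
        else:
            out[i] = rng.multivariate_hypergeometric(counts, depth)
    frame = pd.DataFrame(out, index=kept.index, columns=kept.columns)
    meta = table.sample_meta.loc[keep] if table.sample_meta is not None else None
    return AbundanceTable(counts=frame, taxonomy=table.taxonomy, sample_meta=meta)


def _passes_site_filters(col: pd.Series, median_min: float, prevalence_min: int) -> bool:
    return float(col.median()) > median_min and int((col > 0).sum()) > prevalence_min


def filter_features(
    site_tables: dict[str, pd.DataFrame],
    median_min: float = 50,
    prevalence_min: int = 100,
) -> list[str]:
    """Candidate features passing the per-site abundance/prevalence filters
    at *both* sites of a microenvironment.

    ``site_tables`` maps site name to a samples x features count frame (the
    features must be aligned across the two sites, e.g. a common rank
    aggregation).  A feature is retained iff, at every site, its median
    count is strictly greater than ``median_min`` and it is present
    (count > 0) in strictly more than ``prevalence_min`` participants.
    """
    if len(site_tables) < 1:
        raise ValueError("at least one site table required")
    per_site: list[set[str]] = []
    for site, frame in site_tables.items():
        ok = {
            f
            for f in frame.columns
            if _passes_site_filters(frame[f], median_min, prevalence_min)
        }
        per_site.append(ok)
    shared = set.intersection(*per_site)
    # stable order: first table's column order
    first = next(iter(site_tables.values()))
    ordered = [f for f in first.columns if f in shared]
    ordered += sorted(shared.difference(first.columns))
    return ordered


def _rank_of(name: str) -> str:
    for rank, prefix in RANK_PREFIX.items():
        if name.startswith(prefix):
            return rank
    return "asv"


def cluster_redundant(
    candidates: pd.DataFrame,
    rho_cut: float = 0.985,
    microenv: str = "",
) -> FeatureSet:
    """Merge features whose cross-sample Spearman correlation exceeds
    ``rho_cut``; keep one representative per cluster.

    ``candidates`` is samples x features with prefixed feature names
    (``a./g./f./o./c./p.``).  Clusters are connected components of the
    graph with edges at rho > ``rho_cut``; the representative is the
    feature of deepest taxonomic rank, ties broken alphabetically.
    """
    names = list(candidates.columns)
    k = len(names)
    if k == 0:
        return FeatureSet(microenv=microenv, features=[], clusters={})
    if k == 1:
        return FeatureSet(microenv=microenv, features=names, clusters={names[0]: names[:]})

    rho = stats.spearmanr(candidates.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])

    parent = list(range(k))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if rho[i, j] > rho_cut:
                parent[find(i)] = find(j)

    groups: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        groups.setdefault(find(i), []).append(name)

    clusters: dict[str, list[str]] = {}
    for members in groups.values():
        rep = min(members, key=lambda f: (-_RANK_DEPTH[_rank_of(f)], f))
        clusters[rep] = sorted(members)
    reps = sorted(clusters, key=names.index)
    return FeatureSet(microenv=microenv, features=reps, clusters={r: clusters[r] for r in reps})


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between all sample pairs.

    BC(x, y) = 1 - 2 * sum_i min(x_i, y_i) / (sum_i x_i + sum_i y_i).
    """
    x = table.counts.to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).any():
        bad = list(table.counts.index[x.sum(axis=1) == 0])
        raise ValueError(f"samples with zero total count: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(values=d, ids=list(table.counts.index))


def prefixed_feature_tables(
    table: AbundanceTable,
    ranks: tuple[str, ...] = ("genus", "family", "order", "class", "phylum"),
) -> pd.DataFrame:
    """All candidate univariate features for one site, columns prefixed by
    rank (a.ASV001, g.G001, ...), ASV level included."""
    pieces = [table.counts.add_prefix(RANK_PREFIX["asv"])]
    for rank in ranks:
        if table.taxonomy is not None and rank in table.taxonomy.columns:
            agg = aggregate_taxonomy(table, rank)
            pieces.append(agg.counts.add_prefix(RANK_PREFIX[rank]))
    return pd.concat(pieces, axis=1)


def build_feature_set(
    site_tables: dict[str, AbundanceTable],
    microenv: str,
    median_min: float = 50,
    prevalence_min: int = 100,
    rho_cut: float = 0.985,
) -> FeatureSet:
    """Full univariate feature construction for one microenvironment:
    rank-prefixed candidates -> per-site + both-sites filters -> Spearman
    redundancy clustering (run on the pooled samples of both sites)."""
    prefixed = {site: prefixed_feature_tables(t) for site, t in site_tables.items()}
    common = set.intersection(*(set(f.columns) for f in prefixed.values()))
    prefixed = {s: f.loc[:, sorted(common)] for s, f in prefixed.items()}
    candidates = filter_features(prefixed, median_min=median_min, prevalence_min=prevalence_min)
    if not candidates:
        return FeatureSet(microenv=microenv, features=[], clusters={})
    pooled = pd.concat([f.loc[:, candidates] for f in prefixed.values()], axis=0)
    return cluster_redundant(pooled, rho_cut=rho_cut, microenv=microenv)
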