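"""Exact permutation moments of the quadratic form q(a) = a' G a.

Used by the multivariate distance F-test: with residual ordination
coordinates R (columns centered) and Gram matrix G = R R', the pseudo-F for
a centered dosage vector a is a monotone function of q(a) = a'Ga / (a'a),
and a'a is permutation-invariant.  The null distribution of q under random
relabeling of samples is therefore characterized by the permutation moments
of Q = a_pi' G a_pi, which this module computes exactly.

Method: E[Q^k] expands over index tuples; the expectation of each term
depends only on (i) the equality pattern of the 2k position indices — a set
partition — and (ii) the multiset of exponents it induces on the permuted
values.  Pattern sums over G are obtained from unconstrained einsum
contractions by Moebius inversion on the partition lattice; value-side
distinct-index power sums follow a standard recursion.  All quantities are
exact, so a Pearson type III fit to (mean, variance, skewness) reproduces
large-permutation p-values without sampling.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def set_partitions(elements: tuple[int, ...]):
    """All set partitions of ``elements`` (each a tuple of sorted-tuple blocks)."""
    if not elements:
        yield ()
        return
    first, rest = elements[0], elements[1:]
    for sub in set_partitions(rest):
        # first joins an existing block, or forms its own
        for i in range(len(sub)):
            yield tuple(
                tuple(sorted(block + (first,))) if j == i else block
                for j, block in enumerate(sub)
            )
        yield ((first,),) + sub


def _refines(fine, coarse) -> bool:
    """True iff every block of ``fine`` is contained in a block of ``coarse``."""
    lookup = {}
    for bi, block in enumerate(coarse):
        for e in block:
            lookup[e] = bi
    for block in fine:
        owners = {lookup[e] for e in block}
        if len(owners) != 1:
            return False
    return True


@lru_cache(maxsize=None)
def _partition_lattice(n_slots: int):
    """Partitions of range(n_slots) plus, per partition, the list of strictly
    coarser partitions (for Moebius inversion)."""
    parts = sorted(set_partitions(tuple(range(n_slots))), key=len, reverse=True)
    coarser = []
    for p in parts:
        cs = [q for q in parts if len(q) < len(p) and _refines(p, q)]
        coarser.append(cs)
    return parts, coarser


_LETTERS = "abcdefghijkl"


def _free_pattern_sum(G: np.ndarray, partition, edges) -> float:
    """Sum over all index assignments (blocks equal, collisions allowed) of
    the product of G over ``edges``."""
    block_of = {}
    for bi, block in enumerate(partition):
        for e in block:
            block_of[e] = bi
    subs = ",".join(_LETTERS[block_of[i]] + _LETTERS[block_of[j]] for i, j in edges)
    return float(np.einsum(subs + "->", *([G] * len(edges)), optimize=True))


def _distinct_power_sum(a_powers: np.ndarray, exponents: tuple[int, ...]) -> float:
    """D(e1..er) = sum over distinct indices i1..ir of prod a_{ib}^{eb}.

    ``a_powers[k]`` is the power sum p_k = sum_i a_i^k.  Recursion:
    D(e1..er) = p_er * D(e1..e_{r-1}) - sum_t D(.., e_t + e_r, ..).
    """
    return _dps_cached(tuple(a_powers), tuple(sorted(exponents)))


@lru_cache(maxsize=100_000)
def _dps_cached(powers: tuple[float, ...], exponents: tuple[int, ...]) -> float:
    if len(exponents) == 1:
        return powers[exponents[0]]
    head, last = exponents[:-1], exponents[-1]
    total = powers[last] * _dps_cached(powers, head)
    for t in range(len(head)):
        merged = tuple(sorted(head[:t] + (head[t] + last,) + head[t + 1 :]))
        total -= _dps_cached(powers, merged)
    return total


def _falling(n: int, r: int) -> float:
    out = 1.0
    for i in range(r):
        out *= n - i
    return out


class PermutationMomentEngine:
    """Exact first three permutation moments of Q = a_pi' G a_pi.

    G is fixed (precompute once per feature/site); per-dosage evaluation
    only needs the power sums of the centered dosage vector, so scanning
    many variants is cheap.
    """

    def __init__(self, G: np.ndarray):
        G = np.asarray(G, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("G must be square")
        self.n = G.shape[0]
        self._weights: dict[int, list[tuple[tuple[int, ...], float, int]]] = {}
        for k in (1, 2, 3):
            edges = [(2 * t, 2 * t + 1) for t in range(k)]
            parts, coarser = _partition_lattice(2 * k)
            free = {p: _free_pattern_sum(G, p, edges) for p in parts}
            strict: dict[tuple, float] = {}
            for p in sorted(parts, key=len):  # coarsest first
                strict[p] = free[p] - sum(strict[q] for q in coarser[parts.index(p)])
            entries = []
            for p in parts:
                if strict[p] != 0.0:
                    sizes = tuple(sorted(len(b) for b in p))
                    entries.append((sizes, strict[p], len(p)))
            self._weights[k] = entries

    def raw_moments(self, a: np.ndarray) -> tuple[float, float, float]:
        """(E[Q], E[Q^2], E[Q^3]) for the centered values of ``a``."""
        a = np.asarray(a, dtype=float)
        if a.shape[0] != self.n:
            raise ValueError("dosage length mismatch")
        a = a - a.mean()
        powers = tuple(float(np.sum(a**k)) for k in range(7))
        out = []
        for k in (1, 2, 3):
            total = 0.0
            for sizes, w, r in self._weights[k]:
                total += w * _dps_cached(powers, sizes) / _falling(self.n, r)
            out.append(total)
        return tuple(out)  # type: ignore[return-value]

    def standardized_moments(self, a: np.ndarray) -> tuple[float, float, float]:
        """(mean, variance, skewness) of Q under permutation."""
        m1, m2, m3 = self.raw_moments(a)
        var = m2 - m1 * m1
        mu3 = m3 - 3 * m1 * m2 + 2 * m1**3
        skew = mu3 / var**1.5 if var > 0 else float("nan")
        return m1, var, skew
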