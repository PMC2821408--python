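"""Functional-annotation enrichment in the style of DAVID keyword clustering.

Per-term over-representation of a query gene list is scored with the
upper-tail hypergeometric test and Benjamini-Hochberg adjusted across terms.
Terms are then grouped by gene-set overlap (a deterministic greedy Jaccard
agglomeration standing in for DAVID's fuzzy kappa heuristic) and each group
receives an enrichment score: the mean of -log10(p) over member terms, i.e.
-log10 of the geometric mean p.  Because the score grows with list size, the
significance cutoff is not a constant but is calibrated by simulation:
random gene lists of the same size define the null score distribution and a
quantile of the per-list maxima is the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_model import TermCatalog


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p: probability of >= k members of a size-K
    term in a size-n draw from a size-N universe."""
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if n > N or K > N:
        raise ValueError(f"margins exceed universe: n={n}, K={K}, N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n, K)={min(n, K)}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass(frozen=True)
class TermTestResult:
    term_id: str
    name: str
    k: int  # overlap with query
    n: int  # query size
    K: int  # term size within the universe
    N: int  # universe size
    p_hyper: float
    p_bh: float
    genes: frozenset[str]  # term members within the universe


def enrich_terms(
    query: Iterable[str],
    universe: Iterable[str],
    catalog: TermCatalog,
) -> list[TermTestResult]:
    """Hypergeometric over-representation of every catalog term in ``query``.

    Term memberships are intersected with the universe; terms that do not
    overlap the query (k = 0) are excluded.  Results are sorted by ascending
    raw p (ties by term id) with BH adjustment across all tested terms.
    """
    query_set = set(query)
    universe_set = set(universe)
    if not query_set or not universe_set:
        raise ValueError("query and universe must be non-empty")
    if not query_set <= universe_set:
        extra = sorted(query_set - universe_set)[:5]
        raise ValueError(f"query gene(s) not in universe: {extra}")
    N, n = len(universe_set), len(query_set)
    tested: list[TermTestResult] = []
    for term in catalog:
        members = term.members & universe_set
        K = len(members)
        k = len(members & query_set)
        if K == 0 or k == 0:
            continue
        p = hypergeometric_test(k, n, K, N)
        tested.append(
            TermTestResult(term.term_id, term.name, k, n, K, N, p, p_bh=1.0, genes=frozenset(members))
        )
    if not tested:
        return []
    adjusted = bh_adjust([t.p_hyper for t in tested])
    tested = [
        TermTestResult(t.term_id, t.name, t.k, t.n, t.K, t.N, t.p_hyper, float(q), t.genes)
        for t, q in zip(tested, adjusted)
    ]
    tested.sort(key=lambda t: (t.p_hyper, t.term_id))
    return tested


def enrichment_score(p_values: Sequence[float]) -> float:
    """Cluster enrichment score: mean of -log10(p) over member terms
    (equivalently -log10 of the geometric mean of the p values)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        raise ValueError("no p values")
    if np.any(arr <= 0):
        raise ValueError("p = 0 is not scoreable; floor p values first")
    if np.any(arr > 1):
        raise ValueError("p values must lie in (0, 1]")
    return float(np.mean(-np.log10(arr)))


@dataclass(frozen=True)
class TermCluster:
    term_ids: tuple[str, ...]
    genes: frozenset[str]
    enrichment_score: float
    p_values: tuple[float, ...]


def cluster_terms(
    results: Sequence[TermTestResult],
    catalog: TermCatalog | None = None,
    jaccard_min: float = 0.5,
) -> list[TermCluster]:
    """Greedy single-pass agglomeration of enriched terms by gene overlap.

    Terms are visited in ascending-p order; a term joins the first existing
    cluster whose gene-set Jaccard similarity with the term is >=
    ``jaccard_min``, else it founds a new cluster.  Deterministic given the
    input order.  ``catalog`` supplies memberships for results lacking them.
    """
    if not results:
        raise ValueError("no term results to cluster")
    if not 0.0 <= jaccard_min <= 1.0:
        raise ValueError("jaccard_min must be in [0, 1]")
    ordered = sorted(results, key=lambda t: (t.p_hyper, t.term_id))
    clusters: list[dict] = []
    for res in ordered:
        genes = res.genes
        if not genes and catalog is not None and res.term_id in catalog:
            genes = catalog[res.term_id].members
        placed = False
        for cl in clusters:
            union = cl["genes"] | genes
            jac = len(cl["genes"] & genes) / len(union) if union else 1.0
            if jac >= jaccard_min:
                cl["term_ids"].append(res.term_id)
                cl["genes"] = union
                cl["ps"].append(res.p_hyper)
                placed = True
                break
        if not placed:
            clusters.append(
                {"term_ids": [res.term_id], "genes": set(genes), "ps": [res.p_hyper]}
            )
    return [
        TermCluster(
            term_ids=tuple(cl["term_ids"]),
            genes=frozenset(cl["genes"]),
            enrichment_score=enrichment_score(cl["ps"]),
            p_values=tuple(cl["ps"]),
        )
        for cl in clusters
    ]


@dataclass(frozen=True)
class ScoreThreshold:
    list_size: int
    n_simulations: int
    quantile: float
    threshold: float
    seed: int


def null_score_threshold(
    catalog: TermCatalog,
    universe: Iterable[str],
    list_size: int,
    n_simulations: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
    jaccard_min: float = 0.5,
) -> ScoreThreshold:
    """Simulation-calibrated minimal enrichment score.

    For each simulation a uniform random gene list of ``list_size`` is drawn
    from the universe, run through enrich_terms -> cluster_terms, and the
    maximum cluster score recorded (0 when no term overlaps).  The threshold
    is the empirical ``quantile`` of these maxima; clusters scoring above it
    on the real list are unlikely under random gene sampling.
    """
    universe_list = sorted(set(universe))
    if list_size > len(universe_list):
        raise ValueError("list_size exceeds universe size")
    if list_size < 1:
        raise ValueError("list_size must be >= 1")
    if n_simulations < 100:
        raise ValueError("n_simulations must be >= 100 for a stable quantile")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    rng = np.random.default_rng(seed)
    universe_arr = np.array(universe_list, dtype=object)
    maxima = np.zeros(n_simulations)
    for i in range(n_simulations):
        sample = rng.choice(universe_arr, size=list_size, replace=False)
        results = enrich_terms(set(sample), universe_list, catalog)
        if results:
            clusters = cluster_terms(results, jaccard_min=jaccard_min)
            maxima[i] = max(c.enrichment_score for c in clusters)
    return ScoreThreshold(
        list_size=list_size,
        n_simulations=n_simulations,
        quantile=quantile,
        threshold=float(np.quantile(maxima, quantile)),
        seed=seed,
    )
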