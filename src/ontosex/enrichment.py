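"""Hypergeometric term enrichment of gene clusters with Bonferroni control.

Each co-expression cluster is compared against the analysed background
(all genes admitted by the expression screen, not the whole genome).
Genes without any annotation are, by default, excluded from both the
cluster size n and the background size N (annotated-universe
convention).  The multiple-testing family is the set of terms tested
within one cluster and one namespace.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from scipy import stats

from ontosex.core_io import AnnotationMap

ENRICH_ALPHA = 0.001


@dataclass
class EnrichmentResult:
    term: str
    k: int  # term genes in cluster
    n: int  # cluster size (annotated)
    K: int  # term genes in background
    N: int  # background size (annotated)
    p_raw: float
    p_adj: float
    enriched: bool


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_cluster(
    cluster: set[str],
    background: set[str],
    ann: AnnotationMap,
    alpha: float = ENRICH_ALPHA,
    include_unannotated: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test for every term present in the cluster.

    Bonferroni-adjusts over the terms tested (within this cluster and
    namespace) and returns results sorted by adjusted p then term id.
    """
    if not cluster <= background:
        raise ValueError("cluster must be a subset of the background")
    if include_unannotated:
        cl, bg = cluster, background
    else:
        annotated = ann.annotated_genes()
        cl = cluster & annotated
        bg = background & annotated
    if not cl:
        warnings.warn("cluster has no annotated genes; no terms tested", stacklevel=2)
        return []
    n, N = len(cl), len(bg)
    cluster_terms = Counter(t for g in cl for t in ann.terms_of(g))
    bg_terms = Counter(t for g in bg for t in ann.terms_of(g))
    m = len(cluster_terms)
    results = []
    for term, k in cluster_terms.items():
        K = bg_terms[term]
        p = hypergeom_upper_tail(k, n, K, N)
        p_adj = min(1.0, m * p)
        results.append(
            EnrichmentResult(term, k, n, K, N, p, p_adj, p_adj <= alpha)
        )
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term))
    return results
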