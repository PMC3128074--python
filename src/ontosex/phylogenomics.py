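"""Orthologue-frequency tests and cross-species sex-bias conservation.

"Unique" genes are those without an identifiable orthologue in the
named comparator genome(s) — any orthology type counts as identifiable.
One-to-one orthologue pairs are used only for the expression-bias
conservation comparison, which contrasts each focal gene's adult-stage
call with the sex-bias class of its comparator partner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats

from ontosex.core_io import FEMALE, MALE, UNBIASED, BiasProfile, OrthologyRecord
from ontosex.diffexpr import percentage

COMPARISONS = ("An:Dm", "An:Ae", "An:Ae:Dm")

CONSERVED_MALE = "conserved_male"
CONSERVED_FEMALE = "conserved_female"
REVERSED = "reversed"
FLY_UNBIASED = "fly_unbiased"
AN_UNBIASED_FLY_BIASED = "an_unbiased_fly_biased"


@dataclass
class OrthoFreqResult:
    label: str
    comparison: str
    n_set: int
    n_unique_set: int
    n_background: int
    n_unique_background: int
    p_raw: float
    p_adj: float


@dataclass
class ConservationCall:
    gene: str
    category: str


def _is_unique(rec: OrthologyRecord, comparison: str) -> bool:
    if comparison == "An:Dm":
        return not rec.has_orth_dm
    if comparison == "An:Ae":
        return not rec.has_orth_ae
    if comparison == "An:Ae:Dm":
        return not rec.has_orth_ae and not rec.has_orth_dm
    raise ValueError(f"unknown comparison {comparison!r}")


def unique_fraction(
    gene_set: set[str],
    orth: list[OrthologyRecord],
    comparison: str,
) -> tuple[int, float]:
    """Count and fraction of genes lacking an orthologue in the comparison."""
    by_gene = {r.gene: r for r in orth}
    missing = sorted(gene_set - by_gene.keys())
    if missing:
        raise KeyError(f"gene {missing[0]!r} absent from the orthology table")
    count = sum(1 for g in gene_set if _is_unique(by_gene[g], comparison))
    return count, count / len(gene_set) if gene_set else 0.0


def ortho_enrichment_test(
    gene_set: set[str],
    background: set[str],
    orth: list[OrthologyRecord],
    comparison: str,
    label: str = "",
    family_size: int = 1,
    two_tailed: bool = True,
    mid_p: bool = True,
) -> OrthoFreqResult:
    """Hypergeometric test of unique-gene over/under-representation.

    Two-tailed by default: twice the smaller of the upper and lower
    hypergeometric tails, capped at 1.  With ``mid_p`` (the default)
    each tail carries only half the observed point's probability mass —
    the mid-P convention — which keeps null p-values uniform despite the
    discreteness of the statistic; ``mid_p=False`` gives the plain
    (conservative) tails.  ``family_size`` is the number of
    (set x comparison) tests in the invocation, used for Bonferroni.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    x, _ = unique_fraction(gene_set, orth, comparison)
    K, _ = unique_fraction(background, orth, comparison)
    N, n = len(background), len(gene_set)
    if mid_p:
        pmf = float(stats.hypergeom.pmf(x, N, K, n))
        upper = float(stats.hypergeom.sf(x, N, K, n)) + 0.5 * pmf
        lower = float(stats.hypergeom.cdf(x - 1, N, K, n)) + 0.5 * pmf
    else:
        upper = float(stats.hypergeom.sf(x - 1, N, K, n))
        lower = float(stats.hypergeom.cdf(x, N, K, n))
    p = min(1.0, 2.0 * min(upper, lower)) if two_tailed else upper
    return OrthoFreqResult(
        label=label,
        comparison=comparison,
        n_set=n,
        n_unique_set=x,
        n_background=N,
        n_unique_background=K,
        p_raw=p,
        p_adj=min(1.0, family_size * p),
    )


_CATEGORY = {
    (MALE, MALE): CONSERVED_MALE,
    (FEMALE, FEMALE): CONSERVED_FEMALE,
    (MALE, FEMALE): REVERSED,
    (FEMALE, MALE): REVERSED,
    (MALE, UNBIASED): FLY_UNBIASED,
    (FEMALE, UNBIASED): FLY_UNBIASED,
    (UNBIASED, MALE): AN_UNBIASED_FLY_BIASED,
    (UNBIASED, FEMALE): AN_UNBIASED_FLY_BIASED,
}


def cross_species_conservation(
    profiles: list[BiasProfile],
    orth: list[OrthologyRecord],
    fly: dict[str, str],
    stage: str = "A",
) -> tuple[list[ConservationCall], dict[str, dict[str, float]]]:
    """Classify adult-stage bias conservation against one-to-one partners.

    Only genes with a one-to-one comparator partner and a comparator
    bias entry are classified.  An unbiased x unbiased pair has no
    category and is skipped.  The summary gives, per focal bias class
    (male / female / unbiased), the percentage (nearest integer) of
    each conservation category together with the class size ``n``.
    """
    calls: list[ConservationCall] = []
    per_class: dict[str, dict[str, int]] = {
        MALE: {}, FEMALE: {}, UNBIASED: {},
    }
    class_n = {MALE: 0, FEMALE: 0, UNBIASED: 0}
    partner = {r.gene: r.one2one_dm for r in orth if r.one2one_dm}
    for p in profiles:
        fly_gene = partner.get(p.gene)
        if fly_gene is None:
            continue
        an_call = p.call.get(stage)
        if an_call not in (MALE, FEMALE, UNBIASED):
            continue
        if fly_gene not in fly:
            warnings.warn(
                f"no comparator bias entry for {fly_gene!r}; gene {p.gene!r} skipped",
                stacklevel=2,
            )
            continue
        class_n[an_call] += 1
        category = _CATEGORY.get((an_call, fly[fly_gene]))
        if category is None:
            continue  # unbiased in both species
        calls.append(ConservationCall(p.gene, category))
        per_class[an_call][category] = per_class[an_call].get(category, 0) + 1

    summary: dict[str, dict[str, float]] = {}
    for cls, counts in per_class.items():
        n = class_n[cls]
        summary[cls] = {"n": float(n)}
        for cat, k in sorted(counts.items()):
            summary[cls][cat] = percentage(k, n, decimals=0) if n else float("nan")
    return calls, summary
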