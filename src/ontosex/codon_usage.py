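"""Codon-usage-bias statistics: sequence QC, ENC, optimal codons, Fop.

The effective number of codons (ENC) measures how far a gene's
synonymous codon usage departs from uniform: 61 means all synonyms used
equally, 20 means exactly one codon per amino acid.  Per amino-acid
family with k synonyms and n >= 2 observed codons, the codon
homozygosity is estimated as

    F_hat = (n * sum(p_i^2) - 1) / (n - 1)

and family means F_bar_k are taken per degeneracy class k in {2,3,4,6}
over families with F_hat defined and positive, giving

    ENC = 2 + 9/F_bar_2 + 1/F_bar_3 + 5/F_bar_4 + 3/F_bar_6

(the class weights 9/1/5/3 are the family counts of the standard
nuclear code, with the three 6-fold families Leu/Ser/Arg kept whole).
A missing 3-fold mean is imputed as the average of the 2- and 4-fold
means; if the 2- or 4-fold class is missing the gene's ENC is missing.
The result is capped at 61.

Fop is the fraction of codons, among amino acids with >= 2 synonyms,
that are the dataset-inferred optimal codon for their amino acid.
Optimal codons are inferred by contrasting pooled codon usage of the
most-biased (lowest-ENC) against the least-biased (highest-ENC) decile
of genes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from ontosex.core_io import CdsRecord

MIN_CODONS = 50

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon -> single-letter amino acid over the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)

#: amino acid -> tuple of synonymous codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)

#: amino acids with a single codon (excluded from Fop and optimal sets)
SINGLE_CODON_AA: frozenset[str] = frozenset(
    aa for aa, codons in FAMILIES.items() if len(codons) == 1
)
#: number of codons belonging to degenerate (>= 2 synonym) families
N_DEGENERATE_CODONS = sum(
    len(c) for aa, c in FAMILIES.items() if aa not in SINGLE_CODON_AA
)

#: degeneracy-class weights of the standard code: 9 two-fold families,
#: 1 three-fold (Ile), 5 four-fold, 3 six-fold (Leu, Ser, Arg)
CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class QcVerdict:
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class CodonCounts:
    """Sense-codon counts for one gene (stop codons excluded)."""

    gene: str
    counts: Counter
    total: int


@dataclass
class OptimalCodonSet:
    """One designated optimal codon per multi-synonym amino acid.

    ``weak`` holds amino acids whose codon was chosen by the frequency
    fallback because no candidate reached significance.
    """

    codons: dict[str, str]
    weak: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for aa, codon in self.codons.items():
            if aa in SINGLE_CODON_AA:
                raise ValueError(f"single-codon amino acid {aa} cannot have an optimal codon")
            if CODON_TO_AA.get(codon) != aa:
                raise ValueError(f"{codon} does not encode {aa}")

    def is_optimal(self, codon: str) -> bool:
        aa = CODON_TO_AA.get(codon)
        return aa is not None and self.codons.get(aa) == codon


# ---------------------------------------------------------------------------
# QC and counting
# ---------------------------------------------------------------------------


def qc_cds(record: CdsRecord, transcripts_of_gene: list[CdsRecord] | None = None) -> QcVerdict:
    """Sequence quality control for codon-usage analysis.

    Pass requires: strict {A,C,G,T} alphabet, ATG start, length a
    multiple of three, no internal stop codon (a terminal stop is
    allowed), and being the longest transcript of its gene (ties broken
    by lexicographically smallest transcript id).
    """
    reasons = []
    seq = record.sequence
    if not record.alphabet_ok or not set(seq) <= set("ACGT"):
        reasons.append("non-ACGT characters")
    if not seq.startswith("ATG"):
        reasons.append("no ATG start codon")
    if len(seq) % 3 != 0:
        reasons.append("length not a multiple of three")
    else:
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if any(c in STOP_CODONS for c in codons[:-1]):
            reasons.append("internal stop codon")
    if transcripts_of_gene:
        ranked = sorted(transcripts_of_gene, key=lambda r: (-r.length, r.transcript))
        if ranked[0].transcript != record.transcript:
            reasons.append("not the longest transcript")
    return QcVerdict(passed=not reasons, reasons=reasons)


def select_longest_transcripts(records: list[CdsRecord]) -> list[CdsRecord]:
    """One record per gene: the longest transcript, ties by smallest id."""
    by_gene: dict[str, list[CdsRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    return [
        sorted(rs, key=lambda r: (-r.length, r.transcript))[0]
        for rs in by_gene.values()
    ]


def count_codons(record: CdsRecord) -> CodonCounts:
    """In-frame sense-codon counts; a terminal stop codon is dropped."""
    seq = record.sequence
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts = Counter(c for c in codons if c in CODON_TO_AA)
    return CodonCounts(record.gene, counts, sum(counts.values()))


# ---------------------------------------------------------------------------
# ENC
# ---------------------------------------------------------------------------


def family_homozygosity(counts: Counter, codons: tuple[str, ...]) -> float:
    """Wright's F_hat for one family; NaN if fewer than 2 codons observed."""
    n = sum(counts[c] for c in codons)
    if n < 2:
        return float("nan")
    p2 = sum((counts[c] / n) ** 2 for c in codons)
    return (n * p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCounts, min_codons: int = MIN_CODONS) -> float:
    """Effective number of codons in [20, 61]; NaN below ``min_codons``."""
    if counts.total < min_codons:
        return float("nan")
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in FAMILIES.items():
        k = len(codons)
        if k == 1:
            continue
        f = family_homozygosity(counts.counts, codons)
        if not np.isnan(f) and f > 0:
            class_f[k].append(f)
    fbar = {k: (np.mean(v) if v else np.nan) for k, v in class_f.items()}
    if np.isnan(fbar[2]) or np.isnan(fbar[4]):
        return float("nan")
    if np.isnan(fbar[3]):
        fbar[3] = 0.5 * (fbar[2] + fbar[4])
    if np.isnan(fbar[6]):
        fbar[6] = 0.5 * (fbar[2] + fbar[4])
    value = 2.0 + sum(CLASS_WEIGHTS[k] / fbar[k] for k in (2, 3, 4, 6))
    return min(value, 61.0)


# ---------------------------------------------------------------------------
# Optimal codons and Fop
# ---------------------------------------------------------------------------


def determine_optimal_codons(
    all_stats: list[tuple[CodonCounts, float]],
    decile: float = 0.1,
    alpha: float = 0.05,
) -> OptimalCodonSet:
    """Infer the optimal codon per amino acid from an ENC decile contrast.

    Genes are ranked by ENC; codon counts of the lowest-ENC decile
    (high bias) and the highest-ENC decile (low bias) are pooled.  A
    codon is a candidate if its within-family relative usage is higher
    in the high-bias pool and a two-proportion chi-square test is
    significant after Bonferroni correction over the 59 codons of
    multi-synonym families.  The optimal codon is the candidate with
    the largest usage increase; with no candidate, the most frequent
    codon of the high-bias pool is used and the amino acid flagged weak.
    """
    usable = [(c, e) for c, e in all_stats if not np.isnan(e)]
    if len(usable) < 100:
        raise ValueError("at least 100 genes with an ENC value are required")
    usable.sort(key=lambda ce: ce[1])
    n_dec = max(1, int(round(decile * len(usable))))
    hi_pool: Counter = Counter()
    lo_pool: Counter = Counter()
    for c, _ in usable[:n_dec]:
        hi_pool.update(c.counts)
    for c, _ in usable[-n_dec:]:
        lo_pool.update(c.counts)

    optimal: dict[str, str] = {}
    weak: set[str] = set()
    for aa, codons in FAMILIES.items():
        if aa in SINGLE_CODON_AA:
            continue
        fam_hi = sum(hi_pool[c] for c in codons)
        fam_lo = sum(lo_pool[c] for c in codons)
        if fam_hi == 0 or fam_lo == 0:
            continue  # amino acid unobserved in one pool
        best_codon = None
        best_delta = 0.0
        for codon in codons:
            p_hi = hi_pool[codon] / fam_hi
            p_lo = lo_pool[codon] / fam_lo
            if p_hi <= p_lo:
                continue
            table = np.array(
                [
                    [hi_pool[codon], fam_hi - hi_pool[codon]],
                    [lo_pool[codon], fam_lo - lo_pool[codon]],
                ]
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
            if min(1.0, N_DEGENERATE_CODONS * p) <= alpha and p_hi - p_lo > best_delta:
                best_codon = codon
                best_delta = p_hi - p_lo
        if best_codon is None:
            best_codon = max(codons, key=lambda c: (hi_pool[c], c))
            weak.add(aa)
        optimal[aa] = best_codon
    return OptimalCodonSet(optimal, frozenset(weak))


def fop(
    counts: CodonCounts,
    optimal: OptimalCodonSet,
    min_codons: int = MIN_CODONS,
) -> float:
    """Frequency of optimal codons among multi-synonym family codons.

    Met, Trp and stop codons are excluded from the denominator; NaN
    below the minimum codon count or with an empty denominator.
    """
    if counts.total < min_codons:
        return float("nan")
    denom = sum(
        n for c, n in counts.counts.items()
        if CODON_TO_AA[c] not in SINGLE_CODON_AA
    )
    if denom == 0:
        return float("nan")
    num = sum(n for c, n in counts.counts.items() if optimal.is_optimal(c))
    return num / denom


# ---------------------------------------------------------------------------
# Distribution comparisons
# ---------------------------------------------------------------------------


def ks_compare(subset_values, reference_values) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test with asymptotic p-value."""
    a = np.asarray(subset_values, dtype=float)
    b = np.asarray(reference_values, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("both samples must have at least 5 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bias_vs_expression_corr(fop_values, bias_ratios) -> tuple[float, float]:
    """Spearman correlation between per-gene Fop and |log2| bias ratio.

    Returns (NaN, NaN) when either vector is constant (rank correlation
    undefined); requires at least 10 paired genes.
    """
    a = np.asarray(fop_values, dtype=float)
    b = np.asarray(bias_ratios, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must be paired (equal length)")
    if a.size < 10:
        raise ValueError("at least 10 paired genes required")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
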