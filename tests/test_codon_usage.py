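import itertools
import math
from collections import Counter

import numpy as np
import pytest

from ontosex import codon_usage as cu
from ontosex.core_io import CdsRecord
from ontosex.synthetic_data import CdsSimSpec, gen_cds


def rec(seq, gene="g", transcript="t"):
    return CdsRecord(gene, transcript, seq)


class TestQc:
    def test_clean_minimal_cds_passes(self):
        assert cu.qc_cds(rec("ATGAAATAA")).passed

    def test_internal_stop_fails(self):
        v = cu.qc_cds(rec("ATGTAAAAATAA"))
        assert not v.passed and "internal stop codon" in v.reasons

    def test_length_not_multiple_of_three_fails(self):
        v = cu.qc_cds(rec("ATGAAAA"))
        assert not v.passed and "length not a multiple of three" in v.reasons

    def test_missing_start_and_bad_alphabet_fail(self):
        assert "no ATG start codon" in cu.qc_cds(rec("TTGAAATAA")).reasons
        assert "non-ACGT characters" in cu.qc_cds(
            CdsRecord("g", "t", "ATGNNNTAA", alphabet_ok=False)
        ).reasons

    def test_only_longest_transcript_passes(self):
        short = rec("ATGAAATAA", transcript="t1")
        long_ = rec("ATGAAAAAATAA", transcript="t2")
        assert not cu.qc_cds(short, [short, long_]).passed
        assert cu.qc_cds(long_, [short, long_]).passed

    def test_length_tie_broken_by_smallest_transcript_id(self):
        a = rec("ATGAAATAA", transcript="tA")
        b = rec("ATGAAGTAA", transcript="tB")
        assert cu.qc_cds(a, [a, b]).passed
        assert not cu.qc_cds(b, [a, b]).passed
        assert cu.select_longest_transcripts([a, b]) == [a]


class TestCountCodons:
    def test_terminal_stop_dropped(self):
        counts = cu.count_codons(rec("ATGAAATAA"))
        assert counts.counts == Counter({"ATG": 1, "AAA": 1}) and counts.total == 2

    def test_no_stop_sequence(self):
        assert cu.count_codons(rec("ATGATG")).counts == Counter({"ATG": 2})

    def test_concatenation_additivity(self):
        s1, s2 = "ATGAAACCC", "GGGTTTCTG"
        c1 = cu.count_codons(rec(s1)).counts
        c2 = cu.count_codons(rec(s2)).counts
        c12 = cu.count_codons(rec(s1 + s2)).counts
        assert c12 == c1 + c2


class TestEnc:
    def test_complete_bias_gives_exactly_20(self):
        # one codon per amino-acid family, every family observed n >= 2
        counts = Counter({codons[0]: 3 for codons in cu.FAMILIES.values()})
        cc = cu.CodonCounts("g", counts, sum(counts.values()))
        assert cu.enc(cc, min_codons=10) == pytest.approx(20.0)

    def test_family_homozygosity_hand_example(self):
        # counts (3,1): F = (4 * 0.625 - 1) / 3 = 0.5
        assert cu.family_homozygosity(Counter({"TTT": 3, "TTC": 1}),
                                      ("TTT", "TTC")) == pytest.approx(0.5)

    def test_uniform_usage_approaches_61(self):
        recs, _ = gen_cds(CdsSimSpec(n_genes=1, beta=0.0, length_low=10000,
                                     length_high=10000, seed=3))
        value = cu.enc(cu.count_codons(recs[0]))
        assert abs(value - 61.0) <= 0.5

    def test_below_min_codons_is_missing(self):
        cc = cu.count_codons(rec("ATGAAATAA"))
        assert math.isnan(cu.enc(cc, min_codons=50))

    def test_bounded_on_random_genes(self):
        recs, _ = gen_cds(CdsSimSpec(n_genes=30, beta=1.0, seed=8))
        for r in recs:
            v = cu.enc(cu.count_codons(r))
            assert 20.0 <= v <= 61.0


class TestOptimalCodonsAndFop:
    def test_generated_designations_recovered(self):
        betas = [2.0] * 100 + [0.1] * 100
        recs, truth = gen_cds(CdsSimSpec(n_genes=200, beta=betas, seed=5))
        stats = []
        for r in recs:
            c = cu.count_codons(r)
            stats.append((c, cu.enc(c)))
        optimal = cu.determine_optimal_codons(stats)
        agree = sum(optimal.codons.get(aa) == c for aa, c in truth["designated"].items())
        assert agree == len(truth["designated"])

    def test_uniform_dataset_returns_weak_fallbacks(self):
        recs, _ = gen_cds(CdsSimSpec(n_genes=150, beta=0.0, seed=6))
        stats = []
        for r in recs:
            c = cu.count_codons(r)
            stats.append((c, cu.enc(c)))
        optimal = cu.determine_optimal_codons(stats)
        # no planted signal: most amino acids should need the fallback
        assert len(optimal.weak) >= len(optimal.codons) // 2

    def test_single_codon_amino_acids_never_in_set(self):
        recs, _ = gen_cds(CdsSimSpec(n_genes=150, beta=1.0, seed=7))
        stats = []
        for r in recs:
            c = cu.count_codons(r)
            stats.append((c, cu.enc(c)))
        optimal = cu.determine_optimal_codons(stats)
        assert not set(optimal.codons) & cu.SINGLE_CODON_AA

    def test_fop_all_optimal_is_one_and_none_is_zero(self):
        optimal = cu.OptimalCodonSet({"K": "AAA", "F": "TTT"})
        counts = cu.CodonCounts("g", Counter({"AAA": 5, "TTT": 5}), 10)
        assert cu.fop(counts, optimal, min_codons=5) == 1.0
        counts0 = cu.CodonCounts("g", Counter({"AAG": 5, "TTC": 5}), 10)
        assert cu.fop(counts0, optimal, min_codons=5) == 0.0

    def test_fop_excludes_single_codon_amino_acids(self):
        # 7 optimal of 8 degenerate-family codons; 2 Met codons excluded
        optimal = cu.OptimalCodonSet({"K": "AAA"})
        counts = cu.CodonCounts(
            "g", Counter({"AAA": 7, "AAG": 1, "ATG": 2}), 10
        )
        assert cu.fop(counts, optimal, min_codons=5) == pytest.approx(7 / 8)

    def test_fop_decreases_when_optimal_swapped_out(self):
        optimal = cu.OptimalCodonSet({"K": "AAA"})
        c1 = cu.CodonCounts("g", Counter({"AAA": 6, "AAG": 4}), 10)
        c2 = cu.CodonCounts("g", Counter({"AAA": 5, "AAG": 5}), 10)
        assert cu.fop(c2, optimal, 5) < cu.fop(c1, optimal, 5)


def brute_force_ks_d(a, b):
    """Oracle: maximum ECDF difference over the pooled sample points."""
    points = sorted(set(a) | set(b))
    d = 0.0
    for x in points:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        d = max(d, abs(fa - fb))
    return d


class TestKsCompare:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        d, p = cu.ks_compare(x, x)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = cu.ks_compare(list(range(10)), [v + 100.0 for v in range(10)])
        assert d == 1.0

    def test_matches_ecdf_oracle_on_small_samples(self):
        rng = np.random.default_rng(9)
        for na, nb in itertools.product(range(5, 9), repeat=2):
            for _ in range(5):
                a = list(np.round(rng.normal(0, 1, na), 2))
                b = list(np.round(rng.normal(0.5, 1, nb), 2))
                d, _ = cu.ks_compare(a, b)
                assert d == pytest.approx(brute_force_ks_d(a, b), abs=1e-12)

    def test_power_against_planted_shift(self):
        rng = np.random.default_rng(10)
        rejections = 0
        for _ in range(20):
            a = rng.normal(0, 1, 200)
            b = rng.normal(1, 1, 200)
            _, p = cu.ks_compare(a, b)
            rejections += p < 0.001
        assert rejections == 20

    def test_undersized_sample_rejected(self):
        with pytest.raises(ValueError):
            cu.ks_compare([1.0, 2.0], [1.0, 2.0, 3.0, 4.0, 5.0])


class TestBiasExpressionCorrelation:
    def test_monotone_decreasing_is_minus_one(self):
        x = np.linspace(0, 1, 20)
        rho, _ = cu.bias_vs_expression_corr(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_independent_pairs_are_weakly_correlated(self):
        rng = np.random.default_rng(11)
        small = 0
        for _ in range(20):
            rho, _ = cu.bias_vs_expression_corr(rng.random(500), rng.random(500))
            small += abs(rho) < 0.12
        assert small >= 19

    def test_constant_fop_is_degenerate(self):
        rho, p = cu.bias_vs_expression_corr([0.5] * 10, list(range(10)))
        assert math.isnan(rho) and math.isnan(p)


def test_monotone_generative_check():
    """Stronger synthetic codon bias lowers mean ENC and raises mean Fop."""
    mean_enc, mean_fop = [], []
    for beta in (0.0, 1.0, 2.5):
        recs, truth = gen_cds(CdsSimSpec(n_genes=60, beta=beta, seed=12))
        optimal = cu.OptimalCodonSet(truth["designated"])
        encs, fops = [], []
        for r in recs:
            c = cu.count_codons(r)
            encs.append(cu.enc(c))
            fops.append(cu.fop(c, optimal))
        mean_enc.append(np.nanmean(encs))
        mean_fop.append(np.nanmean(fops))
    assert mean_enc[0] > mean_enc[1] > mean_enc[2]
    assert mean_fop[0] < mean_fop[1] < mean_fop[2]
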